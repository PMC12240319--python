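# faers-dili

Disproportionality signal mining for **statin-associated drug-induced liver
injury (DILI)** in FAERS-style spontaneous-report data.

The FDA Adverse Event Reporting System (FAERS) publishes quarterly
"$"-delimited ASCII tables of demographics (DEMO), reported drugs (DRUG),
MedDRA-coded reactions (REAC), outcomes (OUTC) and therapy dates (THER).
This package is a reproducible pipeline for the standard pharmacovigilance
workflow on such data, specialized to the eight WHO-ATC statins
(atorvastatin, cerivastatin, fluvastatin, lovastatin, pitavastatin,
pravastatin, rosuvastatin, simvastatin):

1. **Ingest** — header-driven, validating readers for the five tables,
   including FAERS's 4/6/8-digit partial dates and age-unit conversion.
2. **Dedup** — one record per case (CASEID), keeping the version with the
   latest FDA receipt date, ties broken by the higher PRIMARYID.
3. **Drug mapping** — raw name strings (brands, salt forms) standardized to
   generic statins via a curated, user-extensible dictionary; exposure
   restricted to the *primary suspected* (PS) role.
4. **DILI cohort** — a case is DILI when any of its Preferred Terms belongs
   to the hepatic narrow-scope SMQ (code 20000007); one DILI record per case
   regardless of how many PTs matched; cases whose therapy started after the
   event date are excluded.
5. **Signals** — per-drug 2×2 tables against all other loaded reports, with
   the reporting odds ratio `ROR = (a/b)/(c/d)` (Woolf 95% CI) and the
   information component `IC = log2(aN / ((a+b)(a+c)))` (Norén or Gamma
   credibility bounds). A drug is signal-positive only when **both** rules
   fire: `n ≥ 3` and `ROR₀₂.₅ > 1`; `IC > 1` and `IC₀₂.₅ > 0`. Age-stratified
   variants (<65 / ≥65 years) restrict target and comparator to the stratum.
6. **Descriptives** — demographic/outcome frequency tables with chi-square
   comparisons, the atorvastatin daily-dose trend, annual report counts, and
   per-drug time-to-onset medians/IQRs with one-way ANOVA plus pairwise
   Welch tests.

A first-class **synthetic-data generator** emits complete five-table
databases with planted drug–DILI odds, duplicate report versions, brand-name
variants and partial dates, together with a truth ledger of the exact
realized 2×2 cells — so the whole pipeline is testable end-to-end without
downloading anything.

## Worked example

Run the pipeline on a 20,000-case synthetic database (half statin cases,
half comparator, planted RORs following the published per-drug values):

```python
from faers_dili import RunConfig, SyntheticConfig, run_pipeline

cfg = RunConfig(synthetic=SyntheticConfig(seed=42, n_cases=20000),
                output_dir="example_out", seed=42)
res = run_pipeline(cfg)
sig = res.tables["signals"]
print(sig[sig.stratum == "overall"].round(2).to_string(index=False))
```

which prints

```
        drug   a    b  ror  ror_l  ror_u   ic  ic_l  signal
atorvastatin 252 4744 1.93   1.64   2.27 0.63  0.42   False
cerivastatin   0    5  NaN    NaN    NaN  NaN   NaN   False
 fluvastatin  12   79 4.56   2.47   8.41 2.01  1.03    True
  lovastatin   6   82 2.18   0.95   5.00 1.06 -0.35   False
pitavastatin   0   94  NaN    NaN    NaN  NaN   NaN   False
 pravastatin  14  333 1.25   0.73   2.14 0.30 -0.60   False
rosuvastatin  91 2396 1.14   0.91   1.43 0.16 -0.19   False
 simvastatin  88 1740 1.57   1.25   1.98 0.56  0.20   False
```

`a`/`b` are the drug's DILI and non-DILI case counts; `ror`/`ror_l`/`ror_u`
the reporting odds ratio with its Woolf 95% CI against all other loaded
cases; `ic`/`ic_l` the information component and its lower credibility
bound. Here only fluvastatin — the drug with the strongest planted
association — clears both rules at this scale; cerivastatin and
pitavastatin drew no DILI cases, so their estimates are undefined and fail
the ≥3-case gate. Note that with a synthetic extract in which half the
universe is statin-exposed, estimates are shrunk toward 1 relative to the
planted values: the comparator itself carries elevated DILI odds, as the
pipeline warns when no background cases are loaded at all.

The same run writes `signals.csv`, `demographics.csv`, `outcomes.csv`,
`onset.csv`, `annual_counts.csv`, `dose_trend.csv` and `run_metadata.json`
(config hash, seed, attrition counts) to the output directory; reruns are
byte-identical.

The CLI mirrors the library:

```sh
faers-dili synth -o db/               # synthetic database + truth ledger
faers-dili signals db/ --drug fluvastatin
faers-dili run -c config.yaml         # full pipeline from a YAML config
faers-dili validate-printed           # recompute published reference values
```

## Layout

```
src/faers_dili/
  faers_io.py      table readers/writers, partial dates, regions
  dedup.py         FDA case-version deduplication rule
  drug_map.py      name → generic statin dictionary mapping
  cohort.py        SMQ classification, temporal exclusion, case assembly
  disprop.py       2×2 tables, ROR, IC, dual signal rule, strata
  descriptives.py  frequency tables, chi-square, dose trend, onset
  synth.py         synthetic five-table generator + truth ledger
  pipeline.py      orchestration, config, printed-value validation
  cli.py           command-line interface
  data/            statin dictionary, SMQ term list (synthetic stand-in),
                   country→region table, published reference values
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
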