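# Methods

## Study design

The pipeline implements a retrospective disproportionality analysis of
spontaneous adverse-event reports: among cases whose primary-suspect (PS)
drug is one of the eight ATC statins, drug-induced liver injury (DILI)
reports are identified and each statin's reporting is compared with the
rest of the loaded database. Disproportionality statistics quantify
*reporting* association only; they establish neither causality nor
incidence, and all the usual spontaneous-report caveats (under-reporting,
stimulated reporting, confounding by indication) apply.

## Case processing

**Deduplication.** FAERS distributes multiple versions of the same case
(one CASEID, several PRIMARYIDs). One record per case is retained: the
version with the latest FDA_DT, ties broken by the numerically higher
PRIMARYID. FDA_DT may be reported at year, month or day precision; within
a case group all dates are truncated to the group's coarsest reported
precision before comparison (missing dates sort lowest). This makes the
survivor the maximum of a per-group total order, so the result is
independent of input order; groups with mixed precision are listed in the
dedup report. PRIMARYIDs are compared numerically when all parse as
integers, otherwise lexicographically after left-zero-padding. Rows of the
DRUG/REAC/OUTC/THER tables belonging to removed versions are dropped in
the same pass.

**Drug standardization.** Raw names are uppercased, whitespace-collapsed
and stripped of trailing salt/hydrate tokens, then looked up in a curated
dictionary (CSV asset: raw_name, generic, atc_code). Lookup is exact-key
only — no substring or fuzzy matching — so every mapping is auditable;
unmapped PS names are counted. Exposure requires the PS role. A case with
several distinct PS statins is kept as a set: it counts once per statin in
per-drug tables and once in overall tallies.

**DILI classification.** A case is DILI when the intersection of its
normalized Preferred Terms with the narrow-scope hepatic SMQ term set
(code 20000007) is non-empty; it contributes exactly one DILI case however
many terms matched. PT matching is case- and whitespace-insensitive exact
string comparison. The packaged term list is a clearly-labelled *synthetic
stand-in* of 144 plausible hepatic PTs: the authoritative SMQ list is
MedDRA-licensed and must be substituted by license holders (plain text,
one PT per line); every downstream number depends on this choice when run
on real data.

**Temporal exclusion.** Cases whose earliest therapy start date is
strictly later than the event date are excluded (a liver event predating
the suspect drug cannot be drug-induced). Dates are compared at their
coarsest common precision; ties and missing dates never exclude — a
deliberately conservative reading of "later than". The earliest start date
prefers THER rows linked to the PS statin's drug_seq and falls back to any
THER row of the case.

**Universe and comparator.** All retained cases — statin-exposed or not —
form the analysis universe. For each target drug, a = target & DILI,
b = target & other, and the comparator (c, d) is every other loaded case.
When the loaded extract contains no non-statin cases the pipeline warns
that RORs are relative to the statin universe only, which shrinks
estimates toward 1 because other statins also carry elevated DILI odds.

## Disproportionality statistics

**ROR.** `(a/b)/(c/d)` with the Woolf log-scale interval
`exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d))`, no continuity correction. Any
zero cell yields an undefined marker rather than a corrected estimate; the
≥3-case gate of the signal rule then fails. An optional +0.5 correction
exists for exploratory use.

**IC.** `log2(a·N/((a+b)(a+c)))`, the plain observed/expected log-ratio
without the +0.5 shrinkage of the classical BCPNN point estimate
(shrinkage is available behind a flag). Credibility bounds are
configurable, because no single published closed form is canonical:

* `noren` (default): asymmetric series approximation,
  lower `IC − 3.3(a+0.5)^-1/2 − 2.0(a+0.5)^-3/2`,
  upper `IC + 2.4(a+0.5)^-1/2 − 0.5(a+0.5)^-3/2`;
* `gamma`: analytic 2.5/97.5 percentiles of
  `log2(Gamma(a+0.5, 1)/(E+0.5))`.

Both are approximations; the method used is recorded in every output row.

**Dual signal rule.** `ror_signal = (a ≥ 3 and ROR₀₂.₅ > 1)`;
`ic_signal = (IC > 1 and IC₀₂.₅ > 0)`; `signal` requires both. Undefined
quantities fail closed. No multiple-testing correction is applied across
drugs (the conventional practice for hypothesis-generating signal scans).

**Age stratification.** Strata are `<65` and `≥65` years (the boundary age
65.0 is elderly); unknown-age cases are excluded from both strata but stay
in the overall analysis. Both the target and the comparator are restricted
to the stratum.

**Recovering the unprinted background.** Published tables print per-drug
(a, b, ROR, IC) but not the comparator cells. Each printed row implies
`q_i = (a_i/b_i)/ROR_i`; the estimator minimizes the sum of squared
relative errors of the implied RORs, which has the closed form
`q = Σq_i²/Σq_i`. Fitting the four highest-count drugs and predicting the
remaining rows reproduces every printed ROR within ~0.5% and every IC
within ~0.01 bits — which also validates the two formula choices above
(in particular, the *unshrunk* IC: the smallest printed row, a = 6 with
drug total 32, is reproduced only without the +0.5 terms). Woolf bounds
for printed rows are evaluated against a comparator of d = 10⁸ preserving
q, where the 1/c + 1/d terms are negligible.

## Descriptive analyses

Percentages use half-up rounding to two decimals against the stated group
denominators. One outcome per case is tabulated, chosen by severity
priority (death > life-threatening > hospitalization > disability >
congenital anomaly > required intervention > other); cases with no OUTC
row appear as Unknown. Reporter occupation codes {MD, PH, HP, OT} roll up
to health professional, {CN, LW} to non-health professional, anything else
unknown. Countries map to seven regions via a shipped ISO-3166 table.
Group comparisons use the Pearson chi-square without continuity
correction, with all-zero rows/columns dropped and a hard error on zero
expected counts.

**Ages.** Reported (value, unit) pairs convert to years (DEC×10, YR×1,
MON÷12, WK÷52.1775, DY÷365.25, HR÷8766); results outside [0, 120] years —
unit typos are common in raw extracts — and unrecognized units are treated
as unknown.

**Dose trend.** Atorvastatin DILI cases are grouped by daily dose
(10/20/40/80 mg; amount × frequency multiplier when the unit is mg, blank
frequency read as once daily, everything else excluded and counted). Since
the input is a single outcome group, the monotone trend is tested as a
multinomial linear-trend z-score on rank scores (exactly 0 for flat
counts), reported alongside the equal-frequency heterogeneity chi-square —
not the binary-outcome Cochran–Armitage test, which would need the
non-DILI denominators per dose.

**Time to onset.** Days from earliest therapy start to event, defined only
when both dates have day precision and the difference is non-negative;
excluded cases are counted. Quantiles use the linear-interpolation
convention (type 7) — published IQRs cannot disambiguate the convention,
so it is fixed and documented. Drugs are compared by one-way ANOVA (the
conventional choice for this analysis despite log-normal skew; a
Kruskal–Wallis alternative is available) plus uncorrected pairwise Welch
tests, flagged at p < 0.05.

## Synthetic data generator

Each case draws: a PS drug from configurable shares (statins plus a
"background" comparator bucket); a DILI flag with odds
`ROR_drug × p0/(1−p0)` (optionally stratum-specific); demographics from
categorical mixes; an event date uniform over the year range; a log-normal
latency (therapy start = event − latency, so the temporal rule never fires
by construction and the truth ledger stays exact); a reporting delay to
FDA_DT; a daily dose from per-drug weight tables; and an outcome category.
DILI cases receive an SMQ Preferred Term (sometimes two, exercising the
one-record-per-case rule); non-DILI cases draw from a disjoint non-hepatic
pool. Statin names appear as brand/salt variants at a configurable rate;
concomitant and secondary-suspect rows exercise the PS restriction.

Duplicates: selected cases emit an extra earlier report version with an
earlier FDA_DT and a lower PRIMARYID, carrying a non-hepatic reaction so a
wrong survivor visibly corrupts downstream counts. A *hostile* mode
alternates two adversarial constructions — same FDA_DT with a lower id
(the tie-break must decide) and earlier FDA_DT with a *higher* id (the
date must override the id).

The truth ledger records every per-case assignment, the duplicate map and
the realized per-drug 2×2 cells; ledger cells equal the pipeline's
contingency cells exactly, which is the end-to-end oracle used in testing.

Defaults mirror the published statin case mix: drug shares proportional to
the published per-drug totals (statins as half of the loaded universe),
planted RORs equal to the published values, background DILI proportion
0.01695 (the recovered comparator proportion), demographic mixes from the
published characteristics table, per-drug log-normal latency medians from
the published onset table, 10% duplicates, 30% brand variants, 15% date
degradation. `paper_scale_config()` packages these at n = 50,000 — chosen
as a desk-scale size at which the headline orderings (atorvastatin's DILI
case share, fluvastatin's top ROR) are stable while a full run takes
seconds.

What passing synthetic tests does **not** show about real data: the
generator plants clean conditional independence (DILI depends only on the
PS drug), exact dictionary-listed name variants, and honest dates; it does
not model reporting biases (Weber effect, stimulated reporting), secular
trends, free-text name noise, or correlated missingness, so real-data
estimates can be biased in ways these tests cannot detect.

## Numerical and degenerate-input choices

* Undefined statistics are NaN markers, never exceptions; signal rules
  fail closed on them.
* Zero cells: no Haldane correction by default (optional flag).
* An empty SMQ term set, a missing mandatory column, or a PRIMARYID shared
  across CASEIDs are hard errors; malformed rows are rejected and counted,
  never fatal.
* Determinism: a single integer seed drives generation; rerunning any
  pipeline with the same config and seed produces byte-identical CSVs.
* Age-stratum labels use ASCII `<65` / `>=65` in all outputs.

## Known limitations

* The packaged SMQ list is synthetic; real-data runs require the licensed
  MedDRA term list.
* Exact-match drug mapping will miss misspelled or compounded names that
  an NLP normalizer would catch; unmapped names are reported, not guessed.
* The comparator is the loaded universe, not all of FAERS, unless a full
  extract is loaded.
* IC credibility bounds are approximations; printed bounds from other
  sources may follow yet another convention, so decision-rule checks on
  published tables feed the printed bounds directly.
* Multi-PS-statin cases make per-drug counts sum to slightly more than
  the case total; this is documented behavior, not double counting within
  one drug.
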