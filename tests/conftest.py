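import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dictionary():
    from faers_dili.drug_map import load_drug_dictionary
    return load_drug_dictionary()


@pytest.fixture(scope="session")
def smq():
    from faers_dili.cohort import load_smq_terms
    return load_smq_terms()


def demo_frame(rows):
    """Build a validated DEMO frame from (primaryid, caseid, fda_dt) triples."""
    from faers_dili.faers_io import read_table
    lines = ["primaryid$caseid$fda_dt"]
    lines += [f"{p}${c}${f}" for p, c, f in rows]
    frame, report = read_table(lines, "DEMO")
    assert report.n_rejected == 0
    return frame


@pytest.fixture(scope="session")
def small_database():
    """A tiny handcrafted five-table database with known composition.

    Four cases: two statin cases (one DILI, one not), one background DILI
    case, one background non-DILI case.
    """
    from faers_dili.faers_io import read_table
    demo, _ = read_table([
        "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod$reporter_country",
        "11$1$20200105$20200101$70$YR$F$MD$US",
        "21$2$20210301$20210208$50$YR$M$CN$FR",
        "31$3$20190601$$$$F$$JP",
        "41$4$20220801$20220701$80$YR$$$",
    ], "DEMO")
    drug, _ = read_table([
        "primaryid$drug_seq$role_cod$drugname$dose_amt$dose_unit$dose_freq",
        "11$1$PS$LIPITOR$20$MG$QD",
        "21$1$PS$Simvastatin$40$MG$QD",
        "21$2$C$ASPIRIN$$$",
        "31$1$PS$METFORMIN$$$",
        "41$1$PS$OMEPRAZOLE$$$",
    ], "DRUG")
    reac, _ = read_table([
        "primaryid$pt",
        "11$Hepatitis",
        "11$Nausea",
        "21$Myalgia",
        "31$Liver injury",
        "41$Headache",
    ], "REAC")
    outc, _ = read_table([
        "primaryid$outc_cod",
        "11$HO",
        "11$DE",
        "21$OT",
        "31$HO",
    ], "OUTC")
    ther, _ = read_table([
        "primaryid$dsg_drug_seq$start_dt",
        "11$1$20191201",
        "21$1$20210101",
        "31$1$20190101",
    ], "THER")
    return {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc,
            "THER": ther}


@pytest.fixture(scope="session")
def small_cohort(small_database, dictionary, smq):
    from faers_dili.cohort import assemble_cohort
    t = small_database
    return assemble_cohort(t["DEMO"], t["DRUG"], t["REAC"], t["OUTC"],
                           t["THER"], dictionary, smq)
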