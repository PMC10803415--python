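import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def demo_frame(rows):
    """DEMO frame from (primaryid, caseid, fda_dt, sex, age, age_cod, country) tuples."""
    cols = ["primaryid", "caseid", "fda_dt", "sex", "age", "age_cod", "occr_country"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])] if rows else cols)
    for c in cols:
        if c not in df.columns:
            df[c] = pd.NA
    df = df.astype("string")
    df["fda_dt_valid"] = pd.to_datetime(df["fda_dt"], format="%Y%m%d", errors="coerce").notna()
    return df


def drug_frame(rows):
    """DRUG frame from (primaryid, drug_seq, role_cod, drugname[, prod_ai]) tuples."""
    cols = ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    for c in cols:
        if c not in df.columns:
            df[c] = pd.NA
    return df.astype("string")


def reac_frame(rows):
    return pd.DataFrame(rows, columns=["primaryid", "pt"]).astype("string")


def outc_frame(rows):
    return pd.DataFrame(rows, columns=["primaryid", "outc_cod"]).astype("string")


@pytest.fixture(scope="session")
def pt_soc():
    from faerspv import load_pt_soc_map

    return load_pt_soc_map()


@pytest.fixture(scope="session")
def drug_dict():
    from faerspv import default_drug_dictionary

    return default_drug_dictionary()


@pytest.fixture(scope="session")
def policy():
    from faerspv import default_exclusion_policy

    return default_exclusion_policy()


@pytest.fixture(scope="session")
def small_corpus():
    """One mid-sized synthetic corpus with two planted signals, shared by tests."""
    from faerspv.synthetic import SyntheticConfig, generate

    cfg = SyntheticConfig(
        n_cases=8000,
        seed=7,
        planted_signals=(
            ("erenumab", "Constipation", 10.0),
            ("galcanezumab", "Injection site pain", 6.0),
        ),
    )
    return generate(cfg)
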