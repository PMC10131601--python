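import numpy as np
import pandas as pd
import pytest

from claimsdid.config import SimConfig


def make_members(rows: list[dict]) -> pd.DataFrame:
    """Build a member table from sparse dicts, filling sensible defaults."""
    defaults = {
        "age": 40,
        "sex": "female",
        "race": "white",
        "location": "urban",
        "plan_type": "fully_insured",
        "pharmacy_data_available": True,
        "comm_receptivity": True,
        "care_management": False,
        "member_advocacy": False,
        "chronic_count": 0,
        "risk_score": 1.0,
        "enrolled": False,
        "enroll_month": pd.NA,
        "eligibility_start": 0,
        "eligibility_end": 29,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"member_id": f"M{i:04d}", **defaults, **row}
        out.append(rec)
    if not out:
        df = pd.DataFrame(columns=["member_id", *defaults])
    else:
        df = pd.DataFrame(out)
    df["enroll_month"] = df["enroll_month"].astype("Int64")
    return df


CLAIM_COLS = [
    "member_id", "month", "category", "amount_cents",
    "nonimpactable", "pregnancy_related", "ed_diag_code",
]


def make_claims(rows: list[tuple]) -> pd.DataFrame:
    """Claims from (member_id, month, category, usd[, nonimp, preg, code])."""
    if not rows:
        df = pd.DataFrame(columns=CLAIM_COLS)
        return df.astype({"month": int, "amount_cents": int,
                          "nonimpactable": bool, "pregnancy_related": bool})
    out = []
    for row in rows:
        mid, month, cat, usd = row[:4]
        nonimp = row[4] if len(row) > 4 else False
        preg = row[5] if len(row) > 5 else False
        code = row[6] if len(row) > 6 else (pd.NA if cat != "ED" else "R07.9")
        out.append(
            {
                "member_id": mid,
                "month": month,
                "category": cat,
                "amount_cents": int(round(usd * 100)),
                "nonimpactable": nonimp,
                "pregnancy_related": preg,
                "ed_diag_code": code,
            }
        )
    return pd.DataFrame(out)[CLAIM_COLS]


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(n_members=800, n_months=24, enroll_window=(12, 16), seed=123)


@pytest.fixture(scope="session")
def midsize_cohort():
    """One cached synthetic cohort with selection bias and a -$10 effect."""
    import claimsdid as cd

    cfg = SimConfig(
        n_members=8000, n_months=24, enroll_window=(12, 16),
        treatment_effect_pupm=-10.0, seed=42,
    )
    members, claims = cd.simulate(cfg)
    return cfg, members, claims
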