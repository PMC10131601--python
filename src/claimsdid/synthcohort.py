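"""Synthetic member rosters and claim lines.

Emulates the statistical structure a retrospective matched cost evaluation
has to cope with: covariate-driven self-selection into the program,
zero-inflated heavy-tailed monthly spend, limited pharmacy-data visibility,
and an injectable post-enlistment treatment effect of known size.  The real
analogue — a national commercial health plan's administrative claims — is
proprietary, so every distributional choice here is a documented stand-in,
not an estimate.

Month indices are 0-based from study start; currency is stored as integer
cents in claim lines and analyzed in USD floats.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    CATEGORIES,
    LOCATION_LEVELS,
    PLAN_LEVELS,
    RACE_LEVELS,
    SEX_LEVELS,
    ConfigError,
    SimConfig,
)

logger = logging.getLogger(__name__)

MEMBER_COLUMNS = [
    "member_id",
    "age",
    "sex",
    "race",
    "location",
    "plan_type",
    "pharmacy_data_available",
    "comm_receptivity",
    "care_management",
    "member_advocacy",
    "chronic_count",
    "risk_score",
    "enrolled",
    "enroll_month",
    "eligibility_start",
    "eligibility_end",
]

CLAIM_COLUMNS = [
    "member_id",
    "month",
    "category",
    "amount_cents",
    "nonimpactable",
    "pregnancy_related",
    "ed_diag_code",
]


def _category_params(config: SimConfig) -> dict[str, tuple[float, float, float, float]]:
    """Per-category (p_zero, log_mean, log_sd, chronic_multiplier), with the
    ED zero-probability derived from the configured annual ED visit rate."""
    params = {}
    for name, cat in config.spend_model.categories.items():
        p0 = cat.p_zero
        if name == "ED":
            p0 = 1.0 - config.ed_rate / 12.0
        params[name] = (p0, cat.log_mean, cat.log_sd, cat.chronic_multiplier)
    return params


def expected_monthly_spend(
    members: pd.DataFrame, config: SimConfig, *, impactable_only: bool = False
) -> np.ndarray:
    """Expected monthly spend in USD for each member under the spend model.

    Sums ``(1-p_zero) * exp(log_mean + log_sd^2/2) * multiplier^chronic_count``
    over the categories the member's data cover (pharmacy categories only
    when pharmacy data are available).  With ``impactable_only`` the total is
    discounted by the probability that a claim line carries an exclusion
    flag, i.e. the portion of spend the analysis actually sees.
    """
    params = _category_params(config)
    cc = members["chronic_count"].to_numpy(dtype=float)
    has_rx = members["pharmacy_data_available"].to_numpy(dtype=bool)
    total = np.zeros(len(members))
    for name in CATEGORIES:
        p0, mu, sigma, mult = params[name]
        e_cat = (1.0 - p0) * np.exp(mu + 0.5 * sigma**2) * np.power(mult, cc)
        if name == "total_rx":
            e_cat = np.where(has_rx, e_cat, 0.0)
        total += e_cat
    if impactable_only:
        sm = config.spend_model
        preg_eligible = (members["sex"].to_numpy() == "female") & (
            members["age"].to_numpy() < 45
        )
        q_preg = np.where(preg_eligible, sm.pregnancy_rate, 0.0)
        total *= (1.0 - sm.nonimpactable_rate) * (1.0 - q_preg)
    return total


def _selection_logit(members: pd.DataFrame, config: SimConfig) -> np.ndarray:
    c = config.selection_coefs
    baseline = expected_monthly_spend(members, config)
    return (
        c.intercept
        + c.age * (members["age"].to_numpy(dtype=float) - 40.0) / 10.0
        + c.sex * (members["sex"].to_numpy() == "female")
        + c.chronic_count * members["chronic_count"].to_numpy(dtype=float)
        + c.baseline_spend * baseline / 100.0
        + c.comm_receptivity * members["comm_receptivity"].to_numpy(dtype=float)
    )


def generate_population(config: SimConfig) -> pd.DataFrame:
    """Draw a member roster with covariate-driven self-selection.

    Enrollment is a Bernoulli draw with probability
    ``sigmoid(selection_coefs · covariates)``; an enrolled member's
    enlistment month is uniform over the part of ``enroll_window`` that
    leaves 12 observable pre months and at least 7 post months within the
    member's eligibility span.  Members whose span cannot accommodate any
    valid enlistment month never enroll.  Deterministic for a fixed seed.
    """
    config.validate()
    d = config.demographics
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_members

    age = np.clip(np.rint(rng.normal(d.age_mean, d.age_sd, n)), 18, 90).astype(int)
    p_male = 1.0 - d.p_female - d.p_nonbinary
    sex = rng.choice(SEX_LEVELS, size=n, p=[p_male, d.p_female, d.p_nonbinary])
    race = rng.choice(RACE_LEVELS, size=n, p=[d.race_probs[r] for r in RACE_LEVELS])
    location = rng.choice(
        LOCATION_LEVELS, size=n, p=[d.location_probs[x] for x in LOCATION_LEVELS]
    )
    plan_type = rng.choice(PLAN_LEVELS, size=n, p=[1 - d.p_self_insured, d.p_self_insured])
    pharmacy = rng.random(n) < d.p_pharmacy_data
    comm = rng.random(n) < d.p_comm_receptive
    care_mgmt = rng.random(n) < d.p_care_management
    advocacy = rng.random(n) < d.p_member_advocacy

    any_chronic = rng.random(n) < d.p_chronic_any
    # Given >=1 condition, the count is shifted-geometric with continuation
    # probability chronic_continue (mean 1/(1-q) conditions).
    extra = rng.geometric(p=1.0 - d.chronic_continue, size=n) - 1
    chronic = np.where(any_chronic, 1 + extra, 0)

    risk_score = np.round(rng.gamma(2.0, 0.4 * (1.0 + 0.5 * chronic)), 4)

    elig_start = np.zeros(n, dtype=int)
    elig_end = np.full(n, config.n_months - 1, dtype=int)
    short = rng.random(n) < d.p_short_eligibility
    # Short spells are censored at a uniform month; these members fail the
    # continuous-eligibility inclusion criterion downstream.
    cut = rng.integers(6, config.n_months - 1, size=n)
    elig_end = np.where(short, cut, elig_end)

    members = pd.DataFrame(
        {
            "member_id": [f"M{i:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "location": location,
            "plan_type": plan_type,
            "pharmacy_data_available": pharmacy,
            "comm_receptivity": comm,
            "care_management": care_mgmt,
            "member_advocacy": advocacy,
            "chronic_count": chronic,
            "risk_score": risk_score,
        }
    )
    members["eligibility_start"] = elig_start
    members["eligibility_end"] = elig_end

    lo = np.maximum(elig_start + 12, config.enroll_window[0])
    hi = np.minimum(elig_end - 7, config.enroll_window[1])
    can_enroll = lo <= hi
    p_enroll = expit(_selection_logit(members, config))
    enrolled = (rng.random(n) < p_enroll) & can_enroll
    # Uniform over each member's feasible enlistment months.
    span = np.where(can_enroll, hi - lo + 1, 1)
    offset = np.floor(rng.random(n) * span).astype(int)
    enroll_month = np.where(enrolled, lo + offset, -1)

    members["enrolled"] = enrolled
    members["enroll_month"] = pd.array(
        np.where(enrolled, enroll_month, np.nan), dtype="Int64"
    )
    logger.info(
        "generated %d members (%d enrolled, %.1f%%)",
        n,
        enrolled.sum(),
        100.0 * enrolled.mean(),
    )
    return members[MEMBER_COLUMNS]


def _treatment_factors(members: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Per-member multiplicative factor applied to impactable post-enlistment
    claim amounts, calibrated so the expected PUPM change equals
    ``treatment_effect_pupm`` exactly."""
    e_imp = expected_monthly_spend(members, config, impactable_only=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 + config.treatment_effect_pupm / np.where(e_imp > 0, e_imp, np.inf)
    if np.any(f < 0):
        logger.warning(
            "treatment_effect_pupm exceeds some members' expected impactable "
            "spend; clipping their post-period factor at 0"
        )
        f = np.maximum(f, 0.0)
    return f


def generate_claims(members: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw monthly claim lines for a roster produced by `generate_population`.

    Per member, month and category, spend is zero-inflated log-normal with a
    chronic-condition multiplier on the log-mean.  Enrolled members' months
    strictly after enlistment receive a multiplicative shift on impactable
    (unflagged) amounts calibrated so the expected monthly change equals
    ``treatment_effect_pupm``.  ED lines carry a diagnosis code sampled from
    the shipped synthetic ED probability table.  Deterministic per seed.
    """
    config.validate()
    bad = members["enroll_month"].notna() & ~members["enrolled"].astype(bool)
    if bad.any():
        raise ValueError(
            "data-consistency error: members with enroll_month but enrolled=False: "
            + ", ".join(members.loc[bad, "member_id"].head(5))
        )
    if (members["enrolled"].astype(bool) & members["enroll_month"].isna()).any():
        raise ValueError("data-consistency error: enrolled members lack enroll_month")

    from .effects import load_ed_table  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(members)
    n_months = config.n_months
    params = _category_params(config)
    sm = config.spend_model

    cc = members["chronic_count"].to_numpy(dtype=float)
    has_rx = members["pharmacy_data_available"].to_numpy(dtype=bool)
    elig_start = members["eligibility_start"].to_numpy()
    elig_end = members["eligibility_end"].to_numpy()
    enrolled = members["enrolled"].to_numpy(dtype=bool)
    enroll_month = members["enroll_month"].fillna(-1).to_numpy(dtype=int)
    preg_eligible = (members["sex"].to_numpy() == "female") & (
        members["age"].to_numpy() < 45
    )
    factors = _treatment_factors(members, config)
    member_ids = members["member_id"].to_numpy()

    month_grid = np.arange(n_months)
    observable = (month_grid[None, :] >= elig_start[:, None]) & (
        month_grid[None, :] <= elig_end[:, None]
    )
    is_post = enrolled[:, None] & (month_grid[None, :] > enroll_month[:, None])

    if sm.effect_weights is not None:
        e_imp_cat = {}
        for name in CATEGORIES:
            p0, mu, sigma, mult = params[name]
            e = (1.0 - p0) * np.exp(mu + 0.5 * sigma**2) * np.power(mult, cc)
            if name == "total_rx":
                e = np.where(has_rx, e, 0.0)
            e_imp_cat[name] = e * (1.0 - sm.nonimpactable_rate) * (
                1.0 - np.where(preg_eligible, sm.pregnancy_rate, 0.0)
            )

    ed_table = load_ed_table()
    ed_codes = ed_table["diag_code"].to_numpy()
    ed_freq = ed_table["frequency"].to_numpy(dtype=float)
    ed_freq = ed_freq / ed_freq.sum()

    frames = []
    for name in CATEGORIES:
        p0, mu, sigma, mult = params[name]
        occurs = (rng.random((n, n_months)) >= p0) & observable
        if name == "total_rx":
            occurs &= has_rx[:, None]
        midx, month = np.nonzero(occurs)
        k = len(midx)
        if k == 0:
            continue
        log_amount = rng.normal(mu + cc[midx] * np.log(mult), sigma)
        amount = np.exp(log_amount)
        nonimp = rng.random(k) < sm.nonimpactable_rate
        preg = (rng.random(k) < sm.pregnancy_rate) & preg_eligible[midx]
        post = is_post[midx, month] & ~nonimp & ~preg
        if sm.effect_weights is not None:
            w = sm.effect_weights.get(name, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_cat = 1.0 + config.treatment_effect_pupm * w / np.where(
                    e_imp_cat[name] > 0, e_imp_cat[name], np.inf
                )
            f_cat = np.maximum(f_cat, 0.0)
            amount = np.where(post, amount * f_cat[midx], amount)
        else:
            amount = np.where(post, amount * factors[midx], amount)
        frame = pd.DataFrame(
            {
                "member_id": member_ids[midx],
                "month": month,
                "category": name,
                "amount_cents": np.rint(amount * 100).astype(np.int64),
                "nonimpactable": nonimp,
                "pregnancy_related": preg,
            }
        )
        if name == "ED":
            frame["ed_diag_code"] = rng.choice(ed_codes, size=k, p=ed_freq)
        else:
            frame["ed_diag_code"] = pd.NA
        frames.append(frame)

    if not frames:
        claims = pd.DataFrame(columns=CLAIM_COLUMNS)
        claims = claims.astype({"month": int, "amount_cents": np.int64})
        return claims
    claims = pd.concat(frames, ignore_index=True)
    claims = claims.sort_values(
        ["member_id", "month", "category"], kind="stable", ignore_index=True
    )
    logger.info("generated %d claim lines", len(claims))
    return claims[CLAIM_COLUMNS]


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (members, claims) pair from one config."""
    members = generate_population(config)
    claims = generate_claims(members, config)
    return members, claims


# -- delimited-file round trip ---------------------------------------------


def write_members(members: pd.DataFrame, path: str | Path) -> None:
    members.to_csv(path, index=False)


def write_claims(claims: pd.DataFrame, path: str | Path) -> None:
    claims.to_csv(path, index=False)


def read_members(path: str | Path) -> pd.DataFrame:
    members = pd.read_csv(
        path,
        dtype={
            "member_id": str,
            "pharmacy_data_available": bool,
            "comm_receptivity": bool,
            "care_management": bool,
            "member_advocacy": bool,
            "enrolled": bool,
        },
    )
    members["enroll_month"] = members["enroll_month"].astype("Int64")
    return members[MEMBER_COLUMNS]


def read_claims(path: str | Path) -> pd.DataFrame:
    claims = pd.read_csv(
        path,
        dtype={
            "member_id": str,
            "month": int,
            "category": str,
            "amount_cents": np.int64,
            "nonimpactable": bool,
            "pregnancy_related": bool,
            "ed_diag_code": "string",
        },
    )
    return claims[CLAIM_COLUMNS]
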