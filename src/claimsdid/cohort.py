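"""Eligibility filtering and 12-month anchored covariate features.

The feature window for a member anchored at month ``a`` is the 12 whole
months ``[a-12, a-1]``; the anchor (enlistment) month itself belongs to
neither the pre nor the post period, because spend in that month mixes
exposed and unexposed time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MEDICAL_CATEGORIES

logger = logging.getLogger(__name__)

PRE_WINDOW_MONTHS = 12
MIN_POST_MONTHS = 7
MAX_POST_MONTHS = 12

FEATURE_COLUMNS = [
    "member_id",
    "anchor_month",
    "age",
    "sex",
    "plan_type",
    "pharmacy_data_available",
    "comm_receptivity",
    "location",
    "care_management",
    "member_advocacy",
    "chronic_count",
    "risk_score",
    "inpatient_visits_12m",
    "ed_visits_12m",
    "diag_code_count_12m",
    "procedure_count_12m",
    "pre_medical_pupm",
    "pre_pharmacy_pupm",
]


class PreWindowError(ValueError):
    """A member lacks the 12 observable months required before an anchor."""


@dataclass
class ClaimsIndex:
    """Cumulative per-member-month aggregates for O(1) window sums.

    ``cs_*`` arrays have shape ``(n_members, n_months + 1)`` where column
    ``k`` holds the sum over months ``< k``; a 12-month window ending just
    before anchor ``a`` is ``cs[:, a] - cs[:, a - 12]``.
    """

    member_pos: pd.Series  # member_id -> row
    n_months: int
    cs_medical_usd: np.ndarray
    cs_pharmacy_usd: np.ndarray
    cs_inpatient_lines: np.ndarray
    cs_ed_lines: np.ndarray
    cs_all_lines: np.ndarray
    ed_claims: pd.DataFrame  # member_id, month, ed_diag_code

    @classmethod
    def build(cls, members: pd.DataFrame, claims: pd.DataFrame, n_months: int) -> "ClaimsIndex":
        n = len(members)
        pos = pd.Series(np.arange(n), index=members["member_id"].to_numpy())
        mi = claims["member_id"].map(pos).to_numpy()
        if np.isnan(mi.astype(float)).any():
            raise ValueError("claims reference member_ids absent from the roster")
        mi = mi.astype(int)
        month = claims["month"].to_numpy(dtype=int)
        usd = claims["amount_cents"].to_numpy(dtype=float) / 100.0
        cat = claims["category"].to_numpy()

        def accum(mask: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
            acc = np.zeros((n, n_months))
            if mask.any():
                w = weights[mask] if weights is not None else 1.0
                np.add.at(acc, (mi[mask], month[mask]), w)
            cs = np.zeros((n, n_months + 1))
            np.cumsum(acc, axis=1, out=cs[:, 1:])
            return cs

        is_med = np.isin(cat, MEDICAL_CATEGORIES)
        ed_mask = cat == "ED"
        ed_claims = claims.loc[ed_mask, ["member_id", "month", "ed_diag_code"]].copy()
        return cls(
            member_pos=pos,
            n_months=n_months,
            cs_medical_usd=accum(is_med, usd),
            cs_pharmacy_usd=accum(~is_med, usd),
            cs_inpatient_lines=accum(cat == "inpatient"),
            cs_ed_lines=accum(ed_mask),
            cs_all_lines=accum(np.ones(len(claims), dtype=bool)),
            ed_claims=ed_claims,
        )

    def window_sum(self, array: np.ndarray, rows: np.ndarray, anchors: np.ndarray) -> np.ndarray:
        return array[rows, anchors] - array[rows, anchors - PRE_WINDOW_MONTHS]


def filter_eligible(
    members: pd.DataFrame,
    claims: pd.DataFrame,
    study_start: int,
    study_end: int,
    *,
    return_reasons: bool = False,
):
    """Apply the study inclusion rules.

    Keeps members who are adults (age >= 18, inclusive), continuously
    eligible over ``[study_start, study_end]``, and — for enrolled members —
    enlisted at a month leaving 12 observable pre months and at least 7
    observable post months.  Non-enrolled members pass the same window test
    for at least one candidate anchor, which continuous eligibility over the
    study period guarantees.  Exclusion reasons are logged per member.
    """
    if len(members) == 0:
        logger.warning("filter_eligible received an empty member table")
        empty = members.iloc[0:0]
        return (empty, pd.DataFrame(columns=["member_id", "reason"])) if return_reasons else empty

    reasons = pd.Series("", index=members.index, dtype=object)
    adult = members["age"] >= 18
    reasons[~adult] = "age_under_18"
    continuous = (members["eligibility_start"] <= study_start) & (
        members["eligibility_end"] >= study_end
    )
    reasons[adult & ~continuous] = "not_continuously_eligible"

    enroll = members["enroll_month"]
    enrolled = members["enrolled"].astype(bool)
    pre_ok = ~enrolled | (enroll >= study_start + PRE_WINDOW_MONTHS).fillna(False)
    post_ok = ~enrolled | (enroll <= study_end - MIN_POST_MONTHS).fillna(False)
    reasons[adult & continuous & ~pre_ok] = "insufficient_pre_window"
    reasons[adult & continuous & pre_ok & ~post_ok] = "insufficient_post_window"

    keep = adult & continuous & pre_ok & post_ok
    excluded = members.loc[~keep, "member_id"]
    for mid, why in zip(excluded, reasons[~keep]):
        logger.debug("excluding member %s: %s", mid, why)
    logger.info(
        "eligibility filter: kept %d of %d members (%d excluded)",
        int(keep.sum()),
        len(members),
        int((~keep).sum()),
    )
    result = members.loc[keep].reset_index(drop=True)
    if return_reasons:
        reason_df = pd.DataFrame(
            {"member_id": excluded.to_numpy(), "reason": reasons[~keep].to_numpy()}
        )
        return result, reason_df
    return result


def build_feature_table(
    members: pd.DataFrame,
    index: ClaimsIndex,
    anchors: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Batch feature construction: one row per member at its anchor month.

    Counts and PUPM values cover exactly the 12 months strictly before the
    anchor.  ``pre_pharmacy_pupm`` is NaN when the member has no pharmacy
    data-sharing agreement.  Raises `PreWindowError` if any member lacks 12
    observable months before its anchor.
    """
    anchors = np.asarray(anchors, dtype=int)
    if len(anchors) != len(members):
        raise ValueError("anchors must align with members")
    rows = members["member_id"].map(index.member_pos).to_numpy(dtype=int)

    start_ok = members["eligibility_start"].to_numpy() <= anchors - PRE_WINDOW_MONTHS
    in_range = (anchors >= PRE_WINDOW_MONTHS) & (anchors <= index.n_months)
    bad = ~(start_ok & in_range)
    if bad.any():
        i = int(np.argmax(bad))
        raise PreWindowError(
            f"member {members['member_id'].iloc[i]} lacks a 12-month pre window "
            f"before anchor {int(anchors[i])}"
        )

    med = index.window_sum(index.cs_medical_usd, rows, anchors)
    rx = index.window_sum(index.cs_pharmacy_usd, rows, anchors)
    inpat = index.window_sum(index.cs_inpatient_lines, rows, anchors)
    ed = index.window_sum(index.cs_ed_lines, rows, anchors)
    lines = index.window_sum(index.cs_all_lines, rows, anchors)

    # Distinct ED diagnosis codes inside each member's window; ED lines are
    # sparse so a pandas pass over them is cheap.
    diag = np.zeros(len(members))
    if len(index.ed_claims):
        anchor_by_id = pd.Series(anchors, index=members["member_id"].to_numpy())
        edc = index.ed_claims[index.ed_claims["member_id"].isin(anchor_by_id.index)]
        if len(edc):
            a = edc["member_id"].map(anchor_by_id).to_numpy()
            in_win = (edc["month"].to_numpy() >= a - PRE_WINDOW_MONTHS) & (
                edc["month"].to_numpy() < a
            )
            edw = edc.loc[in_win]
            if len(edw):
                counts = edw.groupby("member_id")["ed_diag_code"].nunique()
                idx = pd.Index(members["member_id"])
                diag = counts.reindex(idx).fillna(0).to_numpy(dtype=float)

    has_rx = members["pharmacy_data_available"].to_numpy(dtype=bool)
    features = pd.DataFrame(
        {
            "member_id": members["member_id"].to_numpy(),
            "anchor_month": anchors,
            "age": members["age"].to_numpy(),
            "sex": members["sex"].to_numpy(),
            "plan_type": members["plan_type"].to_numpy(),
            "pharmacy_data_available": has_rx,
            "comm_receptivity": members["comm_receptivity"].to_numpy(dtype=bool),
            "location": members["location"].to_numpy(),
            "care_management": members["care_management"].to_numpy(dtype=bool),
            "member_advocacy": members["member_advocacy"].to_numpy(dtype=bool),
            "chronic_count": members["chronic_count"].to_numpy(),
            "risk_score": members["risk_score"].to_numpy(dtype=float),
            "inpatient_visits_12m": inpat.astype(int),
            "ed_visits_12m": ed.astype(int),
            "diag_code_count_12m": diag.astype(int),
            "procedure_count_12m": lines.astype(int),
            "pre_medical_pupm": med / PRE_WINDOW_MONTHS,
            "pre_pharmacy_pupm": np.where(has_rx, rx / PRE_WINDOW_MONTHS, np.nan),
        }
    )
    return features[FEATURE_COLUMNS]


def build_features(
    member: pd.Series | pd.DataFrame,
    claims_or_index: pd.DataFrame | ClaimsIndex,
    anchor_month: int,
    *,
    n_months: int | None = None,
) -> pd.Series:
    """Single-member convenience wrapper around `build_feature_table`."""
    if isinstance(member, pd.Series):
        member = member.to_frame().T
    member = member.reset_index(drop=True)
    if isinstance(claims_or_index, ClaimsIndex):
        index = claims_or_index
    else:
        if n_months is None:
            hi = int(claims_or_index["month"].max()) + 1 if len(claims_or_index) else 0
            n_months = max(hi, anchor_month + 1)
        index = ClaimsIndex.build(member, claims_or_index[
            claims_or_index["member_id"].isin(member["member_id"])
        ], n_months)
    table = build_feature_table(member, index, np.array([anchor_month]))
    return table.iloc[0]


def monthly_comparison_features(
    pool: pd.DataFrame,
    index: ClaimsIndex,
    month: int,
) -> pd.DataFrame:
    """Feature vectors for the still-unmatched comparison pool at one anchor.

    Emits one row per pool member whose eligibility span covers 12 months
    before and at least 7 months after the candidate anchor; others are
    silently omitted (they can never be valid comparisons at this month).
    """
    ok = (pool["eligibility_start"] <= month - PRE_WINDOW_MONTHS) & (
        pool["eligibility_end"] >= month + MIN_POST_MONTHS
    )
    eligible = pool.loc[ok]
    if len(eligible) == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return build_feature_table(
        eligible.reset_index(drop=True), index, np.full(len(eligible), month)
    )
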