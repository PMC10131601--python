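"""Claim-line filtering, percentile capping, and pre/post PUPM summaries.

Spend flagged non-impactable or pregnancy-related is excluded before any
aggregation.  Period totals (pre and post separately) are winsorized at the
nearest-rank 99th percentile of the pooled matched population, so both
groups face a single cap.  PUPM divides a period total by the number of
observed months in the period — months with zero spend count in the
denominator.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .config import CATEGORIES, MEDICAL_CATEGORIES
from .cohort import MAX_POST_MONTHS, MIN_POST_MONTHS, PRE_WINDOW_MONTHS

logger = logging.getLogger(__name__)

SUMMARY_BASE_COLUMNS = [
    "member_id",
    "group",
    "anchor_month",
    "pre_months",
    "post_months",
    "pre_pupm",
    "post_pupm",
    "change",
]


def filter_claims(claims: pd.DataFrame) -> pd.DataFrame:
    """Drop claim lines flagged non-impactable or pregnancy-related.

    A line carrying both flags is removed (and counted) once.
    """
    flagged = claims["nonimpactable"].astype(bool) | claims["pregnancy_related"].astype(bool)
    removed = int(flagged.sum())
    logger.info(
        "claim filter: removed %d of %d lines (%d nonimpactable, %d pregnancy-related)",
        removed,
        len(claims),
        int(claims["nonimpactable"].astype(bool).sum()),
        int(claims["pregnancy_related"].astype(bool).sum()),
    )
    return claims.loc[~flagged].reset_index(drop=True)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """The ceil(p/100 * n)-th order statistic of ``values``."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("cannot take a percentile of an empty vector")
    k = math.ceil(percentile / 100.0 * len(v))
    return float(v[max(k, 1) - 1])


def cap_spending(
    period_totals: pd.Series, percentile: float = 99.0
) -> tuple[pd.Series, float]:
    """Winsorize period totals at the pooled nearest-rank percentile.

    Returns the capped series and the cap value.  Capping only ever reduces
    totals, alters at most ``ceil((1 - p/100) * n)`` members, and is
    idempotent.
    """
    if len(period_totals) == 0:
        raise ValueError("cap_spending requires at least one member")
    cap = nearest_rank_percentile(period_totals.to_numpy(), percentile)
    capped = period_totals.clip(upper=cap)
    n_capped = int((period_totals > cap).sum())
    logger.info(
        "capped %d of %d period totals at %.2f (p%g)",
        n_capped,
        len(period_totals),
        cap,
        percentile,
    )
    return capped, cap


def compute_pupm(
    claims: pd.DataFrame, member_id: str, window_months: Iterable[int]
) -> float:
    """Average USD per month for one member over an explicit month window.

    ``claims`` should already be filtered; months with no claims count in
    the denominator.
    """
    window = list(window_months)
    if not window:
        raise ValueError("compute_pupm requires a non-empty window")
    mask = (claims["member_id"] == member_id) & claims["month"].isin(window)
    total = claims.loc[mask, "amount_cents"].sum() / 100.0
    return float(total) / len(window)


def _period_masks(
    months: np.ndarray, anchors: np.ndarray, post_months: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    pre = (months >= anchors - PRE_WINDOW_MONTHS) & (months < anchors)
    post = (months > anchors) & (months <= anchors + post_months)
    return pre, post


def summarize_members(
    members: pd.DataFrame,
    claims: pd.DataFrame,
    pairs: pd.DataFrame,
    study_end: int,
    *,
    cap_percentile: float = 99.0,
) -> pd.DataFrame:
    """Pre/post PUPM spend summaries for every matched member.

    Comparison members inherit the matched treated partner's anchor month.
    The post window runs from the month after the anchor for
    ``min(12, study_end - anchor)`` months (at least 7 by construction).
    Capping is applied to pooled pre-period totals and pooled post-period
    totals separately, and a member's per-category totals are rescaled
    proportionally so categories still sum to the capped total.

    ``claims`` must already be exclusion-filtered (see `filter_claims`).
    Returns one row per member with total and per-category PUPM columns
    (``pre_<category>`` / ``post_<category>``).
    """
    if len(pairs) == 0:
        raise ValueError("summarize_members requires at least one matched pair")

    roster = pd.concat(
        [
            pd.DataFrame(
                {
                    "member_id": pairs["treated_id"],
                    "group": "treated",
                    "anchor_month": pairs["anchor_month"],
                }
            ),
            pd.DataFrame(
                {
                    "member_id": pairs["control_id"],
                    "group": "comparison",
                    "anchor_month": pairs["anchor_month"],
                }
            ),
        ],
        ignore_index=True,
    )
    if not roster["member_id"].is_unique:
        raise ValueError("a member appears in more than one matched pair")
    roster["post_months"] = np.minimum(
        MAX_POST_MONTHS, study_end - roster["anchor_month"].to_numpy()
    )
    if (roster["post_months"] < MIN_POST_MONTHS).any():
        raise ValueError("some anchors leave fewer than 7 observable post months")

    # Pharmacy spend only counts for members with a data-sharing agreement.
    has_rx = members.set_index("member_id")["pharmacy_data_available"]
    c = claims[claims["member_id"].isin(roster["member_id"])].copy()
    rx_line = ~c["category"].isin(MEDICAL_CATEGORIES)
    observed = ~rx_line | c["member_id"].map(has_rx).fillna(False).astype(bool)
    c = c.loc[observed]

    info = roster.set_index("member_id")
    anchors = c["member_id"].map(info["anchor_month"]).to_numpy(dtype=float)
    post_m = c["member_id"].map(info["post_months"]).to_numpy(dtype=float)
    months = c["month"].to_numpy(dtype=float)
    pre_mask, post_mask = _period_masks(months, anchors, post_m)

    usd = c["amount_cents"].to_numpy(dtype=float) / 100.0
    out = roster.copy()
    for period, mask in (("pre", pre_mask), ("post", post_mask)):
        sub = pd.DataFrame(
            {
                "member_id": c["member_id"].to_numpy()[mask],
                "category": c["category"].to_numpy()[mask],
                "usd": usd[mask],
            }
        )
        cat_totals = (
            sub.pivot_table(
                index="member_id", columns="category", values="usd", aggfunc="sum"
            )
            .reindex(index=out["member_id"], columns=list(CATEGORIES))
            .fillna(0.0)
        )
        raw_total = cat_totals.sum(axis=1)
        capped_total, cap = cap_spending(
            raw_total.reset_index(drop=True), cap_percentile
        )
        capped_total.index = raw_total.index
        scale = np.where(raw_total > 0, capped_total / raw_total.replace(0, np.nan), 1.0)
        cat_totals = cat_totals.mul(pd.Series(scale, index=cat_totals.index), axis=0)

        n_periods = (
            np.full(len(out), PRE_WINDOW_MONTHS, dtype=float)
            if period == "pre"
            else out["post_months"].to_numpy(dtype=float)
        )
        out[f"{period}_pupm"] = capped_total.to_numpy() / n_periods
        for cat in CATEGORIES:
            out[f"{period}_{cat}"] = cat_totals[cat].to_numpy() / n_periods
        out.attrs[f"{period}_cap"] = cap
        out.attrs[f"{period}_n_capped"] = int((raw_total.to_numpy() > cap).sum())

    out["pre_months"] = PRE_WINDOW_MONTHS
    out["change"] = out["post_pupm"] - out["pre_pupm"]
    cols = SUMMARY_BASE_COLUMNS + [
        f"{p}_{cat}" for p in ("pre", "post") for cat in CATEGORIES
    ]
    return out[cols]


def summarize_member(
    member_id: str,
    members: pd.DataFrame,
    claims: pd.DataFrame,
    pairs: pd.DataFrame,
    study_end: int,
) -> pd.Series:
    """Spend summary for a single matched member."""
    in_pairs = (pairs["treated_id"] == member_id) | (pairs["control_id"] == member_id)
    if not in_pairs.any():
        raise ValueError(f"member {member_id} does not appear in any matched pair")
    summaries = summarize_members(members, claims, pairs.loc[in_pairs], study_end)
    return summaries.set_index("member_id").loc[member_id]
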