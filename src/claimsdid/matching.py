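"""Rolling-entry, segment-stratified 1:1 nearest-neighbor matching.

Treated members are processed month by month in enlistment order.  Within
each month, matching is restricted to exact segments defined by
(self-reported sex, pharmacy data availability, health plan type) and is
greedy nearest-neighbor on the absolute difference of propensity-score
logits, without replacement: a comparison member matched in one month is
permanently removed from the pool for all later months.

Greedy order within a segment is descending treated score (extreme-score
treated members have the thinnest candidate sets, so they pick first),
with ties broken by ascending member id for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort, propensity

logger = logging.getLogger(__name__)

SEGMENT_FIELDS = ("sex", "pharmacy_data_available", "plan_type")
SMD_THRESHOLD = 0.1

PAIR_COLUMNS = ["treated_id", "control_id", "anchor_month", "segment", "distance"]


def segment_key(rows: pd.DataFrame) -> pd.Series:
    """Exact-matching stratum label, a pure function of the three fields."""
    return (
        rows["sex"].astype(str)
        + "|rx="
        + rows["pharmacy_data_available"].astype(bool).astype(str)
        + "|"
        + rows["plan_type"].astype(str)
    )


def greedy_match_segment(
    treated_scores: pd.Series,
    control_scores: pd.Series,
    *,
    caliper: float | None = None,
) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbor matching within one segment.

    ``treated_scores`` / ``control_scores`` are propensity scores indexed by
    member id.  Returns a frame of (treated_id, control_id, distance) where
    distance is the absolute logit difference.  Treated are processed in
    descending score order (ties: ascending id); each takes the nearest
    remaining control, so at most ``min(n_t, n_c)`` pairs result.
    """
    if len(treated_scores) == 0 or len(control_scores) == 0:
        return pd.DataFrame(columns=["treated_id", "control_id", "distance"])

    t = treated_scores.sort_index()
    t = t.iloc[np.argsort(-t.to_numpy(), kind="stable")]
    c = control_scores.sort_index()
    t_logit = propensity.logit(t.to_numpy())
    c_logit = propensity.logit(c.to_numpy())
    c_ids = c.index.to_numpy()
    alive = np.ones(len(c), dtype=bool)

    rows = []
    for tid, lt in zip(t.index.to_numpy(), t_logit):
        if not alive.any():
            break
        dist = np.abs(c_logit - lt)
        dist[~alive] = np.inf
        j = int(np.argmin(dist))  # first minimum = lowest control id on ties
        if caliper is not None and dist[j] > caliper:
            continue
        rows.append((tid, c_ids[j], float(dist[j])))
        alive[j] = False
    return pd.DataFrame(rows, columns=["treated_id", "control_id", "distance"])


@dataclass
class MatchResult:
    pairs: pd.DataFrame
    unmatched_treated: list[str] = field(default_factory=list)
    treated_features: pd.DataFrame | None = None
    control_features: pd.DataFrame | None = None


def iterative_match(
    treated_features: pd.DataFrame,
    pool: pd.DataFrame,
    index: cohort.ClaimsIndex,
    model: propensity.PropensityModel,
    *,
    caliper: float | None = None,
) -> MatchResult:
    """Month-by-month matching with a carried-forward comparison pool.

    ``treated_features`` must carry one row per treated member anchored at
    its enlistment month; ``pool`` is the comparison member roster, disjoint
    from the treated set.  For each anchor month in ascending order the
    still-unmatched pool is re-featurized at that month, scored, and matched
    within segments.  Unmatched treated members are reported, never
    silently dropped.
    """
    treated_ids = set(treated_features["member_id"])
    overlap = treated_ids & set(pool["member_id"])
    if overlap:
        raise ValueError(
            f"treated and comparison sets overlap ({len(overlap)} members, "
            f"e.g. {sorted(overlap)[:3]})"
        )

    t_scores_all = pd.Series(
        propensity.score(model, treated_features),
        index=treated_features["member_id"].to_numpy(),
    )
    t_segments_all = pd.Series(
        segment_key(treated_features).to_numpy(),
        index=treated_features["member_id"].to_numpy(),
    )
    anchor_by_treated = pd.Series(
        treated_features["anchor_month"].to_numpy(),
        index=treated_features["member_id"].to_numpy(),
    )

    current_pool = pool.copy()
    all_pairs: list[pd.DataFrame] = []
    unmatched: list[str] = []
    control_feature_rows: list[pd.DataFrame] = []

    for month in sorted(treated_features["anchor_month"].unique()):
        month_treated = treated_features.loc[treated_features["anchor_month"] == month]
        pool_features = cohort.monthly_comparison_features(current_pool, index, int(month))
        if len(pool_features) == 0:
            unmatched.extend(month_treated["member_id"])
            continue
        c_scores = pd.Series(
            propensity.score(model, pool_features),
            index=pool_features["member_id"].to_numpy(),
        )
        c_segments = pd.Series(
            segment_key(pool_features).to_numpy(),
            index=pool_features["member_id"].to_numpy(),
        )

        matched_controls: list[str] = []
        for seg in sorted(month_treated.pipe(segment_key).unique()):
            t_ids = t_segments_all.index[
                (t_segments_all == seg) & t_segments_all.index.isin(month_treated["member_id"])
            ]
            c_ids = c_segments.index[c_segments == seg]
            seg_pairs = greedy_match_segment(
                t_scores_all.loc[t_ids], c_scores.loc[c_ids], caliper=caliper
            )
            if len(seg_pairs):
                seg_pairs["anchor_month"] = int(month)
                seg_pairs["segment"] = seg
                all_pairs.append(seg_pairs)
                matched_controls.extend(seg_pairs["control_id"])
            unmatched.extend(sorted(set(t_ids) - set(seg_pairs["treated_id"])))

        if matched_controls:
            taken = pool_features["member_id"].isin(matched_controls)
            control_feature_rows.append(pool_features.loc[taken])
            current_pool = current_pool.loc[
                ~current_pool["member_id"].isin(matched_controls)
            ]

    pairs = (
        pd.concat(all_pairs, ignore_index=True)[PAIR_COLUMNS]
        if all_pairs
        else pd.DataFrame(columns=PAIR_COLUMNS)
    )
    # Integrity: 1:1 and no replacement across the whole run.
    assert pairs["treated_id"].is_unique and pairs["control_id"].is_unique
    control_features = (
        pd.concat(control_feature_rows, ignore_index=True)
        if control_feature_rows
        else None
    )
    logger.info(
        "matched %d of %d treated members (%d unmatched)",
        len(pairs),
        len(treated_features),
        len(unmatched),
    )
    if unmatched:
        logger.warning("unmatched treated members: %s...", unmatched[:10])
    # anchor bookkeeping sanity
    if len(pairs):
        assert (pairs["anchor_month"].to_numpy() ==
                anchor_by_treated.loc[pairs["treated_id"]].to_numpy()).all()
    return MatchResult(
        pairs=pairs,
        unmatched_treated=unmatched,
        treated_features=treated_features,
        control_features=control_features,
    )


@dataclass
class BalanceReport:
    table: pd.DataFrame
    passed: bool
    alpha: float
    smd_threshold: float = SMD_THRESHOLD


def compute_balance(
    pairs: pd.DataFrame,
    features: pd.DataFrame,
    alpha: float = 0.05,
) -> BalanceReport:
    """Post-match covariate balance diagnostics.

    ``features`` must contain the feature rows used at match time for every
    treated and control member in ``pairs`` (keyed by member_id and
    anchor_month).  Per encoded feature the report gives group means, the
    standardized mean difference (pooled-SD denominator), and a two-tailed
    unpaired Welch test p-value; the overall flag passes when every
    |SMD| <= 0.1.
    """
    if len(pairs) < 2:
        raise ValueError("balance requires at least 2 matched pairs")
    keyed = features.set_index(["member_id", "anchor_month"])
    t_rows = keyed.loc[list(zip(pairs["treated_id"], pairs["anchor_month"]))]
    c_rows = keyed.loc[list(zip(pairs["control_id"], pairs["anchor_month"]))]
    Xt = propensity.encode_features(t_rows.reset_index())
    Xc = propensity.encode_features(c_rows.reset_index())

    rows = []
    for j, name in enumerate(propensity.FEATURE_SCHEMA):
        xt, xc = Xt[:, j], Xc[:, j]
        mt, mc = float(xt.mean()), float(xc.mean())
        pooled_sd = float(np.sqrt((xt.var(ddof=1) + xc.var(ddof=1)) / 2.0))
        degenerate = False
        if pooled_sd == 0.0:
            smd = 0.0 if mt == mc else np.inf
            degenerate = mt != mc
            p_value = 1.0 if mt == mc else 0.0
        else:
            smd = (mt - mc) / pooled_sd
            p_value = float(stats.ttest_ind(xt, xc, equal_var=False).pvalue)
        rows.append(
            {
                "feature": name,
                "treated_mean": mt,
                "comparison_mean": mc,
                "smd": smd,
                "p_value": p_value,
                "flag_smd": abs(smd) > SMD_THRESHOLD,
                "flag_p": p_value < alpha,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    passed = not table["flag_smd"].any()
    logger.info(
        "balance check: max |SMD| = %.4f, %s",
        table["smd"].abs().replace(np.inf, np.nan).max(),
        "pass" if passed else "FAIL",
    )
    return BalanceReport(table=table, passed=passed, alpha=alpha)
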