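"""Effect estimation: within-group changes, difference-in-differences,
cost-category decomposition, ED emergent/non-emergent splitting, and
annualization.

Sign convention: the headline "savings" estimate is
``mean(change_comparison) - mean(change_treated)`` where ``change`` is
post-minus-pre PUPM spend, so an intervention that lowers treated spending
yields a positive savings number.  Within-group changes use a two-tailed
paired t test (one-sample t on the change scores); between-group contrasts
use the two-tailed unequal-variance (Welch) t test.  Confidence level is
fixed at 95% (alpha = .05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .config import CATEGORIES

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class EffectEstimate:
    """A mean change or between-group difference in USD per user per month."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    n_treated: int
    n_comparison: int
    alpha: float = ALPHA

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "n_treated": self.n_treated,
            "n_comparison": self.n_comparison,
            "alpha": self.alpha,
        }


def _degenerate_estimate(label, est, n_t, n_c) -> EffectEstimate:
    if est == 0.0:
        return EffectEstimate(label, 0.0, 0.0, 0.0, 0.0, 1.0, n_t, n_c)
    t = np.inf if est > 0 else -np.inf
    return EffectEstimate(label, est, est, est, t, 0.0, n_t, n_c)


def within_group_change(summaries: pd.DataFrame, label: str = "change") -> EffectEstimate:
    """Two-tailed paired t test on post-minus-pre PUPM within one group.

    The estimate is the mean change (negative means spending decreased).
    If every change score is identical the t statistic is undefined; by
    convention a uniformly zero change reports estimate 0 with p = 1.
    """
    changes = summaries["change"].to_numpy(dtype=float)
    if len(changes) < 2:
        raise ValueError("within_group_change requires at least 2 members")
    n = len(changes)
    mean = float(changes.mean())
    if changes.std(ddof=1) == 0.0:
        return _degenerate_estimate(label, mean, n, 0)
    res = stats.ttest_1samp(changes, 0.0)
    ci = res.confidence_interval(1.0 - ALPHA)
    return EffectEstimate(
        label, mean, float(ci.low), float(ci.high),
        float(res.statistic), float(res.pvalue), n, 0,
    )


def difference_in_differences(
    treated_summaries: pd.DataFrame,
    comparison_summaries: pd.DataFrame,
    label: str = "overall",
    *,
    treated_changes: np.ndarray | None = None,
    comparison_changes: np.ndarray | None = None,
) -> EffectEstimate:
    """Savings difference-in-differences between matched groups.

    estimate = mean(change_comparison) - mean(change_treated), tested with a
    two-tailed Welch t test on the change scores; the 95% CI is reported on
    the same savings scale.
    """
    ct = (
        treated_changes
        if treated_changes is not None
        else treated_summaries["change"].to_numpy(dtype=float)
    )
    cc = (
        comparison_changes
        if comparison_changes is not None
        else comparison_summaries["change"].to_numpy(dtype=float)
    )
    if len(ct) < 2 or len(cc) < 2:
        raise ValueError("difference_in_differences requires >= 2 members per group")
    est = float(cc.mean() - ct.mean())
    if np.std(ct, ddof=1) == 0.0 and np.std(cc, ddof=1) == 0.0:
        return _degenerate_estimate(label, est, len(ct), len(cc))
    res = stats.ttest_ind(cc, ct, equal_var=False)
    ci = res.confidence_interval(1.0 - ALPHA)
    return EffectEstimate(
        label, est, float(ci.low), float(ci.high),
        float(res.statistic), float(res.pvalue), len(ct), len(cc),
    )


def category_breakdown(
    treated_summaries: pd.DataFrame,
    comparison_summaries: pd.DataFrame,
    categories: tuple[str, ...] | list[str] = CATEGORIES,
) -> pd.DataFrame:
    """One savings DiD row per cost category plus the overall row.

    Category change scores are ``post_<cat> - pre_<cat>`` PUPM.  Without
    capping the category savings sum exactly to the overall savings; with
    capping, per-category totals were rescaled to the capped total so the
    identity still holds to rounding.
    """
    rows = []
    for cat in categories:
        col_pre, col_post = f"pre_{cat}", f"post_{cat}"
        for df in (treated_summaries, comparison_summaries):
            if col_pre not in df.columns or col_post not in df.columns:
                raise ValueError(f"unknown category {cat!r}: no {col_pre}/{col_post} columns")
        ct = (treated_summaries[col_post] - treated_summaries[col_pre]).to_numpy(float)
        cc = (comparison_summaries[col_post] - comparison_summaries[col_pre]).to_numpy(float)
        est = difference_in_differences(
            treated_summaries, comparison_summaries, label=cat,
            treated_changes=ct, comparison_changes=cc,
        )
        rows.append(est.to_dict())
    overall = difference_in_differences(treated_summaries, comparison_summaries, "overall")
    rows.append(overall.to_dict())
    return pd.DataFrame(rows)


# -- ED visit classification ------------------------------------------------


def load_ed_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load an ED diagnosis-probability lookup table.

    Without a path, loads the bundled *synthetic* table, which mimics the
    shape of published probabilistic ED classification weights (each
    diagnosis code maps to probabilities of the visit being emergent,
    non-emergent, or other, summing to 1) but carries no empirical content.
    Users holding real algorithm weights supply them in the same format.
    """
    if path is None:
        src = resources.files("claimsdid.data") / "synthetic_ed_probabilities.csv"
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {"diag_code", "p_emergent", "p_nonemergent", "p_other"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ED table is missing columns {sorted(missing)}")
    probs = table[["p_emergent", "p_nonemergent", "p_other"]].to_numpy(float)
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("ED table probabilities must lie in [0,1]")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("ED table rows must sum to 1")
    if "frequency" not in table.columns:
        table["frequency"] = 1.0
    return table


def classify_ed(
    ed_claims: pd.DataFrame,
    table: pd.DataFrame,
    *,
    unknown: str = "other",
) -> pd.DataFrame:
    """Split each ED claim's cost into emergent / non-emergent / other shares.

    The split is fractional: a $100 visit whose code carries
    (p_emergent=0.3, p_nonemergent=0.7) contributes $30 emergent and $70
    non-emergent.  Codes absent from the table follow the ``unknown``
    policy: ``"other"`` (default) assigns the full cost to the other bucket
    with a logged warning; ``"error"`` raises.
    """
    if unknown not in ("other", "error"):
        raise ValueError("unknown policy must be 'other' or 'error'")
    out = ed_claims.copy()
    lut = table.set_index("diag_code")[["p_emergent", "p_nonemergent", "p_other"]]
    codes = out["ed_diag_code"].astype("string")
    known = codes.isin(lut.index)
    if not known.all():
        n_bad = int((~known).sum())
        if unknown == "error":
            bad = sorted(codes[~known].dropna().unique()[:5])
            raise ValueError(f"unknown ED diagnosis codes: {bad}")
        logger.warning(
            "%d ED claims carry diagnosis codes absent from the table; "
            "assigning their cost to 'other'",
            n_bad,
        )
    p = lut.reindex(codes).to_numpy(dtype=float)
    p[~known.to_numpy()] = [0.0, 0.0, 1.0]
    usd = out["amount_cents"].to_numpy(float) / 100.0
    out["emergent_usd"] = usd * p[:, 0]
    out["nonemergent_usd"] = usd * p[:, 1]
    out["other_usd"] = usd * p[:, 2]
    return out


def ed_split_summaries(
    classified: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Per member-period emergent / non-emergent ED PUPM.

    Adds ``pre_ED_emergent`` etc. columns to a copy of ``summaries`` using
    each member's anchor and post-window length.  The split is computed on
    uncapped ED amounts (a sub-decomposition of the ED category).
    """
    out = summaries.copy()
    info = summaries.set_index("member_id")
    cl = classified[classified["member_id"].isin(info.index)]
    anchors = cl["member_id"].map(info["anchor_month"]).to_numpy(float)
    post_m = cl["member_id"].map(info["post_months"]).to_numpy(float)
    months = cl["month"].to_numpy(float)
    from .cohort import PRE_WINDOW_MONTHS

    pre_mask = (months >= anchors - PRE_WINDOW_MONTHS) & (months < anchors)
    post_mask = (months > anchors) & (months <= anchors + post_m)
    for period, mask in (("pre", pre_mask), ("post", post_mask)):
        denom = (
            float(PRE_WINDOW_MONTHS)
            if period == "pre"
            else out.set_index("member_id")["post_months"].astype(float)
        )
        for bucket in ("emergent", "nonemergent"):
            sums = (
                cl.loc[mask].groupby("member_id")[f"{bucket}_usd"].sum()
                .reindex(info.index)
                .fillna(0.0)
            )
            out[f"{period}_ED_{bucket}"] = (sums / denom).to_numpy()
    return out


def annualize(savings_pupm: float, n_users: int, months: int = 12) -> float:
    """Scale a PUPM savings figure to a population-year total in USD."""
    if savings_pupm < 0 or n_users < 0 or months < 0:
        raise ValueError("annualize expects non-negative inputs")
    return float(savings_pupm) * float(n_users) * float(months)


def subgroup_effect(
    pairs: pd.DataFrame,
    summaries: pd.DataFrame,
    member_predicate: Callable[[pd.DataFrame], pd.Series],
    members: pd.DataFrame | None = None,
    label: str = "subgroup",
) -> EffectEstimate:
    """Difference-in-differences restricted to a treated subgroup.

    ``member_predicate`` maps a member attribute table to a boolean mask.
    The comparison side is restricted to the matched partners of the
    selected treated members, preserving the paired design.  With the
    always-true predicate this reproduces the overall estimate.
    """
    attrs = members if members is not None else summaries
    mask = np.asarray(member_predicate(attrs), dtype=bool)
    selected_ids = set(attrs.loc[mask, "member_id"])
    sub_pairs = pairs[pairs["treated_id"].isin(selected_ids)]
    if len(sub_pairs) < 2:
        raise ValueError("subgroup predicate selects fewer than 2 treated members")
    by_id = summaries.set_index("member_id")
    t = by_id.loc[sub_pairs["treated_id"]].reset_index()
    c = by_id.loc[sub_pairs["control_id"]].reset_index()
    return difference_in_differences(t, c, label=label)


def naive_post_difference(
    treated_post_pupm: np.ndarray | pd.Series,
    pool_post_pupm: np.ndarray | pd.Series,
    label: str = "naive_post_contrast",
) -> EffectEstimate:
    """The unadjusted post-period contrast the matched design exists to fix.

    Compares mean post-period PUPM of treated members against an unmatched
    comparison pool over the same calendar window, on the savings scale
    (pool minus treated).  Under self-selection this estimate absorbs the
    baseline spending gap between enlistees and non-enlistees and is biased
    for the true effect; it is exposed so that bias is measurable.
    """
    t = np.asarray(treated_post_pupm, dtype=float)
    p = np.asarray(pool_post_pupm, dtype=float)
    if len(t) < 2 or len(p) < 2:
        raise ValueError("naive contrast requires >= 2 members per group")
    est = float(p.mean() - t.mean())
    res = stats.ttest_ind(p, t, equal_var=False)
    ci = res.confidence_interval(1.0 - ALPHA)
    return EffectEstimate(
        label, est, float(ci.low), float(ci.high),
        float(res.statistic), float(res.pvalue), len(t), len(p),
    )
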