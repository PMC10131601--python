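# Methods

`claimsdid` implements a retrospective, propensity-score-matched, two-group,
pre/post evaluation of a health-plan intervention's effect on claims
spending, together with a synthetic claims generator that reproduces the
statistical obstacles such evaluations face. This note documents the model,
the estimators, the generator's assumptions, and the numerical choices.

## Design and estimand

Members self-enlist in an intervention at some calendar month (their
*anchor*). For each member the **pre period** is the 12 whole months
strictly before the anchor and the **post period** the 7–12 whole months
strictly after it; the anchor month belongs to neither, because spend in
that month mixes exposed and unexposed time. Spending is summarized as
PUPM (per user per month): period total divided by observed period months,
zero-spend months counting in the denominator.

With Δ = post-PUPM − pre-PUPM per member, the headline estimate is the
difference-in-differences on a savings sign convention:

    savings = mean(Δ_comparison) − mean(Δ_treated)

so an intervention that lowers treated spending yields a positive number.
Within-group changes are tested with two-tailed paired t tests (one-sample
t on Δ); the between-group contrast uses a two-tailed Welch (unequal
variance) t test on the Δ scores, even though matching is 1:1 — the
matched pairs are treated as independent samples, not as pair differences.
Confidence intervals are 95%; significance is p < .05. When every Δ in a
contrast is identical the t statistic is undefined; a uniformly zero
contrast reports estimate 0 with p = 1 by convention.

## Eligibility

Included members are adults (age ≥ 18, inclusive), continuously eligible
over the study window, with 12 observable months before and at least 7
after their anchor. "≥ 7" and "≥ 12" are inclusive bounds. Non-enrolled
members must satisfy the same window test for at least one candidate
anchor, which continuous eligibility guarantees. Exclusions are logged per
member with a reason code.

## Propensity model

Enlistment probability is estimated by an ensemble: the arithmetic mean of
the predicted probabilities of an L2-regularized logistic regression (on
standardized inputs) and a gradient-boosted tree classifier, over a shared
encoded design matrix (numeric features as-is; reference-coded indicators
for sex, location and plan type; booleans as 0/1). Scores are clipped to
[1e−6, 1 − 1e−6] so logits stay finite.

Two numerical choices matter here:

- **Tree regularization.** The boosted learner is deliberately small
  (≤ 7 leaves, 50 rounds, ≥ 200 samples per leaf, L2 = 1). An unregularized
  booster can partially memorize the enrollment labels, at which point its
  score is no longer a balancing score: matched cohorts remain imbalanced
  on the very covariates that drive selection even though score distances
  are tiny. With the regularized defaults, post-match |SMD| on large
  cohorts is well under 0.1.
- **Missing pharmacy spend** (members whose pharmacy benefits manager has
  no data-sharing agreement) is encoded as zero plus an explicit
  missing-indicator column, not imputed — availability is itself an
  exact-matching segment and carries signal.

Treated members contribute training rows anchored at their enlistment
month. Comparison training rows are anchored at months drawn (seeded) from
the treated enlistment-month empirical distribution, so both classes see
the same calendar mix.

## Matching

Matching is rolling-entry, 1:1, without replacement. Months are processed
in ascending enlistment order; at each month the still-unmatched comparison
pool is re-featurized at that anchor and scored. Within each exact segment
— (self-reported sex, pharmacy data availability, plan type) — treated
members pick greedily in descending score order (ties broken by ascending
member id), each taking the remaining control nearest in absolute
logit-score distance (ties: lowest control id). Matched controls are
permanently removed from the pool. There is no caliper by default (an
optional caliper argument exists); unmatched treated members are reported
and excluded from estimation, never silently dropped.

The greedy policy is intentionally simple and order-deterministic: the
extreme-score treated members face the thinnest candidate sets, so they
choose first. A brute-force re-implementation of the same policy serves as
an equivalence oracle in the tests on small random instances.

Balance is reported per encoded feature as the standardized mean difference
(mean gap over the pooled SD, `sqrt((s_t² + s_c²)/2)`; binary features use
the same formula on 0/1 values) plus a Welch p-value; a run passes when
every |SMD| ≤ 0.1. Features with zero pooled SD report SMD 0 when the
means agree and are flagged degenerate otherwise. At a few hundred pairs
residual SMDs can hover around the 0.1 convention; the flag is a reporting
device, not a hard gate — a failing run completes and is marked
non-compliant.

## Spend processing

Claim lines flagged non-impactable or pregnancy-related are removed before
any aggregation (a line with both flags is removed once). Pharmacy
(`total_rx`) lines count only for members with pharmacy data; medical
categories always count. Period totals are winsorized at the nearest-rank
99th percentile — the ⌈0.99·n⌉-th order statistic — of the *pooled*
matched population, separately for the pre and post periods, so both groups
face a single cap and the estimand stays symmetric. When a member's total
is capped, the per-category totals are rescaled proportionally, so the
category decomposition still sums to the capped total (exactly, absent
capping; to rounding, with it). Comparison members inherit their matched
partner's anchor for all windows.

Cost-category savings are one DiD per category (ED, specialist, mental
health, inpatient, radiology, primary care, ambulatory, laboratory, home
health, medical Rx, other Rx) plus an overall row. ED spend is further
split probabilistically by diagnosis code: each ED claim's cost is divided
into emergent / non-emergent / other shares according to a lookup table of
per-code probabilities (rows sum to 1). The bundled table
(`data/synthetic_ed_probabilities.csv`) is **synthetic** — it mimics the
format of published probabilistic ED classification weights but carries no
empirical content; users holding real weights supply them in the same
format (unknown codes go to "other" with a warning by default, or raise).

A deliberately naive estimator — the unmatched post-period PUPM contrast
between enrolled members and the whole eligible non-enrolled pool at a
common anchor (the median enlistment month) — is computed alongside the
matched DiD so the selection bias the design removes is measurable rather
than assumed.

## Synthetic data generator

The generator emulates a commercial health plan book of business. All
distributions are stand-ins chosen for shape realism, not estimates of any
real population:

- **Demographics:** age ~ Normal(41, 12) truncated to [18, 90]; sex
  52.1% female / 0.01% nonbinary; urban/suburban/rural ≈ 40/24/36;
  race levels with a large missing fraction; 50% self-insured; 70% with
  pharmacy data; 35.66% with ≥ 1 chronic condition (count
  shifted-geometric beyond that, continuation 0.34); 5% of members have a
  censored eligibility spell and fail the continuity criterion.
- **Spend:** per member × month × category, spend is 0 with probability
  p₀(c), else `exp(Normal(μ_c + k·log m_c, σ_c))` USD, with k the
  chronic-condition count and m_c a per-category multiplier. Defaults give
  ≈ $300–400 PUPM dominated by rare expensive inpatient stays, with
  per-member Δ-score SD ≈ $650 — consistent with the CI width a ~57k-pair
  study of commercial claims reports. ED occurrence probability is
  `ed_rate/12` per month (default 0.18 visits/member-year); ED lines draw
  a diagnosis code from the bundled table's frequency column. 8% of lines
  are flagged non-impactable; 2% pregnancy-related (female members under
  45 only).
- **Selection:** enrollment is Bernoulli with logit linear in intercept,
  (age−40)/10, female, chronic count, expected baseline monthly spend
  ($100 units), and communication receptivity. Defaults encode voluntary
  wellness-program self-selection: younger, healthier, lower-spending,
  contactable members opt in (≈ 10% marginal enrollment). The baseline
  spend covariate uses the closed-form expected spend, not realized spend,
  avoiding circularity between the roster and claims draws.
- **Treatment effect:** enrolled members' months strictly after enlistment
  receive a multiplicative shift applied to impactable, unflagged amounts,
  calibrated per member as `f = 1 + effect / E[impactable monthly spend]`
  so the expected PUPM change equals `treatment_effect_pupm` exactly after
  the exclusion filters (the effect is injected only into spend the
  analysis can see; otherwise the generator's own parameter would be
  unrecoverable by construction). `effect_weights` optionally concentrates
  the effect in chosen categories. Factors that would go negative are
  clipped at zero with a warning.
- **Determinism:** every draw flows from `numpy.random.default_rng` seeded
  by the config seed, so identical configs give byte-identical outputs.

What the generator does **not** model: calendar trends or seasonality in
spend (the process is stationary, which is also why unmatched DiD is
nearly unbiased here while the post-only contrast is not), COVID-era
dynamics, wearable/engagement streams, real diagnosis/procedure coding
(diagnosis codes exist only on ED lines, so the feature
`diag_code_count_12m` counts distinct ED codes and `procedure_count_12m`
counts claim lines in the window), regional cost variation, and
correlation between adjacent months beyond what member covariates induce.
Passing tests therefore demonstrate the estimator's correctness under
covariate-driven selection with heavy-tailed stationary spend — not
robustness to time-varying confounding, which no within-package simulation
can establish.

## Problem sizes used in validation

The simulation-based checks use: parameter recovery at 56,000 members per
replicate (~5,800 treated, ~50,000 pool) over 50 seeded replicates,
requiring ≥ 90% CI coverage of the injected effect and a naive-contrast
bias at least 3× the matched DiD bias; null calibration at 2,500 members
(~255 pairs) over 500 replicates, requiring a 5% ± 2% rejection rate; and
matching-oracle equivalence on 1,000 random instances of up to 8×8. The
`scripts/acceptance.py` entry point runs one 56,000-member replicate end
to end and writes its computed quantities as JSON.

## Known limitations

- Greedy nearest-neighbor matching is not optimal matching; total distance
  is not minimized and small-sample balance can sit near the 0.1 SMD
  convention.
- The Welch test on heavy-tailed change scores relies on CLT behavior;
  below ~100 pairs per group the nominal error rate degrades.
- Nearest-rank capping at p99 introduces a small symmetric attenuation of
  extreme spend in both groups; it is part of the estimand, not corrected
  for.
- The ensemble is fit once on the full sample (no cross-fitting); honest
  regularization rather than sample splitting guards against score
  overfitting.
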