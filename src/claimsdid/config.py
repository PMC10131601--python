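"""Configuration for the synthetic claims generator and pipeline runs.

The simulation config fixes the data-generating process: who the members
are, how they self-select into the intervention, how monthly spend is
drawn, and what per-user-per-month (PUPM) effect enlistment injects into
post-enlistment spending.  All downstream analysis code is agnostic to
these choices; they only matter for generating test data.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Medical cost categories used throughout the pipeline. ``total_rx`` is the
#: outpatient pharmacy benefit (observable only for members whose pharmacy
#: benefits manager shares data); everything else is billed as medical.
CATEGORIES = (
    "ED",
    "specialist",
    "mental_health",
    "inpatient",
    "radiology",
    "primary_care",
    "ambulatory",
    "laboratory",
    "home_health",
    "medical_rx",
    "total_rx",
)

MEDICAL_CATEGORIES = tuple(c for c in CATEGORIES if c != "total_rx")
PHARMACY_CATEGORIES = ("total_rx",)

SEX_LEVELS = ("male", "female", "nonbinary")
LOCATION_LEVELS = ("urban", "suburban", "rural")
PLAN_LEVELS = ("fully_insured", "self_insured")
RACE_LEVELS = (
    "white",
    "black",
    "asian",
    "multiple",
    "other",
    "aian",
    "nhpi",
    "unknown",
    "unanswered",
    "missing",
)


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class CategorySpend:
    """Zero-inflated log-normal parameters for one cost category.

    Monthly spend is 0 with probability ``p_zero``, otherwise
    ``exp(Normal(log_mean + chronic_count * log(chronic_multiplier), log_sd))``
    US dollars.
    """

    p_zero: float
    log_mean: float
    log_sd: float
    chronic_multiplier: float = 1.0


def _default_categories() -> dict[str, CategorySpend]:
    # Calibrated to a commercial-plan-like total of roughly $300-400 PUPM,
    # dominated by rare, expensive inpatient stays; ED p_zero is overridden
    # from SimConfig.ed_rate at generation time.
    return {
        "ED": CategorySpend(0.985, 6.9, 0.8, 1.4),
        "specialist": CategorySpend(0.80, 4.8, 1.0, 1.3),
        "mental_health": CategorySpend(0.95, 4.9, 1.0, 1.2),
        "inpatient": CategorySpend(0.9866, 8.3, 1.0, 1.5),
        "radiology": CategorySpend(0.93, 5.0, 0.9, 1.3),
        "primary_care": CategorySpend(0.85, 4.5, 0.7, 1.2),
        "ambulatory": CategorySpend(0.90, 5.2, 1.0, 1.3),
        "laboratory": CategorySpend(0.85, 3.6, 0.8, 1.2),
        "home_health": CategorySpend(0.99, 5.5, 1.0, 1.3),
        "medical_rx": CategorySpend(0.95, 5.8, 1.1, 1.4),
        "total_rx": CategorySpend(0.60, 3.8, 1.2, 1.5),
    }


@dataclass
class SpendModel:
    """Parameters of the monthly spend generator.

    ``nonimpactable_rate`` / ``pregnancy_rate`` are per-claim-line flag
    probabilities (pregnancy flags only arise for female members under 45).
    ``effect_weights`` optionally distributes the injected treatment effect
    across categories; ``None`` spreads it proportionally to each member's
    expected category spend (a uniform multiplicative shift).
    """

    categories: dict[str, CategorySpend] = field(default_factory=_default_categories)
    nonimpactable_rate: float = 0.08
    pregnancy_rate: float = 0.02
    effect_weights: dict[str, float] | None = None

    def validate(self) -> None:
        for name in CATEGORIES:
            if name not in self.categories:
                raise ConfigError(f"spend_model.categories missing category {name!r}")
        for name, cat in self.categories.items():
            if not 0.0 <= cat.p_zero <= 1.0:
                raise ConfigError(f"spend_model.categories[{name!r}].p_zero must be in [0,1]")
            if cat.log_sd <= 0:
                raise ConfigError(f"spend_model.categories[{name!r}].log_sd must be > 0")
            if cat.chronic_multiplier <= 0:
                raise ConfigError(
                    f"spend_model.categories[{name!r}].chronic_multiplier must be > 0"
                )
        for rate_name in ("nonimpactable_rate", "pregnancy_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r < 1.0:
                raise ConfigError(f"spend_model.{rate_name} must be in [0,1)")
        if self.effect_weights is not None:
            if abs(sum(self.effect_weights.values()) - 1.0) > 1e-9:
                raise ConfigError("spend_model.effect_weights must sum to 1")
            for name in self.effect_weights:
                if name not in self.categories:
                    raise ConfigError(f"spend_model.effect_weights names unknown category {name!r}")


@dataclass
class SelectionCoefs:
    """Coefficients of the enrollment logit.

    The linear predictor is
    ``intercept + age*(age-40)/10 + sex*1[female] + chronic_count*n_chronic
    + baseline_spend*(expected monthly spend / $100) + comm_receptivity*1[receptive]``.

    Defaults encode the self-selection pattern seen in voluntary wellness
    programs: younger, healthier, lower-spending, contactable members opt in.
    """

    intercept: float = -2.3
    age: float = -0.30
    sex: float = 0.30
    chronic_count: float = -0.35
    baseline_spend: float = -0.08
    comm_receptivity: float = 0.80


@dataclass
class Demographics:
    """Marginal distributions of member attributes.

    Category probabilities mirror a large national commercial book of
    business; ~35.7% of members carry at least one chronic condition.
    """

    age_mean: float = 41.0
    age_sd: float = 12.0
    p_female: float = 0.5209
    p_nonbinary: float = 0.0001
    race_probs: dict[str, float] = field(
        default_factory=lambda: {
            "white": 0.3146,
            "black": 0.0451,
            "asian": 0.0430,
            "multiple": 0.0461,
            "other": 0.0145,
            "aian": 0.0027,
            "nhpi": 0.0012,
            "unknown": 0.0349,
            "unanswered": 0.1063,
            "missing": 0.3916,
        }
    )
    location_probs: dict[str, float] = field(
        default_factory=lambda: {"urban": 0.3978, "suburban": 0.2427, "rural": 0.3595}
    )
    p_self_insured: float = 0.5
    p_pharmacy_data: float = 0.7
    p_comm_receptive: float = 0.5
    p_care_management: float = 0.10
    p_member_advocacy: float = 0.05
    p_chronic_any: float = 0.3566
    chronic_continue: float = 0.34
    p_short_eligibility: float = 0.05

    def validate(self) -> None:
        for pname in (
            "p_female",
            "p_nonbinary",
            "p_self_insured",
            "p_pharmacy_data",
            "p_comm_receptive",
            "p_care_management",
            "p_member_advocacy",
            "p_chronic_any",
            "chronic_continue",
            "p_short_eligibility",
        ):
            p = getattr(self, pname)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"demographics.{pname} must be in [0,1]")
        if self.p_female + self.p_nonbinary > 1.0:
            raise ConfigError("demographics.p_female + p_nonbinary must be <= 1")
        if self.age_sd <= 0:
            raise ConfigError("demographics.age_sd must be > 0")
        for name, probs, levels in (
            ("race_probs", self.race_probs, RACE_LEVELS),
            ("location_probs", self.location_probs, LOCATION_LEVELS),
        ):
            if set(probs) != set(levels):
                raise ConfigError(f"demographics.{name} must have levels {levels}")
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"demographics.{name} must sum to 1")


@dataclass
class SimConfig:
    """Full specification of one synthetic study population.

    ``treatment_effect_pupm`` is the additive expected change (USD per user
    per month, typically negative) injected into the impactable portion of
    enrolled members' post-enlistment spending.
    """

    n_members: int = 20000
    n_months: int = 30
    enroll_window: tuple[int, int] = (12, 22)
    selection_coefs: SelectionCoefs = field(default_factory=SelectionCoefs)
    spend_model: SpendModel = field(default_factory=SpendModel)
    demographics: Demographics = field(default_factory=Demographics)
    treatment_effect_pupm: float = 0.0
    ed_rate: float = 0.18
    seed: int = 0

    def validate(self) -> None:
        if self.n_members <= 0:
            raise ConfigError("n_members must be a positive integer")
        if self.n_months < 24:
            raise ConfigError(
                "n_months must be >= 24 (12 pre months plus at least 7 post months)"
            )
        lo, hi = self.enroll_window
        if not (0 <= lo <= hi < self.n_months):
            raise ConfigError("enroll_window must be an inclusive range within the study")
        if lo < 12:
            raise ConfigError("enroll_window start must be >= 12 to allow a full pre window")
        if hi > self.n_months - 1 - 7:
            raise ConfigError("enroll_window end must leave >= 7 post months")
        if not 0.0 <= self.ed_rate <= 12.0:
            raise ConfigError("ed_rate must be in [0, 12] visits per member-year")
        self.spend_model.validate()
        self.demographics.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "selection_coefs" in d and isinstance(d["selection_coefs"], dict):
            d["selection_coefs"] = SelectionCoefs(**d["selection_coefs"])
        if "demographics" in d and isinstance(d["demographics"], dict):
            d["demographics"] = Demographics(**d["demographics"])
        if "spend_model" in d and isinstance(d["spend_model"], dict):
            sm = dict(d["spend_model"])
            if "categories" in sm:
                sm["categories"] = {
                    k: CategorySpend(**v) if isinstance(v, dict) else v
                    for k, v in sm["categories"].items()
                }
            d["spend_model"] = SpendModel(**sm)
        if "enroll_window" in d:
            d["enroll_window"] = tuple(d["enroll_window"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
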