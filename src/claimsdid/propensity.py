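"""Ensemble propensity model for enlistment.

The enlistment probability is estimated by averaging two heterogeneous
learners — an L2 logistic regression and a gradient-boosted tree classifier
— over a shared encoded feature matrix.  Averaging probabilities across
model families is the simplest ensemble that hedges the linear model's
misspecification against the trees' variance.

Missing pharmacy spend (members without a data-sharing agreement) is
encoded as zero plus an explicit missing-indicator column rather than
imputed: availability itself is an exact-matching segment and carries
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logit as _logit
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

SCORE_CLIP = 1e-6  # keeps logits finite for matching distances


class SchemaError(ValueError):
    """A required feature column is absent or malformed."""


#: (output column, source column, encoding) triples; categorical encodings
#: are reference-coded indicators.
_ENCODERS: list[tuple[str, str, object]] = [
    ("age", "age", float),
    ("chronic_count", "chronic_count", float),
    ("risk_score", "risk_score", float),
    ("inpatient_visits_12m", "inpatient_visits_12m", float),
    ("ed_visits_12m", "ed_visits_12m", float),
    ("diag_code_count_12m", "diag_code_count_12m", float),
    ("procedure_count_12m", "procedure_count_12m", float),
    ("pre_medical_pupm", "pre_medical_pupm", float),
    ("pre_pharmacy_pupm", "pre_pharmacy_pupm", "fillna0"),
    ("pharmacy_missing", "pre_pharmacy_pupm", "isna"),
    ("pharmacy_data_available", "pharmacy_data_available", bool),
    ("comm_receptivity", "comm_receptivity", bool),
    ("care_management", "care_management", bool),
    ("member_advocacy", "member_advocacy", bool),
    ("sex_female", "sex", ("eq", "female")),
    ("sex_nonbinary", "sex", ("eq", "nonbinary")),
    ("location_suburban", "location", ("eq", "suburban")),
    ("location_rural", "location", ("eq", "rural")),
    ("plan_self_insured", "plan_type", ("eq", "self_insured")),
]

FEATURE_SCHEMA: tuple[str, ...] = tuple(name for name, _, _ in _ENCODERS)


def encode_features(features: pd.DataFrame) -> np.ndarray:
    """Encode a feature table into the fixed numeric design matrix."""
    cols = []
    for name, source, enc in _ENCODERS:
        if source not in features.columns:
            raise SchemaError(f"feature table is missing required column {source!r}")
        col = features[source]
        if enc is float:
            cols.append(col.to_numpy(dtype=float))
        elif enc is bool:
            cols.append(col.to_numpy(dtype=bool).astype(float))
        elif enc == "fillna0":
            cols.append(col.fillna(0.0).to_numpy(dtype=float))
        elif enc == "isna":
            cols.append(col.isna().to_numpy(dtype=float))
        else:
            _, level = enc
            cols.append((col.to_numpy() == level).astype(float))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise SchemaError("encoded feature matrix contains non-finite values")
    return X


@dataclass
class PropensityModel:
    base_learners: list = field(default_factory=list)
    feature_schema: tuple[str, ...] = FEATURE_SCHEMA
    training_meta: dict = field(default_factory=dict)


def default_learners(seed: int) -> list:
    """The default heterogeneous pair: linear-logistic + boosted trees."""
    return [
        make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, C=1.0)
        ),
        # Strong regularization keeps the tree learner an honest estimate of
        # the enlistment probability rather than a memorized label: an
        # overfit score is no longer a balancing score and matching on it
        # leaves systematic covariate imbalance.
        HistGradientBoostingClassifier(
            max_iter=50,
            max_leaf_nodes=7,
            learning_rate=0.1,
            min_samples_leaf=200,
            l2_regularization=1.0,
            early_stopping=False,
            random_state=int(seed) % (2**31),
        ),
    ]


def fit_propensity(
    features: pd.DataFrame,
    labels: Sequence[bool] | np.ndarray,
    seed: int,
    *,
    learners: list | None = None,
) -> PropensityModel:
    """Fit the enlistment ensemble.

    ``labels`` is True for enrolled (treated) rows.  Scoring a fitted model
    is deterministic; refitting with the same data and seed reproduces the
    same scores.
    """
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(features):
        raise ValueError("labels must align with features")
    if y.all() or not y.any():
        raise ValueError("fitting requires both enrolled and comparison rows")
    X = encode_features(features)
    models = learners if learners is not None else default_learners(seed)
    for m in models:
        m.fit(X, y.astype(int))
    meta = {"n_treated": int(y.sum()), "n_comparison": int((~y).sum()), "seed": int(seed)}
    logger.info(
        "fit propensity ensemble (%d learners) on %d treated / %d comparison rows",
        len(models),
        meta["n_treated"],
        meta["n_comparison"],
    )
    return PropensityModel(base_learners=models, training_meta=meta)


def score(model: PropensityModel, features: pd.DataFrame) -> np.ndarray:
    """Ensemble scores in (0, 1): the mean of base-learner probabilities,
    clipped away from {0, 1}; order-preserving with the input rows."""
    if not model.base_learners:
        raise ValueError("model has no fitted base learners")
    X = encode_features(features)
    probs = np.mean([m.predict_proba(X)[:, 1] for m in model.base_learners], axis=0)
    return np.clip(probs, SCORE_CLIP, 1.0 - SCORE_CLIP)


def logit(scores: np.ndarray) -> np.ndarray:
    """Log-odds transform used for matching distance."""
    return _logit(np.asarray(scores, dtype=float))
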