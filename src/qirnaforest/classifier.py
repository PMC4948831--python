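"""Random-forest training, scoring and persistence.

The ensemble itself is scikit-learn's ``RandomForestClassifier`` (bagging +
random feature subsets per split, out-of-bag accuracy); this module pins
down the contract around it: deterministic training under a seed, scores on
a [0, 1] probability scale, a decision cutoff with ties going positive, and
models that bundle the training-time :class:`~qirnaforest.features.ScoreMatrix`
so new sequences are featurized with training statistics, never with
statistics of the query set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix, FeatureSpec, ScoreMatrix, featurize
from .seqio import SequenceSet

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    Defaults follow the classical random-forest package defaults: 500 trees
    and floor(sqrt(d)) candidate features per split.
    """

    n_trees: int = 500
    features_per_split: int | Literal["sqrt"] = "sqrt"
    seed: int = 0
    class_weighting: Literal["none", "balanced"] = "none"

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to score new sequences."""

    forest: RandomForestClassifier
    feature_names: list[str]
    feature_spec: FeatureSpec
    score_matrix: ScoreMatrix | None
    config: ForestConfig
    oob_estimate: float | None = None
    format_version: int = MODEL_FORMAT_VERSION

    @property
    def window(self) -> int | None:
        return self.score_matrix.window if self.score_matrix is not None else None


class ModelFormatError(ValueError):
    """Raised when a model file has the wrong schema or version."""


def train(
    fm: FeatureMatrix,
    cfg: ForestConfig = ForestConfig(),
    score_matrix: ScoreMatrix | None = None,
    feature_spec: FeatureSpec | None = None,
) -> TrainedModel:
    """Fit a random forest on a labeled feature matrix.

    Deterministic under ``cfg.seed``. OOB accuracy is recorded from the
    bootstrap's held-out samples. Raises on single-class input.
    """
    if fm.labels is None:
        raise ValueError("feature matrix has no labels")
    classes = set(np.unique(fm.labels))
    if classes != {-1, 1}:
        raise ValueError(f"training requires both classes; got labels {sorted(classes)}")
    if cfg.features_per_split != "sqrt" and cfg.features_per_split > fm.n_features:
        raise ValueError("features_per_split exceeds total feature count")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.features_per_split,
        bootstrap=True,
        oob_score=True,
        random_state=cfg.seed,
        class_weight=None if cfg.class_weighting == "none" else "balanced",
        n_jobs=1,
    )
    forest.fit(fm.X, fm.labels)
    return TrainedModel(
        forest=forest,
        feature_names=list(fm.feature_names),
        feature_spec=feature_spec or FeatureSpec(kind="kmer"),
        score_matrix=score_matrix,
        config=cfg,
        oob_estimate=float(forest.oob_score_),
    )


def score_features(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """Positive-class probability for each row of a feature matrix.

    Rejects inputs whose feature names or order differ from training.
    """
    if fm.feature_names != model.feature_names:
        raise ValueError("feature names/order differ from the trained model's")
    pos_col = list(model.forest.classes_).index(1)
    return model.forest.predict_proba(fm.X)[:, pos_col]


@dataclass
class Predictions:
    """Per-sequence scores plus the ids of sequences too short to score."""

    ids: list[str]
    scores: np.ndarray
    skipped_ids: list[str] = field(default_factory=list)

    def labels(self, cutoff: float = 0.5) -> np.ndarray:
        return classify(self.scores, cutoff)


def predict_scores(model: TrainedModel, s: SequenceSet) -> Predictions:
    """Score new sequences with the model's bundled training featurization.

    The score is the forest's averaged positive-class vote in [0, 1].
    Sequences shorter than the model's window cannot be featurized; they are
    reported in ``skipped_ids`` rather than silently dropped.
    """
    w = model.window
    if w is not None:
        usable = [r for r in s.records if r.length >= w]
        skipped = [r.id for r in s.records if r.length < w]
    else:
        usable, skipped = list(s.records), []
    sub = SequenceSet(records=usable, label=s.label)
    if not usable:
        return Predictions(ids=[], scores=np.empty(0), skipped_ids=skipped)
    fm = featurize(sub, model.feature_spec, matrix=model.score_matrix)
    return Predictions(ids=fm.ids, scores=score_features(model, fm), skipped_ids=skipped)


def classify(scores: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Map scores to {+1, -1} labels; ties at the cutoff go positive.

    The default cutoff is 0.5; a stringent cutoff of 0.667 trades
    sensitivity for specificity when shortlisting experimental candidates.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores >= cutoff, 1, -1)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model; round-trips predictions bit-for-bit."""
    joblib.dump({"schema": "qirnaforest-model", "version": model.format_version,
                 "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`.

    Raises
    ------
    ModelFormatError
        On a wrong schema or unsupported version (never returns garbage).
    """
    try:
        payload = joblib.load(path)
    except Exception as exc:  # unreadable pickle, wrong file type
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != "qirnaforest-model":
        raise ModelFormatError(f"{path} is not a qirnaforest model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {payload.get('version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    model = payload["model"]
    if not isinstance(model, TrainedModel):
        raise ModelFormatError(f"{path} does not contain a TrainedModel")
    return model
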