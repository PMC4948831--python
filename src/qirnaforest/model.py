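"""High-level Model/Results interface over the full pipeline.

``QirnaForestModel`` holds the training data (a positive and a negative
sequence set) and the modelling choices (feature encoding, forest
hyperparameters); ``fit()`` builds the class PPMs and log-odds score
matrix, trains the forest and returns a ``QirnaForestResults`` carrying the
fitted objects, the out-of-bag accuracy, the F-score ranking of features,
and methods for prediction, cross-validation and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from .classifier import (
    ForestConfig,
    Predictions,
    TrainedModel,
    load_model,
    predict_scores,
    save_model,
    train,
)
from .evaluation import CVPlan, EvaluationReport, cross_validate
from .features import (
    FeatureSpec,
    FScoreTable,
    ScoreMatrix,
    build_score_matrix,
    fscore_rank,
    labeled_feature_matrix,
)
from .seqio import SequenceSet, read_fasta


class QirnaForestModel:
    """A qiRNA-vs-background classifier specification bound to training data.

    Parameters
    ----------
    positives, negatives:
        Labeled training sequence sets.
    feature_spec:
        Feature encoding (default: positional log-odds over a 10-position
        window at each end, i.e. 80 features).
    forest:
        Random-forest hyperparameters (default: 500 trees, sqrt(d) features
        per split).
    """

    def __init__(
        self,
        positives: SequenceSet,
        negatives: SequenceSet,
        feature_spec: FeatureSpec = FeatureSpec(),
        forest: ForestConfig = ForestConfig(),
    ):
        if len(positives) == 0 or len(negatives) == 0:
            raise ValueError("both training sets must be non-empty")
        self.positives = positives
        self.negatives = negatives
        self.feature_spec = feature_spec
        self.forest = forest

    @classmethod
    def from_fasta(
        cls,
        positives_path: str | Path,
        negatives_path: str | Path,
        feature_spec: FeatureSpec = FeatureSpec(),
        forest: ForestConfig = ForestConfig(),
    ) -> "QirnaForestModel":
        return cls(
            read_fasta(positives_path, label="positive"),
            read_fasta(negatives_path, label="negative"),
            feature_spec=feature_spec,
            forest=forest,
        )

    def fit(self, seed: int | None = None) -> "QirnaForestResults":
        """Build PPMs/score matrix from the training data and train the forest."""
        cfg = self.forest if seed is None else replace(self.forest, seed=seed)
        matrix = None
        if self.feature_spec.kind in ("ppm", "both"):
            matrix = build_score_matrix(
                self.positives, self.negatives,
                window=self.feature_spec.window,
                pseudocount=self.feature_spec.pseudocount,
            )
        fm = labeled_feature_matrix(self.positives, self.negatives, self.feature_spec, matrix)
        trained = train(fm, cfg, score_matrix=matrix, feature_spec=self.feature_spec)
        return QirnaForestResults(
            model=self, trained=trained, score_matrix=matrix, fscores=fscore_rank(fm)
        )

    def cross_validate(
        self, plan: CVPlan = CVPlan(), global_ppm: bool = False
    ) -> EvaluationReport:
        """Leakage-safe CV of this model specification on its training data."""
        return cross_validate(
            self.positives, self.negatives, plan=plan, cfg=self.forest,
            feature_spec=self.feature_spec, global_ppm=global_ppm,
        )


@dataclass
class QirnaForestResults:
    """A fitted classifier with its training-time statistics."""

    model: QirnaForestModel
    trained: TrainedModel
    score_matrix: ScoreMatrix | None
    fscores: FScoreTable

    @property
    def oob_accuracy(self) -> float | None:
        """Out-of-bag accuracy estimated during bootstrap training."""
        return self.trained.oob_estimate

    def predict(self, sequences: SequenceSet) -> Predictions:
        """Score new sequences with the bundled training featurization;
        call ``.labels(cutoff)`` on the result for hard calls."""
        return predict_scores(self.trained, sequences)

    def save(self, path: str | Path) -> None:
        save_model(self.trained, path)

    @staticmethod
    def load_trained(path: str | Path) -> TrainedModel:
        return load_model(path)

    def summary(self, top_features: int = 10) -> str:
        """Human-readable fit summary: data sizes, settings, OOB, top features."""
        spec = self.model.feature_spec
        lines = [
            "qiRNA random-forest classifier — fit summary",
            "=" * 46,
            f"positive sequences:   {len(self.model.positives)}",
            f"negative sequences:   {len(self.model.negatives)}",
            f"feature encoding:     {spec.kind} (window={spec.window}, kmax={spec.kmax})",
            f"features:             {self.trained.forest.n_features_in_}",
            f"trees:                {self.model.forest.n_trees}",
            f"features per split:   {self.model.forest.features_per_split}",
            f"seed:                 {self.model.forest.seed}",
        ]
        if self.oob_accuracy is not None:
            lines.append(f"OOB accuracy:         {self.oob_accuracy:.4f}")
        lines.append("")
        lines.append(f"top {top_features} features by F-score:")
        head = self.fscores.table.head(top_features)
        for _, row in head.iterrows():
            val = "inf" if row["infinite"] else f"{row['fscore']:.4f}"
            lines.append(f"  {row['feature']:>10}  F = {val}")
        return "\n".join(lines)
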