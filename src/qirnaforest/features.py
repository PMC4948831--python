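"""Position-probability-matrix log-odds features, k-mer features, F-scores.

The positional encoding works on a signed index set: positions ``1..w``
count from the 5' end (1 = first base) and ``-1..-w`` from the 3' end
(-1 = last base). For a window of ``w`` positions per end, a positive-set
PPM ``P`` and a negative-set PPM ``N`` give per-cell log-odds scores

    S(i, j) = log2(P_ij / N_ij),   i in {A, C, G, U},

with S set to 0 whenever ``P_ij`` or ``N_ij`` is zero (a zero probability
reflects limited sampling, not infinite evidence). Each sequence is encoded
as a ``4 * 2w``-dimensional vector holding, for every position ``j``, the
score of the nucleotide actually observed there (its three sibling slots
are zero) — at the default ``w = 10`` this is the 80-feature encoding.

Sequences shorter than ``w`` are skipped; sequences shorter than ``2w``
contribute their middle bases to both a 5'-anchored and a 3'-anchored
position, mirroring how very short RNAs overlap the two windows.

The discriminative power of each feature is ranked by the F-score

    F(i) = [(m+ - m)^2 + (m- - m)^2] / [s+^2 + s-^2]

where ``m``, ``m+``, ``m-`` are the overall / positive / negative means of
feature ``i`` and ``s+^2``, ``s-^2`` the within-class sample variances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceSet

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "U")


def position_index_set(window: int) -> list[int]:
    """Signed positions [1..w] then [-1..-w] (5'-anchored before 3'-anchored)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return list(range(1, window + 1)) + list(range(-1, -window - 1, -1))


@dataclass
class PositionProbabilityMatrix:
    """Per-position nucleotide probabilities over a signed position index set."""

    probs: pd.DataFrame  # index: A,C,G,U; columns: signed positions
    window: int
    n_sequences: int
    n_skipped: int = 0

    def __getitem__(self, key: tuple[str, int]) -> float:
        nuc, pos = key
        return float(self.probs.at[nuc, pos])


@dataclass
class ScoreMatrix:
    """log2-odds scores S(i, j) derived from a positive and a negative PPM."""

    scores: pd.DataFrame  # index: A,C,G,U; columns: signed positions
    window: int

    def __getitem__(self, key: tuple[str, int]) -> float:
        nuc, pos = key
        return float(self.scores.at[nuc, pos])

    def to_tsv(self, path: str | Path) -> None:
        cols = list(range(-self.window, 0)) + list(range(1, self.window + 1))
        self.scores[cols].to_csv(path, sep="\t", index_label="nucleotide")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col="nucleotide")
        df.columns = [int(c) for c in df.columns]
        window = max(df.columns)
        order = position_index_set(window)
        return cls(scores=df[order], window=window)


@dataclass
class FeatureMatrix:
    """Per-sequence feature rows with optional +1/-1 labels."""

    ids: list[str]
    X: np.ndarray  # shape (n, d)
    feature_names: list[str]
    labels: np.ndarray | None = None  # entries in {+1, -1}
    kind: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError("feature matrix shape does not match ids/names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise ValueError("labels length does not match rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels if self.labels is not None else pd.NA)
        df.insert(0, "id", self.ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
        labels = None
        if not df["label"].isna().all():
            labels = df["label"].astype(int).to_numpy()
        return cls(
            ids=df["id"].astype(str).tolist(),
            X=df.drop(columns=["id", "label"]).to_numpy(dtype=float),
            feature_names=[c for c in df.columns if c not in ("id", "label")],
            labels=labels,
            kind=kind,
        )

    def subset(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            feature_names=list(self.feature_names),
            labels=None if self.labels is None else self.labels[idx],
            kind=self.kind,
        )


def build_ppm(s: SequenceSet, window: int = 10) -> PositionProbabilityMatrix:
    """Count nucleotide occurrence probabilities at positions 1..w and -1..-w.

    Each contributing sequence (length >= w) adds one count per position;
    sequences shorter than 2w add their overlapping middle bases to both the
    5'-anchored and the 3'-anchored cell. Columns therefore sum to 1.

    Raises
    ------
    ValueError
        If no sequence is long enough for the window.
    """
    positions = position_index_set(window)
    counts = pd.DataFrame(0.0, index=list(NUCLEOTIDES), columns=positions)
    n_used = 0
    n_skipped = 0
    for rec in s.records:
        if rec.length < window:
            n_skipped += 1
            continue
        n_used += 1
        for j in range(1, window + 1):
            counts.at[rec.seq[j - 1], j] += 1
        for j in range(1, window + 1):
            counts.at[rec.seq[rec.length - j], -j] += 1
    if n_used == 0:
        raise ValueError(f"no sequences long enough for window {window}")
    if n_skipped:
        logger.info("build_ppm: skipped %d sequence(s) shorter than %d nt", n_skipped, window)
    return PositionProbabilityMatrix(
        probs=counts / n_used, window=window, n_sequences=n_used, n_skipped=n_skipped
    )


def score_matrix(
    pos: PositionProbabilityMatrix,
    neg: PositionProbabilityMatrix,
    pseudocount: float = 0.0,
) -> ScoreMatrix:
    """S(i,j) = log2(P_ij / N_ij); zero when either probability is zero.

    An optional additive pseudocount is applied to both PPMs' underlying
    counts before the ratio (off by default — the zero-score guard is the
    standard behavior).
    """
    if pos.window != neg.window:
        raise ValueError(f"window mismatch: {pos.window} vs {neg.window}")
    p = pos.probs.to_numpy(copy=True)
    n = neg.probs.to_numpy(copy=True)
    if pseudocount:
        p = (p * pos.n_sequences + pseudocount) / (pos.n_sequences + 4 * pseudocount)
        n = (n * neg.n_sequences + pseudocount) / (neg.n_sequences + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where((p > 0) & (n > 0), np.log2(np.where(p > 0, p, 1) / np.where(n > 0, n, 1)), 0.0)
    return ScoreMatrix(
        scores=pd.DataFrame(s, index=pos.probs.index, columns=pos.probs.columns),
        window=pos.window,
    )


def build_score_matrix(
    positives: SequenceSet,
    negatives: SequenceSet,
    window: int = 10,
    pseudocount: float = 0.0,
) -> ScoreMatrix:
    """Convenience: PPMs from both classes, then their log-odds matrix."""
    return score_matrix(
        build_ppm(positives, window), build_ppm(negatives, window), pseudocount=pseudocount
    )


def ppm_feature_names(window: int) -> list[str]:
    """'jN' names, e.g. '1U', '10C', '-1A'; 8w names at window w."""
    return [f"{j}{nuc}" for j in position_index_set(window) for nuc in NUCLEOTIDES]


def ppm_featurize(
    s: SequenceSet, m: ScoreMatrix, binary: bool = False
) -> FeatureMatrix:
    """Encode each sequence as one-hot-masked positional scores.

    The feature named ``jN`` holds ``S(N, j)`` when the sequence carries
    nucleotide N at position j and 0 otherwise (with ``binary=True`` the
    indicator 1/0 is used instead of the score). Rows have ``8w`` entries
    with at most one nonzero slot per position. Sequences shorter than the
    window are skipped with a logged count.
    """
    w = m.window
    names = ppm_feature_names(w)
    nuc_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    scores = m.scores  # index A,C,G,U
    rows = []
    ids = []
    n_skipped = 0
    for rec in s.records:
        if rec.length < w:
            n_skipped += 1
            continue
        vec = np.zeros(8 * w)
        for slot, j in enumerate(position_index_set(w)):
            base = rec.seq[j - 1] if j > 0 else rec.seq[rec.length + j]
            vec[4 * slot + nuc_idx[base]] = 1.0 if binary else float(scores.at[base, j])
        rows.append(vec)
        ids.append(rec.id)
    if n_skipped:
        logger.info("ppm_featurize: skipped %d sequence(s) shorter than %d nt", n_skipped, w)
    X = np.array(rows) if rows else np.empty((0, 8 * w))
    return FeatureMatrix(ids=ids, X=X, feature_names=names, kind="ppm")


def kmer_feature_names(kmax: int) -> list[str]:
    names = []
    for m in range(1, kmax + 1):
        names.extend("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=m))
    return names


def kmer_featurize(s: SequenceSet, kmax: int = 5) -> FeatureMatrix:
    """Overlapping k-mer frequencies for k = 1..kmax.

    For each k the 4^k frequencies are counts divided by L - k + 1, so each
    k-block of a row sums to 1; the total dimension is sum_{m<=kmax} 4^m
    (1364 at kmax = 5).
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    names = kmer_feature_names(kmax)
    index = {kmer: i for i, kmer in enumerate(names)}
    rows = []
    for rec in s.records:
        if rec.length < kmax:
            raise ValueError(
                f"sequence {rec.id!r} ({rec.length} nt) shorter than kmax={kmax}"
            )
        vec = np.zeros(len(names))
        for m in range(1, kmax + 1):
            denom = rec.length - m + 1
            for start in range(denom):
                vec[index[rec.seq[start:start + m]]] += 1.0 / denom
        rows.append(vec)
    X = np.array(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(ids=[r.id for r in s.records], X=X, feature_names=names, kind="kmer")


@dataclass
class FScoreTable:
    """Per-feature F-scores with class means; sorted descending (inf first)."""

    table: pd.DataFrame  # columns: feature, fscore, infinite, mean_all, mean_pos, mean_neg
    n_pos: int
    n_neg: int

    def top(self, k: int) -> list[str]:
        return self.table["feature"].head(k).tolist()

    def rank_of(self, feature: str) -> int:
        """1-based rank of a feature in the descending F-score order."""
        hits = self.table.index[self.table["feature"] == feature]
        if len(hits) == 0:
            raise KeyError(feature)
        return int(hits[0]) + 1

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fscore_rank(fm: FeatureMatrix) -> FScoreTable:
    """Rank features by F-score: squared class-mean separation over pooled
    within-class sample variance.

    A zero denominator with positive numerator is flagged infinite and ranks
    first; 0/0 (a feature constant everywhere) scores 0.
    """
    if fm.labels is None:
        raise ValueError("feature matrix has no labels")
    pos_mask = fm.labels == 1
    neg_mask = fm.labels == -1
    n_pos, n_neg = int(pos_mask.sum()), int(neg_mask.sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 samples per class for F-scores")
    Xp, Xn = fm.X[pos_mask], fm.X[neg_mask]
    m_all = fm.X[pos_mask | neg_mask].mean(axis=0)
    m_pos = Xp.mean(axis=0)
    m_neg = Xn.mean(axis=0)
    numer = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
    denom = Xp.var(axis=0, ddof=1) + Xn.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, numer / np.where(denom > 0, denom, 1), 0.0)
    infinite = (denom == 0) & (numer > 0)
    f = np.where(infinite, np.inf, f)
    df = pd.DataFrame({
        "feature": fm.feature_names,
        "fscore": f,
        "infinite": infinite,
        "mean_all": m_all,
        "mean_pos": m_pos,
        "mean_neg": m_neg,
    })
    df = df.sort_values("fscore", ascending=False, kind="stable").reset_index(drop=True)
    return FScoreTable(table=df, n_pos=n_pos, n_neg=n_neg)


def combine_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of two feature matrices over the same rows.

    Names get class prefixes (e.g. ``ppm:1U``, ``kmer:ACG``) so the combined
    names stay unique; combining with an empty (0-column) matrix is the
    identity.
    """
    if b.n_features == 0:
        return a
    if a.n_features == 0:
        return b
    if a.ids != b.ids:
        raise ValueError("feature matrices cover different sequences or orders")
    if a.labels is not None and b.labels is not None and not np.array_equal(a.labels, b.labels):
        raise ValueError("feature matrices disagree on labels")
    pa, pb = a.kind or "a", b.kind or "b"
    names = [f"{pa}:{n}" for n in a.feature_names] + [f"{pb}:{n}" for n in b.feature_names]
    return FeatureMatrix(
        ids=list(a.ids),
        X=np.hstack([a.X, b.X]),
        feature_names=names,
        labels=a.labels if a.labels is not None else b.labels,
        kind="combined",
    )


def combine_rows(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Stack two feature matrices with identical columns row-wise."""
    if a.feature_names != b.feature_names:
        raise ValueError("row-wise combination requires identical feature columns")
    if (a.labels is None) != (b.labels is None):
        raise ValueError("cannot stack a labeled and an unlabeled matrix")
    labels = None if a.labels is None else np.concatenate([a.labels, b.labels])
    return FeatureMatrix(
        ids=list(a.ids) + list(b.ids),
        X=np.vstack([a.X, b.X]) if a.n_samples + b.n_samples else a.X,
        feature_names=list(a.feature_names),
        labels=labels,
        kind=a.kind,
    )


def with_labels(fm: FeatureMatrix, label: int) -> FeatureMatrix:
    """Return a copy of ``fm`` with every row labeled +1 or -1."""
    if label not in (1, -1):
        raise ValueError("label must be +1 or -1")
    return FeatureMatrix(
        ids=list(fm.ids), X=fm.X.copy(), feature_names=list(fm.feature_names),
        labels=np.full(fm.n_samples, label, dtype=int), kind=fm.kind,
    )


@dataclass(frozen=True)
class FeatureSpec:
    """How sequences are turned into feature rows.

    kind: 'ppm' (positional log-odds, 8w dims), 'kmer' (composition,
    sum 4^m dims) or 'both' (prefixed concatenation).
    """

    kind: Literal["ppm", "kmer", "both"] = "ppm"
    window: int = 10
    kmax: int = 5
    binary: bool = False
    pseudocount: float = 0.0


def featurize(
    s: SequenceSet, spec: FeatureSpec, matrix: ScoreMatrix | None = None
) -> FeatureMatrix:
    """Apply a :class:`FeatureSpec`; PPM-based specs need the ScoreMatrix
    computed from the *training* data (never from the query set)."""
    if spec.kind in ("ppm", "both") and matrix is None:
        raise ValueError("PPM featurization requires a ScoreMatrix")
    if spec.kind == "ppm":
        return ppm_featurize(s, matrix, binary=spec.binary)
    if spec.kind == "kmer":
        return kmer_featurize(s, spec.kmax)
    # both: the k-mer side must skip the same too-short sequences
    sub = SequenceSet(
        records=[r for r in s.records if r.length >= matrix.window], label=s.label
    )
    return combine_features(
        ppm_featurize(sub, matrix, binary=spec.binary), kmer_featurize(sub, spec.kmax)
    )


def labeled_feature_matrix(
    positives: SequenceSet,
    negatives: SequenceSet,
    spec: FeatureSpec,
    matrix: ScoreMatrix | None = None,
) -> FeatureMatrix:
    """Featurize a positive and a negative set into one labeled matrix."""
    return combine_rows(
        with_labels(featurize(positives, spec, matrix), 1),
        with_labels(featurize(negatives, spec, matrix), -1),
    )
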