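"""Construction of negative (background) training sets.

Two negative-set styles are built from a user-supplied pool of longer
non-coding RNA sequences, both length-matched exactly to the positive set:

* "random" negatives — the pool is cut into non-overlapping segments, each
  segment's nucleotides are uniformly permuted to destroy any functional
  sequence structure, and segments are sampled so the length histogram
  equals that of the positives.
* "fragment" negatives — identical pipeline without the permutation step;
  segments stay verbatim substrings of the pool, emulating degradation
  fragments of longer small RNAs.

A third style (curated confusable RNAs such as fungal milRNAs) is not
constructed here; such sets are plain FASTA files loaded through
:mod:`qirnaforest.seqio`.

All randomness is driven by explicit integer seeds; identical seeds give
identical output.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)


class ShortfallError(ValueError):
    """Raised when a pool cannot supply enough segments of a required length."""

    def __init__(self, deficits: dict[int, int]):
        self.deficits = dict(deficits)
        detail = ", ".join(f"{l} nt: short by {d}" for l, d in sorted(deficits.items()))
        super().__init__(f"pool cannot supply required segment lengths ({detail})")


@dataclass
class LengthHistogram:
    """Counts of sequences per length (nt)."""

    counts: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_sequences(cls, s: SequenceSet) -> "LengthHistogram":
        return cls(counts=dict(Counter(r.length for r in s.records)))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, LengthHistogram):
            return NotImplemented
        return {k: v for k, v in self.counts.items() if v} == {
            k: v for k, v in other.counts.items() if v
        }


def length_histogram(s: SequenceSet) -> LengthHistogram:
    """Exact per-length counts of a sequence set."""
    return LengthHistogram.from_sequences(s)


def fragment_pool(
    pool: SequenceSet, target: LengthHistogram, seed: int
) -> SequenceSet:
    """Cut non-overlapping segments from pool sequences to meet a length demand.

    Pool sequences are visited in a seeded random order and consumed left to
    right; each cut's length is drawn from the lengths still in demand,
    weighted by remaining demand, which guarantees disjoint source intervals
    and exact demand coverage whenever pool capacity suffices.

    Raises
    ------
    ShortfallError
        If some demanded length cannot be supplied, listing the deficient
        lengths.
    """
    rng = np.random.default_rng(seed)
    demand = {l: c for l, c in target.counts.items() if c > 0}
    if not demand:
        return SequenceSet(records=[], label="negative")
    segments: list[SequenceRecord] = []
    order = rng.permutation(len(pool.records))
    for idx in order:
        if not demand:
            break
        rec = pool.records[idx]
        offset = 0
        while demand and offset < rec.length:
            feasible = [l for l in demand if offset + l <= rec.length]
            if not feasible:
                break
            weights = np.array([demand[l] for l in feasible], dtype=float)
            l = int(rng.choice(feasible, p=weights / weights.sum()))
            segments.append(
                SequenceRecord(
                    id=f"{rec.id}|{offset}-{offset + l}",
                    seq=rec.seq[offset:offset + l],
                )
            )
            offset += l
            demand[l] -= 1
            if demand[l] == 0:
                del demand[l]
    if demand:
        raise ShortfallError(demand)
    return SequenceSet(records=segments, label="negative")


def shuffle_sequence(r: SequenceRecord, seed: int, rounds: int = 1) -> SequenceRecord:
    """Uniformly permute a sequence's characters, preserving its composition.

    One uniform permutation already destroys positional structure; ``rounds``
    composes additional permutations for literal reproduction of repeated-
    shuffle protocols (the composition of uniform shuffles is itself a
    uniform shuffle, so the distribution is unchanged).
    """
    rng = np.random.default_rng(seed)
    chars = np.array(list(r.seq))
    for _ in range(max(1, rounds)):
        chars = chars[rng.permutation(len(chars))]
    return SequenceRecord(id=r.id, seq="".join(chars), description=r.description)


def shuffle_dinucleotide(r: SequenceRecord, seed: int) -> SequenceRecord:
    """Dinucleotide-preserving shuffle (Altschul–Erickson style Euler walk).

    Preserves the exact dinucleotide multiset of the input. Off by default in
    the negative-set pipelines; exposed for sensitivity analysis.
    """
    rng = np.random.default_rng(seed)
    seq = r.seq
    if len(seq) < 3:
        return r
    # Build adjacency multigraph of the de Bruijn walk and sample an Eulerian
    # path with the same start/end vertices by repeated arc shuffling.
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    for _ in range(1000):
        trial = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        out = [seq[0]]
        cursor = {a: 0 for a in trial}
        node = seq[0]
        ok = True
        total = sum(len(b) for b in trial.values())
        for _step in range(total):
            lst = trial.get(node, [])
            if cursor[node] >= len(lst):
                ok = False
                break
            nxt = lst[cursor[node]]
            cursor[node] += 1
            out.append(nxt)
            node = nxt
        if ok and node == last and len(out) == len(seq):
            return SequenceRecord(id=r.id, seq="".join(out), description=r.description)
    logger.warning("dinucleotide shuffle failed to find an Eulerian walk; returning input")
    return r


def sample_matched(
    candidates: SequenceSet, target: LengthHistogram, seed: int
) -> SequenceSet:
    """Sample candidates without replacement so the output length histogram
    equals ``target`` exactly (uniform within each length class)."""
    rng = np.random.default_rng(seed)
    by_length: dict[int, list[SequenceRecord]] = {}
    for rec in candidates.records:
        by_length.setdefault(rec.length, []).append(rec)
    deficits = {
        l: c - len(by_length.get(l, []))
        for l, c in target.counts.items()
        if c > len(by_length.get(l, []))
    }
    if deficits:
        raise ShortfallError(deficits)
    chosen: list[SequenceRecord] = []
    for l in sorted(k for k, c in target.counts.items() if c > 0):
        bucket = by_length[l]
        picks = rng.choice(len(bucket), size=target.counts[l], replace=False)
        chosen.extend(bucket[i] for i in sorted(picks))
    return SequenceSet(records=chosen, label="negative")


def _inflated(target: LengthHistogram) -> LengthHistogram:
    # ~10% spare per length so negatives colliding with positives can be
    # replaced without re-fragmenting.
    return LengthHistogram(
        counts={l: c + max(1, c // 10) for l, c in target.counts.items() if c > 0}
    )


def _build(
    pool: SequenceSet,
    positives: SequenceSet,
    seed: int,
    shuffle: bool,
    shuffle_rounds: int = 1,
    dinucleotide: bool = False,
) -> SequenceSet:
    if len(pool) == 0:
        raise ValueError("negative source pool is empty")
    target = LengthHistogram.from_sequences(positives)
    root = np.random.SeedSequence(seed)
    frag_seed, shuf_seed, pick_seed = (int(s.generate_state(1)[0] % 2**31)
                                       for s in root.spawn(3))
    try:
        candidates = fragment_pool(pool, _inflated(target), frag_seed)
    except ShortfallError:
        candidates = fragment_pool(pool, target, frag_seed)
    if shuffle:
        shuf_rng = np.random.default_rng(shuf_seed)
        shuffled = []
        for rec in candidates.records:
            sub = int(shuf_rng.integers(0, 2**31))
            if dinucleotide:
                shuffled.append(shuffle_dinucleotide(rec, sub))
            else:
                shuffled.append(shuffle_sequence(rec, sub, rounds=shuffle_rounds))
        candidates = SequenceSet(records=shuffled, label="negative")
    # Negatives identical to a positive would contradict the labels.
    pos_seqs = set(positives.sequences)
    clean = [r for r in candidates.records if r.seq not in pos_seqs]
    dropped = len(candidates.records) - len(clean)
    if dropped:
        logger.info("dropped %d candidate segment(s) identical to a positive", dropped)
    return sample_matched(SequenceSet(records=clean, label="negative"), target, pick_seed)


def build_random_negatives(
    pool: SequenceSet,
    positives: SequenceSet,
    seed: int,
    shuffle_rounds: int = 1,
    dinucleotide: bool = False,
) -> SequenceSet:
    """Shuffled, length-matched pool segments: fragment -> shuffle -> sample.

    Output size equals the positive set's size and its length histogram
    matches the positives' exactly.
    """
    return _build(pool, positives, seed, shuffle=True,
                  shuffle_rounds=shuffle_rounds, dinucleotide=dinucleotide)


def build_fragment_negatives(
    pool: SequenceSet, positives: SequenceSet, seed: int
) -> SequenceSet:
    """Length-matched verbatim pool segments (no shuffling); analogue of
    degradation fragments of longer small RNAs."""
    return _build(pool, positives, seed, shuffle=False)
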