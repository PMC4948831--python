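"""Reading, validating and writing short-RNA sequence sets in FASTA.

Sequences are normalized to the RNA alphabet {A, C, G, U}: input is
uppercased and T is mapped to U, so DNA- and RNA-style FASTA files are
interchangeable. Records whose sequence contains any other character are
considered ambiguous and can be dropped with :func:`filter_ambiguous`;
exact duplicate sequences (first occurrence kept) are removed with
:func:`deduplicate`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGU")
_NORMALIZE = str.maketrans({"t": "U", "T": "U", "a": "A", "c": "C", "g": "G", "u": "U"})
_VALID_RE = re.compile(r"^[ACGU]+$")

Label = Literal["positive", "negative", "unlabeled"]


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


def normalize_sequence(raw: str) -> str:
    """Uppercase and map T->U; characters outside {A,C,G,T,U} are only
    uppercased, leaving ambiguity detection to :func:`filter_ambiguous`."""
    return raw.translate(_NORMALIZE).upper()


@dataclass(frozen=True)
class SequenceRecord:
    """One short RNA sequence with an identifier.

    ``seq`` is stored normalized (uppercase, T mapped to U). ``description``
    keeps any FASTA header text after the first whitespace; it plays no role
    in identity or deduplication.
    """

    id: str
    seq: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    def is_valid(self) -> bool:
        """True when the sequence is non-empty and uses only A/C/G/U."""
        return bool(_VALID_RE.match(self.seq))


@dataclass
class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with a class label."""

    records: list[SequenceRecord] = field(default_factory=list)
    label: Label = "unlabeled"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    @property
    def lengths(self) -> list[int]:
        return [r.length for r in self.records]

    def with_label(self, label: Label) -> "SequenceSet":
        return SequenceSet(records=list(self.records), label=label)


def read_fasta(path: str | Path, label: Label = "unlabeled") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequences are normalized (uppercase, T->U); file order is preserved and
    duplicate headers are allowed. An empty file yields an empty set with a
    logged warning.

    Raises
    ------
    FastaParseError
        If the file contains non-FASTA content (text before the first ``>``
        header); the error names the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        # Biopython silently skips leading junk; reject it explicitly.
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} is not a FASTA header: {line.strip()!r}"
                )
            break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(
            SequenceRecord(id=entry.id, seq=normalize_sequence(str(entry.seq)), description=desc)
        )
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return SequenceSet(records=records, label=label)


def write_fasta(s: SequenceSet, path: str | Path) -> None:
    """Write a :class:`SequenceSet` as single-line-body FASTA.

    Round-trips losslessly through :func:`read_fasta` for ids and sequences.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for r in s.records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(f"{header}\n{r.seq}\n")


def filter_ambiguous(s: SequenceSet) -> tuple[SequenceSet, int]:
    """Drop records containing undefined bases (anything outside A/C/G/U
    after normalization). Returns the filtered set and the removal count."""
    kept = [r for r in s.records if r.is_valid()]
    removed = len(s.records) - len(kept)
    if removed:
        logger.info("filter_ambiguous: removed %d record(s) with undefined bases", removed)
    return SequenceSet(records=kept, label=s.label), removed


def deduplicate(s: SequenceSet) -> tuple[SequenceSet, int]:
    """Remove exact duplicate sequences, keeping the first occurrence.

    Identity is full-string equality of the normalized sequence; ids and
    descriptions are ignored. Returns the deduplicated set and the count
    removed.
    """
    seen: set[str] = set()
    kept = []
    for r in s.records:
        if r.seq in seen:
            continue
        seen.add(r.seq)
        kept.append(r)
    removed = len(s.records) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d duplicate record(s)", removed)
    return SequenceSet(records=kept, label=s.label), removed


def from_strings(seqs: Iterable[str], label: Label = "unlabeled", prefix: str = "seq") -> SequenceSet:
    """Build a SequenceSet from bare sequence strings (normalized)."""
    records = [
        SequenceRecord(id=f"{prefix}{i + 1}", seq=normalize_sequence(s))
        for i, s in enumerate(seqs)
    ]
    return SequenceSet(records=records, label=label)
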