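"""Core data types for annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout (GenBank convention).
Origin-spanning features on a circular genome are represented with
``end < start``; their span length is computed modulo the genome length.
Strands are labelled ``H`` (heavy) and ``L`` (light); GenBank
``complement(..)`` locations map to ``L``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_NUCLEOTIDES",
    "FEATURE_CLASSES",
    "GenomeRecord",
    "Feature",
    "GeneTable",
    "ValidationError",
]

IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")
FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control")

_GAP_RE = re.compile(r"[NRYSWKMBDHV]+")


class ValidationError(ValueError):
    """An object violates a structural invariant."""


def _check_alphabet(sequence: str) -> None:
    bad = sorted(set(sequence.upper()) - IUPAC_NUCLEOTIDES)
    if bad:
        raise ValidationError(
            "non-IUPAC nucleotide symbols: %s" % ", ".join(repr(b) for b in bad)
        )


@dataclass
class GenomeRecord:
    """A (possibly partial) nucleotide sequence with declared length.

    ``sequence`` may be absent (annotation-only mode, e.g. a GenBank
    record without an ORIGIN block).  ``gap_runs`` lists 1-based
    inclusive intervals of ambiguous/unknown sequence.
    """

    id: str
    length: int
    circular: bool = True
    sequence: str | None = None
    gap_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"genome length must be positive, got {self.length}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            _check_alphabet(self.sequence)
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
            if not self.gap_runs:
                self.gap_runs = [
                    (m.start() + 1, m.end()) for m in _GAP_RE.finditer(self.sequence)
                ]

    @classmethod
    def from_sequence(cls, id: str, sequence: str, circular: bool = True) -> "GenomeRecord":
        return cls(id=id, length=len(sequence), circular=circular, sequence=sequence)

    def slice(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval, wrapping the origin
        when ``end < start`` on a circular genome."""
        if self.sequence is None:
            raise ValidationError(f"record {self.id} has no sequence (annotation-only)")
        if not (1 <= start <= self.length and 1 <= end <= self.length):
            raise ValidationError(
                f"interval {start}-{end} outside genome 1-{self.length}"
            )
        if end >= start:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValidationError(
                f"interval {start}-{end} wraps the origin of a linear genome"
            )
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass
class Feature:
    """One annotated gene or region on the genome."""

    name: str
    klass: str
    strand: str | None
    start: int
    end: int
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    declared_length: int | None = None
    declared_ovl_its: int | None = None  # printed junction value, never trusted

    def __post_init__(self) -> None:
        if self.klass not in FEATURE_CLASSES:
            raise ValidationError(
                f"{self.name}: unknown feature class {self.klass!r}; "
                f"expected one of {FEATURE_CLASSES}"
            )
        if self.strand not in ("H", "L", None):
            raise ValidationError(f"{self.name}: strand must be H, L or None")
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.name}: coordinates must be >= 1")

    def span_length(self, genome_length: int) -> int:
        """end - start + 1, wrapping the origin when end < start."""
        if self.end >= self.start:
            return self.end - self.start + 1
        return self.end + genome_length - self.start + 1

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start


@dataclass
class GeneTable:
    """Ordered collection of features on one genome, sorted by start."""

    features: list[Feature]
    genome_length: int
    circular: bool = True

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: f.start)
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValidationError(f"duplicate gene name: {f.name}")
            seen.add(f.name)
            if f.start > self.genome_length or f.end > self.genome_length:
                raise ValidationError(
                    f"{f.name}: coordinates {f.start}-{f.end} exceed genome "
                    f"length {self.genome_length}"
                )
            if f.wraps_origin and not self.circular:
                raise ValidationError(
                    f"{f.name}: origin-spanning feature on a linear genome"
                )

    def by_class(self, klass: str) -> list[Feature]:
        return [f for f in self.features if f.klass == klass]

    @property
    def pcgs(self) -> list[Feature]:
        return self.by_class("PCG")

    @property
    def trnas(self) -> list[Feature]:
        return self.by_class("tRNA")

    @property
    def rrnas(self) -> list[Feature]:
        return self.by_class("rRNA")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name or f.name.split("(")[0] == name:
                return f
        raise KeyError(name)
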