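"""Base counts, AT/GC skew, and the per-class / per-codon-position
composition breakdown.

Skews follow AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C).
Ambiguous bases (N, R, Y, ...) are excluded from skew numerators and
denominators and from A+T%, so unknown stretches cannot bias the
statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio.Seq import Seq

from .model import Feature, GeneTable, GenomeRecord, ValidationError

__all__ = [
    "CompositionStats",
    "CompositionTable",
    "composition",
    "composition_table",
    "round_half_up",
    "COMPOSITION_ROWS",
]

COMPOSITION_ROWS = (
    "whole_genome",
    "protein_coding_genes",
    "codon_position_1",
    "codon_position_2",
    "codon_position_3",
    "tRNA_genes",
    "rRNA_genes",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used for display (matches printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionStats:
    counts: dict
    ambiguous: int

    @property
    def length(self) -> int:
        return sum(self.counts.values()) + self.ambiguous

    @property
    def unambiguous(self) -> int:
        return sum(self.counts.values())

    def fraction(self, base: str) -> float | None:
        return self.counts[base] / self.unambiguous if self.unambiguous else None

    @property
    def at_percent(self) -> float | None:
        if not self.unambiguous:
            return None
        return 100.0 * (self.counts["A"] + self.counts["T"]) / self.unambiguous

    @property
    def at_skew(self) -> float | None:
        at = self.counts["A"] + self.counts["T"]
        return (self.counts["A"] - self.counts["T"]) / at if at else None

    @property
    def gc_skew(self) -> float | None:
        gc = self.counts["G"] + self.counts["C"]
        return (self.counts["G"] - self.counts["C"]) / gc if gc else None

    def percent_row(self) -> dict:
        """Display row rounded half-up to one decimal (T%, C%, A%, G%, A+T%,
        AT-skew, GC-skew; skews to three decimals)."""
        def pct(base):
            f = self.fraction(base)
            return None if f is None else round_half_up(100 * f, 1)

        return {
            "T%": pct("T"),
            "C%": pct("C"),
            "A%": pct("A"),
            "G%": pct("G"),
            "A+T%": None if self.at_percent is None else round_half_up(self.at_percent, 1),
            "AT-skew": None if self.at_skew is None else round_half_up(self.at_skew, 3),
            "GC-skew": None if self.gc_skew is None else round_half_up(self.gc_skew, 3),
        }


def composition(seq: str) -> CompositionStats:
    """Exact base counts and skew statistics for one sequence."""
    seq = seq.upper()
    c = Counter(seq)
    counts = {b: c.get(b, 0) for b in "ATGC"}
    ambiguous = len(seq) - sum(counts.values())
    return CompositionStats(counts=counts, ambiguous=ambiguous)


def _merge(parts: list[str]) -> CompositionStats:
    return composition("".join(parts))


def sense_sequence(record: GenomeRecord, feature: Feature) -> str:
    """Feature sequence on its sense strand (reverse complement for L)."""
    seq = record.slice(feature.start, feature.end)
    if feature.strand == "L":
        seq = str(Seq(seq).reverse_complement())
    return seq


@dataclass
class CompositionTable:
    rows: dict  # row name -> CompositionStats

    def percent_table(self) -> list[tuple[str, dict]]:
        return [(name, stats.percent_row()) for name, stats in self.rows.items()]


def _pcg_sequence(record: GenomeRecord, feature: Feature, include_stops: bool) -> str:
    seq = sense_sequence(record, feature)
    if not include_stops:
        rem = len(seq) % 3
        seq = seq[: len(seq) - (rem if rem else 3)]
    return seq


def composition_table(
    record: GenomeRecord,
    table: GeneTable,
    include_stop_codons: bool = True,
) -> CompositionTable:
    """Composition of the whole genome, the protein genes (sense strand,
    concatenated in genome order), their three codon positions, and the
    tRNA/rRNA gene classes.

    Codon positions are assigned per gene by frame from the start codon; a
    trailing incomplete stop contributes its 1-2 bases to positions 1-2.
    With ``include_stop_codons=False`` the final (complete or incomplete)
    stop of each protein gene is dropped first.
    """
    if record.sequence is None:
        raise ValidationError("composition requires sequence (annotation-only input)")
    pcg_seqs = []
    pos_parts: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for f in table.pcgs:
        seq = _pcg_sequence(record, f, include_stop_codons)
        pcg_seqs.append(seq)
        for frame in range(3):
            pos_parts[frame].append(seq[frame::3])
    rows = {
        "whole_genome": composition(record.sequence),
        "protein_coding_genes": _merge(pcg_seqs),
        "codon_position_1": _merge(pos_parts[0]),
        "codon_position_2": _merge(pos_parts[1]),
        "codon_position_3": _merge(pos_parts[2]),
        "tRNA_genes": _merge([sense_sequence(record, f) for f in table.trnas]),
        "rRNA_genes": _merge([sense_sequence(record, f) for f in table.rrnas]),
    }
    return CompositionTable(rows=rows)
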