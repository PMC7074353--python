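"""Circular-genome junction arithmetic.

For consecutive features in coordinate order (wrapping last -> first on a
circular genome) the junction gap is ``downstream.start - upstream.end - 1``:
negative values are overlaps (OVL), positive values intergenic spacers
(ITS), zero means the genes abut exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Feature, GeneTable

__all__ = [
    "JunctionGap",
    "OrganizationSummary",
    "LengthDiscrepancy",
    "junction_gaps",
    "summarize_organization",
    "audit_lengths",
    "stop_codon_bp",
]

# bp occupied by each stop-codon annotation (T/TA are incomplete stops)
_STOP_BP = {"TAA": 3, "TAG": 3, "TGA": 3, "TA": 2, "T": 1}


@dataclass(frozen=True)
class JunctionGap:
    upstream: str
    downstream: str
    gap: int  # negative = overlap, positive = spacer, 0 = contiguous


@dataclass
class OrganizationSummary:
    overlap_total_bp: int
    overlap_junctions: int
    overlap_range: tuple[int, int] | None
    spacer_total_bp: int
    spacer_positions: int
    spacer_range: tuple[int, int] | None
    largest_spacer: tuple[int, str, str] | None
    strand_counts: dict[str, int]
    class_totals: dict[str, int]
    stop_codon_bp: int | None = None
    encoded_residues: int | None = None

    def as_json_dict(self) -> dict:
        return {
            "overlap_bp": self.overlap_total_bp,
            "overlap_n": self.overlap_junctions,
            "spacer_bp": self.spacer_total_bp,
            "spacer_n": self.spacer_positions,
            "largest_spacer": list(self.largest_spacer) if self.largest_spacer else None,
            "strand_H": self.strand_counts.get("H", 0),
            "strand_L": self.strand_counts.get("L", 0),
        }


@dataclass(frozen=True)
class LengthDiscrepancy:
    name: str
    declared: int
    computed: int


def _effective_end(f: Feature, genome_length: int) -> int:
    # unwrap origin-spanning features into linear coordinates past the end
    return f.end + genome_length if f.wraps_origin else f.end


def junction_gaps(table: GeneTable) -> list[JunctionGap]:
    """Signed gaps between consecutive features in genome order.

    On a circular table the wrap-around junction (last feature back to the
    first) is included; a single feature yields its self-junction unless it
    tiles the whole circle.
    """
    feats = table.features
    L = table.genome_length
    if not feats:
        return []
    if len(feats) == 1:
        f = feats[0]
        if not table.circular or f.span_length(L) == L:
            return []
        gap = f.start + L - _effective_end(f, L) - 1
        return [JunctionGap(f.name, f.name, gap)]
    gaps = []
    for up, down in zip(feats, feats[1:]):
        gaps.append(JunctionGap(up.name, down.name, down.start - up.end - 1))
    if table.circular:
        up, down = feats[-1], feats[0]
        gaps.append(JunctionGap(up.name, down.name, down.start + L - _effective_end(up, L) - 1))
    return gaps


def stop_codon_bp(table: GeneTable) -> int | None:
    """Total bp occupied by annotated stop codons over all protein genes.

    Complete TAA/TAG stops count 3 bp, incomplete T/TA stops 1/2 bp.
    Returns None when any protein gene lacks a stop annotation.
    """
    total = 0
    for f in table.pcgs:
        if f.stop_codon is None:
            return None
        bp = _STOP_BP.get(f.stop_codon.upper().replace("U", "T"))
        if bp is None:
            return None
        total += bp
    return total


def summarize_organization(table: GeneTable) -> OrganizationSummary:
    """Aggregate junction gaps, strand usage and per-class length totals.

    The control region participates in junction arithmetic but is excluded
    from gene strand counts.  Largest-spacer ties break to the first
    junction in genome order.
    """
    gaps = junction_gaps(table)
    overlaps = [g for g in gaps if g.gap < 0]
    spacers = [g for g in gaps if g.gap > 0]
    largest = None
    for g in spacers:
        if largest is None or g.gap > largest.gap:
            largest = g

    strand_counts = {"H": 0, "L": 0}
    for f in table:
        if f.klass != "control" and f.strand in strand_counts:
            strand_counts[f.strand] += 1

    class_totals = {
        klass: sum(f.span_length(table.genome_length) for f in table.by_class(klass))
        for klass in ("PCG", "tRNA", "rRNA")
    }

    stops = stop_codon_bp(table)
    residues = None
    if stops is not None:
        coding = class_totals["PCG"] - stops
        residues = coding // 3 if coding % 3 == 0 else None

    return OrganizationSummary(
        overlap_total_bp=sum(-g.gap for g in overlaps),
        overlap_junctions=len(overlaps),
        overlap_range=(min(-g.gap for g in overlaps), max(-g.gap for g in overlaps))
        if overlaps
        else None,
        spacer_total_bp=sum(g.gap for g in spacers),
        spacer_positions=len(spacers),
        spacer_range=(min(g.gap for g in spacers), max(g.gap for g in spacers))
        if spacers
        else None,
        largest_spacer=(largest.gap, largest.upstream, largest.downstream)
        if largest
        else None,
        strand_counts=strand_counts,
        class_totals=class_totals,
        stop_codon_bp=stops,
        encoded_residues=residues,
    )


def audit_lengths(table: GeneTable) -> list[LengthDiscrepancy]:
    """Flag features whose declared length disagrees with the coordinate span."""
    out = []
    for f in table:
        if f.declared_length is None:
            continue
        computed = f.span_length(table.genome_length)
        if computed != f.declared_length:
            out.append(LengthDiscrepancy(f.name, f.declared_length, computed))
    return out
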