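"""Synthetic annotated mitogenomes and diverged coding alignments with
known ground truth.

The default genome layout is the 37-gene ancestral insect arrangement
(13 protein genes, 22 tRNAs, 2 rRNAs, AT-rich control region) with
small junction overlaps/spacers; all randomness flows from a single
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Seq import Seq

from .genetic_codes import BASES, DEFAULT_TABLE_ID, get_code
from .model import Feature, GeneTable, GenomeRecord, ValidationError

__all__ = [
    "GeneSpecEntry",
    "GenomeSpec",
    "EvolSpec",
    "EvolResult",
    "default_gene_order",
    "generate_genome",
    "evolve_cds",
]


@dataclass(frozen=True)
class GeneSpecEntry:
    name: str
    klass: str
    strand: str
    length: int
    anticodon: str | None = None


def default_gene_order() -> list[GeneSpecEntry]:
    """The packaged 37-gene arrangement (control region excluded; it is
    sized from the leftover circle)."""
    from .io import read_gene_table  # local import: avoid cycle

    ref = resources.files("mitoprofile.data") / "amara_aulica_gene_table.tsv"
    with resources.as_file(ref) as path:
        table = read_gene_table(path, genome_length=16646, circular=True)
    return [
        GeneSpecEntry(
            name=f.name,
            klass=f.klass,
            strand=f.strand,
            length=f.span_length(table.genome_length),
            anticodon=f.anticodon,
        )
        for f in table
        if f.klass != "control"
    ]


# junction-gap population sampled uniformly: mostly contiguous/short
# spacers, occasional small overlaps, rare long spacer
DEFAULT_GAP_CHOICES = (-2, -1, -1, 0, 0, 0, 0, 0, 1, 1, 1, 2, 2, 3, 4, 6, 10)


@dataclass
class GenomeSpec:
    genome_length: int = 16646
    gene_order: list[GeneSpecEntry] | None = None
    at_bias: float = 0.80
    gap_choices: tuple[int, ...] = DEFAULT_GAP_CHOICES
    nonstandard_start_genes: tuple[str, ...] = ()
    seed: int = 0

    def resolved_order(self) -> list[GeneSpecEntry]:
        return list(self.gene_order) if self.gene_order is not None else default_gene_order()


def _codon_at_bias(target: float, table_id: int) -> float:
    """Per-base A/T probability whose accepted (non-stop) codons have the
    target A+T fraction, solved by bisection."""
    code = get_code(table_id)

    def accepted_at_fraction(a: float) -> float:
        p = {"A": a / 2, "T": a / 2, "G": (1 - a) / 2, "C": (1 - a) / 2}
        total_p = total_at = 0.0
        for codon in code.sense_codons:
            pc = p[codon[0]] * p[codon[1]] * p[codon[2]]
            total_p += pc
            total_at += pc * sum(1 for b in codon if b in "AT") / 3.0
        return total_at / total_p

    lo, hi = 0.01, 0.999
    for _ in range(60):
        mid = (lo + hi) / 2
        if accepted_at_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sample_sense_codons(rng, n: int, at_prob: float, code) -> list[str]:
    p = np.array([at_prob / 2, at_prob / 2, (1 - at_prob) / 2, (1 - at_prob) / 2])
    bases = np.array(list("ATGC"))
    out: list[str] = []
    while len(out) < n:
        draw = rng.choice(bases, size=(max(16, n - len(out)), 3), p=p)
        for row in draw:
            codon = "".join(row)
            if not code.is_stop(codon):
                out.append(codon)
                if len(out) == n:
                    break
    return out


def generate_genome(spec: GenomeSpec) -> tuple[GenomeRecord, GeneTable]:
    """Build a deterministic annotated circular genome from a spec.

    Protein genes begin with ATN (or an injected nonstandard start), end
    with TAA/TAG, or with an incomplete T/TA stop when the declared length
    is not a multiple of 3.  Adjacent protein genes are never allowed to
    overlap so their codon structure survives placement.
    """
    rng = np.random.default_rng(spec.seed)
    code = get_code(DEFAULT_TABLE_ID)
    order = spec.resolved_order()
    if not order:
        raise ValidationError("gene order is empty")

    # place genes sequentially, drawing a junction gap after each
    placements: list[tuple[GeneSpecEntry, int, int]] = []
    pos = 1
    for i, g in enumerate(order):
        start = pos
        end = start + g.length - 1
        placements.append((g, start, end))
        if i + 1 < len(order):
            nxt = order[i + 1]
            gap = int(rng.choice(spec.gap_choices))
            if g.klass == "PCG" and nxt.klass == "PCG":
                gap = max(gap, 0)
            if gap < 0 and -gap >= min(g.length, nxt.length):
                gap = 0
            pos = end + gap + 1
        else:
            pos = end + 1
    control_start = pos
    control_length = spec.genome_length - control_start + 1
    if control_length < 50:
        raise ValidationError(
            f"infeasible spec: only {control_length} bp left for the control region"
        )

    # background sequence with the target A+T bias
    p = np.array([spec.at_bias / 2, spec.at_bias / 2, (1 - spec.at_bias) / 2, (1 - spec.at_bias) / 2])
    seq = rng.choice(np.array(list("ATGC")), size=spec.genome_length, p=p)

    codon_bias = _codon_at_bias(spec.at_bias, DEFAULT_TABLE_ID)
    features: list[Feature] = []
    for g, start, end in placements:
        start_codon = stop_codon = None
        if g.klass == "PCG":
            rem = g.length % 3
            if g.name in spec.nonstandard_start_genes:
                start_codon = "CGA"
            else:
                start_codon = str(rng.choice(["ATA", "ATT", "ATG"]))
            if rem == 0:
                stop_codon = str(rng.choice(["TAA", "TAG"]))
                n_internal = g.length // 3 - 2
            else:
                stop_codon = "T" if rem == 1 else "TA"
                n_internal = (g.length - rem) // 3 - 1
            if n_internal < 0:
                raise ValidationError(f"{g.name}: length {g.length} too short for a CDS")
            cds = start_codon + "".join(
                _sample_sense_codons(rng, n_internal, codon_bias, code)
            ) + stop_codon
            if g.strand == "L":
                cds = str(Seq(cds).reverse_complement())
            seq[start - 1 : end] = list(cds)
        features.append(
            Feature(
                name=g.name,
                klass=g.klass,
                strand=g.strand,
                start=start,
                end=end,
                anticodon=g.anticodon,
                start_codon=start_codon,
                stop_codon=stop_codon,
                declared_length=g.length,
            )
        )
    features.append(
        Feature(
            name="control_region",
            klass="control",
            strand=None,
            start=control_start,
            end=spec.genome_length,
            declared_length=control_length,
        )
    )
    record = GenomeRecord(
        id=f"SYN{spec.seed:06d}",
        length=spec.genome_length,
        circular=True,
        sequence="".join(seq),
    )
    table = GeneTable(features=features, genome_length=spec.genome_length, circular=True)
    return record, table


@dataclass
class EvolSpec:
    n_codons: int = 300
    n_taxa: int = 6
    branch_length: float = 0.15  # expected accepted substitutions per codon
    omega_target: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_codons, self.n_taxa) < 1 or self.branch_length < 0 or self.omega_target <= 0:
            raise ValidationError("EvolSpec parameters must be positive")


@dataclass
class EvolResult:
    alignment: list[tuple[str, str]]
    ancestor: str
    branch_counts: dict  # taxon -> (synonymous, nonsynonymous) accepted changes
    pair_counts: dict  # (taxon, taxon) sorted tuple -> (synonymous, nonsynonymous)


def evolve_cds(spec: EvolSpec, table_id: int = DEFAULT_TABLE_ID) -> EvolResult:
    """Diverge taxa from a common ancestor on a star tree.

    Single-base codon changes are proposed uniformly; synonymous proposals
    are always accepted, nonsynonymous ones with probability
    ``omega_target``, and changes creating stop codons are rejected.
    Realized synonymous/nonsynonymous counts are returned as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    code = get_code(table_id)
    sense = list(code.sense_codons)
    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=spec.n_codons)]

    alignment = []
    branch_counts = {}
    for t in range(spec.n_taxa):
        taxon = f"taxon_{t + 1}"
        codons = list(ancestor)
        target = int(rng.poisson(spec.n_codons * spec.branch_length))
        accepted = syn = nonsyn = 0
        guard = 0
        while accepted < target:
            guard += 1
            if guard > 10_000 * (target + 1):
                raise RuntimeError("substitution sampler failed to converge")
            ci = int(rng.integers(spec.n_codons))
            pos = int(rng.integers(3))
            base = BASES[int(rng.integers(4))]
            codon = codons[ci]
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            synonymous = code.translate(mutant) == code.translate(codon)
            if not synonymous and rng.random() >= spec.omega_target:
                continue
            codons[ci] = mutant
            accepted += 1
            if synonymous:
                syn += 1
            else:
                nonsyn += 1
        alignment.append((taxon, "".join(codons)))
        branch_counts[taxon] = (syn, nonsyn)

    pair_counts = {}
    ids = [t for t, _ in alignment]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            si, ni = branch_counts[ids[i]]
            sj, nj = branch_counts[ids[j]]
            pair_counts[(ids[i], ids[j])] = (si + sj, ni + nj)
    return EvolResult(
        alignment=alignment,
        ancestor="".join(ancestor),
        branch_counts=branch_counts,
        pair_counts=pair_counts,
    )
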