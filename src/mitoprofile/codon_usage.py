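"""CDS extraction, start/stop codon classification, codon counting and
relative synonymous codon usage (RSCU).

RSCU(codon) = family_size * count(codon) / family_total, with synonym
families taken from the genetic code (default transl_table 5, the
invertebrate mitochondrial code).  Stop codons, incomplete stops and
codons containing ambiguous bases are excluded from counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .composition import sense_sequence
from .genetic_codes import DEFAULT_TABLE_ID, GeneticCode, get_code
from .model import Feature, GeneTable, GenomeRecord, ValidationError

__all__ = [
    "Cds",
    "RscuRow",
    "RscuTable",
    "StartStopRecord",
    "extract_cds",
    "start_stop_summary",
    "rscu",
]

COMPLETE_STOPS = {"TAA", "TAG"}
ATN_STARTS = {"ATA", "ATT", "ATG", "ATC"}


@dataclass
class Cds:
    """An extracted coding sequence, split into codons on the sense strand.

    ``codons`` covers the full annotated span in frame; when the span
    length is not a multiple of 3 the 1-2 trailing bases are held in
    ``stop_codon`` with ``incomplete_stop=True`` (polyadenylation-completed
    stops).  For complete stops the final codon appears both as
    ``codons[-1]`` and ``stop_codon``.
    """

    gene: str
    codons: list[str]
    start_codon: str
    stop_codon: str
    incomplete_stop: bool

    @property
    def span_bp(self) -> int:
        return 3 * len(self.codons) + (len(self.stop_codon) if self.incomplete_stop else 0)

    def sense_codons(self, code: GeneticCode | None = None) -> list[str]:
        """Codons counted for usage statistics: the stop (complete or
        incomplete) is excluded."""
        code = code or get_code()
        if self.incomplete_stop:
            return list(self.codons)
        if self.codons and code.is_stop(self.codons[-1]):
            return self.codons[:-1]
        return list(self.codons)

    def translate(self, code: GeneticCode | None = None) -> str:
        code = code or get_code()
        return "".join(
            code.translate(c) if set(c) <= set("ACGT") else "X"
            for c in self.sense_codons(code)
        )


def extract_cds(record: GenomeRecord, feature: Feature, table_id: int = DEFAULT_TABLE_ID) -> Cds:
    """Extract a protein gene as in-frame codons on its sense strand.

    The start codon is reported verbatim (no ATN enforcement).  Internal
    stop codons before the final one raise a warning listing positions.
    """
    if feature.klass != "PCG":
        raise ValidationError(f"{feature.name}: extract_cds requires a PCG feature")
    seq = sense_sequence(record, feature)
    code = get_code(table_id)
    n_full = len(seq) // 3
    rem = len(seq) % 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_full)]
    if rem:
        stop = seq[3 * n_full :]
        incomplete = True
    else:
        stop = codons[-1] if codons else ""
        incomplete = False
    internal = [
        i + 1
        for i, c in enumerate(codons[:-1] if not incomplete else codons)
        if set(c) <= set("ACGT") and code.is_stop(c)
    ]
    if internal:
        warnings.warn(
            f"{feature.name}: internal stop codon(s) at codon position(s) "
            + ", ".join(map(str, internal)),
            stacklevel=2,
        )
    return Cds(
        gene=feature.name,
        codons=codons,
        start_codon=codons[0] if codons else "",
        stop_codon=stop,
        incomplete_stop=incomplete,
    )


@dataclass(frozen=True)
class StartStopRecord:
    gene: str
    start_codon: str
    stop_codon: str
    incomplete_stop: bool
    start_is_atn: bool


def start_stop_summary(
    record: GenomeRecord, table: GeneTable, table_id: int = DEFAULT_TABLE_ID
) -> list[StartStopRecord]:
    """Per-gene start/stop codons with ATN-conformity flags.

    Nonstandard starts (like cox1's CGA) are flagged, never corrected."""
    out = []
    for f in table.pcgs:
        cds = extract_cds(record, f, table_id)
        out.append(
            StartStopRecord(
                gene=f.name,
                start_codon=cds.start_codon,
                stop_codon=cds.stop_codon,
                incomplete_stop=cds.incomplete_stop,
                start_is_atn=cds.start_codon in ATN_STARTS,
            )
        )
    return out


@dataclass(frozen=True)
class RscuRow:
    codon: str  # DNA alphabet
    amino_acid: str  # display label (Leu1/Leu2, Ser1/Ser2 sub-families)
    family_size: int
    count: int
    rscu: float

    @property
    def codon_rna(self) -> str:
        return self.codon.replace("T", "U")


@dataclass
class RscuTable:
    rows: list[RscuRow]
    genetic_code: int
    ambiguous_codons: int = 0

    def by_codon(self, codon: str) -> RscuRow:
        codon = codon.upper().replace("U", "T")
        for r in self.rows:
            if r.codon == codon:
                return r
        raise KeyError(codon)

    @property
    def total_codons(self) -> int:
        return sum(r.count for r in self.rows)

    def top_codons(self, k: int = 5) -> list[str]:
        """The k highest-count codons (RNA alphabet), ties by codon order."""
        ranked = sorted(self.rows, key=lambda r: (-r.count, r.codon))
        return [r.codon_rna for r in ranked[:k]]


def rscu(cds_set: list[Cds], table_id: int = DEFAULT_TABLE_ID) -> RscuTable:
    """Codon counts and RSCU over a set of coding sequences.

    Codons containing ambiguous bases are dropped from counts and reported
    in ``ambiguous_codons``.
    """
    code = get_code(table_id)
    counts = {c: 0 for c in code.sense_codons}
    ambiguous = 0
    for cds in cds_set:
        for codon in cds.sense_codons(code):
            if set(codon) <= set("ACGT") and not code.is_stop(codon):
                counts[codon] += 1
            else:
                ambiguous += 1
    rows = []
    for codon in sorted(counts):
        fam = code.family(codon)
        fam_total = sum(counts[c] for c in fam)
        value = len(fam) * counts[codon] / fam_total if fam_total else 0.0
        rows.append(
            RscuRow(
                codon=codon,
                amino_acid=code.aa_label(codon),
                family_size=len(fam),
                count=counts[codon],
                rscu=value,
            )
        )
    return RscuTable(rows=rows, genetic_code=table_id, ambiguous_codons=ambiguous)
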