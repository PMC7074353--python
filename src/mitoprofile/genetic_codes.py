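"""Thin wrapper over NCBI genetic-code tables (default: invertebrate
mitochondrial, transl_table 5)."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

__all__ = ["GeneticCode", "get_code", "DEFAULT_TABLE_ID"]

DEFAULT_TABLE_ID = 5

BASES = "ACGT"

# display sub-family labels used in codon-usage reports (tRNA isoacceptors)
_SUBFAMILY = {
    "TTA": "Leu2", "TTG": "Leu2",
    "CTT": "Leu1", "CTC": "Leu1", "CTA": "Leu1", "CTG": "Leu1",
    "TCT": "Ser2", "TCC": "Ser2", "TCA": "Ser2", "TCG": "Ser2",
    "AGT": "Ser1", "AGC": "Ser1", "AGA": "Ser1", "AGG": "Ser1",
}


@dataclass(frozen=True)
class GeneticCode:
    table_id: int
    name: str
    forward: dict  # codon -> one-letter amino acid, '*' for stop

    def translate(self, codon: str) -> str:
        """One-letter amino acid for a DNA codon; '*' for stop."""
        return self.forward[codon.upper().replace("U", "T")]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in self.forward.items() if aa != "*")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in self.forward.items() if aa == "*")

    def family(self, codon: str) -> tuple[str, ...]:
        """All codons coding the same amino acid (the synonym set)."""
        aa = self.translate(codon)
        return tuple(c for c, a in self.forward.items() if a == aa)

    def aa_label(self, codon: str) -> str:
        """Three-letter amino-acid label, with Leu1/Leu2 and Ser1/Ser2
        sub-family labels where the codon's own label differs by isoacceptor."""
        codon = codon.upper().replace("U", "T")
        aa = self.translate(codon)
        if aa == "*":
            return "Stop"
        if self.table_id == 5 and codon in _SUBFAMILY:
            return _SUBFAMILY[codon]
        return seq3(aa)


@lru_cache(maxsize=None)
def get_code(table_id: int = DEFAULT_TABLE_ID) -> GeneticCode:
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    forward = {"".join(c): "*" for c in product(BASES, repeat=3)}
    forward.update(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        forward[stop] = "*"
    return GeneticCode(table_id=table_id, name=ncbi.names[0], forward=forward)
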