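"""Pairwise synonymous/nonsynonymous substitution rates in the
Nei-Gojobori (1986) counting style with Jukes-Cantor correction.

Per-codon site counts: at each of the three positions, the fraction of
the single-base changes that are synonymous, with changes creating stop
codons excluded from the denominator.  Differences between codon pairs
are classified by pathway averaging: all orderings of the differing
positions are enumerated, pathways passing through stop codons are
discarded, and the synonymous/nonsynonymous step counts are averaged
over the remaining pathways.  Proportions are corrected with
k = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

from .genetic_codes import BASES, DEFAULT_TABLE_ID, get_code

__all__ = [
    "RatePair",
    "TaxonRates",
    "ng86_sites",
    "codon_pair_differences",
    "pairwise_kaks",
    "taxon_mean_rates",
    "jukes_cantor",
]


def jukes_cantor(p: float) -> float | None:
    """JC69 distance for a proportion of differences; None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@lru_cache(maxsize=None)
def ng86_sites(codon: str, table_id: int = DEFAULT_TABLE_ID, count_stops: bool = False) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    With ``count_stops=False`` (the usual convention) mutations to stop
    codons are excluded from the per-position denominators; otherwise
    they count as nonsynonymous.  Always returns s + n = 3.
    """
    codon = codon.upper().replace("U", "T")
    code = get_code(table_id)
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                if count_stops:
                    denom += 1
                continue
            denom += 1
            if code.translate(mutant) == aa:
                syn += 1
        if denom:
            s += syn / denom
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_pair_differences(
    a: str, b: str, table_id: int = DEFAULT_TABLE_ID
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged over all mutational pathways.

    Pathways passing through stop codons are discarded; if every pathway
    does, the average falls back to all pathways with stop-crossing steps
    counted as nonsynonymous.
    """
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    code = get_code(table_id)
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order, allow_stops: bool):
        sd = nd = 0.0
        current = a
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if code.is_stop(nxt) and not allow_stops:
                return None
            if code.is_stop(current) or code.is_stop(nxt):
                nd += 1.0  # only reachable in the fallback pass
            elif code.translate(current) == code.translate(nxt):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    for allow_stops in (False, True):
        results = [
            r for order in permutations(diff_positions) if (r := walk(order, allow_stops))
        ]
        if results:
            sd = sum(r[0] for r in results) / len(results)
            nd = sum(r[1] for r in results) / len(results)
            return sd, nd
    raise AssertionError("unreachable")


@dataclass
class RatePair:
    """NG86 counts and corrected distances for one sequence pair."""

    seq_a: str
    seq_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    excluded_codons: int

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pn(self) -> float:
        return self.Nd / self.N if self.N else 0.0

    @property
    def ks(self) -> float | None:
        return jukes_cantor(self.ps)

    @property
    def ka(self) -> float | None:
        return jukes_cantor(self.pn)

    @property
    def omega(self) -> float | None:
        ks, ka = self.ks, self.ka
        if ks is None or ka is None or ks == 0.0:
            return None
        return ka / ks


def _clean_codon(codon: str) -> bool:
    return set(codon) <= set("ACGT")


def pairwise_kaks(
    a: str,
    b: str,
    seq_a: str = "a",
    seq_b: str = "b",
    table_id: int = DEFAULT_TABLE_ID,
) -> RatePair:
    """NG86 ka/ks for two aligned in-frame sequences.

    Codons containing gaps/ambiguity in either sequence, and codon pairs
    involving stop codons, are skipped and tallied in ``excluded_codons``.
    Site counts S and N are averaged over the two sequences.
    """
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"alignment length {len(a)} is not a multiple of 3")
    code = get_code(table_id)
    S = N = Sd = Nd = 0.0
    excluded = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (_clean_codon(ca) and _clean_codon(cb)):
            excluded += 1
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            excluded += 1
            continue
        sa, na = ng86_sites(ca, table_id)
        sb, nb = ng86_sites(cb, table_id)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_pair_differences(ca, cb, table_id)
        Sd += sd
        Nd += nd
    return RatePair(seq_a=seq_a, seq_b=seq_b, S=S, N=N, Sd=Sd, Nd=Nd, excluded_codons=excluded)


@dataclass
class TaxonRates:
    taxon: str
    mean_ks: float | None
    mean_ka: float | None
    ratio: float | None
    n_pairs: int
    n_undefined: int


def taxon_mean_rates(
    alignment: list[tuple[str, str]],
    reference: str | None = None,
    table_id: int = DEFAULT_TABLE_ID,
) -> list[TaxonRates]:
    """Per-taxon mean ks and ka over pairwise comparisons.

    Default: every taxon is averaged over all pairs containing it.  With
    ``reference`` set, each taxon is compared to the reference sequence
    only (the reference row averages over all its pairs).  Undefined
    pairwise distances are excluded from means and counted.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [rid for rid, _ in alignment]
    if reference is not None and reference not in ids:
        raise ValueError(f"reference {reference!r} not in alignment")
    pair_of: dict[frozenset, RatePair] = {}
    for (ia, sa), (ib, sb) in combinations(alignment, 2):
        pair_of[frozenset((ia, ib))] = pairwise_kaks(sa, sb, ia, ib, table_id)

    out = []
    for taxon in ids:
        pairs = [
            rp
            for key, rp in pair_of.items()
            if taxon in key and (reference is None or reference in key)
        ]
        ks_vals = [rp.ks for rp in pairs if rp.ks is not None]
        ka_vals = [rp.ka for rp in pairs if rp.ka is not None]
        undefined = sum(1 for rp in pairs if rp.ks is None or rp.ka is None)
        mean_ks = sum(ks_vals) / len(ks_vals) if ks_vals else None
        mean_ka = sum(ka_vals) / len(ka_vals) if ka_vals else None
        ratio = None
        if mean_ks not in (None, 0.0) and mean_ka is not None:
            ratio = mean_ka / mean_ks
        out.append(
            TaxonRates(
                taxon=taxon,
                mean_ks=mean_ks,
                mean_ka=mean_ka,
                ratio=ratio,
                n_pairs=len(pairs),
                n_undefined=undefined,
            )
        )
    return out
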