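import math
import random
from itertools import permutations, product

import pytest

from mitoprofile.genetic_codes import get_code
from mitoprofile.rates import (
    codon_pair_differences,
    jukes_cantor,
    ng86_sites,
    pairwise_kaks,
    taxon_mean_rates,
)

CODE = get_code(5)
SENSE = CODE.sense_codons


# ---------------------------------------------------------------- oracles


def naive_sites(codon):
    """Site counts by direct enumeration of the 9 single-base neighbours."""
    aa = CODE.translate(codon)
    s = 0.0
    for pos in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if CODE.translate(mutant) == "*":
                continue
            outcomes.append(CODE.translate(mutant) == aa)
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def naive_pathways(a, b):
    """Pathway-averaged difference counts by explicit enumeration."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    valid = []
    for order in permutations(positions):
        steps = []
        cur = a
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if CODE.translate(nxt) == "*":
                ok = False
                break
            steps.append(CODE.translate(cur) == CODE.translate(nxt))
            cur = nxt
        if ok:
            valid.append(steps)
    if not valid:
        return None  # fallback regime, checked separately
    sd = sum(sum(steps) for steps in valid) / len(valid)
    nd = sum(len(steps) - sum(steps) for steps in valid) / len(valid)
    return sd, nd


def random_coding_pair(rng, n_codons):
    a = [rng.choice(SENSE) for _ in range(n_codons)]
    b = []
    for codon in a:
        c = codon
        for _ in range(rng.randrange(3)):
            pos = rng.randrange(3)
            base = rng.choice("ACGT")
            cand = c[:pos] + base + c[pos + 1 :]
            if CODE.translate(cand) != "*":
                c = cand
        b.append(c)
    return "".join(a), "".join(b)


# ---------------------------------------------------------------- sites


class TestNg86Sites:
    def test_phe_ttt(self):
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_sites_sum_to_three_for_all_sense_codons(self):
        for codon in SENSE:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_sites("TAA")

    def test_full_table_matches_enumeration_oracle(self):
        for codon in SENSE:
            assert ng86_sites(codon) == pytest.approx(naive_sites(codon)), codon

    def test_rna_input_accepted(self):
        assert ng86_sites("UUU") == ng86_sites("TTT")


# ---------------------------------------------------------------- pathways


class TestPathwayCounting:
    def test_identical_codons(self):
        assert codon_pair_differences("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_difference(self):
        # TTT -> TTC is Phe -> Phe
        assert codon_pair_differences("TTT", "TTC") == (1.0, 0.0)

    def test_exhaustive_agreement_with_pathway_oracle(self):
        for a, b in product(SENSE, repeat=2):
            expected = naive_pathways(a, b)
            if expected is None:
                continue
            got = codon_pair_differences(a, b)
            assert got == pytest.approx(expected), (a, b)

    def test_steps_conserved(self):
        rng = random.Random(0)
        for _ in range(300):
            a, b = rng.choice(SENSE), rng.choice(SENSE)
            k = sum(x != y for x, y in zip(a, b))
            sd, nd = codon_pair_differences(a, b)
            assert sd + nd == pytest.approx(k)

    def test_symmetric_in_arguments(self):
        rng = random.Random(1)
        for _ in range(300):
            a, b = rng.choice(SENSE), rng.choice(SENSE)
            assert codon_pair_differences(a, b) == pytest.approx(
                codon_pair_differences(b, a)
            )


# ---------------------------------------------------------------- pairwise


class TestPairwiseKaks:
    def test_identical_sequences(self):
        seq = "ATGAAATTTGGG"
        rp = pairwise_kaks(seq, seq)
        assert rp.Sd == rp.Nd == 0.0
        assert rp.ks == 0.0 and rp.ka == 0.0
        assert rp.omega is None  # ks = 0

    def test_site_totals(self):
        seq = "ATGAAATTTGGG"
        rp = pairwise_kaks(seq, seq)
        assert rp.S + rp.N == pytest.approx(3 * 4)

    def test_symmetry_every_field(self):
        rng = random.Random(2)
        for _ in range(20):
            a, b = random_coding_pair(rng, 30)
            x, y = pairwise_kaks(a, b), pairwise_kaks(b, a)
            assert (x.S, x.N, x.Sd, x.Nd, x.excluded_codons) == (
                y.S, y.N, y.Sd, y.Nd, y.excluded_codons
            )
            assert x.ks == y.ks and x.ka == y.ka

    def test_random_pairs_match_per_codon_oracle(self):
        rng = random.Random(3)
        for _ in range(100):
            a, b = random_coding_pair(rng, 100)
            rp = pairwise_kaks(a, b)
            S = N = Sd = Nd = 0.0
            for i in range(0, len(a), 3):
                ca, cb = a[i : i + 3], b[i : i + 3]
                sa, na = naive_sites(ca)
                sb, nb = naive_sites(cb)
                S += (sa + sb) / 2
                N += (na + nb) / 2
                res = naive_pathways(ca, cb)
                if res is None:
                    res = codon_pair_differences(ca, cb)  # fallback regime
                Sd += res[0]
                Nd += res[1]
            assert rp.S == pytest.approx(S) and rp.N == pytest.approx(N)
            assert rp.Sd == pytest.approx(Sd) and rp.Nd == pytest.approx(Nd)
            # closed-form correction
            if rp.ks is not None:
                assert rp.ks == pytest.approx(-0.75 * math.log(1 - 4 * rp.ps / 3))
            if rp.ka is not None:
                assert rp.ka == pytest.approx(-0.75 * math.log(1 - 4 * rp.pn / 3))

    def test_gapped_and_ambiguous_codons_excluded(self):
        rp = pairwise_kaks("ATG---TTT", "ATGAAATTN")
        assert rp.excluded_codons == 2
        assert rp.S + rp.N == pytest.approx(3)

    def test_stop_codon_pairs_excluded(self):
        rp = pairwise_kaks("ATGTAA", "ATGTAA")
        assert rp.excluded_codons == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_kaks("ATGAAA", "ATG")
        with pytest.raises(ValueError, match="multiple of 3"):
            pairwise_kaks("ATGA", "ATGA")

    def test_adding_synonymous_substitution_monotone(self):
        rng = random.Random(4)
        checked = 0
        while checked < 50:
            a, b = random_coding_pair(rng, 40)
            base = pairwise_kaks(a, b)
            # find a codon where a == b and a synonymous neighbour exists
            codons = [(i, b[i : i + 3]) for i in range(0, len(b), 3)]
            rng.shuffle(codons)
            mutated = None
            for i, codon in codons:
                if a[i : i + 3] != codon:
                    continue
                for pos in range(3):
                    for nb in "ACGT":
                        if nb == codon[pos]:
                            continue
                        cand = codon[:pos] + nb + codon[pos + 1 :]
                        if CODE.translate(cand) == CODE.translate(codon) != "*":
                            mutated = b[:i] + cand + b[i + 3 :]
                            break
                    if mutated:
                        break
                if mutated:
                    break
            if mutated is None:
                continue
            after = pairwise_kaks(a, mutated)
            assert after.Nd == pytest.approx(base.Nd)
            if base.ks is not None and after.ks is not None:
                assert after.ks >= base.ks - 1e-12
            checked += 1


# ---------------------------------------------------------------- per-taxon


class TestTaxonMeanRates:
    def test_two_sequences_equal_single_pair(self):
        rng = random.Random(5)
        a, b = random_coding_pair(rng, 50)
        rp = pairwise_kaks(a, b)
        rows = taxon_mean_rates([("x", a), ("y", b)])
        for row in rows:
            assert row.mean_ks == pytest.approx(rp.ks)
            assert row.mean_ka == pytest.approx(rp.ka)
            assert row.n_pairs == 1

    def test_order_invariance(self):
        rng = random.Random(6)
        aln = []
        a, _ = random_coding_pair(rng, 40)
        for i in range(4):
            _, s = random_coding_pair(rng, 40)
            aln.append((f"t{i}", s))
        fwd = {r.taxon: (r.mean_ks, r.mean_ka, r.ratio) for r in taxon_mean_rates(aln)}
        rev = {r.taxon: (r.mean_ks, r.mean_ka, r.ratio) for r in taxon_mean_rates(aln[::-1])}
        assert fwd == rev

    def test_reference_mode(self):
        rng = random.Random(7)
        aln = [(f"t{i}", random_coding_pair(rng, 40)[1]) for i in range(4)]
        rows = {r.taxon: r for r in taxon_mean_rates(aln, reference="t0")}
        for taxon, row in rows.items():
            assert row.n_pairs == (3 if taxon == "t0" else 1)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError, match="at least 2"):
            taxon_mean_rates([("a", "ATG")])

    def test_unknown_reference(self):
        with pytest.raises(ValueError, match="reference"):
            taxon_mean_rates([("a", "ATG"), ("b", "ATG")], reference="zzz")


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_saturation_undefined(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.9) is None

    def test_closed_form_value(self):
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(1 - 0.4))
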