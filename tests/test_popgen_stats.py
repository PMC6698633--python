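"""Diversity/neutrality estimators against independent brute-force oracles."""

import math

import numpy as np
import pytest

from rhizodem.mlst_io import LocusAlignment, collapse_haplotypes
from rhizodem import popgen_stats as ps


# ---------------------------------------------------------------------------
# independent oracles (re-derived from first principles; never reuse the
# implementation's helpers)
# ---------------------------------------------------------------------------

def oracle_pairwise(seqs):
    names = list(seqs)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = sum(x != y for x, y in zip(seqs[a], seqs[b]))
    return out


def oracle_pi(seqs):
    d = oracle_pairwise(seqs)
    return sum(d.values()) / len(d)


def oracle_S(seqs):
    cols = zip(*seqs.values())
    return sum(1 for c in cols if len(set(c)) > 1)


def oracle_tajima_d(seqs):
    n = len(seqs)
    S = oracle_S(seqs)
    if S == 0:
        return None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (oracle_pi(seqs) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_stirling_unsigned(n):
    """Exact integer |s(n, k)| by the textbook recurrence."""
    rows = [[1]]
    for m in range(1, n + 1):
        prev = rows[-1]
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = (m - 1) * (prev[k] if k < m else 0) + prev[k - 1]
        rows.append(row)
    return rows[n]


def oracle_fs(seqs):
    """Fu's Fs via exact Ewens probabilities (safe only for small n)."""
    n = len(seqs)
    theta = oracle_pi(seqs)
    if theta == 0:
        return None
    k_obs = len(set(seqs.values()))
    s = oracle_stirling_unsigned(n)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    probs = [s[k] * theta ** k / rising for k in range(1, n + 1)]
    sp = sum(probs[k_obs - 1:])
    return math.log(sp / (1 - sp))


def _aln(seqs):
    return LocusAlignment("t", seqs)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestPairwiseAndPi:
    def test_toy_pairwise(self, toy_aln):
        d = ps.pairwise_difference_matrix(toy_aln)
        vals = sorted(d[np.triu_indices(4, 1)])
        assert vals == [1, 1, 1, 2, 2, 3]

    def test_identical_pair_zero(self):
        d = ps.pairwise_difference_matrix(_aln({"a": "AAA", "b": "AAA"}))
        assert d[0, 1] == 0

    def test_toy_pi(self, toy_aln):
        pi_abs, pi_ps = ps.nucleotide_diversity(toy_aln)
        assert pi_abs == pytest.approx(10 / 6)
        assert pi_ps == pytest.approx(10 / 18)

    def test_two_seq_per_site(self):
        pi_abs, pi_ps = ps.nucleotide_diversity(
            _aln({"a": "AAAAAAAAAA", "b": "TTAAAAAAAA"}))
        assert pi_ps == pytest.approx(0.2)

    def test_reorder_invariance(self, random_alignment_factory):
        rng = np.random.default_rng(2)
        aln = random_alignment_factory(rng, 8, 30)
        shuffled = LocusAlignment("t", {k: aln.sequences[k]
                                        for k in reversed(aln.strains)})
        assert ps.nucleotide_diversity(aln) == ps.nucleotide_diversity(shuffled)
        assert ps.watterson_theta(aln) == ps.watterson_theta(shuffled)


class TestWatterson:
    def test_monomorphic(self):
        assert ps.watterson_theta(_aln({"a": "AAA", "b": "AAA"}))[0] == 0

    def test_n4_s3(self, toy_aln):
        th, _ = ps.watterson_theta(toy_aln)
        assert th == pytest.approx(3 / (1 + 0.5 + 1 / 3))

    def test_n2(self):
        th, _ = ps.watterson_theta(_aln({"a": "ACGTA", "b": "TTTTT"}))
        assert th == pytest.approx(4.0)  # 4 segregating sites, a_1 = 1

    def test_per_site_times_length(self, toy_aln):
        th_abs, th_ps = ps.watterson_theta(toy_aln)
        assert th_ps * toy_aln.masked().length == pytest.approx(th_abs)


class TestTajimasD:
    def test_toy_value(self, toy_aln):
        d, _ = ps.tajimas_d(toy_aln)
        assert d == pytest.approx(0.168, abs=5e-4)

    def test_monomorphic_not_computable(self):
        d, p = ps.tajimas_d(_aln({c: "AAAA" for c in "abcd"}))
        assert d is None and p is None

    def test_oracle_equivalence_random(self, random_alignment_factory):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 13))
            L = int(rng.integers(5, 51))
            aln = random_alignment_factory(rng, n, L, alphabet="ACGT")
            expect = oracle_tajima_d(aln.sequences)
            if expect is None:
                continue
            got, _ = ps.tajimas_d(aln)
            assert got == pytest.approx(expect, abs=1e-9)
            checked += 1

    def test_singleton_excess_negative(self):
        # star-like: every variant private to one sequence
        n, L = 20, 40
        seqs = {f"s{i:02d}": list("A" * L) for i in range(n)}
        for i in range(n):
            seqs[f"s{i:02d}"][2 * i] = "T"
        aln = _aln({k: "".join(v) for k, v in seqs.items()})
        d, _ = ps.tajimas_d(aln)
        assert d < 0


class TestFusFs:
    def test_hand_example(self):
        fs, _ = ps.fus_fs(_aln({"a": "AA", "b": "AA", "c": "AT"}))
        assert fs == pytest.approx(math.log(0.55 / 0.45), abs=1e-9)

    def test_monomorphic_undefined(self):
        fs, _ = ps.fus_fs(_aln({"a": "AA", "b": "AA"}))
        assert fs is None

    def test_ewens_probabilities_sum_to_one(self):
        for n in range(2, 13):
            for theta in (0.1, 1.0, 7.3):
                total = np.exp(ps.ewens_log_pk(n, theta)).sum()
                assert total == pytest.approx(1.0, abs=1e-10)

    def test_oracle_equivalence_random(self, random_alignment_factory):
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 100:
            n = int(rng.integers(3, 13))
            aln = random_alignment_factory(rng, n, int(rng.integers(5, 30)))
            expect = oracle_fs(aln.sequences)
            if expect is None:
                continue
            got, _ = ps.fus_fs(aln)
            assert got == pytest.approx(expect, rel=1e-9, abs=1e-9)
            checked += 1

    def test_many_haplotypes_small_theta_strongly_negative(self):
        # low diversity but every sequence distinct: Fs far below 0
        n, L = 100, 300
        seqs = {f"s{i:03d}": list("A" * L) for i in range(n)}
        for i in range(1, n):
            seqs[f"s{i:03d}"][i] = "T"
        fs, _ = ps.fus_fs(_aln({k: "".join(v) for k, v in seqs.items()}))
        assert fs < -10

    def test_large_n_stability(self):
        # overflow-safe for samples of hundreds
        logs = ps.ewens_log_pk(300, 5.0)
        assert np.isfinite(logs).all()
        assert np.exp(logs).sum() == pytest.approx(1.0, abs=1e-8)


class TestNeiGojobori:
    def test_synonymous_pair(self):
        res = ps.pn_ps_dn_ds(LocusAlignment("c", {"a": "ATGTTT", "b": "ATGTTC"},
                                            coding=True))
        assert res.p_n == 0 and res.pn_ps == 0 and res.dn_ds == 0
        assert res.d_s > 0

    def test_identical_sequences(self):
        res = ps.pn_ps_dn_ds(LocusAlignment("c", {"a": "ATGTTT", "b": "ATGTTT"},
                                            coding=True))
        assert res.p_n == 0 and res.p_s == 0
        assert res.pn_ps is None and res.dn_ds is None

    def test_nonsynonymous_pair(self):
        res = ps.pn_ps_dn_ds(LocusAlignment("c", {"a": "ATGAAA", "b": "ATGGAA"},
                                            coding=True))
        assert res.p_s == 0 and res.pn_ps is None
        assert res.d_n > 0

    def test_noncoding_rejected(self, toy_aln):
        with pytest.raises(ValueError):
            ps.pn_ps_dn_ds(toy_aln)


class TestHaplotypeDiversity:
    def test_all_identical(self):
        t = collapse_haplotypes(_aln({"a": "AA", "b": "AA", "c": "AA"}))
        assert ps.haplotype_diversity(t) == 0

    def test_two_distinct(self):
        t = collapse_haplotypes(_aln({"a": "AA", "b": "AT"}))
        assert ps.haplotype_diversity(t) == pytest.approx(1.0)

    def test_counts_three_one(self):
        t = collapse_haplotypes(_aln({"a": "AA", "b": "AA", "c": "AA", "d": "TT"}))
        assert ps.haplotype_diversity(t) == pytest.approx(0.5)


class TestHudsonFst:
    def test_hand_value(self):
        aln = _aln({"g1a": "AA", "g1b": "AC", "g2a": "GG", "g2b": "GT"})
        out = ps.hudson_fst(aln, {"g1": ["g1a", "g1b"], "g2": ["g2a", "g2b"]})
        assert out[("g1", "g2")] == pytest.approx(0.5)

    def test_fixed_differences(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTT"})
        out = ps.hudson_fst(aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert out[("A", "B")] == pytest.approx(1.0)

    def test_panmictic_near_zero(self, random_alignment_factory):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(20):
            aln = random_alignment_factory(rng, 20, 50)
            names = aln.strains
            out = ps.hudson_fst(aln, {"A": names[:10], "B": names[10:]})
            vals.append(out[("A", "B")])
        assert abs(np.mean(vals)) < 0.02

    def test_undefined_when_no_between_variation(self):
        aln = _aln({"a1": "AA", "a2": "AA", "b1": "AA", "b2": "AA"})
        out = ps.hudson_fst(aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert out[("A", "B")] is None
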