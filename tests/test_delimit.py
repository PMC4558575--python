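import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cophylokit as ck
from cophylokit.delimit import (
    DelimitationConfig,
    DistanceModel,
    SeqAlignment,
    alignment_stats,
    calibrate_rate,
    collapse_haplotypes,
    delimit_species,
    distance_matrix,
    pairwise_distance,
    prune_similar,
)
from cophylokit.trees import DistanceMatrix


def matrix(labels, pairs):
    n = len(labels)
    D = np.zeros((n, n))
    for (i, j), v in pairs.items():
        D[i, j] = D[j, i] = v
    return DistanceMatrix(labels, D)


class TestAlignmentStats:
    @pytest.mark.parametrize(
        "seqs, expected",
        [
            (["ACGT", "ACGA", "ACGA"], (4, 1, 0)),
            (["AAAA", "AAAA"], (4, 0, 0)),
            (["ACGT", "ACGT", "TGCA", "TGCA"], (4, 4, 4)),
        ],
    )
    def test_hand_counted_examples(self, seqs, expected):
        aln = SeqAlignment([f"s{i}" for i in range(len(seqs))], seqs)
        assert alignment_stats(aln) == expected

    def test_gaps_and_ns_not_states(self):
        aln = SeqAlignment(["a", "b", "c"], ["A-GT", "ANGT", "AAGT"])
        # column 2: only one unambiguous state among {-, N, A}
        assert alignment_stats(aln) == (4, 0, 0)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            SeqAlignment(["a", "b"], ["ACGT", "ACG"])

    def test_codon_position_mask(self):
        # saturated third positions can be excluded before distances
        aln = SeqAlignment(["a", "b"], ["ACGACG", "ACTACT"])
        masked = aln.mask_codon_position(3)
        assert masked.sequences == ["ACAC", "ACAC"]
        assert ck.pairwise_distance(*masked.sequences) == 0
        with pytest.raises(ValueError):
            aln.mask_codon_position(4)


class TestHaplotypes:
    def test_multiplicities(self):
        aln = SeqAlignment(list("abcd"), ["ACGT", "ACGT", "ACGT", "AGGT"])
        haps = collapse_haplotypes(aln)
        assert haps.n_haplotypes == 2
        assert sorted(haps.multiplicities) == [1, 3]

    def test_case_insensitive(self):
        aln = SeqAlignment(["a", "b"], ["acgt", "ACGT"])
        assert collapse_haplotypes(aln).n_haplotypes == 1

    def test_all_distinct(self):
        aln = SeqAlignment(list("abc"), ["ACGT", "AGGT", "ATGT"])
        assert collapse_haplotypes(aln).n_haplotypes == 3


class TestPairwiseDistance:
    def test_p_distance(self):
        assert pairwise_distance("ACGT", "ACGA") == pytest.approx(0.25)

    def test_identical_zero_all_models(self):
        for model in (DistanceModel("p"), DistanceModel("JC"), DistanceModel("JC+G", 0.4)):
            assert pairwise_distance("ACGT", "ACGT", model) == 0

    def test_jc_gamma_closed_form(self):
        # p = 0.05 over 20 sites, alpha = 0.40 (nuclear ITS default)
        s1 = "A" * 20
        s2 = "C" + "A" * 19
        d = pairwise_distance(s1, s2, DistanceModel("JC+G", 0.40))
        expected = 0.75 * 0.40 * ((1 - 4 * 0.05 / 3) ** (-1 / 0.40) - 1)
        assert d == pytest.approx(expected)
        assert d == pytest.approx(0.0565, abs=5e-4)

    def test_gamma_converges_to_jc(self):
        s1, s2 = "ACGTACGTAC", "ACGTACGTAA"
        jc = pairwise_distance(s1, s2, DistanceModel("JC"))
        jcg = pairwise_distance(s1, s2, DistanceModel("JC+G", 1e6))
        assert abs(jc - jcg) < 1e-6

    def test_pairwise_deletion(self):
        assert pairwise_distance("AC-T", "ACNT") == 0.0
        assert pairwise_distance("ACGT", "AC-A") == pytest.approx(1 / 3)

    def test_saturation_and_empty_overlap(self):
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distance("AAAA", "CCCC", DistanceModel("JC"))
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("----", "ACGT")


class TestDelimitation:
    def test_two_haplotypes_above_threshold(self):
        D = matrix(["h1", "h2"], {(0, 1): 0.048})
        n, _ = delimit_species(D, DelimitationConfig(threshold=0.01))
        assert n == 2

    def test_two_haplotypes_below_threshold(self):
        D = matrix(["h1", "h2"], {(0, 1): 0.002})
        n, _ = delimit_species(D, DelimitationConfig(threshold=0.02))
        assert n == 1

    def test_four_close_haplotypes_one_species(self):
        rng = np.random.default_rng(0)
        vals = {}
        for i in range(4):
            for j in range(i + 1, 4):
                vals[(i, j)] = rng.uniform(0.001, 0.007)
        D = matrix([f"h{i}" for i in range(4)], vals)
        n, _ = delimit_species(D, DelimitationConfig(threshold=0.01))
        assert n == 1

    def test_single_haplotype(self):
        assert delimit_species(matrix(["h1"], {}))[0] == 1

    def test_percent_unit_declared(self):
        D = matrix(["h1", "h2"], {(0, 1): 4.8})
        n, _ = delimit_species(D, DelimitationConfig(threshold=0.01), unit="percent")
        assert n == 2
        with pytest.raises(ValueError, match="unit"):
            delimit_species(D, DelimitationConfig(threshold=0.01), unit="furlongs")

    def test_complete_linkage_variant(self):
        # chain: a-b close, b-c close, a-c far; single joins all, complete not
        D = matrix(list("abc"), {(0, 1): 0.005, (1, 2): 0.005, (0, 2): 0.03})
        single, _ = delimit_species(D, DelimitationConfig(threshold=0.01))
        complete, _ = delimit_species(
            D, DelimitationConfig(threshold=0.01, linkage="complete")
        )
        assert single == 1 and complete == 2

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        X = rng.uniform(0, 0.05, size=(n, 1))
        D = DistanceMatrix(
            [f"h{i}" for i in range(n)], np.abs(X - X.T)
        )
        counts = [
            delimit_species(D, DelimitationConfig(threshold=t))[0]
            for t in (0.005, 0.01, 0.02, 0.04)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_simulated_clusters_recovered(self):
        """Well-separated simulated clusters are counted exactly."""
        theta = 0.01
        rng = np.random.default_rng(42)
        hits = 0
        for rep in range(100):
            k = int(rng.integers(2, 6))
            sizes = rng.integers(1, 4, size=k)
            # clusters >= 3 theta apart, spread < theta/2 within
            centers = np.arange(k) * 4 * theta
            pts = np.concatenate(
                [c + rng.uniform(0, theta / 2 * 0.98, size=s)
                 for c, s in zip(centers, sizes)]
            )
            D = DistanceMatrix(
                [f"h{i}" for i in range(len(pts))],
                np.abs(pts[:, None] - pts[None, :]),
            )
            n, _ = delimit_species(D, DelimitationConfig(threshold=theta))
            hits += n == k
        assert hits >= 99


class TestPruneSimilar:
    def _haps(self, labels, seqs=None, mults=None):
        seqs = seqs or ["A" * 4] * len(labels)
        mults = mults or [1] * len(labels)
        return ck.HaplotypeSet(
            list(labels), seqs, [[f"{l}_{i}" for i in range(m)] for l, m in zip(labels, mults)]
        )

    def test_near_identical_removed(self):
        haps = self._haps(["h1", "h2"], mults=[3, 1])
        D = matrix(["h1", "h2"], {(0, 1): 0.005})
        out = prune_similar(haps, D, 0.01)
        assert out.representatives == ["h1"]

    def test_distant_kept(self):
        haps = self._haps(["h1", "h2"])
        D = matrix(["h1", "h2"], {(0, 1): 0.02})
        assert prune_similar(haps, D, 0.01).n_haplotypes == 2

    def test_greedy_by_multiplicity(self):
        # h3 most frequent seeds first; h1, h2 within theta of h3 join it
        haps = self._haps(["h1", "h2", "h3"], mults=[1, 2, 5])
        D = matrix(
            ["h1", "h2", "h3"],
            {(0, 1): 0.02, (0, 2): 0.005, (1, 2): 0.005},
        )
        out = prune_similar(haps, D, 0.01)
        assert out.representatives == ["h3"]

    def test_representatives_respect_greedy_rule(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 0.1, size=8)
        D = DistanceMatrix(
            [f"h{i}" for i in range(8)], np.abs(pts[:, None] - pts[None, :])
        )
        haps = self._haps([f"h{i}" for i in range(8)])
        out = prune_similar(haps, D, 0.01)
        reps = out.representatives
        # every dropped haplotype sits within theta of some retained seed,
        # and every retained seed was >= theta from all earlier seeds
        for lab in D.labels:
            if lab not in reps:
                assert any(D[lab, r] < 0.01 for r in reps)
        for i, a in enumerate(reps):
            assert all(D[a, b] >= 0.01 for b in reps[:i])


class TestCalibrateRate:
    @pytest.mark.parametrize(
        "d_lo, d_hi, T, expected",
        [
            (2.0, 7.0, 2.4, (0.4, 1.5)),
            (0.0, 0.0, 1.0, (0.0, 0.0)),
            (4.8, 4.8, 2.4, (1.0, 1.0)),
        ],
    )
    def test_rate_endpoints(self, d_lo, d_hi, T, expected):
        assert calibrate_rate(d_lo, d_hi, T) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_rate(1, 2, 0)
        with pytest.raises(ValueError):
            calibrate_rate(3, 2, 1)
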