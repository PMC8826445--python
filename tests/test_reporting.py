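"""Core frequency matrices, KL logos, length histograms, consistency."""

import math

import numpy as np
import pytest

from motifdecon.constants import AA_INDEX, TRASH, UNIFORM_BACKGROUND
from motifdecon.datamodel import Assignment, MhcClass, RankTable
from motifdecon.deconvolution import DeconvolutionConfig, DeconvolutionResult
from motifdecon.reporting import (
    MotifSummary,
    consistency_matrix,
    core_frequency_matrix,
    flatten_freq,
    kl_logo_data,
    length_distribution,
    motif_summary,
)


class TestCoreFrequencyMatrix:
    def test_single_core_point_mass(self):
        f = core_frequency_matrix(["AAAAAAAAA"])
        assert np.all(f[:, AA_INDEX["A"]] == 1.0)
        assert f.sum() == pytest.approx(9.0)

    def test_two_cores_half_half(self):
        f = core_frequency_matrix(["AAAAAAAAA", "CCCCCCCCC"])
        assert np.all(f[:, AA_INDEX["A"]] == 0.5)
        assert np.all(f[:, AA_INDEX["C"]] == 0.5)

    def test_matches_hand_tally_on_random_cores(self):
        rng = np.random.default_rng(8)
        from motifdecon.constants import AMINO_ACIDS

        cores = [
            "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 9))
            for _ in range(10)
        ]
        f = core_frequency_matrix(cores)
        np.testing.assert_allclose(f.sum(axis=1), 1.0)
        # independent tally
        for i in range(9):
            for a in range(20):
                expected = sum(c[i] == AMINO_ACIDS[a] for c in cores) / 10
                assert f[i, a] == pytest.approx(expected)

    def test_non_9mer_rejected(self):
        with pytest.raises(ValueError, match="9-mer"):
            core_frequency_matrix(["AAAA"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no cores"):
            core_frequency_matrix([])


class TestKlLogo:
    def test_zero_information_when_p_equals_q(self):
        f = np.tile(UNIFORM_BACKGROUND, (9, 1))
        df = kl_logo_data(f)
        assert df["info"].abs().max() == pytest.approx(0.0)

    def test_point_mass_is_log2_20_bits(self):
        f = core_frequency_matrix(["AAAAAAAAA"])
        df = kl_logo_data(f)
        info_p1 = df[df.position == 1]["info"].iloc[0]
        assert info_p1 == pytest.approx(math.log2(20))

    def test_half_half_closed_form(self):
        # p = {A: 0.5, C: 0.5} vs uniform: KL = log2(10); heights split evenly
        f = core_frequency_matrix(["AAAAAAAAA", "CCCCCCCCC"])
        df = kl_logo_data(f)
        p1 = df[df.position == 1]
        assert p1["info"].iloc[0] == pytest.approx(math.log2(10))
        h_a = p1[p1.residue == "A"]["height"].iloc[0]
        h_c = p1[p1.residue == "C"]["height"].iloc[0]
        assert h_a == pytest.approx(0.5 * math.log2(10))
        assert h_a == pytest.approx(h_c)

    def test_information_nonnegative_for_random_frequencies(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            f = rng.dirichlet(np.ones(20), size=9)
            df = kl_logo_data(f)
            assert (df["info"] >= -1e-12).all()
            assert (df["height"] >= -1e-12).all()

    def test_zero_background_rejected(self):
        f = np.tile(UNIFORM_BACKGROUND, (9, 1))
        q = np.zeros(20)
        q[0] = 1.0
        with pytest.raises(ValueError, match="positive"):
            kl_logo_data(f, q)


def _result(assignments, counts, length_range=(13, 21)):
    cfg = DeconvolutionConfig(
        mhc_class=MhcClass.II, length_min=length_range[0], length_max=length_range[1]
    )
    return DeconvolutionResult(
        assignments=assignments,
        cluster_counts=counts,
        config=cfg,
        rank_table=RankTable([]),
    )


class TestLengthDistribution:
    def test_counts_per_length(self):
        asg = [
            Assignment("s", "K" * 15, "DRB1*15:01", 1.0, "K" * 9),
            Assignment("s", "L" * 15, "DRB1*15:01", 1.0, "L" * 9),
            Assignment("s", "M" * 14, "DRB1*15:01", 1.0, "M" * 9),
        ]
        res = _result(asg, {"DRB1*15:01": 3, TRASH: 0})
        hist = length_distribution(res, "DRB1*15:01")
        assert hist[14] == 1 and hist[15] == 2
        assert hist[13] == 0 and hist[21] == 0  # zeros included

    def test_empty_cluster_all_zero(self):
        res = _result([], {"DRB1*15:01": 0, TRASH: 0})
        hist = length_distribution(res, TRASH)
        assert all(v == 0 for v in hist.values())
        assert set(hist) == set(range(13, 22))

    def test_unknown_cluster_rejected(self):
        res = _result([], {"DRB1*15:01": 0})
        with pytest.raises(KeyError):
            length_distribution(res, "DRB1*99:99")

    def test_histogram_total_equals_cluster_count(self):
        rng = np.random.default_rng(12)
        asg = []
        counts = {"DRB1*15:01": 0, TRASH: 0}
        for i in range(40):
            L = int(rng.integers(13, 22))
            cluster = "DRB1*15:01" if rng.random() < 0.7 else TRASH
            asg.append(Assignment("s", "K" * L, cluster, 1.0, "K" * 9))
            counts[cluster] += 1
        res = _result(asg, counts)
        for cluster, n in counts.items():
            assert sum(length_distribution(res, cluster).values()) == n


def _summary(freq):
    return MotifSummary(
        allele="DRB1*15:01", n_peptides=10, freq=freq,
        info=np.zeros(9), length_hist={},
    )


class TestConsistencyMatrix:
    def test_identical_matrices_pcc_one(self):
        rng = np.random.default_rng(13)
        f = rng.dirichlet(np.ones(20), size=9)
        cm = consistency_matrix(
            {"s1": _summary(f), "s2": _summary(f.copy())}, "DRB1*15:01"
        )
        assert cm.pcc[0, 1] == pytest.approx(1.0)
        assert cm.mean_pcc == pytest.approx(1.0)

    def test_flattened_vector_has_180_elements(self):
        f = np.tile(UNIFORM_BACKGROUND, (9, 1))
        assert flatten_freq(f).shape == (180,)

    def test_mean_of_three_pairwise_values_matches_direct_pcc(self):
        rng = np.random.default_rng(14)
        mats = {f"s{i}": rng.dirichlet(np.ones(20), size=9) for i in range(3)}
        cm = consistency_matrix(
            {k: _summary(v) for k, v in mats.items()}, "DRB1*15:01"
        )
        # brute-force oracle on the 180-vectors
        keys = list(mats)
        direct = []
        for i in range(3):
            for j in range(i + 1, 3):
                vi, vj = mats[keys[i]].reshape(-1), mats[keys[j]].reshape(-1)
                direct.append(np.corrcoef(vi, vj)[0, 1])
        assert cm.mean_pcc == pytest.approx(np.mean(direct))
        # symmetry and diagonal
        np.testing.assert_allclose(cm.pcc, cm.pcc.T)
        np.testing.assert_allclose(np.diag(cm.pcc), 1.0)

    def test_constant_vector_pair_excluded_from_mean(self):
        rng = np.random.default_rng(15)
        f = rng.dirichlet(np.ones(20), size=9)
        const = np.tile(UNIFORM_BACKGROUND, (9, 1))  # zero variance
        cm = consistency_matrix(
            {"s1": _summary(f), "s2": _summary(f * 0.999 + const * 0.001),
             "s3": _summary(const)},
            "DRB1*15:01",
        )
        assert np.isnan(cm.pcc[0, 2]) and np.isnan(cm.pcc[1, 2])
        assert not math.isnan(cm.mean_pcc)

    def test_permutation_equivariant_in_sample_order(self):
        rng = np.random.default_rng(16)
        mats = {f"s{i}": rng.dirichlet(np.ones(20), size=9) for i in range(3)}
        cm1 = consistency_matrix(
            {k: _summary(mats[k]) for k in ["s0", "s1", "s2"]}, "X*01:01"
        )
        cm2 = consistency_matrix(
            {k: _summary(mats[k]) for k in ["s2", "s0", "s1"]}, "X*01:01"
        )
        assert cm1.mean_pcc == pytest.approx(cm2.mean_pcc)

    def test_fewer_than_two_samples_rejected(self):
        f = np.tile(UNIFORM_BACKGROUND, (9, 1))
        with pytest.raises(ValueError, match="2 samples"):
            consistency_matrix({"s1": _summary(f)}, "X*01:01")


class TestMotifSummary:
    def test_logo_suppressed_below_minimum(self):
        asg = [Assignment("s", "K" * 15, "DRB1*15:01", 1.0, "K" * 9)]
        res = _result(asg, {"DRB1*15:01": 1, TRASH: 0})
        ms = motif_summary(res, "DRB1*15:01")  # default minimum is 10
        assert ms.logo_suppressed
        assert ms.n_peptides == 1  # counts still reported

    def test_frequencies_from_assigned_cores(self):
        asg = [
            Assignment("s", "K" * 15, "DRB1*15:01", 1.0, "K" * 9)
            for _ in range(12)
        ]
        res = _result(asg, {"DRB1*15:01": 12, TRASH: 0})
        ms = motif_summary(res, "DRB1*15:01")
        assert not ms.logo_suppressed
        assert ms.freq[0, AA_INDEX["K"]] == 1.0
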