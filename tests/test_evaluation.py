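"""Connectome scoring: bundle classification, Youden's index, normalized
edge-weight errors and the thresholding/random-removal baselines."""

import numpy as np
import pytest

import tractofilter as tf
from tractofilter.connectome import Connectome


@pytest.fixture
def truth():
    return Connectome.from_edges([1, 2, 3, 4], [(1, 2, 10.0), (3, 4, 5.0)])


class TestClassifyBundles:
    def test_perfect_estimate(self, truth):
        vb, ib, _, _ = tf.classify_bundles(truth, truth)
        assert (vb, ib) == (2, 0)

    def test_disjoint_estimate(self, truth):
        est = Connectome.from_edges([1, 2, 3, 4], [(1, 3, 1.0), (2, 4, 1.0)])
        vb, ib, _, _ = tf.classify_bundles(est, truth)
        assert (vb, ib) == (0, 2)

    def test_hand_enumerated_mixture(self, truth):
        est = Connectome.from_edges([1, 2, 3, 4],
                                    [(1, 2, 6.0), (1, 3, 2.0), (2, 3, 1.0)],
                                    "streamline_count")
        vb, ib, vc, ic = tf.classify_bundles(est, truth)
        assert (vb, ib) == (1, 2)
        assert vc == pytest.approx(6 / 9)
        assert ic == pytest.approx(3 / 9)

    def test_label_mismatch_rejected(self, truth):
        est = Connectome.from_edges([1, 2, 3], [(1, 2, 1.0)])
        with pytest.raises(ValueError, match="label"):
            tf.classify_bundles(est, truth)


class TestYouden:
    def test_printed_headline_value(self):
        j = tf.youden(VB=27, IB=20, P=27, N=594)
        assert j == pytest.approx(0.96633, abs=1e-5)
        assert tf.round_half_away(j, 2) == 0.97

    def test_printed_thresholding_value(self):
        j = tf.youden(VB=25, IB=120, P=27, N=594)
        assert j == pytest.approx(0.72391, abs=1e-5)
        assert tf.round_half_away(j, 2) == 0.72

    def test_bounds_attained(self):
        assert tf.youden(27, 0, 27, 594) == 1.0
        assert tf.youden(0, 594, 27, 594) == -1.0

    def test_bounds_violations_rejected(self):
        with pytest.raises(ValueError):
            tf.youden(28, 0, 27, 594)
        with pytest.raises(ValueError):
            tf.youden(1, 600, 27, 594)
        with pytest.raises(ValueError):
            tf.youden(1, 1, 0, 594)

    def test_specificity_identity(self):
        assert tf.specificity(20, 594) * 100 == pytest.approx(96.6, abs=0.05)
        assert tf.specificity(441, 594) * 100 == pytest.approx(25.8, abs=0.05)


class TestConnectomeError:
    def test_identical_connectomes_zero(self, truth):
        assert tf.connectome_error(truth, truth) == 0.0

    def test_scale_invariance(self, truth):
        scaled = Connectome(truth.roi_labels, truth.matrix * 3.7, "fiber_count")
        assert tf.connectome_error(scaled, truth) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_edge_example(self):
        t = Connectome.from_edges([1, 2, 3], [(1, 2, 4.0), (2, 3, 2.0)])
        e = Connectome.from_edges([1, 2, 3], [(1, 2, 1.0), (1, 3, 1.0)])
        # normalized truth: (1, 0.5, 0); normalized estimate: (1, 0, 1)
        expected = np.sqrt(0.0 + 0.25 + 1.0)
        assert tf.connectome_error(e, t) == pytest.approx(expected)
        assert tf.connectome_error(e, t, "tp_only") == pytest.approx(0.5)

    def test_tp_restriction_never_larger(self, truth):
        est = Connectome.from_edges([1, 2, 3, 4], [(1, 2, 3.0), (1, 4, 2.0)])
        assert tf.connectome_error(est, truth, "tp_only") <= \
            tf.connectome_error(est, truth, "all")

    def test_full_matrix_mode_is_sqrt_two_upper(self, truth):
        est = Connectome.from_edges([1, 2, 3, 4], [(1, 2, 3.0), (1, 4, 2.0)])
        up = tf.connectome_error(est, truth, triangle="upper")
        full = tf.connectome_error(est, truth, triangle="full")
        assert full == pytest.approx(np.sqrt(2.0) * up)

    def test_all_zero_estimate_treated_as_zeros(self, truth):
        est = Connectome([1, 2, 3, 4], np.zeros((4, 4)))
        expected = np.sqrt(1.0 + 0.25)  # normalized truth entries 1 and 0.5
        assert tf.connectome_error(est, truth) == pytest.approx(expected)


class TestThresholdFilter:
    @pytest.fixture
    def counts(self):
        return Connectome.from_edges(
            [1, 2, 3, 4], [(1, 2, 10.0), (3, 4, 2.0), (1, 3, 1.0)],
            "streamline_count")

    def test_k_zero_keeps_everything(self, counts):
        assert tf.threshold_filter(counts, 0).edge_set() == counts.edge_set()

    def test_k_above_max_empties(self, counts):
        assert tf.threshold_filter(counts, 10).edge_set() == set()

    def test_monotone_in_k(self, counts, truth):
        prev_vb, prev_ib = np.inf, np.inf
        for k in range(11):
            vb, ib, _, _ = tf.classify_bundles(tf.threshold_filter(counts, k), truth)
            assert vb <= prev_vb and ib <= prev_ib
            prev_vb, prev_ib = vb, ib

    def test_wrong_weight_definition_rejected(self, truth):
        with pytest.raises(ValueError, match="count"):
            tf.threshold_filter(Connectome(truth.roi_labels, truth.matrix,
                                           "sum_of_weights"), 1)


class TestRandomFilter:
    def test_rate_zero_is_unfiltered_J(self, truth):
        est = Connectome.from_edges([1, 2, 3, 4], [(1, 2, 1.0), (1, 3, 1.0)],
                                    "streamline_count")
        vb, ib, _, _ = tf.classify_bundles(est, truth)
        j = tf.youden(vb, ib, 2, 4)
        assert tf.random_filter_score(est, truth, 2, 4, 0.0, 10, seed=0) == \
            pytest.approx(j)

    def test_rate_one_removes_everything(self, truth):
        est = Connectome.from_edges([1, 2, 3, 4], [(1, 2, 1.0), (1, 3, 1.0)],
                                    "streamline_count")
        assert tf.random_filter_score(est, truth, 2, 4, 1.0, 10, seed=0) == \
            pytest.approx(0.0)

    def test_matches_closed_form_expectation(self, truth):
        """E[J] under keeping each edge with probability (n-m)/n."""
        est = Connectome.from_edges(
            [1, 2, 3, 4],
            [(1, 2, 1.0), (3, 4, 1.0), (1, 3, 1.0), (1, 4, 1.0), (2, 4, 1.0)],
            "streamline_count")
        P, N, rate = 2, 4, 0.4
        vb, ib, _, _ = tf.classify_bundles(est, truth)
        n_edges = len(est.edge_set())
        p_keep = (n_edges - int(np.floor(rate * n_edges))) / n_edges
        expected = p_keep * vb / P + (1.0 - p_keep * ib / N) - 1.0
        mc = tf.random_filter_score(est, truth, P, N, rate, 10_000, seed=1)
        assert mc == pytest.approx(expected, abs=0.01)

    def test_deterministic_given_seed(self, truth):
        est = Connectome.from_edges([1, 2, 3, 4], [(1, 2, 1.0), (1, 3, 1.0)],
                                    "streamline_count")
        a = tf.random_filter_score(est, truth, 2, 4, 0.5, 50, seed=9)
        b = tf.random_filter_score(est, truth, 2, 4, 0.5, 50, seed=9)
        assert a == b


class TestRocSweep:
    def test_max_J_dominates_lambda_zero(self, experiment):
        roc = experiment.roc
        assert roc["J"].max() >= roc["J"].iloc[0]

    def test_best_row_has_fewer_invalid_bundles(self, experiment):
        """On the spliced phantom, regularization strictly reduces IB."""
        roc = experiment.roc
        best = roc.loc[roc["J"].idxmax()]
        assert best["IB"] < roc["IB"].iloc[0] or roc["IB"].iloc[0] == 0

    def test_row_self_consistency(self, experiment):
        roc = experiment.roc
        for _, row in roc.iterrows():
            assert row["J"] == pytest.approx(
                tf.youden(int(row["VB"]), int(row["IB"]),
                          experiment.P, experiment.N))
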