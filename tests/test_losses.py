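"""Hand-oracle values and analytic properties of the adversarial losses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unlearn import losses as L
from unlearn.autodiff import Tensor


# ---------------------------------------------------------------------------
# Per-scanner task loss (scanner-balanced sum of within-scanner means)
# ---------------------------------------------------------------------------


class TestPerScannerTaskLoss:
    def test_two_domain_hand_example(self):
        # domain A squared errors (1, 9) -> mean 5; domain B (4) -> total 9
        val = L.per_scanner_task_loss([5, 7, 3], [4, 4, 1], [0, 0, 1])
        assert val == pytest.approx(9.0)

    def test_zero_when_predictions_equal_labels(self):
        assert L.per_scanner_task_loss([2, 3], [2, 3], [0, 1]) == 0.0

    def test_single_domain_reduces_to_plain_mean(self):
        val = L.per_scanner_task_loss([1, 2], [0, 0], [0, 0])
        assert val == pytest.approx(2.5)

    def test_invariant_to_duplicating_one_domain(self):
        # duplicating every sample of domain B leaves the value unchanged
        val = L.per_scanner_task_loss([5, 7, 3, 3], [4, 4, 1, 1], [0, 0, 1, 1])
        assert val == pytest.approx(9.0, abs=1e-12)

    @given(st.integers(1, 5), st.integers(2, 6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_duplication_property_random(self, dup, n_b):
        rng = np.random.default_rng(n_b * 10 + dup)
        pa, ya = rng.normal(size=3), rng.normal(size=3)
        pb, yb = rng.normal(size=n_b), rng.normal(size=n_b)
        base = L.per_scanner_task_loss(
            np.concatenate([pa, pb]), np.concatenate([ya, yb]),
            [0] * 3 + [1] * n_b)
        dup_val = L.per_scanner_task_loss(
            np.concatenate([pa, np.tile(pb, dup)]),
            np.concatenate([ya, np.tile(yb, dup)]),
            [0] * 3 + [1] * (n_b * dup))
        assert dup_val == pytest.approx(base, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            L.per_scanner_task_loss([], [], [])


# ---------------------------------------------------------------------------
# Domain classification and confusion losses
# ---------------------------------------------------------------------------


class TestDomainLosses:
    def test_one_hot_correct_gives_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert L.domain_classification_loss(probs, [0, 1, 2]) == pytest.approx(
            0.0, abs=1e-7)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_uniform_predictions_give_ln_n(self, n):
        probs = np.full((5, n), 1.0 / n)
        assert L.domain_classification_loss(probs, [0] * 5) == pytest.approx(np.log(n))
        assert L.confusion_loss(probs) == pytest.approx(np.log(n))

    def test_single_sample_hand_values(self):
        assert L.domain_classification_loss([[0.8, 0.2]], [0]) == pytest.approx(
            0.2231, abs=1e-4)
        assert L.confusion_loss([[0.9, 0.1]]) == pytest.approx(1.2040, abs=1e-4)

    def test_zero_probability_is_floored_not_infinite(self):
        val = L.domain_classification_loss([[1.0, 0.0]], [1])
        assert np.isfinite(val)

    @given(st.integers(2, 6), st.integers(1, 8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_confusion_loss_lower_bound_ln_n(self, n, s):
        rng = np.random.default_rng(n * 100 + s)
        probs = rng.dirichlet(np.ones(n), size=s)
        assert L.confusion_loss(probs) >= np.log(n) - 1e-9

    def test_permutation_invariance_over_samples(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=6)
        labels = rng.integers(3, size=6)
        perm = rng.permutation(6)
        assert L.domain_classification_loss(probs, labels) == pytest.approx(
            L.domain_classification_loss(probs[perm], labels[perm]))
        assert L.confusion_loss(probs) == pytest.approx(L.confusion_loss(probs[perm]))

    def test_logit_forms_match_probability_forms(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(5, 4))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(4, size=5)
        assert L.domain_ce_from_logits(Tensor(logits), labels).item() == pytest.approx(
            L.domain_classification_loss(probs, labels))
        assert L.confusion_from_logits(Tensor(logits)).item() == pytest.approx(
            L.confusion_loss(probs))


# ---------------------------------------------------------------------------
# Aggregate objective
# ---------------------------------------------------------------------------


class TestTotalLoss:
    def test_degenerate_weights_give_lp(self):
        w = L.LossWeights(alpha=0.0, beta=0.0)
        assert L.total_unlearning_loss(3.7, 9, 9, {}, w) == pytest.approx(3.7)

    def test_weighted_sum_hand_values(self):
        w = L.LossWeights(alpha=1.0, beta=10.0)
        assert L.total_unlearning_loss(1, 2, 3, {}, w) == pytest.approx(33.0)
        w2 = L.LossWeights(alpha=1.0, beta=10.0, gamma={"sex": 2.0}, phi={"sex": 1.0})
        total = L.total_unlearning_loss(1, 2, 3, {"sex": (0.5, 0.7)}, w2)
        assert total == pytest.approx(34.7)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(alpha=-0.1)
        with pytest.raises(ValueError):
            L.LossWeights(gamma={"sex": -1.0}, phi={"sex": 1.0})


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


class TestDice:
    def test_perfect_prediction_gives_zero_loss(self):
        y = np.eye(3)[np.random.default_rng(0).integers(3, size=20)]
        assert L.multiclass_dice_loss(y, y) == pytest.approx(0.0, abs=1e-4)

    def test_disjoint_hard_maps_give_loss_one(self):
        pred = np.eye(2)[[0, 0, 0]]
        lab = np.eye(2)[[1, 1, 1]]
        assert L.multiclass_dice_loss(pred, lab, eps=0.0) == pytest.approx(1.0)

    def test_four_voxel_hand_example(self):
        pred = np.eye(2)[[0, 0, 1, 1]]
        lab = np.eye(2)[[0, 1, 1, 1]]
        # Dice_A = 2/3, Dice_B = 4/5 -> loss = 1 - 11/15
        assert L.multiclass_dice_loss(pred, lab, eps=0.0) == pytest.approx(
            1.0 - (2 / 3 + 4 / 5) / 2)

    def test_absent_class_counts_as_perfect(self):
        pred = np.zeros((4, 2))
        pred[:, 0] = 1.0
        lab = pred.copy()
        assert L.multiclass_dice_loss(pred, lab) == pytest.approx(0.0, abs=1e-4)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_loss_in_unit_interval_for_hard_maps(self, seed):
        rng = np.random.default_rng(seed)
        pred = np.eye(3)[rng.integers(3, size=12)]
        lab = np.eye(3)[rng.integers(3, size=12)]
        val = L.multiclass_dice_loss(pred, lab, eps=1e-12)
        assert -1e-9 <= val <= 1.0 + 1e-9

    def test_background_exclusion(self):
        # with background (class 0) excluded, only classes 1..K-1 are averaged
        pred = np.eye(3)[[0, 0, 1, 2]]
        lab = np.eye(3)[[1, 1, 1, 2]]
        val = L.multiclass_dice_loss(pred, lab, eps=0.0, background_index=0)
        # Dice_1 = 2*1/(1+3) = 0.5, Dice_2 = 1.0
        assert val == pytest.approx(1.0 - 0.75)


# ---------------------------------------------------------------------------
# Soft age labels and KL
# ---------------------------------------------------------------------------


class TestSoftLabels:
    def test_default_sigma_is_ten_years(self):
        assert L.make_soft_label(50.0).sigma == 10.0

    @given(st.floats(0.0, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_probs_sum_to_one(self, age):
        sl = L.make_soft_label(age)
        assert sl.probs.sum() == pytest.approx(1.0)
        assert np.all(sl.probs >= 0)

    def test_gaussian_density_ratio(self):
        sl = L.make_soft_label(50.0)
        i50 = np.flatnonzero(sl.bin_centers == 50.0)[0]
        i60 = np.flatnonzero(sl.bin_centers == 60.0)[0]
        assert sl.probs[i50] / sl.probs[i60] == pytest.approx(np.exp(0.5))

    def test_argmax_bin_contains_mu(self):
        sl = L.make_soft_label(37.0)
        assert sl.bin_centers[sl.probs.argmax()] == 37.0

    def test_age_outside_range_rejected(self):
        with pytest.raises(ValueError):
            L.make_soft_label(150.0)

    def test_kl_hand_values_and_asymmetry(self):
        assert L.kl_task_loss([0.5, 0.5], [0.75, 0.25]) == pytest.approx(
            0.1308, abs=1e-4)
        assert L.kl_task_loss([0.75, 0.25], [0.5, 0.5]) == pytest.approx(
            0.1438, abs=1e-4)

    def test_kl_zero_iff_identical(self):
        assert L.kl_task_loss([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_kl_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.dirichlet(np.ones(5))
        p = rng.dirichlet(np.ones(5))
        assert L.kl_task_loss(p, t) >= -1e-10


class TestAgePointEstimate:
    def test_degenerate_distribution(self):
        p = np.zeros(101)
        p[65] = 1.0
        assert L.age_point_estimate(p, np.arange(101)) == 65.0

    def test_uniform_gives_midpoint(self):
        p = np.full(101, 1 / 101)
        assert L.age_point_estimate(p, np.arange(101)) == pytest.approx(50.0)

    def test_bimodal_expectation(self):
        assert L.age_point_estimate([0.5, 0.5], [40, 60]) == pytest.approx(50.0)

    def test_argmax_option(self):
        assert L.age_point_estimate([0.6, 0.4], [40, 60], method="argmax") == 40.0
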