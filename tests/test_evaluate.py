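"""Screening metrics against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genscreen.evaluate import (PSNR_INF, auroc, auroc_ci, compare_groups,
                                confusion_metrics, fixed_sensitivity_threshold,
                                recon_quality, screening_report)


def pairwise_auroc(scores, labels):
    """Brute-force Mann-Whitney: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant(self):
        assert auroc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_fuzzed_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)
            assert auroc(scores, labels) == pytest.approx(
                pairwise_auroc(scores, labels), abs=1e-12
            )


class TestAurocCI:
    def test_perfectly_separated_interval_is_degenerate(self):
        lo, hi = auroc_ci([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0], n_boot=200)
        assert lo == 1.0 and hi == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a = auroc_ci(scores, labels, n_boot=300, seed=7)
        b = auroc_ci(scores, labels, n_boot=300, seed=7)
        assert a == b

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(40, int), np.zeros(60, int)]
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 60)]
        lo, hi = auroc_ci(scores, labels, n_boot=500, seed=0)
        assert lo <= auroc(scores, labels) <= hi

    def test_delong_agrees_with_bootstrap_on_gaussian_scores(self):
        rng = np.random.default_rng(4)
        labels = np.r_[np.ones(80, int), np.zeros(120, int)]
        scores = np.r_[rng.normal(1, 1, 80), rng.normal(0, 1, 120)]
        lo_d, hi_d = auroc_ci(scores, labels, method="delong")
        lo_b, hi_b = auroc_ci(scores, labels, n_boot=2000, seed=0)
        point = auroc(scores, labels)
        assert lo_d <= point <= hi_d
        assert abs(lo_d - lo_b) < 0.04 and abs(hi_d - hi_b) < 0.04

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            auroc_ci([0.1, 0.9], [0, 1], method="jackknife")

    def test_coverage_of_analytic_auroc(self):
        # balanced Gaussian shift delta: true AUROC = Phi(delta/sqrt(2))
        from scipy.stats import norm

        delta = 1.0
        true_auc = norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(3)
        hits = 0
        reps = 50
        for _ in range(reps):
            pos = rng.normal(delta, 1, 1000)
            neg = rng.normal(0, 1, 1000)
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(1000, int), np.zeros(1000, int)]
            lo, hi = auroc_ci(scores, labels, n_boot=200,
                              seed=int(rng.integers(2**31)))
            hits += lo <= true_auc <= hi
        assert hits / reps >= 0.9


class TestFixedSensitivityThreshold:
    def test_all_positives_must_be_captured(self):
        scores = [0.9, 0.1, 0.5]
        labels = [1, 1, 0]
        # ceil(0.9 * 2) = 2: both positives needed -> threshold at 0.1
        assert fixed_sensitivity_threshold(scores, labels, 0.9) == 0.1

    def test_separable_scores_give_perfect_specificity(self):
        scores = [0.9, 0.8, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0]
        t = fixed_sensitivity_threshold(scores, labels, 0.9)
        rep = confusion_metrics(scores, labels, t)
        assert rep.sensitivity >= 0.9
        assert rep.specificity == 1.0

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            fixed_sensitivity_threshold([0.1, 0.9], [0, 1], 0.0)
        with pytest.raises(ValueError):
            fixed_sensitivity_threshold([0.1, 0.9], [0, 1], 1.5)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_tightness_on_fuzzed_scores(self, data):
        n_pos = data.draw(st.integers(2, 25))
        n_neg = data.draw(st.integers(2, 25))
        vals = st.sampled_from([0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 0.9])
        pos = data.draw(st.lists(vals, min_size=n_pos, max_size=n_pos))
        neg = data.draw(st.lists(vals, min_size=n_neg, max_size=n_neg))
        scores = np.array(pos + neg)
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        t = fixed_sensitivity_threshold(scores, labels, 0.9)
        sens = ((scores >= t) & (labels == 1)).sum() / n_pos
        assert sens >= 0.9
        higher = np.unique(scores[scores > t])
        if higher.size:
            t2 = higher.min()
            sens2 = ((scores >= t2) & (labels == 1)).sum() / n_pos
            assert sens2 < 0.9


class TestConfusionMetrics:
    def test_hand_computed_rates(self):
        scores = np.r_[np.full(9, 0.8), [0.2], np.full(7, 0.1), np.full(3, 0.9)]
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        rep = confusion_metrics(scores, labels, 0.5)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (9, 1, 7, 3)
        assert rep.sensitivity == 0.9
        assert rep.specificity == 0.7
        assert rep.ppv == 0.75
        assert rep.npv == 0.875
        assert rep.accuracy == 0.8

    def test_threshold_extremes(self):
        scores = [0.2, 0.4, 0.6, 0.8]
        labels = [0, 1, 0, 1]
        low = confusion_metrics(scores, labels, 0.0)
        assert low.sensitivity == 1.0 and low.specificity == 0.0
        high = confusion_metrics(scores, labels, 0.9)
        assert high.sensitivity == 0.0 and high.specificity == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_rate_invariants_on_fuzzed_tables(self, data):
        n = data.draw(st.integers(4, 60))
        labels = np.array(
            data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        )
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.array(
            data.draw(
                st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
            )
        )
        t = data.draw(st.floats(0.05, 0.95))
        rep = confusion_metrics(scores, labels, t)
        assert rep.tp + rep.fp + rep.tn + rep.fn == n
        if rep.tp + rep.fn:
            assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        if rep.tn + rep.fp:
            assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))
        for rate in (rep.sensitivity, rep.specificity, rep.accuracy):
            assert np.isnan(rate) or 0.0 <= rate <= 1.0


class TestReconQuality:
    def test_identical_images(self):
        img = np.random.default_rng(0).random((32, 32))
        q = recon_quality(img, img)
        assert q.rmse == 0.0
        assert q.psnr == PSNR_INF
        assert q.ssim == pytest.approx(1.0)

    def test_constant_offset_closed_form(self):
        img = np.full((64, 64), 0.4)
        shifted = img + 10.0 / 255.0
        q = recon_quality(img, shifted)
        assert q.rmse == pytest.approx(10.0, abs=1e-9)
        assert q.psnr == pytest.approx(20.0 * np.log10(25.5), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recon_quality(np.zeros((8, 8)), np.zeros((8, 9)))

    def test_checkerboard_vs_inverse_matches_reference(self):
        yy, xx = np.mgrid[0:32, 0:32]
        board = ((yy + xx) % 2).astype(float)
        from skimage.metrics import structural_similarity

        expected = structural_similarity(
            board * 255, (1 - board) * 255, data_range=255.0, win_size=7
        )
        q = recon_quality(board, 1 - board)
        assert q.ssim == pytest.approx(expected, abs=1e-6)


class TestCompareGroups:
    def test_identical_groups_paired_is_degenerate(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "paired")
        assert res.degenerate and res.t == 0.0 and res.p == 1.0

    def test_identical_groups_independent(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "independent")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_welch_matches_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va / 4 + vb / 4)
        nu = (va / 4 + vb / 4) ** 2 / (
            (va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3
        )
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), nu)
        res = compare_groups(a, b, "independent")
        assert res.t == pytest.approx(t_hand)
        assert res.p == pytest.approx(p_hand)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0], "paired")


def test_screening_report_end_to_end():
    rng = np.random.default_rng(5)
    labels = np.r_[np.ones(50, int), np.zeros(100, int)]
    scores = np.r_[rng.normal(1.2, 1, 50), rng.normal(0, 1, 100)]
    rep = screening_report(scores, labels, target_sensitivity=0.9,
                           n_boot=300, seed=0)
    assert rep.sensitivity >= 0.9
    assert rep.ci_low <= rep.auroc <= rep.ci_high
    text = rep.to_json()
    assert '"auroc"' in text
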