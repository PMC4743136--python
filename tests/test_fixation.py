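"""Threshold sweep, linear discriminants, decisions and performance counts."""

import numpy as np
import pytest

from rbscreen import (
    LDAModel,
    ThresholdModel,
    classify_record,
    evaluate,
    fit_lda,
    load_model,
    save_model,
    session_decision,
    sweep_threshold,
)
from rbscreen.fixation import lda_features
from rbscreen.spectral import NormalizedFeatures


def nf(r_cf=1.0, r_para=0.5, r25=0.5, r65=0.5, r35=0.25, r55=0.25):
    return NormalizedFeatures(r_cf=r_cf, r_para=r_para, r25=r25, r65=r65,
                              r35=r35, r55=r55)


class TestSweepThreshold:
    def test_imbalanced_classes_pull_to_grid_edge(self):
        # the pooled L1 objective is dominated by the larger class; with 480
        # para values at 0.2 the minimizer sits at the grid floor 0.3
        m = sweep_threshold([2.0] * 120, [0.2] * 480)
        assert m.theta == pytest.approx(0.3)

    def test_tie_breaks_to_smallest_theta(self):
        m = sweep_threshold([1.5] * 50, [0.5] * 50)
        assert m.theta == pytest.approx(0.5)

    def test_single_point_classes(self):
        m = sweep_threshold([1.0], [1.0])
        assert m.theta == pytest.approx(1.0)

    def test_grid_minimizer_is_pooled_median(self, rng):
        # independent oracle: the L1 minimizer is the grid point nearest the
        # pooled median (clipped into the grid)
        grid = ThresholdModel().grid
        for _ in range(20):
            # odd pooled count -> unique median, unique L1 minimizer
            n_cf = int(rng.integers(5, 60))
            n_para = int(rng.integers(5, 60)) | 1
            if n_cf % 2 == 1:
                n_para += 1
            cf = rng.lognormal(0.3, 0.6, size=n_cf)
            para = rng.lognormal(-1.5, 0.8, size=n_para)
            m = sweep_threshold(cf, para)
            pooled = np.concatenate([cf, para])
            med = np.median(pooled)
            expected = grid[np.argmin(np.abs(grid - np.clip(med, grid[0], grid[-1])))]
            # brute-force objective check on the full grid (leftmost tie)
            obj = np.array([np.sum(np.abs(pooled - t)) for t in grid])
            brute = grid[np.argmax(obj <= obj.min() * (1 + 1e-12) + 1e-12)]
            assert m.theta == pytest.approx(brute, abs=1e-12)
            assert abs(m.theta - expected) <= m.grid_step + 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold([], [1.0])

    def test_monotonicity_of_decision(self):
        v = nf(r_cf=1.2)
        passes = [
            classify_record(v, ThresholdModel(theta=t)) for t in (0.5, 1.0, 1.3, 2.0)
        ]
        # once failing, raising theta never flips back to pass
        assert passes == sorted(passes, reverse=True)


class TestLDA:
    def test_mirrored_clouds_recover_separating_plane(self, rng):
        # two spherical clouds mirrored about the plane x0 = 1: the fitted
        # boundary normal is e0 and the offset is 1
        base = rng.normal(size=(200, 3)) * 0.3
        cf = base + [2.0, 0.0, 0.0]
        para = base * np.array([-1, 1, 1]) + [0.0, 0.0, 0.0]
        X = np.vstack([cf, para])
        y = np.r_[np.ones(200), np.zeros(200)]
        m = fit_lda(X, y)
        n = m.L / np.linalg.norm(m.L)
        np.testing.assert_allclose(np.abs(n), [1, 0, 0], atol=1e-6)
        # boundary crosses x0 = 1: K + [1,0,0] L = 0
        assert m.K + m.L[0] == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_mahalanobis_oracle(self, rng):
        cf = rng.multivariate_normal([2, 1, 3], np.diag([0.5, 0.3, 0.8]), 80)
        para = rng.multivariate_normal([0.5, 0.8, 0.6], np.diag([0.5, 0.3, 0.8]), 120)
        X = np.vstack([cf, para])
        y = np.r_[np.ones(80), np.zeros(120)]
        m = fit_lda(X, y)
        mu1, mu0 = cf.mean(0), para.mean(0)
        S = (
            (cf - mu1).T @ (cf - mu1) + (para - mu0).T @ (para - mu0)
        ) / (len(X) - 2)
        Sinv = np.linalg.inv(S)
        pts = rng.normal(1.0, 1.5, size=(50, 3))
        for p in pts:
            maha = ((p - mu1) @ Sinv @ (p - mu1)) < ((p - mu0) @ Sinv @ (p - mu0))
            assert (float(m.K + p @ m.L) > 0) == bool(maha)

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        cf = rng.normal([2, 1], 0.4, size=(60, 2))
        para = rng.normal([0, 0], 0.4, size=(90, 2))
        X = np.vstack([cf, para])
        y = np.r_[np.ones(60), np.zeros(90)]
        m = fit_lda(X, y)
        ref = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        pts = rng.normal(1.0, 1.0, size=(40, 2))
        ours = (pts @ m.L + m.K) > 0
        np.testing.assert_array_equal(ours, ref.predict(pts).astype(bool))

    def test_a_coefficient_conversion(self):
        m = LDAModel(dims=3, K=2.0, L=np.array([1.0, -3.0, 4.0]))
        np.testing.assert_allclose(m.a, [-0.5, -0.25, 0.75])
        assert m.a[0] == pytest.approx(-m.K / m.L[2])

    def test_published_3d_coefficients_example(self):
        # a0=0.768, a1=0.056, a2=-0.289: at x=0.5, y=1.0 the boundary sits at
        # z = 0.507, so a measurement with P6.5/P4.5 = 1.0 passes
        m = LDAModel.from_a([0.768, 0.056, -0.289])
        v = nf(r_para=0.5, r25=1.0, r65=1.0)
        z = m.a[0] + m.a[1] * 0.5 + m.a[2] * 1.0
        assert z == pytest.approx(0.507, abs=1e-12)
        assert classify_record(v, m)
        # exactly on the plane: strict inequality fails
        v_on = nf(r_para=0.5, r25=1.0, r65=z)
        assert not classify_record(v_on, m)

    def test_feature_maps(self):
        v = nf(r_cf=1.1, r_para=0.7, r25=0.6, r65=0.5, r35=0.4, r55=0.3)
        np.testing.assert_allclose(lda_features(v, 2), [0.7, 1.1])
        np.testing.assert_allclose(lda_features(v, 3), [0.7, 0.6, 0.5])
        np.testing.assert_allclose(lda_features(v, 4), [0.4, 0.3, 0.6, 0.5])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.ones((3, 2)), [1, 0, 0])


class TestThresholdClassification:
    def test_pass_above_published_theta(self):
        assert classify_record(nf(r_cf=1.0), ThresholdModel(theta=0.8750))

    def test_exact_boundary_fails(self):
        assert not classify_record(nf(r_cf=0.8750), ThresholdModel(theta=0.8750))


class TestSessionDecision:
    @pytest.mark.parametrize(
        "n_pass, expected", [(2, True), (1, False), (12, True), (0, False)]
    )
    def test_two_of_twelve_rule(self, n_pass, expected):
        flags = [True] * n_pass + [False] * (12 - n_pass)
        assert session_decision(flags) is expected

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            session_decision([True] * 11)


class TestEvaluate:
    def test_fd_row_arithmetic(self):
        # 17 TN, 2 FP, 18 TP, 0 FN -> sensitivity 100 %, specificity 89.5 %
        pred = [False] * 17 + [True] * 2 + [True] * 18
        gold = [False] * 19 + [True] * 18
        r = evaluate(pred, gold)
        assert (r["TN"], r["FP"], r["TP"], r["FN"]) == (17, 2, 18, 0)
        assert r["sensitivity_pct"] == pytest.approx(100.0)
        assert r["specificity_pct"] == pytest.approx(89.5, abs=0.05)

    def test_combined_row_arithmetic(self):
        pred = [False] * 36 + [True] * 2 + [True] * 36
        gold = [False] * 38 + [True] * 36
        r = evaluate(pred, gold)
        assert r["specificity_pct"] == pytest.approx(94.7, abs=0.05)
        assert r["sensitivity_pct"] == pytest.approx(100.0)

    def test_all_correct(self):
        r = evaluate([True, False], [True, False])
        assert r["sensitivity_pct"] == 100.0 and r["specificity_pct"] == 100.0

    def test_undefined_rate_reported_absent(self):
        r = evaluate([False, False], [False, False])
        assert r["sensitivity_pct"] is None


class TestModelIO:
    def test_threshold_round_trip(self, tmp_path):
        m = sweep_threshold([1.5] * 5, [0.2] * 5)
        p = save_model(m, tmp_path / "m.json")
        back = load_model(p)
        assert isinstance(back, ThresholdModel)
        assert back.theta == m.theta

    def test_lda_round_trip(self, tmp_path):
        m = LDAModel.from_a([0.768, 0.056, -0.289])
        back = load_model(save_model(m, tmp_path / "m.json"))
        assert back.dims == 3
        np.testing.assert_allclose(back.a, m.a)
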