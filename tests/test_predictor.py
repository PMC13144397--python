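"""Four-step cross-validated predictor: ranking, LOOCV, threshold search,
surrogate significance, leakage safety."""

import numpy as np
import pytest

from entropath import (
    FeatureTensor,
    allsensor_control,
    fit_final_predictor,
    loocv_r2,
    optimize_threshold,
    rank_features,
)
from entropath.predictor import _loocv_engine


def _tensor(values, subjects=None):
    values = np.asarray(values)
    n, e, t = values.shape
    return FeatureTensor(
        values=values,
        feature_name="LZc",
        subjects=tuple(subjects or (f"sub-{i:02d}" for i in range(n))),
        electrodes=tuple(f"E{i}" for i in range(e)),
        timepoints=tuple(f"T{i}" for i in range(t)),
    )


class TestRankFeatures:
    def test_self_correlated_feature_ranked_first(self, rng):
        vals = rng.standard_normal((10, 3, 3))
        target = vals[:, 1, 2].copy()
        ranked = rank_features(_tensor(vals), target)
        el, tp, r = ranked.entries[0]
        assert (el, tp) == ("E1", "T2")
        assert r == pytest.approx(1.0)

    def test_entry_count_matches_grid(self, rng):
        ranked = rank_features(_tensor(rng.standard_normal((8, 3, 3))), rng.standard_normal(8))
        assert len(ranked.entries) == 9
        rs = [e[2] for e in ranked.entries]
        assert rs == sorted(rs, reverse=True)
        assert all(abs(r) <= 1 for r in rs)

    def test_null_targets_rarely_reach_high_correlation(self):
        """At n=28 the maximal spurious |r| over 57 features stays below 0.6."""
        hits = 0
        for s in range(60):
            r2 = np.random.default_rng(s)
            ranked = rank_features(
                _tensor(r2.standard_normal((28, 19, 3))), r2.standard_normal(28)
            )
            rs = np.array([e[2] for e in ranked.entries])
            hits += np.abs(rs).max() < 0.6
        assert hits >= 57  # >= 95%

    def test_zero_variance_feature_warns_and_ranks_zero(self, rng):
        vals = rng.standard_normal((10, 2, 2))
        vals[:, 0, 0] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            ranked = rank_features(_tensor(vals), rng.standard_normal(10))
        r_const = [e for e in ranked.entries if (e[0], e[1]) == ("E0", "T0")][0][2]
        assert r_const == 0.0

    def test_too_few_subjects_error(self, rng):
        with pytest.raises(ValueError, match="4 subjects"):
            rank_features(_tensor(rng.standard_normal((3, 2, 2))), np.zeros(3))


class TestLoocvR2:
    def test_noiseless_single_feature_recovery(self, rng):
        X = rng.standard_normal((28, 57))
        y = 2.0 * X[:, 10] + 1.0
        assert loocv_r2(X, y, 0.85) > 0.99

    def test_null_data_negative_r2_median(self):
        r2s = []
        for s in range(60):
            r = np.random.default_rng(200 + s)
            r2s.append(loocv_r2(r.standard_normal((28, 57)), r.standard_normal(28), 0.3))
        assert np.median(r2s) <= 0.0

    def test_planted_effect_yields_positive_r2(self):
        vals = []
        for s in range(40):
            r = np.random.default_rng(500 + s)
            y = r.standard_normal(28)
            X = r.standard_normal((28, 57))
            X[:, 7] = 0.7 * y + np.sqrt(1 - 0.49) * r.standard_normal(28)
            vals.append(loocv_r2(X, y, 0.5))
        assert np.mean(vals) > 0.2

    def test_invalid_theta(self, rng):
        with pytest.raises(ValueError, match="theta"):
            loocv_r2(rng.standard_normal((10, 5)), rng.standard_normal(10), 1.2)


class TestOptimizeThreshold:
    def test_singleton_grid_returned(self, rng):
        X = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        assert optimize_threshold(X, y, theta_grid=[0.25]) == 0.25

    def test_perfect_predictor_gets_high_threshold(self):
        r = np.random.default_rng(0)
        y = r.standard_normal(28)
        X = r.standard_normal((28, 57))
        X[:, 3] = y
        theta = optimize_threshold(X, y)
        assert theta >= 0.6
        m = fit_final_predictor(X, y, theta_star=theta, n_perm=0)
        assert ("f3", "-") in m.selected_features
        assert len(m.selected_features) <= 3

    def test_flat_curve_tie_breaks_to_largest(self, rng):
        # a grid entirely above any attainable correlation: every fold selects
        # nothing, every theta scores identically, the largest theta wins
        X = rng.standard_normal((16, 4)) * 1e-2
        y = rng.standard_normal(16)
        with pytest.raises(ValueError, match="revise"):
            optimize_threshold(X, y, theta_grid=[0.97, 0.98, 0.99])

    def test_empty_grid_error(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            optimize_threshold(rng.standard_normal((10, 4)), rng.standard_normal(10), theta_grid=[])


class TestFinalPredictor:
    def test_surrogate_p_monotone_in_effect_strength(self):
        r = np.random.default_rng(5)
        y = r.standard_normal(28)
        X_null = r.standard_normal((28, 57))
        X_strong = X_null.copy()
        X_strong[:, 4] = 0.9 * y + 0.2 * r.standard_normal(28)
        p_null = fit_final_predictor(X_null, y, n_perm=300, seed=0).surrogate_p
        p_strong = fit_final_predictor(X_strong, y, n_perm=300, seed=0).surrogate_p
        assert p_strong < p_null
        assert p_strong < 0.05

    def test_determinism_given_seed(self, rng):
        X = rng.standard_normal((20, 12))
        y = rng.standard_normal(20)
        m1 = fit_final_predictor(X, y, n_perm=200, seed=42)
        m2 = fit_final_predictor(X, y, n_perm=200, seed=42)
        assert m1.surrogate_p == m2.surrogate_p
        assert m1.theta_star == m2.theta_star
        assert np.array_equal(m1.predictions, m2.predictions)

    def test_p_in_open_unit_interval(self, rng):
        X = rng.standard_normal((16, 8))
        y = rng.standard_normal(16)
        m = fit_final_predictor(X, y, n_perm=100, seed=1)
        assert 0.0 < m.surrogate_p <= 1.0

    def test_leakage_probe_held_out_target_does_not_change_prediction(self):
        """Corrupting one subject's target must not move its own prediction."""
        r = np.random.default_rng(7)
        y = r.standard_normal(20)
        X = r.standard_normal((20, 10))
        X[:, 2] = 0.8 * y + 0.3 * r.standard_normal(20)
        theta = 0.4
        m_clean = fit_final_predictor(X, y, theta_star=theta, n_perm=0)
        y_corrupt = y.copy()
        y_corrupt[5] += 100.0
        m_corrupt = fit_final_predictor(X, y_corrupt, theta_star=theta, n_perm=0)
        assert m_corrupt.predictions[5] == pytest.approx(m_clean.predictions[5])

    def test_engine_matches_direct_loocv(self, rng):
        """The batched engine and the public single-theta path agree."""
        X = rng.standard_normal((14, 9))
        y = rng.standard_normal(14)
        grid = np.array([0.0, 0.2, 0.4])
        _, r2, _ = _loocv_engine(X, y[:, None], grid)
        for g, theta in enumerate(grid):
            assert r2[0, g] == pytest.approx(loocv_r2(X, y, float(theta)))


class TestAllSensorControl:
    def test_bonferroni_factor_is_timepoint_count(self, rng):
        vals = rng.standard_normal((20, 19, 3))
        y = rng.standard_normal(20)
        out = allsensor_control(_tensor(vals), y, timepoints=("T0", "T1", "T2"), n_perm=200, seed=0)
        for tp in ("T0", "T1", "T2"):
            assert out[tp]["p_bonferroni"] == pytest.approx(min(1.0, 3 * out[tp]["p"]))

    def test_global_effect_detected_with_positive_sign(self):
        r = np.random.default_rng(3)
        y = r.standard_normal(24)
        vals = r.standard_normal((24, 19, 3)) * 0.3
        vals[:, :, 1] += y[:, None]  # global entropy effect at one timepoint
        out = allsensor_control(_tensor(vals), y, timepoints=("T1",), n_perm=300, seed=0)
        assert out["T1"]["r2"] > 0.2
        assert out["T1"]["p_bonferroni"] < 0.05
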