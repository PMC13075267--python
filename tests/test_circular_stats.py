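import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import babyimu as bi
from babyimu.circular_stats import UndefinedCircularMeanError

from conftest import make_static_recording


class TestCircularMean:
    def test_constant_series(self):
        mean, rbar = bi.circular_mean([10.0, 10.0, 10.0])
        assert mean == pytest.approx(10.0)
        assert rbar == pytest.approx(1.0)

    def test_wrap_around_symmetry(self):
        mean, _ = bi.circular_mean([350.0, 10.0])
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_uniform_four_points_undefined(self):
        with pytest.raises(UndefinedCircularMeanError):
            bi.circular_mean([0.0, 90.0, 180.0, 270.0])

    def test_matches_scipy_circmean(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(40.0, 30.0, 500)
        mean, _ = bi.circular_mean(theta)
        ref = np.degrees(stats.circmean(np.radians(theta),
                                        high=np.pi, low=-np.pi))
        assert mean == pytest.approx(ref, abs=1e-9)


class TestCircularSd:
    def test_constant_series_has_zero_sd(self):
        assert bi.circular_sd(np.full(100, 42.0)) == pytest.approx(0.0,
                                                                   abs=1e-6)

    def test_recovers_wrapped_normal_sigma(self):
        rng = np.random.default_rng(12345)
        theta = rng.normal(0.0, 10.0, 10_000)
        assert bi.circular_sd(theta) == pytest.approx(10.0, abs=0.5)

    def test_agrees_with_linear_sd_for_tight_data(self):
        rng = np.random.default_rng(7)
        for sigma in (5.0, 10.0, 15.0):
            theta = rng.normal(100.0, sigma, 20_000)
            csd = bi.circular_sd(theta)
            assert csd == pytest.approx(float(np.std(theta)), rel=0.02)

    def test_matches_scipy_circstd(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(-20.0, 25.0, 1000)
        ref = np.degrees(stats.circstd(np.radians(theta)))
        assert bi.circular_sd(theta) == pytest.approx(ref, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(offset=st.floats(-720.0, 720.0))
    def test_rotation_offset_invariance(self, offset):
        rng = np.random.default_rng(9)
        theta = rng.normal(0.0, 20.0, 300)
        base = bi.circular_sd(theta)
        assert bi.circular_sd(theta + offset) == pytest.approx(base, abs=1e-9)


class TestCircularCovariance:
    def test_constant_axes_give_zero_matrix(self):
        c = np.full(50, 5.0)
        cov = bi.circular_covariance_matrix(c, c + 10, c - 30)
        np.testing.assert_allclose(cov, 0.0, atol=1e-12)

    def test_independent_tight_axes_diagonal_in_rad_squared(self):
        rng = np.random.default_rng(21)
        sigmas = (5.0, 8.0, 11.0)
        series = [rng.normal(0, s, 50_000) for s in sigmas]
        cov = bi.circular_covariance_matrix(*series)
        for j, s in enumerate(sigmas):
            assert cov[j, j] == pytest.approx(np.radians(s) ** 2, rel=0.05)
        off = cov[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 3e-4)

    def test_duplicated_axis_is_rank_deficient(self):
        rng = np.random.default_rng(5)
        pitch = rng.normal(0, 12.0, 1000)
        yaw = rng.normal(0, 20.0, 1000)
        cov = bi.circular_covariance_matrix(pitch, pitch, yaw)
        assert bi.generalized_variance(cov) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_positive_semidefinite(self):
        rng = np.random.default_rng(6)
        cov = bi.circular_covariance_matrix(rng.normal(0, 30, 500),
                                            rng.normal(10, 50, 500),
                                            rng.normal(-40, 70, 500))
        np.testing.assert_allclose(cov, cov.T, atol=1e-15)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_linearized_variant_agrees_for_tight_data(self):
        rng = np.random.default_rng(8)
        series = [rng.normal(0, 5.0, 5000) for _ in range(3)]
        sine = bi.circular_covariance_matrix(*series, definition="sine")
        lin = bi.circular_covariance_matrix(*series, definition="linearized")
        np.testing.assert_allclose(sine, lin, rtol=0.02, atol=1e-6)


class TestGeneralizedVariance:
    def test_zero_matrix(self):
        assert bi.generalized_variance(np.zeros((3, 3))) == 0.0

    def test_diagonal_closed_form(self):
        assert bi.generalized_variance(np.diag([2.0, 3.0, 4.0])) == \
            pytest.approx(24.0)

    def test_matches_cofactor_expansion_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            cov = a @ a.T
            m = cov
            brute = (m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
                     - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
                     + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0]))
            assert bi.generalized_variance(cov) == pytest.approx(
                brute, abs=1e-12 * max(1.0, abs(brute)))

    def test_non_symmetric_rejected(self):
        m = np.diag([1.0, 2.0, 3.0])
        m[0, 1] = 0.5
        with pytest.raises(ValueError):
            bi.generalized_variance(m)

    def test_hadamard_inequality_on_computed_matrices(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            L = rng.normal(size=(3, 3))
            corr = L @ L.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
            z = rng.multivariate_normal(np.zeros(3), corr, size=2000)
            series = [np.degrees(z[:, j]) * s
                      for j, s in enumerate((10.0, 20.0, 30.0))]
            cov = bi.circular_covariance_matrix(*series)
            assert bi.generalized_variance(cov) <= np.prod(np.diag(cov)) + 1e-15

    def test_small_dispersion_limit_is_product_of_linear_variances(self):
        rng = np.random.default_rng(23)
        series = [rng.normal(0, 5.0, 100_000) for _ in range(3)]
        cov = bi.circular_covariance_matrix(*series)
        gv = bi.generalized_variance(cov)
        prod = np.prod([np.var(np.radians(s)) for s in series])
        assert gv == pytest.approx(prod, rel=0.05)


class TestWindowMetrics:
    def test_static_recording_has_near_zero_metrics(self):
        rec = make_static_recording(pitch=15.0, roll=30.0, duration=30.0,
                                    noise=bi.NoiseParams(0.01, 0.02, 0.001),
                                    seed=2)
        orient = bi.fuse(rec)
        m = bi.window_metrics(orient, (5.0, 30.0))
        assert m.pitch_csd < 0.5
        assert m.roll_csd < 0.5
        assert m.yaw_csd < 0.5
        assert m.gen_var < 1e-9

    def test_recovers_generating_dispersions(self, default_truth,
                                             fused_default):
        m = bi.window_metrics(fused_default, (5.0, 300.0))
        targets = default_truth.config.movement.per_axis_dispersion
        assert m.pitch_csd == pytest.approx(targets[0], rel=0.10)
        assert m.roll_csd == pytest.approx(targets[1], rel=0.10)
        assert m.yaw_csd == pytest.approx(targets[2], rel=0.10)
        assert m.gen_var > 0.0
        assert m.n > 5000

    def test_invariant_to_adding_full_turns(self, fused_default):
        base = bi.window_metrics(fused_default, (10.0, 200.0))
        shifted = bi.OrientationSeries(
            time=fused_default.time, quat=fused_default.quat,
            pitch=fused_default.pitch,
            roll=fused_default.roll + 360.0,
            yaw=fused_default.yaw - 720.0,
            fs=fused_default.fs, flags=fused_default.flags, mode="fused")
        m = bi.window_metrics(shifted, (10.0, 200.0))
        assert m.roll_csd == pytest.approx(base.roll_csd, abs=1e-9)
        assert m.yaw_csd == pytest.approx(base.yaw_csd, abs=1e-9)
        assert m.gen_var == pytest.approx(base.gen_var, rel=1e-9)

    def test_warmup_samples_excluded(self, fused_default):
        m = bi.window_metrics(fused_default, (0.0, 300.0))
        assert m.n <= fused_default.n_samples - int(5.0 * fused_default.fs)

    def test_insufficient_data_raises(self, fused_default):
        with pytest.raises(ValueError, match="insufficient"):
            bi.window_metrics(fused_default, (0.0, 1.0))  # inside warm-up
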