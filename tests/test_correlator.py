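"""Correlation estimators: brute-force oracle, multi-tau, error estimates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fccs_kin as fk
from fccs_kin.correlate import CorrelationCurve
from fccs_kin.simulate import ChannelTrace


def brute_force_g(a, b, lag):
    """Independent lagged-product oracle with symmetric normalisation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size - lag
    prods = [a[i] * b[i + lag] for i in range(n)]
    mean_a = sum(a[:n]) / n
    mean_b = sum(b[lag:]) / n
    return sum(prods) / n / (mean_a * mean_b) - 1.0


def channel(arr, bin_width=1.0):
    return ChannelTrace(np.asarray(arr), bin_width)


class TestDirectEstimator:
    def test_constant_trace_has_zero_correlation(self):
        curve = fk.correlate_direct(channel([5] * 64), channel([5] * 64), 8)
        assert np.allclose(curve.G, 0.0, atol=1e-14)

    def test_cross_of_identical_traces_equals_auto(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(4.0, 512)
        auto = fk.correlate_direct(channel(a), channel(a), 20)
        cross = fk.correlate_direct(channel(a), channel(a.copy()), 20)
        assert np.allclose(auto.G, cross.G, rtol=1e-12)

    def test_alternating_trace_exact_values(self):
        """[1,0,1,0,...] x 64: G(1) = -1 and G(2) = +1 exactly."""
        a = np.tile([1, 0], 32)
        curve = fk.correlate_direct(channel(a), channel(a), 2)
        assert curve.G[0] == pytest.approx(-1.0, abs=1e-12)
        assert curve.G[1] == pytest.approx(1.0, abs=1e-12)
        assert curve.G[0] == pytest.approx(-curve.G[1], abs=1e-12)
        # agree with the independent brute-force oracle
        for lag_idx, lag in enumerate((1, 2)):
            assert curve.G[lag_idx] == pytest.approx(brute_force_g(a, a, lag), abs=1e-12)

    def test_zero_mean_channel_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            fk.correlate_direct(channel([0] * 64), channel([0] * 64), 4)

    def test_mismatched_traces_rejected(self):
        with pytest.raises(ValueError):
            fk.correlate_direct(channel([1] * 64), channel([1] * 32), 4)


class TestMultiTau:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_level0_matches_direct_estimator(self, seed):
        """Multi-tau level-0 lags equal the direct oracle to 1e-10 relative."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(64, 512))
        a = rng.poisson(3.0, n) + 1  # +1 keeps means positive
        mt = fk.autocorrelate_multitau(channel(a), m=16, levels=1)
        direct = fk.correlate_direct(channel(a), channel(a), 16)
        np.testing.assert_allclose(mt.G, direct.G, rtol=1e-10, atol=1e-12)

    def test_coarse_level_matches_direct_on_decimated_trace(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(5.0, 4096).astype(float)
        mt = fk.autocorrelate_multitau(channel(a), m=16, levels=2)
        a2 = 0.5 * (a[0::2] + a[1::2])
        direct2 = fk.correlate_direct(channel(a2, 2.0), channel(a2, 2.0), 16)
        # level-1 lags are 9..16 at doubled bin width
        np.testing.assert_allclose(mt.G[16:], direct2.G[8:], rtol=1e-10)
        assert np.all(np.diff(mt.lags) > 0)

    def test_constant_trace_zero_everywhere(self):
        mt = fk.autocorrelate_multitau(channel([7] * 2048), m=16, levels=3)
        assert np.allclose(mt.G, 0.0, atol=1e-13)

    def test_too_short_trace_names_minimum_length(self):
        with pytest.raises(ValueError, match=str(16 * 2**4)):
            fk.autocorrelate_multitau(channel([1] * 100), m=16, levels=4)

    def test_odd_or_small_m_rejected(self):
        for m in (7, 15, 4):
            with pytest.raises(ValueError, match="m must be"):
                fk.autocorrelate_multitau(channel([1, 2] * 256), m=m, levels=1)

    def test_cross_of_independent_traces_is_null(self):
        """|G| < 3 G_err for >= 95% of lags on independent Poisson traces."""
        rng = np.random.default_rng(12)
        a = rng.poisson(5.0, 2**15)
        b = rng.poisson(5.0, 2**15)
        curve = fk.estimate_curve_errors(channel(a), channel(b), n_segments=8)
        ok = np.abs(curve.G) < 3 * np.maximum(curve.G_err, 1e-12)
        assert ok.mean() >= 0.95

    def test_cross_symmetry_within_noise(self):
        """cross(A,B) equals cross(B,A) within 3 estimator errors."""
        rng = np.random.default_rng(3)
        base = np.repeat(rng.poisson(4.0, 2**12), 8)  # correlated common signal
        a = base + rng.poisson(2.0, base.size)
        b = base + rng.poisson(2.0, base.size)
        ab = fk.estimate_curve_errors(channel(a), channel(b), n_segments=8)
        ba = fk.estimate_curve_errors(channel(b), channel(a), n_segments=8)
        err = np.sqrt(ab.G_err**2 + ba.G_err**2) + 1e-12
        assert np.mean(np.abs(ab.G - ba.G) < 3 * err) >= 0.9

    def test_fitted_diffusion_time_matches_input(self, geometry, n2_trace, n2_system):
        """Simulated single species: fitted tau_D ~ w_xy^2/(4D) within 15%."""
        curve = fk.autocorrelate_multitau(n2_trace.green)
        fit = fk.fit_autocorrelation(curve, s=geometry.s)
        expected = geometry.w_xy**2 / (4 * n2_system.ligand.D)
        assert fit.tau_D == pytest.approx(expected, rel=0.15)


class TestCurveErrors:
    def test_segment_mean_consistent_with_full_trace(self, n2_trace):
        seg = fk.estimate_curve_errors(n2_trace.green, n_segments=4, m=16, levels=6)
        full = fk.autocorrelate_multitau(n2_trace.green, m=16, levels=6)
        ok = np.abs(seg.G - full.G) < 3 * np.maximum(seg.G_err, 1e-12)
        assert ok.mean() >= 0.9

    def test_duplicated_segments_have_zero_error(self):
        rng = np.random.default_rng(9)
        block = rng.poisson(4.0, 1024)
        tiled = np.tile(block, 4)
        curve = fk.estimate_curve_errors(channel(tiled), n_segments=4, m=16, levels=2)
        assert np.allclose(curve.G_err, 0.0, atol=1e-12)

    def test_single_segment_rejected(self, n2_trace):
        with pytest.raises(ValueError, match="n_segments"):
            fk.estimate_curve_errors(n2_trace.green, n_segments=1)


class TestCurveContainer:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([1.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([0.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([1.0, 2.0]), np.array([0.1, 0.2]),
                             G_err=np.array([-0.1, 0.0]))
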