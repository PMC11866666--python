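"""Seed-chain tests: QC gate boundaries, masking, smoothing, HRF
kernel, convolution, volume resampling, differentiation and the chain's
linearity/locality invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from pupilseed import pupil


def make_trace(diameter, confidence=None, missing=None, rate=60.0):
    n = len(diameter)
    return pupil.PupilTrace(
        time=np.arange(n) / rate,
        diameter=np.asarray(diameter, dtype=float),
        confidence=np.ones(n) if confidence is None else np.asarray(confidence),
        missing=np.zeros(n, bool) if missing is None else np.asarray(missing, bool),
    )


class TestQC:
    def test_clean_trace_passes(self):
        assert pupil.qc_evaluate(make_trace(np.ones(100))).passed

    def test_quarter_missing_fails(self):
        missing = np.zeros(100, bool)
        missing[:25] = True
        assert not pupil.qc_evaluate(make_trace(np.ones(100), missing=missing)).passed

    def test_exactly_twenty_percent_unsuccessful_fails(self):
        # the gate is strict: "less than 20%"
        missing = np.zeros(100, bool)
        missing[:20] = True
        rep = pupil.qc_evaluate(make_trace(np.ones(100), missing=missing))
        assert rep.frac_unsuccessful == 0.20
        assert not rep.passed

    def test_exactly_seventy_five_percent_high_confidence_passes(self):
        conf = np.full(100, 0.95)
        conf[:25] = 0.5  # not > 0.9
        rep = pupil.qc_evaluate(make_trace(np.ones(100), confidence=conf))
        assert rep.frac_high_confidence == 0.75
        assert rep.passed


class TestMasking:
    def test_high_confidence_unchanged(self):
        tr = make_trace(np.arange(10.0))
        out = pupil.mask_low_confidence(tr)
        assert not out.missing.any()
        np.testing.assert_array_equal(out.diameter, tr.diameter)

    def test_all_low_confidence_all_missing(self):
        tr = make_trace(np.ones(5), confidence=np.full(5, 0.5))
        assert pupil.mask_low_confidence(tr).missing.all()

    def test_threshold_is_strict_less_than(self):
        tr = make_trace(np.ones(3), confidence=np.array([0.95, 0.89, 0.91]))
        out = pupil.mask_low_confidence(tr)
        np.testing.assert_array_equal(out.missing, [False, True, False])


class TestSmoothing:
    def test_constant_series_unchanged(self):
        tr = make_trace(np.full(200, 2.5))
        out = pupil.smooth_sliding(tr, window=57)
        np.testing.assert_allclose(out.diameter, 2.5)

    def test_linear_ramp_interior_unchanged(self):
        # centered mean of a symmetric window on a line is the center value
        tr = make_trace(0.3 * np.arange(300.0))
        out = pupil.smooth_sliding(tr, window=57)
        np.testing.assert_allclose(out.diameter[28:-28], tr.diameter[28:-28])

    def test_fully_missing_window_stays_missing(self):
        missing = np.zeros(300, bool)
        missing[100:157] = True  # 57-frame gap
        tr = make_trace(np.ones(300), missing=missing)
        out = pupil.smooth_sliding(tr, window=57)
        assert out.missing[128]  # gap centre: whole window missing
        assert not out.missing[100]  # gap edge sees valid frames

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pupil.smooth_sliding(make_trace(np.ones(100)), window=56)

    def test_median_smoother_ignores_outlier(self):
        d = np.ones(101)
        d[50] = 100.0
        out = pupil.smooth_sliding(make_trace(d), window=5, smoother="median")
        assert out.diameter[50] == 1.0


class TestHRF:
    def test_peak_between_five_and_six_seconds(self):
        k = pupil.canonical_hrf(dt=0.01)
        assert 4.8 <= np.argmax(k) * 0.01 <= 6.0

    def test_zero_at_time_zero(self):
        assert pupil.canonical_hrf(dt=0.5)[0] == 0.0

    def test_time_rescaling_identity(self):
        c = 2.0
        base = pupil.canonical_hrf(pupil.HRFParams(), dt=0.1)
        scaled = pupil.canonical_hrf(
            pupil.HRFParams(
                peak_delay=6 * c, undershoot_delay=16 * c,
                peak_dispersion=c, undershoot_dispersion=c,
                length=32 * c,
            ),
            dt=0.1 * c,
        )
        np.testing.assert_allclose(base, scaled, atol=1e-12)


class TestConvolution:
    def test_impulse_reproduces_kernel(self):
        k = pupil.canonical_hrf(dt=0.1)
        x = np.zeros(1000)
        x[0] = 1.0
        out = pupil.convolve_hrf(make_trace(x, rate=10.0), k)
        np.testing.assert_allclose(out.diameter[: k.size], k)
        np.testing.assert_allclose(out.diameter[k.size:], 0.0)

    def test_zero_input_zero_output(self):
        k = pupil.canonical_hrf(dt=0.1)
        out = pupil.convolve_hrf(make_trace(np.zeros(500), rate=10.0), k)
        assert np.all(out.diameter == 0.0)

    def test_step_approaches_kernel_sum(self):
        k = pupil.canonical_hrf(dt=0.1)
        out = pupil.convolve_hrf(make_trace(np.ones(2000), rate=10.0), k)
        np.testing.assert_allclose(out.diameter[-1], k.sum(), rtol=1e-10)

    def test_kernel_longer_than_trace_rejected(self):
        k = pupil.canonical_hrf(dt=0.1)
        with pytest.raises(ValueError):
            pupil.convolve_hrf(make_trace(np.ones(10), rate=10.0), k)

    def test_gaps_are_linearly_bridged(self):
        d = np.arange(100.0)
        missing = np.zeros(100, bool)
        missing[40:50] = True
        d[missing] = -999.0  # ignored values
        out = pupil.convolve_hrf(make_trace(d, missing=missing), np.array([1.0]))
        np.testing.assert_allclose(out.diameter, np.arange(100.0))
        np.testing.assert_array_equal(out.meta["bridged_frames"],
                                      np.arange(40, 50))


class TestResampling:
    def test_exact_frame_times_copied(self):
        tr = make_trace(np.arange(100.0), rate=10.0)
        seed = pupil.resample_to_volumes(tr, tr.time[::10])
        np.testing.assert_allclose(seed.value, tr.diameter[::10])

    def test_midpoint_interpolation(self):
        tr = make_trace(np.array([2.0, 4.0]), rate=1.0)
        seed = pupil.resample_to_volumes(tr, np.array([0.5]))
        assert seed.value[0] == 3.0

    def test_study_volume_grid_length(self):
        vt = pupil.default_volume_times(320, 1.89)
        tr = make_trace(np.ones(int(320 * 1.89 * 60) + 1), rate=60.0)
        seed = pupil.resample_to_volumes(tr, vt)
        assert seed.n_volumes == 320

    def test_out_of_span_names_volume(self):
        tr = make_trace(np.ones(10), rate=1.0)
        with pytest.raises(ValueError, match="volume 2"):
            pupil.resample_to_volumes(tr, np.array([1.0, 5.0, 20.0]))


class TestDerivative:
    def test_constant_gives_zeros(self):
        seed = pupil.SeedSeries(np.full(10, 2.0), np.arange(10.0), "diameter")
        np.testing.assert_allclose(pupil.differentiate(seed).value, 0.0)

    def test_linear_ramp_gives_constant_slope(self):
        t = 1.89 * np.arange(50)
        seed = pupil.SeedSeries(0.7 * t, t, "diameter")
        np.testing.assert_allclose(pupil.differentiate(seed).value, 0.7)

    def test_sinusoid_error_within_taylor_bound(self):
        # (2 pi f TR)^2 / 6 ~ 0.9% of the cosine amplitude on interior points
        f, tr = 0.02, 1.89
        t = pupil.default_volume_times(320, tr)
        seed = pupil.SeedSeries(np.sin(2 * np.pi * f * t), t, "diameter")
        deriv = pupil.differentiate(seed).value
        exact = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        amp = 2 * np.pi * f
        assert np.max(np.abs(deriv[1:-1] - exact[1:-1])) < 0.01 * amp
        assert np.max(np.abs(deriv - exact)) < 0.02 * amp

    def test_too_short_rejected(self):
        seed = pupil.SeedSeries(np.ones(2), np.arange(2.0), "diameter")
        with pytest.raises(ValueError):
            pupil.differentiate(seed)


def oracle_chain(latent, rate, volume_times):
    """Independent reference chain: double-gamma kernel written from its
    closed form, steady-state-padded convolution, linear interpolation."""
    dt = 1.0 / rate
    t = np.arange(0.0, 32.0 + dt / 2, dt)
    k = sp_stats.gamma.pdf(t, 6.0, scale=1.0) - sp_stats.gamma.pdf(
        t, 16.0, scale=1.0) / 6.0
    k = k / k.max()
    padded = np.concatenate([np.full(k.size - 1, latent[0]), latent])
    conv = np.convolve(padded, k)[k.size - 1 : k.size - 1 + latent.size]
    return np.interp(volume_times, np.arange(latent.size) * dt, conv)


class TestBuildSeedPair:
    def test_noiseless_trace_recovers_oracle_regressor(self):
        rng = np.random.default_rng(0)
        rate = 20.0
        n = int(300 * rate) + 1
        latent = np.cumsum(rng.standard_normal(n)) * 0.01 + 4.0
        tr = make_trace(latent, rate=rate)
        vt = pupil.default_volume_times(150, 1.89)
        diam, deriv = pupil.build_seed_pair(tr, vt)
        expected = oracle_chain(latent, rate, vt)
        r = np.corrcoef(diam.value, expected)[0, 1]
        assert r > 0.99
        assert diam.kind == "diameter" and deriv.kind == "derivative"

    def test_failing_qc_raises_with_report(self):
        missing = np.ones(100, bool)
        missing[:50] = False
        tr = make_trace(np.ones(100), missing=missing)
        with pytest.raises(pupil.RejectedSubjectError) as exc:
            pupil.build_seed_pair(tr, np.array([0.5]))
        assert exc.value.report.frac_unsuccessful == 0.5

    def test_constant_trace_gives_zero_derivative(self):
        tr = make_trace(np.full(4000, 3.0))
        vt = pupil.default_volume_times(30, 1.89)
        _, deriv = pupil.build_seed_pair(tr, vt)
        np.testing.assert_allclose(deriv.value, 0.0, atol=1e-12)


class TestChainInvariants:
    @given(a=st.floats(0.5, 3.0), b=st.floats(-2.0, 2.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_input_linearity(self, a, b):
        # smoothing/convolution/interpolation are linear; the derivative
        # kills the constant offset
        rng = np.random.default_rng(5)
        rate = 10.0
        latent = 4.0 + np.cumsum(rng.standard_normal(1200)) * 0.02
        vt = pupil.default_volume_times(40, 1.89)
        d0, v0 = pupil.build_seed_pair(make_trace(latent, rate=rate), vt)
        d1, v1 = pupil.build_seed_pair(make_trace(a * latent + b, rate=rate), vt)
        k = pupil.canonical_hrf(dt=1.0 / rate)
        offset = b * k.sum()  # steady-state gain of the kernel
        np.testing.assert_allclose(d1.value, a * d0.value + offset, rtol=1e-9,
                                   atol=1e-9)
        np.testing.assert_allclose(v1.value, a * v0.value, rtol=1e-7, atol=1e-9)

    def test_output_length_independent_of_camera_rate(self):
        vt = pupil.default_volume_times(25, 1.89)
        for rate in (10.0, 30.0):
            n = int(50 * rate) + 1
            tr = make_trace(np.ones(n) * 2, rate=rate)
            d, v = pupil.build_seed_pair(tr, vt)
            assert d.n_volumes == v.n_volumes == 25

    def test_missing_frame_values_never_matter(self):
        rng = np.random.default_rng(9)
        latent = 4.0 + rng.standard_normal(2000) * 0.1
        missing = rng.random(2000) < 0.1
        vt = pupil.default_volume_times(30, 1.89)
        a = make_trace(latent.copy(), missing=missing, rate=20.0)
        garbled = latent.copy()
        garbled[missing] = 1e6
        b = make_trace(garbled, missing=missing, rate=20.0)
        da, _ = pupil.build_seed_pair(a, vt)
        db, _ = pupil.build_seed_pair(b, vt)
        np.testing.assert_allclose(da.value, db.value)
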