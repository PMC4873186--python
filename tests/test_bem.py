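"""Energy-model units: receptive fields, temporal kernel and responses."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stereobem.bem import (
    BEMUnit,
    GaborParams,
    TemporalKernelParams,
    complex_response,
    gabor_rf,
    kernel_peak_frequency,
    monocular_response,
    normalized_response,
    positive_lobe_duration,
    simple_response,
    temporal_kernel,
    tuning_curve,
)
from stereobem.stimulus import StereoFrameSequence, StimulusParams, make_dynamic_rds

# Peak of the default biphasic kernel's amplitude spectrum, frozen from a
# continuous Fourier-transform quadrature oracle (see test below): the
# asymmetric gamma envelope pushes the peak just above the 4 Hz
# oscillation frequency of the cosine carrier.
KERNEL_PEAK_HZ = 4.605


def centered_coords(n=41, deg_per_px=0.03):
    return (np.arange(n) - (n - 1) / 2.0) * deg_per_px


class TestGabor:
    def test_maximal_at_center(self):
        g = GaborParams(phi=0.0, dx=0.0, sigma_x=0.1, sigma_y=0.1, f=3.125)
        rf = gabor_rf(g, centered_coords())
        assert rf[20, 20] == pytest.approx(1.0)
        assert rf.max() == pytest.approx(1.0)

    def test_even_symmetry_at_zero_phase(self):
        rf = gabor_rf(GaborParams(phi=0.0, dx=0.0), centered_coords())
        assert np.allclose(rf, rf[:, ::-1], atol=1e-12)

    @pytest.mark.parametrize("deg_per_px", [0.03, 0.003])
    def test_quadrature_pair_orthogonal(self, deg_per_px):
        n = int(41 * 0.03 / deg_per_px)
        coords = centered_coords(n | 1, deg_per_px)
        g0 = gabor_rf(GaborParams(phi=0.0, sigma_x=0.1, sigma_y=0.1, f=3.125), coords)
        g90 = gabor_rf(
            GaborParams(phi=math.pi / 2, sigma_x=0.1, sigma_y=0.1, f=3.125), coords
        )
        inner = abs(np.vdot(g0, g90))
        assert inner < 1e-3 * min(np.linalg.norm(g0) ** 2, np.linalg.norm(g90) ** 2)

    def test_disparity_offset_shifts_whole_gabor(self):
        coords = centered_coords(81)
        left = gabor_rf(GaborParams(dx=0.12, eye_sign=+1), coords)
        right = gabor_rf(GaborParams(dx=0.12, eye_sign=-1), coords)
        # +/- dx/2 = 2 px each way: shifting one onto the other matches.
        assert np.allclose(left[:, 4:], right[:, :-4], atol=1e-10)

    def test_undersampled_carrier_warns(self):
        with pytest.warns(RuntimeWarning, match="undersamples"):
            gabor_rf(GaborParams(f=20.0), centered_coords())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GaborParams(f=-1.0)
        with pytest.raises(ValueError):
            GaborParams(eye_sign=0)


class TestTemporalKernel:
    def test_defaults_sign_structure(self):
        # Negative lobe before 62.5 ms, positive lobe 62.5 - 187.5 ms.
        k = temporal_kernel(TemporalKernelParams())
        t = np.arange(k.size) * 1e-3
        assert np.all(k[(t > 0.005) & (t < 0.060)] < 0)
        assert np.all(k[(t > 0.065) & (t < 0.185)] > 0)

    def test_positive_lobe_duration_125ms(self):
        assert positive_lobe_duration(TemporalKernelParams()) * 1e3 == pytest.approx(125.0)

    def test_peak_frequency_matches_continuous_oracle(self):
        # Continuous-FT quadrature oracle for |K(f)| on a fine grid.
        from scipy.integrate import quad
        from scipy.special import gamma as G

        tk = TemporalKernelParams()

        def amp(f):
            w = 2 * math.pi * f

            def integrand_re(t):
                env = t ** (tk.alpha - 1) * math.exp(-t / tk.tau)
                return env * math.cos(tk.omega * t + tk.phase) * math.cos(w * t)

            def integrand_im(t):
                env = t ** (tk.alpha - 1) * math.exp(-t / tk.tau)
                return env * math.cos(tk.omega * t + tk.phase) * math.sin(w * t)

            re = quad(integrand_re, 0, 1.0, limit=200)[0]
            im = quad(integrand_im, 0, 1.0, limit=200)[0]
            return math.hypot(re, im) / (G(tk.alpha) * tk.tau**tk.alpha)

        grid = np.arange(3.5, 5.5, 0.01)
        oracle_peak = grid[np.argmax([amp(f) for f in grid])]
        assert oracle_peak == pytest.approx(KERNEL_PEAK_HZ, abs=0.02)
        assert kernel_peak_frequency(tk) == pytest.approx(oracle_peak, abs=0.02)

    def test_time_rescaling_scales_peak(self):
        tk = TemporalKernelParams()
        s = 2.0
        scaled = TemporalKernelParams(tau=tk.tau * s, omega=tk.omega / s)
        assert kernel_peak_frequency(scaled) == pytest.approx(
            kernel_peak_frequency(tk) / s, rel=0.01
        )

    def test_lowpass_peaks_at_zero(self):
        lp = TemporalKernelParams(kind="lowpass")
        assert kernel_peak_frequency(lp) == 0.0
        assert np.all(temporal_kernel(lp) >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TemporalKernelParams(alpha=0.0)
        with pytest.raises(ValueError):
            TemporalKernelParams(tau=-1.0)


def _single_frame_seq(left, right, params):
    return StereoFrameSequence(
        left=left[None].astype(np.float32),
        right=right[None].astype(np.float32),
        frame_times=np.array([0.0]),
        params=params,
    )


def small_seq(seed=0, **kw):
    defaults = dict(
        field_size_px=48, layout="full", density=0.24, refresh_rate_hz=20.0, duration_s=0.2
    )
    defaults.update(kw)
    return make_dynamic_rds(StimulusParams(**defaults), seed)


class TestResponses:
    def test_gray_stimulus_silent(self):
        seq = small_seq(density=0.0)
        unit = BEMUnit(dx=0.0, sigma=0.1, temporal=TemporalKernelParams())
        assert not monocular_response(unit, seq).any()
        trace = complex_response(unit, seq)
        assert not trace.C.any() and not trace.C2.any()

    def test_static_single_frame_is_single_number(self):
        params = StimulusParams(
            field_size_px=48, layout="full", density=0.24, refresh_rate_hz=20.0, duration_s=0.05
        )
        seq = make_dynamic_rds(params, 1)
        unit = BEMUnit(dx=0.0, sigma=0.1, temporal=None)
        v = monocular_response(unit, seq)
        assert v.shape == (1,)

    def test_contrast_inversion_negates_monocular_drive(self):
        seq = small_seq(3)
        inverted = StereoFrameSequence(
            left=-seq.left, right=seq.right, frame_times=seq.frame_times, params=seq.params
        )
        unit = BEMUnit(dx=0.0, sigma=0.1, temporal=TemporalKernelParams())
        assert np.allclose(
            monocular_response(unit, seq), -monocular_response(unit, inverted)
        )

    def test_causality_appending_frames_preserves_past(self):
        seq = small_seq(4, duration_s=0.2)
        extra = small_seq(99, duration_s=0.2)
        longer = StereoFrameSequence(
            left=np.concatenate([seq.left, extra.left]),
            right=np.concatenate([seq.right, extra.right]),
            frame_times=np.arange(seq.n_frames + extra.n_frames) / 20.0,
            params=replace(seq.params, duration_s=0.4),
        )
        unit = BEMUnit(dx=0.0, sigma=0.1, temporal=TemporalKernelParams())
        v_short = monocular_response(unit, seq)
        v_long = monocular_response(unit, longer)
        assert np.allclose(v_long[: v_short.size], v_short)

    def test_rf_outside_field_rejected(self):
        seq = small_seq(0)
        with pytest.raises(ValueError, match="beyond"):
            monocular_response(BEMUnit(x0=0.6, dx=0.0, sigma=0.1), seq)

    def test_response_trace_invariants(self):
        seq = small_seq(5)
        trace = complex_response(BEMUnit(dx=0.06, sigma=0.1, temporal=TemporalKernelParams()), seq)
        for arr in (trace.S1, trace.S2, trace.C, trace.C2):
            assert np.all(arr >= 0)
        assert np.allclose(trace.C2, trace.C**2)

    def test_phase_invariance_to_drifting_grating(self):
        # The quadrature pair makes C invariant to the spatial phase of a
        # sinusoidal grating at the unit's frequency.  Invariance is not
        # perfect at finite bandwidth: the cos- and sin-Gabor spectra
        # differ by exp(-(2*pi*f*sigma)^2) ~ 2% at f*sigma = 0.3125, which
        # bounds the residual ripple near (2%)^2.
        unit = BEMUnit(dx=0.0, sigma=0.1, f=3.125, temporal=None)
        params = StimulusParams(field_size_px=64, layout="full", refresh_rate_hz=20, duration_s=0.05)
        coords = params.pixel_coords()
        responses = []
        for phase in np.linspace(0, 2 * math.pi, 16, endpoint=False):
            grating = np.cos(2 * math.pi * 3.125 * coords + phase)
            img = np.tile(grating, (64, 1))
            seq = _single_frame_seq(img, img, params)
            responses.append(complex_response(unit, seq).C[0])
        responses = np.array(responses)
        assert responses.std() / responses.mean() < 5e-3


class TestSimpleCell:
    @given(
        v=hnp.arrays(np.float64, 8, elements=st.floats(-5, 5)),
        w=hnp.arrays(np.float64, 8, elements=st.floats(-5, 5)),
    )
    def test_binomial_identity(self, v, w):
        s = simple_response(v, w)
        assert np.allclose(s, v**2 + w**2 + 2 * v * w, atol=1e-9)
        assert np.all(s >= 0)

    def test_negating_one_eye_flips_cross_term_only(self):
        v = np.array([1.0, -2.0, 0.5])
        w = np.array([0.3, 1.0, -1.0])
        flipped = simple_response(v, -w)
        assert np.allclose(simple_response(v, w) - flipped, 4 * v * w)


@pytest.fixture(scope="module")
def quick_tuning():
    from stereobem.experiments import full_field_params

    unit = BEMUnit(dx=0.09, sigma=0.1, output_exponent=2)
    params = full_field_params(0.1, 0.24, max_disparity_deg=0.36)
    disparities = np.linspace(-0.27, 0.27, 7)
    return tuning_curve(unit, params, disparities, 300, np.random.default_rng(8))


class TestTuning:

    def test_uncorrelated_tuning_flat(self, quick_tuning):
        ts = quick_tuning
        m, s = ts.mean["uncorrelated"], ts.sem["uncorrelated"]
        grand = m.mean()
        assert np.all(np.abs(m - grand) < 4 * s)

    def test_mean_square_identity(self, quick_tuning):
        # E[C^2] = E[C]^2 + Var[C] holds on any ensemble; with exponent 2
        # the stored mean is E[C^2] and mean_C is E[C].
        ts = quick_tuning
        assert np.all(ts.mean["correlated"] >= ts.mean_C["correlated"] ** 2)

    def test_squared_model_peaks_at_preferred(self, quick_tuning):
        ts = quick_tuning
        hm = ts.mean["half_matched"]
        peak = ts.disparities[np.argmax(hm)]
        assert abs(peak - ts.preferred_disparity) <= 0.09 + 1e-9

    def test_n_patterns_validated(self):
        from stereobem.experiments import full_field_params

        unit = BEMUnit(dx=0.0, sigma=0.1)
        with pytest.raises(ValueError):
            tuning_curve(unit, full_field_params(0.1, 0.24), np.array([0.0]), 0, np.random.default_rng(0))


class TestNormalizedResponse:
    def test_anchor_values(self):
        assert normalized_response(2.0, 2.0, 5.0) == 0.0
        assert normalized_response(5.0, 2.0, 5.0) == 1.0

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalized_response(1.0, 2.0, 2.0)
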