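"""Binocular energy model units.

A unit is built from two binocular simple cells in quadrature: each simple
cell sums a left- and a right-eye monocular drive and squares the result,
S = (V_L + V_R)^2, and the complex response is C = S_1 + S_2, which is
invariant to stimulus phase.  Disparity selectivity is positional: the
left-eye Gabor is shifted by +dx/2 and the right-eye Gabor by -dx/2, with
no phase disparity.  The *binocularly linear* model reads out C directly;
the modified model adds a static squaring output nonlinearity, C^2, which
converts trial-to-trial variability in local binocular correlation into a
change in mean response (E[X^2] = E[X]^2 + Var[X]) and is what gives the
model its disparity tuning to half-matched stereograms.

Time, when enabled, enters through a separable biphasic temporal kernel
(a gamma-density envelope times a cosine); monocular drives are the
temporal convolution of the kernel with the per-millisecond spatial inner
product of the receptive field and the image.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gamma as _gamma_fn

from .stimulus import StimulusParams, StereoFrameSequence, render_pattern_batch

__all__ = [
    "GaborParams",
    "TemporalKernelParams",
    "BEMUnit",
    "ResponseTrace",
    "TuningStats",
    "gabor_rf",
    "temporal_kernel",
    "kernel_peak_frequency",
    "positive_lobe_duration",
    "monocular_response",
    "simple_response",
    "complex_response",
    "tuning_curve",
    "normalized_response",
    "normalized_response_with_se",
    "STIMULUS_CLASSES",
]

DT = 1e-3  # simulation grid, seconds

STIMULUS_CLASSES = ("correlated", "half_matched", "anticorrelated", "uncorrelated")
_CLASS_MATCH = {"correlated": 1.0, "half_matched": 0.5, "anticorrelated": 0.0}


@dataclass
class GaborParams:
    """Monocular receptive field: a vertically oriented Gabor.

    ``eye_sign`` is +1 for the left eye and -1 for the right; the whole
    Gabor (envelope and carrier together) is shifted by ``eye_sign*dx/2``,
    implementing a position disparity of ``dx``.
    """

    x0: float = 0.0
    y0: float = 0.0
    dx: float = 0.0
    sigma_x: float = 0.1
    sigma_y: float = 0.1
    f: float = 3.125
    phi: float = 0.0
    eye_sign: int = 1

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("spatial frequency must be positive")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("envelope SDs must be positive")
        if self.eye_sign not in (+1, -1):
            raise ValueError("eye_sign must be +1 (left) or -1 (right)")


@dataclass
class TemporalKernelParams:
    """Biphasic (or low-pass) temporal kernel parameters.

    The biphasic kernel is ``t^(alpha-1) exp(-t/tau) cos(omega*t + phase)
    / (Gamma(alpha) tau^alpha)`` for t >= 0 and 0 otherwise; the envelope
    is a gamma probability density, fixing the normalization convention.
    ``kind='lowpass'`` drops the cosine, leaving a non-oscillatory gamma
    envelope with the same integration time.
    """

    alpha: float = 2.5
    omega: float = 8.0 * math.pi
    phase: float = -math.pi
    tau: float = 0.035
    kind: str = "biphasic"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.kind not in ("biphasic", "lowpass"):
            raise ValueError("kind must be 'biphasic' or 'lowpass'")


def temporal_kernel(
    tk: TemporalKernelParams, dt: float = DT, envelope_cutoff: float = 1e-6
) -> np.ndarray:
    """Sample the kernel on a ``dt`` grid, truncated where the envelope
    falls below ``envelope_cutoff`` of its peak."""
    peak_t = max((tk.alpha - 1.0) * tk.tau, dt)
    # The envelope decays like exp(-t/tau); 60 tau beyond the peak is far
    # below any sensible cutoff.
    t = np.arange(0.0, peak_t + 60.0 * tk.tau, dt)
    envelope = t ** (tk.alpha - 1.0) * np.exp(-t / tk.tau)
    envelope /= _gamma_fn(tk.alpha) * tk.tau**tk.alpha
    keep = np.nonzero(envelope >= envelope_cutoff * envelope.max())[0]
    last = keep[-1] if keep.size else 0
    envelope = envelope[: last + 1]
    if tk.kind == "lowpass":
        return envelope
    return envelope * np.cos(tk.omega * t[: last + 1] + tk.phase)


def kernel_peak_frequency(tk: TemporalKernelParams, dt: float = DT, n_fft: int = 1 << 20) -> float:
    """Frequency (Hz) at which the kernel's amplitude spectrum is maximal.

    Computed from the sampled kernel with fine zero-padding.
    """
    k = temporal_kernel(tk, dt=dt)
    spectrum = np.abs(np.fft.rfft(k, n_fft))
    freqs = np.fft.rfftfreq(n_fft, dt)
    return float(freqs[np.argmax(spectrum)])


def positive_lobe_duration(tk: TemporalKernelParams) -> float:
    """Duration (s) of the kernel's positive lobe.

    The two smallest positive roots of ``cos(omega*t + phase) = 0`` that
    bracket an interval where the cosine factor is positive are found; the
    lobe duration is always ``pi/omega`` but the roots are located
    explicitly so the sign convention of ``phase`` is respected.
    """
    if tk.kind != "biphasic":
        raise ValueError("only the biphasic kernel has a positive cosine lobe")
    roots = []
    k = -int(abs(tk.phase) / math.pi) - 2
    while len(roots) < 2 and k < 10_000:
        t = (math.pi / 2.0 + k * math.pi - tk.phase) / tk.omega
        k += 1
        if t <= 0:
            continue
        mid_next = t + math.pi / (2.0 * tk.omega)
        if math.cos(tk.omega * mid_next + tk.phase) > 0:
            roots = [t]  # left edge of a positive half-cycle
        elif roots:
            roots.append(t)
    if len(roots) < 2:
        raise RuntimeError("failed to bracket the positive lobe")
    return roots[1] - roots[0]


def gabor_rf(gp: GaborParams, coords: np.ndarray, deg_per_px: float | None = None) -> np.ndarray:
    """Sample the Gabor on a square pixel grid.

    ``coords`` is the 1-D array of pixel-centre coordinates in degrees
    (shared by x and y, see ``StimulusParams.pixel_coords``).  Emits a
    warning when the grid undersamples the carrier (< 2 samples/period).
    """
    if deg_per_px is None:
        deg_per_px = float(coords[1] - coords[0]) if len(coords) > 1 else 0.03
    if gp.f * deg_per_px > 0.5:
        warnings.warn(
            f"grid spacing {deg_per_px} deg undersamples carrier at {gp.f} c/deg",
            RuntimeWarning,
            stacklevel=2,
        )
    xc = gp.x0 + gp.eye_sign * gp.dx / 2.0
    dxs = coords - xc
    dys = coords - gp.y0
    env_x = np.exp(-(dxs**2) / (2.0 * gp.sigma_x**2))
    env_y = np.exp(-(dys**2) / (2.0 * gp.sigma_y**2))
    carrier = np.cos(2.0 * math.pi * gp.f * dxs + gp.phi)
    return np.outer(env_y, env_x * carrier)


@dataclass
class BEMUnit:
    """One model complex cell.

    Two quadrature subunit phase pairs (``phi0`` and ``phi0 + pi/2``), each
    pairing a left- and a right-eye Gabor that share (x0, y0, sigma, f) and
    differ only in the sign of the dx/2 positional offset.
    ``output_exponent`` 1 is the binocularly linear energy model (response
    C); 2 adds the squaring output nonlinearity (response C^2).
    """

    x0: float = 0.0
    y0: float = 0.0
    dx: float = 0.09
    sigma: float = 0.1
    f: float | None = None
    phi0: float = 0.0
    output_exponent: int = 2
    temporal: TemporalKernelParams | None = None

    def __post_init__(self) -> None:
        if self.f is None:
            # Bandwidth-preserving default: f*sigma = 0.3125 cycles.
            self.f = 0.3125 / self.sigma
        if self.output_exponent not in (1, 2):
            raise ValueError("output_exponent must be 1 or 2")

    @property
    def preferred_disparity(self) -> float:
        return self.dx

    def gabors(self) -> list[GaborParams]:
        """The four monocular Gabors, ordered (phase1 L, phase1 R, phase2 L, phase2 R)."""
        out = []
        for phi in (self.phi0, self.phi0 + math.pi / 2.0):
            for eye in (+1, -1):
                out.append(
                    GaborParams(
                        x0=self.x0,
                        y0=self.y0,
                        dx=self.dx,
                        sigma_x=self.sigma,
                        sigma_y=self.sigma,
                        f=self.f,
                        phi=phi,
                        eye_sign=eye,
                    )
                )
        return out

    def weight_stack(self, params: StimulusParams) -> np.ndarray:
        """(4, npix) flattened Gabor weights in ``gabors()`` order."""
        coords = params.pixel_coords()
        self.check_in_field(params)
        return np.stack(
            [gabor_rf(g, coords, params.deg_per_px).ravel() for g in self.gabors()]
        )

    def check_in_field(self, params: StimulusParams, n_sigma: float = 4.0) -> None:
        half = params.field_extent_deg / 2.0
        reach = max(
            abs(self.x0 + s * self.dx / 2.0) + n_sigma * self.sigma for s in (+1, -1)
        )
        reach_y = abs(self.y0) + n_sigma * self.sigma
        if reach > half or reach_y > half:
            raise ValueError(
                f"receptive field (centre ({self.x0}, {self.y0}), sigma "
                f"{self.sigma}) extends beyond the +/-{half:.2f} deg field; "
                f"placement must keep +/-{n_sigma} sigma inside"
            )


@dataclass
class ResponseTrace:
    """Time-resolved responses of one unit.

    ``V_L``/``V_R`` hold the monocular drives of the two quadrature
    subunits (shape ``(2, T)``); S1, S2 are the simple-cell responses,
    C the complex response and C2 its square.
    """

    times: np.ndarray
    V_L: np.ndarray
    V_R: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    C: np.ndarray
    C2: np.ndarray


def simple_response(V_L: np.ndarray, V_R: np.ndarray) -> np.ndarray:
    """Binocular simple cell: pointwise (V_L + V_R)^2."""
    return (np.asarray(V_L) + np.asarray(V_R)) ** 2


def _frame_drives(unit: BEMUnit, seq: StereoFrameSequence) -> np.ndarray:
    """Spatial inner products per frame: shape (4, n_frames)."""
    weights = unit.weight_stack(seq.params)  # (4, npix)
    n = seq.n_frames
    left = seq.left.reshape(n, -1).astype(np.float64)
    right = seq.right.reshape(n, -1).astype(np.float64)
    drives = np.empty((4, n))
    drives[0] = left @ weights[0]
    drives[1] = right @ weights[1]
    drives[2] = left @ weights[2]
    drives[3] = right @ weights[3]
    return drives


def _temporal_filter(drives: np.ndarray, seq: StereoFrameSequence, tk: TemporalKernelParams) -> np.ndarray:
    """Causal convolution of zero-order-held frame drives with the kernel."""
    idx = seq.frame_index_on_grid(DT)
    held = drives[:, idx]  # (4, T)
    kernel = temporal_kernel(tk)
    out = fftconvolve(held, kernel[None, :], axes=1)[:, : held.shape[1]]
    return out * DT


def monocular_response(unit: BEMUnit, seq: StereoFrameSequence, eye: str = "left") -> np.ndarray:
    """Monocular drive V(t) of the first subunit for one eye.

    Static mode (no temporal kernel) returns one value per frame — for a
    single-frame stimulus, a single number.  With a kernel, the frames are
    zero-order-held on the 1 ms grid and convolved causally.
    """
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    drives = _frame_drives(unit, seq)
    row = 0 if eye == "left" else 1
    if unit.temporal is None:
        return drives[row]
    return _temporal_filter(drives, seq, unit.temporal)[row]


def complex_response(unit: BEMUnit, seq: StereoFrameSequence) -> ResponseTrace:
    """Full response trace of one unit to a frame sequence."""
    drives = _frame_drives(unit, seq)
    if unit.temporal is None:
        V = drives
        times = seq.frame_times.copy()
    else:
        V = _temporal_filter(drives, seq, unit.temporal)
        times = np.arange(V.shape[1]) * DT
    V_L = V[(0, 2), :]
    V_R = V[(1, 3), :]
    S1 = simple_response(V_L[0], V_R[0])
    S2 = simple_response(V_L[1], V_R[1])
    C = S1 + S2
    return ResponseTrace(times=times, V_L=V_L, V_R=V_R, S1=S1, S2=S2, C=C, C2=C**2)


@dataclass
class TuningStats:
    """Monte-Carlo disparity tuning of one unit.

    ``mean`` / ``sem`` map stimulus class name to per-disparity arrays for
    the unit's output (C for exponent 1, C^2 for exponent 2); ``mean_C``
    holds the pre-nonlinearity complex response for reference.
    """

    disparities: np.ndarray
    mean: dict
    sem: dict
    mean_C: dict
    n_patterns: int
    preferred_disparity: float


def _class_params(base: StimulusParams, cls: str) -> StimulusParams:
    if cls == "uncorrelated":
        return replace(base, uncorrelated=True)
    return replace(base, match_level=_CLASS_MATCH[cls], uncorrelated=False)


def tuning_curve(
    unit: BEMUnit,
    params: StimulusParams,
    disparities: np.ndarray,
    n_patterns: int,
    rng: np.random.Generator,
    classes: tuple[str, ...] = STIMULUS_CLASSES,
) -> TuningStats:
    """Mean static response per disparity per stimulus class.

    Uses single-frame stimuli with no temporal kernel (the static model).
    The response averaged is C^2 for ``output_exponent`` 2 and C for 1.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    weights = unit.weight_stack(params)
    mean = {c: np.empty(len(disparities)) for c in classes}
    sem = {c: np.empty(len(disparities)) for c in classes}
    mean_C = {c: np.empty(len(disparities)) for c in classes}
    for j, disp in enumerate(disparities):
        for cls in classes:
            p = _class_params(replace(params, disparity_deg=float(disp)), cls)
            batch = render_pattern_batch(p, n_patterns, rng)
            VL = batch[:, 0, :].astype(np.float64) @ weights[(0, 2), :].T  # (n, 2)
            VR = batch[:, 1, :].astype(np.float64) @ weights[(1, 3), :].T
            C = ((VL + VR) ** 2).sum(axis=1)
            resp = C if unit.output_exponent == 1 else C**2
            mean[cls][j] = resp.mean()
            sem[cls][j] = resp.std(ddof=1) / math.sqrt(n_patterns)
            mean_C[cls][j] = C.mean()
    return TuningStats(
        disparities=np.asarray(disparities, dtype=float),
        mean=mean,
        sem=sem,
        mean_C=mean_C,
        n_patterns=n_patterns,
        preferred_disparity=unit.preferred_disparity,
    )


def normalized_response(
    hm: float, uncorr: float, corr: float
) -> float:
    """Normalized half-matched response (hm - uncorr) / (corr - uncorr).

    1 means the half-matched response equals the correlated response at
    the preferred disparity; 0 means it equals the uncorrelated baseline.
    """
    denom = corr - uncorr
    if denom <= 0:
        raise ValueError(
            "degenerate normalization: correlated response does not exceed "
            "the uncorrelated baseline at the preferred disparity"
        )
    return (hm - uncorr) / denom


def normalized_response_with_se(
    hm: float, hm_se: float, uncorr: float, uncorr_se: float, corr: float, corr_se: float
) -> tuple[float, float]:
    """Normalized response plus its delta-method standard error."""
    denom = corr - uncorr
    value = normalized_response(hm, uncorr, corr)
    d_hm = 1.0 / denom
    d_corr = -(hm - uncorr) / denom**2
    d_unc = (hm - corr) / denom**2
    se = math.sqrt((d_hm * hm_se) ** 2 + (d_corr * corr_se) ** 2 + (d_unc * uncorr_se) ** 2)
    return value, se


def tuning_normalized_response(ts: TuningStats) -> tuple[float, float]:
    """R_norm evaluated at the unit's preferred disparity from a TuningStats."""
    j = int(np.argmin(np.abs(ts.disparities - ts.preferred_disparity)))
    return normalized_response_with_se(
        ts.mean["half_matched"][j],
        ts.sem["half_matched"][j],
        ts.mean["uncorrelated"][j],
        ts.sem["uncorrelated"][j],
        ts.mean["correlated"][j],
        ts.sem["correlated"][j],
    )
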