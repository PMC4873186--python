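"""Exact color-averaged response moments of energy-model units.

The dot colors of a stereogram are independent Rademacher (+1/-1)
variables, and alpha compositing makes every painted pixel *linear* in
them: pixel = sum_d color_d * w_d, where w_d is the dot's anti-aliased
coverage attenuated by the transparency of every dot painted over it.  A
monocular drive V is therefore a Rademacher linear form, V = sum_k y_k
a_k, and the first two moments of the complex response C = U1^2 + U2^2
(with U_p the binocular drive of subunit p) have closed forms:

    E[U^4]       = 3 (sum a^2)^2 - 2 sum a^4
    E[U1^2 U2^2] = (sum a1^2)(sum a2^2) + 2 (sum a1 a2)^2 - 2 sum a1^2 a2^2

Averaging over the colors analytically (a Rao-Blackwellization) removes
roughly two thirds of the Monte-Carlo variance of mean-response
estimates at a given number of dot layouts; only the layout and the
matched-subset assignment remain stochastic.  The samplers here pair the
correlated, half-matched and uncorrelated classes on a shared layout, so
class differences are estimated with common random numbers.
"""

from __future__ import annotations

import math

import numpy as np

from . import bem
from ._render import footprint_gabor_weights
from .bem import BEMUnit, temporal_kernel
from .stimulus import StimulusParams, _deg_to_px, _matched_flags, _sample_monocular_dots

__all__ = ["rademacher_complex_moments", "StaticMomentSampler", "DynamicMomentSampler"]

CLASSES = ("correlated", "half_matched", "uncorrelated")


def rademacher_complex_moments(a1: np.ndarray, a2: np.ndarray) -> tuple[float, float]:
    """E[C] and E[C^2] for C = (sum y a1)^2 + (sum y a2)^2, y Rademacher."""
    s2_1 = float(a1 @ a1)
    s2_2 = float(a2 @ a2)
    s4_1 = float(np.sum(a1**4))
    s4_2 = float(np.sum(a2**4))
    cross = float(a1 @ a2)
    mixed = float(np.sum((a1 * a2) ** 2))
    ec = s2_1 + s2_2
    ec2 = (
        (3.0 * s2_1**2 - 2.0 * s4_1)
        + (3.0 * s2_2**2 - 2.0 * s4_2)
        + 2.0 * (s2_1 * s2_2 + 2.0 * cross**2 - 2.0 * mixed)
    )
    return ec, ec2


class StaticMomentSampler:
    """Per-layout exact color moments of a static unit's response.

    One ``sample`` draws a dot layout (plus a fresh right-eye layout for
    the uncorrelated class and a matched subset for the half-matched
    class) and returns, per stimulus class, the exact expectation over
    colors of C and C^2.
    """

    def __init__(self, unit: BEMUnit, params: StimulusParams):
        self.unit = unit
        self.params = params
        n = params.field_size_px
        W = unit.weight_stack(params)
        self._gab_left = (W[0].reshape(n, n), W[2].reshape(n, n))
        self._gab_right = (W[1].reshape(n, n), W[3].reshape(n, n))

    def _footprints(self, x_deg, y_deg, gabors) -> np.ndarray:
        p = self.params
        transparency = np.ones((p.field_size_px, p.field_size_px))
        b = np.zeros((2, x_deg.size))
        footprint_gabor_weights(
            np.ascontiguousarray(_deg_to_px(x_deg, p)),
            np.ascontiguousarray(_deg_to_px(y_deg, p)),
            p.dot_radius_deg / p.deg_per_px,
            transparency,
            gabors[0],
            gabors[1],
            b,
        )
        return b

    def _class_coefficients(self, rng: np.random.Generator) -> dict:
        """Rademacher coefficient vectors (a1, a2) per stimulus class."""
        p = self.params
        x, y, region = _sample_monocular_dots(p, rng)
        order = rng.permutation(x.size)
        x, y, region = x[order], y[order], region[order]
        is_center = region == 0
        half_shift = np.where(is_center, p.disparity_deg / 2.0, 0.0)
        bL = self._footprints(x + half_shift, y, self._gab_left)
        bR = self._footprints(x - half_shift, y, self._gab_right)
        mu = np.ones(x.size)
        mc = _matched_flags(int(is_center.sum()), 0.5, rng)
        mu[is_center] = np.where(mc, 1.0, -1.0)
        if p.surround_mode == "same_as_center" and (~is_center).any():
            ms = _matched_flags(int((~is_center).sum()), 0.5, rng)
            mu[~is_center] = np.where(ms, 1.0, -1.0)
        x2, y2, _ = _sample_monocular_dots(p, rng)
        o2 = rng.permutation(x2.size)
        bR_unc = self._footprints(x2[o2], y2[o2], self._gab_right)
        return {
            "correlated": (bL[0] + bR[0], bL[1] + bR[1]),
            "half_matched": (bL[0] + mu * bR[0], bL[1] + mu * bR[1]),
            "uncorrelated": (
                np.concatenate([bL[0], bR_unc[0]]),
                np.concatenate([bL[1], bR_unc[1]]),
            ),
        }

    def sample(self, rng: np.random.Generator) -> dict:
        """{class: color-averaged response} for one layout.

        The response is E[C] for a linear unit (exponent 1) and E[C^2]
        for the squared unit.
        """
        coefs = self._class_coefficients(rng)
        out = {}
        for cls, (a1, a2) in coefs.items():
            ec, ec2 = rademacher_complex_moments(a1, a2)
            out[cls] = ec if self.unit.output_exponent == 1 else ec2
        return out


class DynamicMomentSampler(StaticMomentSampler):
    """Exact color moments for dynamic trials with the temporal kernel.

    Frame colors are independent, so the convolved subunit drive is again
    a Rademacher linear form whose coefficients factor into a per-frame
    temporal weight K_f(t) (the kernel mass overlapping frame f's hold
    window at time t) and the per-dot spatial weight.  The per-time-point
    moment sums then reduce to sums over frames of K_f^2 and K_f^4 times
    per-frame dot sums.
    """

    def __init__(self, unit: BEMUnit, params: StimulusParams):
        super().__init__(unit, params)
        if unit.temporal is None:
            raise ValueError("DynamicMomentSampler requires a temporal kernel")
        kernel = temporal_kernel(unit.temporal)
        n_frames = int(math.ceil(params.duration_s * params.refresh_rate_hz - 1e-9))
        n_grid = int(round(params.duration_s / bem.DT))
        onsets_idx = np.ceil(
            np.arange(n_frames) / params.refresh_rate_hz / bem.DT - 1e-9
        ).astype(int)
        ends_idx = np.append(onsets_idx[1:], n_grid)
        cum = np.concatenate([[0.0], np.cumsum(kernel)]) * bem.DT
        L = kernel.size
        tau = np.arange(n_grid)
        K = np.empty((n_frames, n_grid))
        for f in range(n_frames):
            hi = np.clip(tau - onsets_idx[f] + 1, 0, L)
            lo = np.clip(tau - ends_idx[f] + 1, 0, L)
            K[f] = cum[hi] - cum[lo]
        self.n_frames = n_frames
        self._K2 = K**2
        self._K4 = K**4

    def sample_trial(self, rng: np.random.Generator) -> dict:
        """{class: time-averaged color-averaged response} for one trial."""
        F = self.n_frames
        P2 = {c: np.empty((2, F)) for c in CLASSES}
        P4 = {c: np.empty((2, F)) for c in CLASSES}
        X = {c: np.empty(F) for c in CLASSES}
        Y = {c: np.empty(F) for c in CLASSES}
        for f in range(F):
            coefs = self._class_coefficients(rng)
            for cls, (a1, a2) in coefs.items():
                P2[cls][0, f] = a1 @ a1
                P2[cls][1, f] = a2 @ a2
                P4[cls][0, f] = np.sum(a1**4)
                P4[cls][1, f] = np.sum(a2**4)
                X[cls][f] = a1 @ a2
                Y[cls][f] = np.sum((a1 * a2) ** 2)
        out = {}
        for cls in CLASSES:
            A1 = P2[cls][0] @ self._K2
            A2 = P2[cls][1] @ self._K2
            if self.unit.output_exponent == 1:
                out[cls] = float((A1 + A2).mean())
                continue
            B1 = P4[cls][0] @ self._K4
            B2 = P4[cls][1] @ self._K4
            Q = X[cls] @ self._K2
            Z = Y[cls] @ self._K4
            ec2_t = (
                (3.0 * A1**2 - 2.0 * B1)
                + (3.0 * A2**2 - 2.0 * B2)
                + 2.0 * (A1 * A2 + 2.0 * Q**2 - 2.0 * Z)
            )
            out[cls] = float(ec2_t.mean())
        return out
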