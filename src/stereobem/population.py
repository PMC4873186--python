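"""Opponent population and perceptual decision rule.

The decision model pools 160 energy-model complex cells with a squaring
output nonlinearity: 40 cells at each of four preferred disparities
(-0.48, -0.03, +0.03, +0.48 deg).  Receptive field size scales with
preferred disparity magnitude (the size-disparity correlation),
sigma = 0.023 + 0.41*|dx| deg, and the Gabor carrier frequency scales
inversely, f = 0.3125/sigma.  Within a disparity group the cells differ
only in retinal position, with non-overlapping receptive fields.

Each cell's response is normalized by its mean response to correlated
stereograms at its preferred disparity (presented at 21.25 Hz), so all
cells peak at 1 in those units.  Multiplicative Gaussian noise is added
at every time point: P_ik = C2_ik/<C2_i> + kappa*eps_ik with
eps_ik ~ N(0, C2_ik/<C2_i>), independent across cells and time points.

Every cell is paired with its *antineuron* — the cell at the same retinal
location tuned to the opposite-sign disparity.  The opponent signal of a
pair is summed over time, R(i) = sum_k (P_ik - N_ik), and the decision is
a linear readout: report "far" (psi = 1) iff sum_i R(i) > 0, "near"
otherwise (ties, which have measure zero under continuous noise, fall to
"near" by the strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.signal import fftconvolve
from scipy.special import ndtr
from scipy.stats import beta as _beta

from . import bem
from .bem import BEMUnit, TemporalKernelParams, gabor_rf, temporal_kernel
from .stimulus import (
    AlternationParams,
    StimulusParams,
    StereoFrameSequence,
    make_alternating_rds,
    make_dynamic_rds,
)

__all__ = [
    "PopulationSpec",
    "NoiseModel",
    "TrialOutcome",
    "Condition",
    "Population",
    "build_population",
    "estimate_norm_constants",
    "noisy_response",
    "decide_trial",
    "run_psychometric",
    "calibrate_kappa",
    "clopper_pearson",
]

NORM_REFRESH_HZ = 21.25  # normalization constants are defined at this refresh rate


@dataclass
class PopulationSpec:
    """Layout and tuning rules of the decision population."""

    preferred_disparities: tuple = (-0.48, -0.03, 0.03, 0.48)
    n_per_disparity: int = 40
    sigma_intercept: float = 0.023  # deg
    sigma_slope: float = 0.41  # deg per deg of |dx|
    freq_scale: float = 0.3125  # cycles; f = freq_scale / sigma
    spacing_factor: float = 2.0  # target centre spacing in units of sigma
    output_exponent: int = 2
    temporal: TemporalKernelParams | None = field(default_factory=TemporalKernelParams)

    def sigma_for(self, dx: float) -> float:
        return self.sigma_intercept + self.sigma_slope * abs(dx)

    def freq_for(self, dx: float) -> float:
        return self.freq_scale / self.sigma_for(dx)

    @property
    def n_units(self) -> int:
        return len(self.preferred_disparities) * self.n_per_disparity


@dataclass
class NoiseModel:
    """Multiplicative Gaussian noise: variance kappa^2 * normalized response."""

    kappa: float
    norm_constants: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if np.any(self.norm_constants <= 0):
            raise ValueError("normalization constants must be strictly positive")


@dataclass
class TrialOutcome:
    R_per_pair: np.ndarray
    decision: int  # 0 near, 1 far
    correct: bool | None


@dataclass
class Condition:
    """One psychometric condition (stimulus family for a block of trials)."""

    correlation: float = 1.0  # binocular correlation, 2*match_level - 1
    disparity_mag_deg: float = 0.03
    refresh_rate_hz: float = 21.25
    duration_s: float = 1.5
    density: float = 0.24
    dot_radius_deg: float = 0.09
    alternation_rate_hz: float | None = None
    start_phase: str = "random"
    surround_mode: str = "correlated"

    def stimulus_params(self, sign: int, geometry: StimulusParams) -> StimulusParams:
        return replace(
            geometry,
            match_level=(self.correlation + 1.0) / 2.0,
            disparity_deg=sign * self.disparity_mag_deg,
            refresh_rate_hz=self.refresh_rate_hz,
            duration_s=self.duration_s,
            density=self.density,
            dot_radius_deg=self.dot_radius_deg,
            surround_mode=self.surround_mode,
        )


def _poisson_disk(
    n: int, radius: float, spacing: float, rng: np.random.Generator, max_tries: int = 20_000
) -> np.ndarray | None:
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        u = rng.uniform()
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r = radius * math.sqrt(u)
        x, y = r * math.cos(theta), r * math.sin(theta)
        if all((x - px) ** 2 + (y - py) ** 2 >= spacing**2 for px, py in pts):
            pts.append((x, y))
    if len(pts) < n:
        return None
    return np.array(pts)


class Population:
    """The built population: units, antineuron pairing and fast response math.

    ``raw_responses`` evaluates C (exponent 1) or C^2 (exponent 2) for all
    units on a frame sequence, using one sparse matrix of Gabor weights per
    eye; with a temporal kernel the per-frame drives are zero-order-held on
    the 1 ms grid and convolved causally.
    """

    def __init__(
        self,
        spec: PopulationSpec,
        geometry: StimulusParams,
        units: list[BEMUnit],
        pair_pos: np.ndarray,
        pair_neg: np.ndarray,
        spacing_achieved: dict,
    ):
        self.spec = spec
        self.geometry = geometry
        self.units = units
        self.pair_pos = pair_pos
        self.pair_neg = pair_neg
        self.spacing_achieved = spacing_achieved
        self.norm_constants: np.ndarray | None = None
        self._build_weights()

    @property
    def n_units(self) -> int:
        return len(self.units)

    def _build_weights(self, n_sigma: float = 4.5) -> None:
        params = self.geometry
        coords = params.pixel_coords()
        npix = params.field_size_px**2
        n_side = params.field_size_px
        rows_l, cols_l, vals_l = [], [], []
        rows_r, cols_r, vals_r = [], [], []
        for u_idx, unit in enumerate(self.units):
            unit.check_in_field(params)
            for p_idx, g in enumerate(unit.gabors()):
                xc = g.x0 + g.eye_sign * g.dx / 2.0
                ci = np.nonzero(np.abs(coords - xc) <= n_sigma * g.sigma_x)[0]
                ri = np.nonzero(np.abs(coords - g.y0) <= n_sigma * g.sigma_y)[0]
                sub = gabor_rf(g, coords, params.deg_per_px)[np.ix_(ri, ci)]
                rr, cc = np.meshgrid(ri, ci, indexing="ij")
                flat = (rr * n_side + cc).ravel()
                row_id = 2 * u_idx + p_idx // 2
                target = (rows_l, cols_l, vals_l) if g.eye_sign == 1 else (rows_r, cols_r, vals_r)
                target[0].append(np.full(flat.size, row_id))
                target[1].append(flat)
                target[2].append(sub.ravel())
        n_rows = 2 * self.n_units
        # float32 weights: the stimulus is float32 and responses feed a
        # Monte-Carlo estimate, so single precision halves the memory
        # bandwidth of the per-frame products at no meaningful cost.
        self.W_left = sparse.csr_matrix(
            (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
            shape=(n_rows, npix),
            dtype=np.float32,
        )
        self.W_right = sparse.csr_matrix(
            (np.concatenate(vals_r), (np.concatenate(rows_r), np.concatenate(cols_r))),
            shape=(n_rows, npix),
            dtype=np.float32,
        )
        if self.spec.temporal is not None:
            self._kernel = temporal_kernel(self.spec.temporal)
        else:
            self._kernel = None

    def raw_responses(self, seq: StereoFrameSequence) -> np.ndarray:
        """(n_units, T) array of C^output_exponent."""
        nf = seq.n_frames
        left = np.ascontiguousarray(seq.left.reshape(nf, -1).T)
        right = np.ascontiguousarray(seq.right.reshape(nf, -1).T)
        UL = (self.W_left @ left).astype(np.float64)  # (2*nu, nf)
        UR = (self.W_right @ right).astype(np.float64)
        if self._kernel is None:
            VL, VR = UL, UR
        else:
            idx = seq.frame_index_on_grid(bem.DT)
            VL = fftconvolve(UL[:, idx], self._kernel[None, :], axes=1)[:, : idx.size] * bem.DT
            VR = fftconvolve(UR[:, idx], self._kernel[None, :], axes=1)[:, : idx.size] * bem.DT
        S = (VL + VR) ** 2
        C = S[0::2] + S[1::2]  # (n_units, T)
        if self.spec.output_exponent == 1:
            return C
        return C**2

    def normalized_responses(self, seq: StereoFrameSequence) -> np.ndarray:
        if self.norm_constants is None:
            raise RuntimeError("normalization constants have not been estimated")
        return self.raw_responses(seq) / self.norm_constants[:, None]

    def trial_statistics(self, seq: StereoFrameSequence) -> tuple[float, float]:
        """Deterministic opponent sum and total noise-variance weight.

        With noise, the decision variable is D = det + kappa*sqrt(var)*z
        with z standard normal: each unit-time point contributes an
        independent Gaussian of variance kappa^2 * X_ik, and sums of
        independent Gaussians combine exactly.
        """
        X = self.normalized_responses(seq)
        det = float(X[self.pair_pos].sum() - X[self.pair_neg].sum())
        var = float(X.sum())
        return det, var


def build_population(
    spec: PopulationSpec,
    geometry: StimulusParams,
    rng: np.random.Generator | int | None = None,
) -> Population:
    """Place the units and build the population response machinery.

    Centres are placed inside the disparity-defined disk by dart-throwing
    with a minimum spacing of ``spacing_factor * sigma`` per group (RFs
    with Gaussian envelopes overlap negligibly at 2 sigma separation).
    When a group cannot be packed at the target spacing, the spacing
    relaxes geometrically to the maximum feasible value, which is
    recorded in ``spacing_achieved``.
    """
    rng = np.random.default_rng(rng)
    disk_r = geometry.disk_diameter_deg / 2.0
    mags = sorted({abs(d) for d in spec.preferred_disparities})
    units: list[BEMUnit] = []
    pair_pos, pair_neg = [], []
    spacing_achieved = {}
    for mag in mags:
        sigma = spec.sigma_for(mag)
        spacing = spec.spacing_factor * sigma
        pts = None
        while pts is None:
            pts = _poisson_disk(spec.n_per_disparity, disk_r, spacing, rng)
            if pts is None:
                if spacing < geometry.deg_per_px / 4.0:
                    raise RuntimeError(
                        f"cannot place {spec.n_per_disparity} RFs of sigma {sigma} "
                        f"in a disk of radius {disk_r} even without spacing"
                    )
                spacing *= 0.9
        spacing_achieved[mag] = spacing
        idx_by_sign = {}
        for sign in (+1, -1):
            if sign * mag not in spec.preferred_disparities:
                continue
            start = len(units)
            for x0, y0 in pts:
                units.append(
                    BEMUnit(
                        x0=float(x0),
                        y0=float(y0),
                        dx=sign * mag,
                        sigma=sigma,
                        f=spec.freq_for(mag),
                        output_exponent=spec.output_exponent,
                        temporal=spec.temporal,
                    )
                )
            idx_by_sign[sign] = np.arange(start, len(units))
        if +1 in idx_by_sign and -1 in idx_by_sign:
            pair_pos.append(idx_by_sign[+1])
            pair_neg.append(idx_by_sign[-1])
    return Population(
        spec=spec,
        geometry=geometry,
        units=units,
        pair_pos=np.concatenate(pair_pos) if pair_pos else np.array([], dtype=int),
        pair_neg=np.concatenate(pair_neg) if pair_neg else np.array([], dtype=int),
        spacing_achieved=spacing_achieved,
    )


def estimate_norm_constants(
    pop: Population,
    n_patterns: int = 100,
    rng: np.random.Generator | int | None = None,
    duration_s: float = 1.5,
) -> np.ndarray:
    """Mean response to correlated stereograms at each cell's preferred
    disparity, presented at 21.25 Hz (static populations use single
    frames).  Stored on the population and returned."""
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    rng = np.random.default_rng(rng)
    constants = np.zeros(pop.n_units)
    group_dx = np.array([u.dx for u in pop.units])
    for dx in np.unique(group_dx):
        members = group_dx == dx
        params = replace(
            pop.geometry,
            match_level=1.0,
            disparity_deg=float(dx),
            refresh_rate_hz=NORM_REFRESH_HZ,
            duration_s=duration_s,
        )
        acc = np.zeros(int(members.sum()))
        for _ in range(n_patterns):
            seq = make_dynamic_rds(params, rng)
            acc += pop.raw_responses(seq)[members].mean(axis=1)
        constants[members] = acc / n_patterns
    pop.norm_constants = constants
    return constants


def noisy_response(
    nm: NoiseModel,
    C2_trace: np.ndarray,
    unit_index: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Noisy scaled response P_k = X_k + kappa*eps_k, eps_k ~ N(0, X_k),
    with X_k = C2_k / <C2_i>; independent draws per time point."""
    rng = np.random.default_rng(rng)
    X = np.asarray(C2_trace, dtype=float) / nm.norm_constants[unit_index]
    return X + nm.kappa * np.sqrt(X) * rng.standard_normal(X.shape)


def decide_trial(
    pop: Population,
    nm: NoiseModel,
    seq: StereoFrameSequence,
    rng: np.random.Generator | int | None = None,
) -> TrialOutcome:
    """Run the full decision rule on one stimulus with per-time-point noise."""
    rng = np.random.default_rng(rng)
    X = pop.raw_responses(seq) / nm.norm_constants[:, None]
    P = X + nm.kappa * np.sqrt(X) * rng.standard_normal(X.shape)
    R = P[pop.pair_pos].sum(axis=1) - P[pop.pair_neg].sum(axis=1)
    decision = 1 if R.sum() > 0 else 0
    disp = seq.params.disparity_deg
    correct = None if disp == 0 else bool((decision == 1) == (disp > 0))
    return TrialOutcome(R_per_pair=R, decision=decision, correct=correct)


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(_beta.ppf(alpha / 2.0, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(_beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes))
    return lo, hi


def _make_sequence(
    cond: Condition, sign: int, geometry: StimulusParams, rng: np.random.Generator
) -> StereoFrameSequence:
    params = cond.stimulus_params(sign, geometry)
    if cond.alternation_rate_hz is None:
        return make_dynamic_rds(params, rng)
    ap = AlternationParams(
        base=params,
        alternation_rate_hz=cond.alternation_rate_hz,
        start_phase=cond.start_phase,
    )
    return make_alternating_rds(ap, rng)


def simulate_trial_batch(
    pop: Population,
    cond: Condition,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic per-trial statistics (det, var, correct-sign).

    The disparity sign of each trial is drawn at random; for zero-disparity
    control conditions the "correct" target sign is a coin flip, so
    accuracy converges to chance.
    """
    det = np.empty(n_trials)
    var = np.empty(n_trials)
    signs = np.where(rng.integers(2, size=n_trials) == 1, 1, -1)
    for t in range(n_trials):
        seq = _make_sequence(cond, int(signs[t]), pop.geometry, rng)
        det[t], var[t] = pop.trial_statistics(seq)
    return det, var, signs


def _accuracy_given_kappa(det, var, signs, kappa) -> float:
    """Exact expected accuracy over the noise distribution (stimulus MC only)."""
    if kappa == 0:
        return float(np.mean(np.sign(det) == signs) + 0.5 * np.mean(det == 0))
    sd = kappa * np.sqrt(np.maximum(var, 1e-300))
    return float(np.mean(ndtr(signs * det / sd)))


@dataclass
class PsychometricPoint:
    condition: Condition
    n_trials: int
    n_correct: int
    proportion_correct: float
    ci_lo: float
    ci_hi: float
    kappa: float


def run_psychometric(
    pop: Population,
    kappa: float,
    cond: Condition,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
) -> PsychometricPoint:
    """Monte-Carlo proportion correct for one condition.

    Stimulus variability is simulated trial by trial; the Gaussian response
    noise enters through its exact aggregate over cells and time points
    (a single zero-mean Gaussian whose variance is the summed per-point
    noise variance — an identity for sums of independent Gaussians, not an
    approximation).
    """
    rng = np.random.default_rng(rng)
    det, var, signs = simulate_trial_batch(pop, cond, n_trials, rng)
    noise = kappa * np.sqrt(np.maximum(var, 0.0)) * rng.standard_normal(n_trials)
    decision_var = det + noise
    psi = (decision_var > 0).astype(int)
    correct = psi == (signs > 0).astype(int)
    n_correct = int(correct.sum())
    lo, hi = clopper_pearson(n_correct, n_trials)
    return PsychometricPoint(
        condition=cond,
        n_trials=n_trials,
        n_correct=n_correct,
        proportion_correct=n_correct / n_trials,
        ci_lo=lo,
        ci_hi=hi,
        kappa=kappa,
    )


def calibrate_kappa(
    pop: Population,
    cond: Condition,
    target: float = 0.95,
    n_trials: int = 400,
    bounds: tuple[float, float] = (1e-4, 1e4),
    rng: np.random.Generator | int | None = None,
    tol: float = 1e-3,
) -> float:
    """Find the noise magnitude giving ``target`` accuracy at ``cond``.

    Accuracy is a decreasing function of kappa; bisection runs on log
    kappa using one cached set of stimulus trials, with the noise
    expectation taken exactly, so the search is smooth and cheap.
    """
    if not 0.5 < target < 1.0:
        raise ValueError("target accuracy must lie in (0.5, 1)")
    rng = np.random.default_rng(rng)
    det, var, signs = simulate_trial_batch(pop, cond, n_trials, rng)
    acc_lo = _accuracy_given_kappa(det, var, signs, bounds[0])
    acc_hi = _accuracy_given_kappa(det, var, signs, bounds[1])
    if acc_lo < target:
        raise ValueError(
            f"target {target} unreachable: noise-free ceiling is {acc_lo:.3f} "
            f"at kappa={bounds[0]}"
        )
    if acc_hi > target:
        raise ValueError(
            f"target {target} unreachable: accuracy is still {acc_hi:.3f} "
            f"at kappa={bounds[1]}"
        )
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _accuracy_given_kappa(det, var, signs, math.exp(mid)) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return math.exp(0.5 * (lo + hi))
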