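"""Scripted reproductions of the model simulations, plus the statistics
used to analyse them (fractional area, Monte-Carlo proportion test, exact
binomial confidence intervals).

The full-size simulations average tens of thousands of stereograms per
condition; every function here therefore takes explicit pattern/trial
counts so that desk-scale runs (the test-suite defaults) and full-scale
runs share one code path.  All Monte-Carlo outputs carry standard errors
so that qualitative comparisons can be made with an explicit error budget.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import bem
from .bem import BEMUnit, TemporalKernelParams, normalized_response, tuning_curve
from .population import (
    Condition,
    Population,
    PopulationSpec,
    build_population,
    calibrate_kappa,
    clopper_pearson,
    estimate_norm_constants,
    run_psychometric,
)
from .stimulus import StimulusParams, render_pattern_batch, render_rnorm_triplet

__all__ = [
    "SweepGrid",
    "PsychometricResult",
    "unit_for_sigma",
    "full_field_params",
    "decision_geometry",
    "decision_population",
    "sweep_density_rf",
    "sweep_refresh_rf",
    "figure3_experiment",
    "figure5_experiment",
    "figure6_experiment",
    "dot_size_experiment",
    "alternation_experiment",
    "fractional_area",
    "mc_proportion_test",
    "binomial_ci",
]

DOT_RADIUS_DEG = 0.09


@dataclass
class SweepGrid:
    """Parameter grids of the model-cell sweeps, at publication scale.

    ``scale_factor`` rescales the Monte-Carlo sample counts (not the
    physical parameters) for desk-scale runs.
    """

    densities: np.ndarray = field(
        default_factory=lambda: np.logspace(math.log10(0.01), math.log10(5.12), 11)
    )
    sigmas: np.ndarray = field(
        default_factory=lambda: np.logspace(math.log10(0.01), math.log10(0.3), 30)
    )
    refresh_rates: np.ndarray = field(
        default_factory=lambda: np.logspace(0.0, 2.0, 11)
    )
    dot_radius_deg: float = DOT_RADIUS_DEG
    n_patterns: int = 20_000
    n_trials: int = 5_000
    trial_duration_s: float = 10.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError("scale_factor must lie in (0, 1]")

    @property
    def n_patterns_scaled(self) -> int:
        return max(20, int(round(self.n_patterns * self.scale_factor)))

    @property
    def n_trials_scaled(self) -> int:
        return max(20, int(round(self.n_trials * self.scale_factor)))


@dataclass
class PsychometricResult:
    """Proportion correct versus one stimulus variable, with exact CIs."""

    x: np.ndarray
    x_name: str
    proportion_correct: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_trials: np.ndarray
    kappa: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportion_correct, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.x_name: self.x,
                "proportion_correct": self.proportion_correct,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n_trials": self.n_trials,
                "kappa": self.kappa,
            }
        )


def unit_for_sigma(
    sigma: float, dx: float = 0.0, output_exponent: int = 2, temporal=None
) -> BEMUnit:
    """A centred model cell with the bandwidth-preserving frequency rule."""
    return BEMUnit(
        x0=0.0, y0=0.0, dx=dx, sigma=sigma, output_exponent=output_exponent, temporal=temporal
    )


def full_field_params(
    sigma: float,
    density: float,
    dot_radius_deg: float = DOT_RADIUS_DEG,
    max_disparity_deg: float = 0.0,
    deg_per_px: float = 0.03,
    **kwargs,
) -> StimulusParams:
    """A full-field dot carpet just large enough for a centred unit.

    The field covers the +/-4 sigma receptive-field support plus the
    half-disparity shift; dots are sampled from a padded region so edges
    are not depleted.
    """
    half = 4.0 * sigma + max_disparity_deg / 2.0 + 4.0 * deg_per_px
    n = int(math.ceil(2.0 * half / deg_per_px))
    return StimulusParams(
        field_size_px=n,
        deg_per_px=deg_per_px,
        dot_radius_deg=dot_radius_deg,
        density=density,
        layout="full",
        **kwargs,
    )


def decision_geometry(field_size_px: int = 160) -> StimulusParams:
    """Stimulus geometry for decision-model runs.

    The raster is trimmed to the disk-plus-annulus region (plus the reach
    of the largest receptive fields); dots beyond it cannot drive any unit.
    """
    return StimulusParams(field_size_px=field_size_px, deg_per_px=0.03)


@functools.lru_cache(maxsize=8)
def _cached_population(
    output_exponent: int, kernel_kind: str | None, seed: int, field_size_px: int, n_norm: int
) -> Population:
    temporal = None if kernel_kind is None else TemporalKernelParams(kind=kernel_kind)
    spec = PopulationSpec(output_exponent=output_exponent, temporal=temporal)
    pop = build_population(spec, decision_geometry(field_size_px), rng=seed)
    estimate_norm_constants(pop, n_patterns=n_norm, rng=seed + 1)
    return pop


def decision_population(
    output_exponent: int = 2,
    kernel_kind: str | None = "biphasic",
    seed: int = 2016,
    field_size_px: int = 160,
    n_norm: int = 100,
) -> Population:
    """The standard 160-cell decision population, built and normalized.

    Cached per configuration: RF placement and normalization constants are
    deterministic in ``seed``, so repeated experiments share one build.
    """
    return _cached_population(output_exponent, kernel_kind, seed, field_size_px, n_norm)


# ---------------------------------------------------------------------------
# Model-cell sweeps
# ---------------------------------------------------------------------------


def _rnorm_from_samples(
    corr: np.ndarray, hm: np.ndarray, unc: np.ndarray
) -> tuple[float, float]:
    """R_norm and its SE from paired per-pattern class responses.

    The three classes are simulated with common random numbers (shared
    left eye and dot layout), so the delta-method error propagation uses
    their full covariance, not just the marginal variances.
    """
    n = corr.size
    hbar, ubar, cbar = hm.mean(), unc.mean(), corr.mean()
    value = normalized_response(hbar, ubar, cbar)
    d = cbar - ubar
    grad = np.array([1.0 / d, (hbar - cbar) / d**2, -(hbar - ubar) / d**2])
    cov = np.cov(np.vstack([hm, unc, corr]))
    var = float(grad @ cov @ grad) / n
    return value, math.sqrt(max(var, 0.0))


def _static_rnorm(
    unit: BEMUnit, params: StimulusParams, n_patterns: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Paired, color-averaged Monte-Carlo estimate of R_norm (static unit).

    Each pattern contributes the exact expectation of the response over
    dot colors given the layout (see ``moments``), with the three classes
    sharing the layout; only layout and matched-subset randomness remain.
    """
    from .moments import StaticMomentSampler

    sampler = StaticMomentSampler(unit, params)
    samples = {c: np.empty(n_patterns) for c in ("correlated", "half_matched", "uncorrelated")}
    for i in range(n_patterns):
        vals = sampler.sample(rng)
        for cls, v in vals.items():
            samples[cls][i] = v
    return _rnorm_from_samples(
        samples["correlated"], samples["half_matched"], samples["uncorrelated"]
    )


def render_based_rnorm(
    unit: BEMUnit, params: StimulusParams, n_patterns: int, rng: np.random.Generator
) -> tuple[float, float]:
    """R_norm through the image-rendering pipeline (paired classes).

    Slower and noisier than ``_static_rnorm``'s analytic color averaging;
    kept as the independent route for cross-checking it.
    """
    weights = unit.weight_stack(params)
    WL = weights[(0, 2), :].T  # (npix, 2)
    WR = weights[(1, 3), :].T
    samples = {c: np.empty(n_patterns) for c in ("correlated", "half_matched", "uncorrelated")}
    for i in range(n_patterns):
        triplet = render_rnorm_triplet(params, rng)
        vl = triplet["correlated"][0].ravel().astype(np.float64) @ WL
        for cls, (_, right) in triplet.items():
            vr = right.ravel().astype(np.float64) @ WR
            c_resp = float(((vl + vr) ** 2).sum())
            samples[cls][i] = c_resp if unit.output_exponent == 1 else c_resp**2
    return _rnorm_from_samples(
        samples["correlated"], samples["half_matched"], samples["uncorrelated"]
    )


def sweep_density_rf(
    densities: np.ndarray,
    sigmas: np.ndarray,
    n_patterns: int,
    rng: np.random.Generator | int | None = None,
    dot_radius_deg: float = DOT_RADIUS_DEG,
) -> pd.DataFrame:
    """Normalized half-matched response over a density x sigma/r grid.

    Static model, single-frame stimuli, disparity 0 (each unit's preferred
    disparity).  Returns one row per grid cell with the delta-method SE.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for sigma in sigmas:
        unit = unit_for_sigma(float(sigma))
        for density in densities:
            params = full_field_params(float(sigma), float(density), dot_radius_deg)
            rnorm, se = _static_rnorm(unit, params, n_patterns, rng)
            rows.append(
                {
                    "density": density,
                    "sigma_deg": sigma,
                    "rel_rf_size": sigma / dot_radius_deg,
                    "rnorm": rnorm,
                    "rnorm_se": se,
                    "n_patterns": n_patterns,
                }
            )
    return pd.DataFrame(rows)


def _dynamic_rnorm(
    unit: BEMUnit,
    params: StimulusParams,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Paired, color-averaged Monte-Carlo estimate of R_norm over dynamic
    trials; the per-trial response is the time average of the unit's
    output over the trial."""
    from .moments import DynamicMomentSampler

    sampler = DynamicMomentSampler(unit, params)
    samples = {c: np.empty(n_trials) for c in ("correlated", "half_matched", "uncorrelated")}
    for t in range(n_trials):
        vals = sampler.sample_trial(rng)
        for cls, v in vals.items():
            samples[cls][t] = v
    return _rnorm_from_samples(
        samples["correlated"], samples["half_matched"], samples["uncorrelated"]
    )


def sweep_refresh_rf(
    refresh_rates: np.ndarray,
    sigmas: np.ndarray,
    n_trials: int,
    duration_s: float = 1.0,
    density: float = 0.24,
    rng: np.random.Generator | int | None = None,
    dot_radius_deg: float = DOT_RADIUS_DEG,
) -> pd.DataFrame:
    """Normalized half-matched response over a refresh-rate x sigma/r grid.

    Temporal kernel active; each cell is the mean over ``n_trials`` dynamic
    trials of ``duration_s`` seconds.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for sigma in sigmas:
        unit = unit_for_sigma(float(sigma), temporal=TemporalKernelParams())
        for refresh in refresh_rates:
            params = full_field_params(
                float(sigma),
                density,
                dot_radius_deg,
                refresh_rate_hz=float(refresh),
                duration_s=duration_s,
            )
            rnorm, se = _dynamic_rnorm(unit, params, n_trials, rng)
            rows.append(
                {
                    "refresh_rate_hz": refresh,
                    "sigma_deg": sigma,
                    "rel_rf_size": sigma / dot_radius_deg,
                    "rnorm": rnorm,
                    "rnorm_se": se,
                    "n_trials": n_trials,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figure experiments
# ---------------------------------------------------------------------------


def figure3_experiment(
    n_patterns: int = 1000,
    disparities: np.ndarray | None = None,
    sigma: float = 0.1,
    dx: float = 0.09,
    density: float = 0.24,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Disparity tuning of one static unit for both output exponents.

    One Monte-Carlo pass serves both models: the linear model's response
    is C and the squared model's is C^2, accumulated from the same
    stereograms.  Returns tidy rows (model, class, disparity, mean, sem).
    """
    rng = np.random.default_rng(rng)
    if disparities is None:
        disparities = np.linspace(-0.45, 0.45, 21)
    unit = unit_for_sigma(sigma, dx=dx)
    params = full_field_params(
        sigma, density, max_disparity_deg=float(np.max(np.abs(disparities))) + abs(dx)
    )
    weights = unit.weight_stack(params)
    rows = []
    for disp in disparities:
        for cls in ("correlated", "half_matched", "anticorrelated", "uncorrelated"):
            p = bem._class_params(replace(params, disparity_deg=float(disp)), cls)
            batch = render_pattern_batch(p, n_patterns, rng)
            VL = batch[:, 0, :].astype(np.float64) @ weights[(0, 2), :].T
            VR = batch[:, 1, :].astype(np.float64) @ weights[(1, 3), :].T
            C = ((VL + VR) ** 2).sum(axis=1)
            for model, resp in (("linear", C), ("squared", C**2)):
                rows.append(
                    {
                        "model": model,
                        "class": cls,
                        "disparity_deg": disp,
                        "mean": resp.mean(),
                        "sem": resp.std(ddof=1) / math.sqrt(n_patterns),
                        "n_patterns": n_patterns,
                    }
                )
    return pd.DataFrame(rows)


def figure5_experiment(
    n_patterns: int = 500,
    disparities: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Normalized tuning curves of the four decision-model cell types.

    Static single-frame stimuli; each curve is scaled by its own peak so
    fine and coarse cells have equal maxima, as in the decision model's
    response normalization.
    """
    rng = np.random.default_rng(rng)
    if disparities is None:
        disparities = np.concatenate(
            [np.linspace(-1.0, 1.0, 41), np.linspace(-0.1, 0.1, 11)]
        )
        disparities = np.unique(np.round(disparities, 4))
    spec = PopulationSpec(temporal=None)
    rows = []
    for dx in spec.preferred_disparities:
        sigma = spec.sigma_for(dx)
        unit = BEMUnit(dx=dx, sigma=sigma, f=spec.freq_for(dx), output_exponent=2)
        params = full_field_params(
            sigma, 0.24, max_disparity_deg=float(np.max(np.abs(disparities))) + abs(dx)
        )
        ts = tuning_curve(
            unit, params, disparities, n_patterns, rng, classes=("correlated",)
        )
        peak = ts.mean["correlated"].max()
        for d, m, s in zip(disparities, ts.mean["correlated"], ts.sem["correlated"]):
            rows.append(
                {
                    "preferred_disparity_deg": dx,
                    "disparity_deg": d,
                    "normalized_response": m / peak,
                    "sem": s / peak,
                    "n_patterns": n_patterns,
                }
            )
    return pd.DataFrame(rows)


def _run_curve(
    pop: Population,
    kappa: float,
    base: Condition,
    correlations: np.ndarray,
    n_trials: int,
    rng: np.random.Generator,
    x_name: str = "correlation",
    meta: dict | None = None,
) -> PsychometricResult:
    props, los, his, ns = [], [], [], []
    for corr in correlations:
        point = run_psychometric(pop, kappa, replace(base, correlation=float(corr)), n_trials, rng)
        props.append(point.proportion_correct)
        los.append(point.ci_lo)
        his.append(point.ci_hi)
        ns.append(point.n_trials)
    return PsychometricResult(
        x=np.asarray(correlations, dtype=float),
        x_name=x_name,
        proportion_correct=np.array(props),
        ci_lo=np.array(los),
        ci_hi=np.array(his),
        n_trials=np.array(ns),
        kappa=kappa,
        meta=meta or {},
    )


def figure6_experiment(
    n_trials: int = 1000,
    calib_trials: int = 400,
    correlations: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    calibration_target: float = 0.95,
) -> dict[str, PsychometricResult]:
    """Proportion correct vs binocular correlation.

    Panel a: fine (+/-0.03 deg) vs coarse (+/-0.48 deg) disparity at
    21.25 Hz.  Panel b: 5.3 Hz vs 42.5 Hz refresh at fine disparity.  The
    noise magnitude is calibrated per refresh rate to ``calibration_target``
    accuracy on fully correlated fine-disparity stimuli.
    """
    rng = np.random.default_rng(rng)
    if correlations is None:
        correlations = np.arange(-1.0, 1.01, 0.2)
    # Panel a uses static receptive fields (one time point per frame), the
    # configuration under which the fine/coarse comparison was defined;
    # panel b needs the temporal kernel, whose integration window is the
    # mechanism behind the refresh-rate effect.
    pop_static = decision_population(kernel_kind=None)
    pop_temporal = decision_population()
    out = {}
    kappas = {}
    for pop, refresh in ((pop_static, 21.25), (pop_temporal, 5.3), (pop_temporal, 42.5)):
        cond = Condition(correlation=1.0, disparity_mag_deg=0.03, refresh_rate_hz=refresh)
        kappas[refresh] = calibrate_kappa(
            pop, cond, target=calibration_target, n_trials=calib_trials, rng=rng
        )
    for key, pop, disparity, refresh in (
        ("fine_21.25Hz", pop_static, 0.03, 21.25),
        ("coarse_21.25Hz", pop_static, 0.48, 21.25),
        ("fine_5.3Hz", pop_temporal, 0.03, 5.3),
        ("fine_42.5Hz", pop_temporal, 0.03, 42.5),
    ):
        base = Condition(disparity_mag_deg=disparity, refresh_rate_hz=refresh)
        out[key] = _run_curve(
            pop,
            kappas[refresh],
            base,
            correlations,
            n_trials,
            rng,
            meta={"disparity_mag_deg": disparity, "refresh_rate_hz": refresh},
        )
    return out


def dot_size_experiment(
    n_trials: int = 1000,
    calib_trials: int = 400,
    dot_sizes: tuple = (0.025, 0.05, 0.075),
    disparity_mag_deg: float = 0.03,
    rng: np.random.Generator | int | None = None,
    calibration_target: float = 0.95,
    include_zero_disparity_control: bool = False,
) -> dict[str, PsychometricResult]:
    """Accuracy vs dot radius for half-matched and correlated stereograms.

    21.25 Hz refresh, 500 ms trials, density 24%.  The model is probed at
    its fine preferred disparity (+/-0.03 deg by default): the population
    encodes only four disparities, and at intermediate test disparities
    such as the +/-0.075 deg shown to human observers the side lobes of
    the cells' disparity tuning produce false-match ("wallpaper") signals
    that invert the readout, so the population model is meaningful only at
    disparities near its preferred values.  The noise magnitude is the
    largest kappa at which correlated accuracy reaches ``calibration_target``
    at *every* dot size (accuracy is decreasing in kappa, so this is the
    minimum of the per-size calibrations), matching the observation that
    humans stay at or above 95% correct for all dot sizes when the
    stereogram is fully correlated.
    """
    rng = np.random.default_rng(rng)
    pop = decision_population()
    base = Condition(
        correlation=1.0,
        disparity_mag_deg=disparity_mag_deg,
        refresh_rate_hz=21.25,
        duration_s=0.5,
        dot_radius_deg=min(dot_sizes),
    )
    kappa = min(
        calibrate_kappa(
            pop,
            replace(base, dot_radius_deg=float(r)),
            target=calibration_target,
            n_trials=calib_trials,
            rng=rng,
        )
        for r in dot_sizes
    )
    out = {}
    for name, corr in (("half_matched", 0.0), ("correlated", 1.0)):
        props, los, his, ns = [], [], [], []
        for r in dot_sizes:
            cond = replace(base, correlation=corr, dot_radius_deg=float(r))
            point = run_psychometric(pop, kappa, cond, n_trials, rng)
            props.append(point.proportion_correct)
            los.append(point.ci_lo)
            his.append(point.ci_hi)
            ns.append(point.n_trials)
        out[name] = PsychometricResult(
            x=np.asarray(dot_sizes, dtype=float),
            x_name="dot_radius_deg",
            proportion_correct=np.array(props),
            ci_lo=np.array(los),
            ci_hi=np.array(his),
            n_trials=np.array(ns),
            kappa=kappa,
            meta={"correlation": corr},
        )
    if include_zero_disparity_control:
        cond = replace(base, correlation=0.0, disparity_mag_deg=0.0, dot_radius_deg=max(dot_sizes))
        point = run_psychometric(pop, kappa, cond, n_trials, rng)
        out["zero_disparity_control"] = PsychometricResult(
            x=np.array([0.075]),
            x_name="dot_radius_deg",
            proportion_correct=np.array([point.proportion_correct]),
            ci_lo=np.array([point.ci_lo]),
            ci_hi=np.array([point.ci_hi]),
            n_trials=np.array([point.n_trials]),
            kappa=kappa,
            meta={"disparity_mag_deg": 0.0},
        )
    return out


def alternation_experiment(
    n_trials: int = 1000,
    calib_trials: int = 400,
    rates: tuple = (3.75, 7.5, 15.0, 30.0, 60.0),
    kernel_kind: str = "biphasic",
    output_exponent: int = 2,
    disparity_mag_deg: float = 0.03,
    rng: np.random.Generator | int | None = None,
    calibration_target: float = 0.95,
) -> PsychometricResult:
    """Accuracy vs correlation-alternation rate.

    120 Hz pattern refresh, 500 ms trials, density 200%, surround with the
    same correlation as the centre, start phase randomized.  The noise
    magnitude is calibrated on the non-alternating fully correlated
    stimulus at the same refresh rate and duration.
    """
    rng = np.random.default_rng(rng)
    pop = decision_population(output_exponent=output_exponent, kernel_kind=kernel_kind)
    calib = Condition(
        correlation=1.0,
        disparity_mag_deg=disparity_mag_deg,
        refresh_rate_hz=120.0,
        duration_s=0.5,
        density=2.0,
        surround_mode="same_as_center",
    )
    kappa = calibrate_kappa(pop, calib, target=calibration_target, n_trials=calib_trials, rng=rng)
    props, los, his, ns = [], [], [], []
    for rate in rates:
        cond = replace(calib, alternation_rate_hz=float(rate), start_phase="random")
        point = run_psychometric(pop, kappa, cond, n_trials, rng)
        props.append(point.proportion_correct)
        los.append(point.ci_lo)
        his.append(point.ci_hi)
        ns.append(point.n_trials)
    return PsychometricResult(
        x=np.asarray(rates, dtype=float),
        x_name="alternation_rate_hz",
        proportion_correct=np.array(props),
        ci_lo=np.array(los),
        ci_hi=np.array(his),
        n_trials=np.array(ns),
        kappa=kappa,
        meta={"kernel_kind": kernel_kind, "output_exponent": output_exponent},
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def fractional_area(
    correlations: np.ndarray,
    proportions: np.ndarray,
    n_grid: int = 2001,
) -> dict:
    """Odd-symmetry statistic of a psychometric function of correlation.

    The curve is interpolated with a shape-preserving monotone spline
    (PCHIP) through the condition means, clipped to [0, 1], and the
    absolute deviation from chance is integrated separately over negative
    and positive correlations: FA = A-/A+.  FA = 1 when deviations from
    chance are exactly proportionate on the two sides (an odd-symmetric
    curve about (0, 0.5)); FA = 0 when all different-from-chance
    performance occurs at positive correlations.  ``fa_raw`` integrates
    the raw points by the trapezoid rule instead of the fitted curve.
    A+ = 0 yields NaN (undefined, reported as missing).
    """
    x = np.asarray(correlations, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
        raise ValueError("correlations must be strictly increasing, length >= 2")
    if x[0] > -1.0 + 1e-9 or x[-1] < 1.0 - 1e-9:
        raise ValueError("the curve must span correlations [-1, 1]")
    fit = PchipInterpolator(x, p)

    def _area(lo: float, hi: float, fn) -> float:
        grid = np.linspace(lo, hi, n_grid)
        vals = np.abs(np.clip(fn(grid), 0.0, 1.0) - 0.5)
        return float(np.trapezoid(vals, grid))

    a_neg = _area(-1.0, 0.0, fit)
    a_pos = _area(0.0, 1.0, fit)

    def _raw_fn(g):  # piecewise-linear through the raw points
        return np.interp(g, x, p)

    a_neg_raw = _area(-1.0, 0.0, _raw_fn)
    a_pos_raw = _area(0.0, 1.0, _raw_fn)
    return {
        "fa_fitted": a_neg / a_pos if a_pos > 0 else float("nan"),
        "fa_raw": a_neg_raw / a_pos_raw if a_pos_raw > 0 else float("nan"),
        "area_neg": a_neg,
        "area_pos": a_pos,
        "definition": "FA = int_{-1}^{0}|fit-0.5| / int_{0}^{1}|fit-0.5|, PCHIP fit clipped to [0,1]",
    }


def mc_proportion_test(
    group_proportions: np.ndarray,
    n_per_group: np.ndarray | int,
    n_resamples: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo test for unequal binomial proportions across groups.

    Null draws use a single success probability equal to the mean of the
    observed group proportions; the test statistic is the across-group
    variance of the resampled proportions.  The returned p-value uses the
    add-one correction p = (1 + #{null >= observed}) / (1 + n_resamples),
    which keeps it positive and slightly conservative.
    """
    rng = np.random.default_rng(rng)
    props = np.asarray(group_proportions, dtype=float)
    if props.ndim != 1 or props.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any((props < 0) | (props > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    ns = np.broadcast_to(np.asarray(n_per_group, dtype=int), props.shape)
    if np.any(ns < 1):
        raise ValueError("each group needs n >= 1")
    if n_resamples < 1000:
        warnings.warn(
            f"{n_resamples} resamples gives coarse p-value resolution",
            RuntimeWarning,
            stacklevel=2,
        )
    obs_var = props.var()
    p0 = props.mean()
    null = rng.binomial(ns[None, :], p0, size=(n_resamples, props.size)) / ns[None, :]
    null_var = null.var(axis=1)
    exceed = int(np.count_nonzero(null_var >= obs_var - 1e-15))
    return (1 + exceed) / (1 + n_resamples)


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    return clopper_pearson(successes, n, level)
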