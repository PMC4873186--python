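"""Run configuration, validation and result serialization.

A run is described by a flat YAML mapping; every key has a default equal
to the standard simulation value, unknown keys are rejected, and the full
resolved configuration (plus seed, versions and a config hash) is written
to a JSON manifest next to the result files so any output can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, experiments

__all__ = ["RunConfig", "load_config", "save_config", "run"]

_EXPERIMENTS = ("fig3", "fig4a", "fig4b", "fig5", "fig6", "fig7b", "fig9")


@dataclass
class RunConfig:
    """Flat configuration of one experiment run."""

    experiment: str = "fig3"
    seed: int = 0
    scale: float = 1.0
    out_dir: str = "results"
    # stimulus
    field_size_px: int = 292
    deg_per_px: float = 0.03
    dot_radius_deg: float = 0.09
    density: float = 0.24
    disk_diameter_deg: float = 2.5
    annulus_width_deg: float = 1.0
    # model
    kernel_kind: str = "biphasic"
    output_exponent: int = 2
    calibration_target: float = 0.95
    kappa: float | None = None  # fixed noise magnitude; None calibrates

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {_EXPERIMENTS}, got {self.experiment!r}"
            )
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must lie in (0, 1]")
        for name in ("deg_per_px", "dot_radius_deg", "disk_diameter_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.kernel_kind not in ("biphasic", "lowpass"):
            raise ValueError("kernel_kind must be 'biphasic' or 'lowpass'")
        if self.output_exponent not in (1, 2):
            raise ValueError("output_exponent must be 1 or 2")
        if not 0.5 < self.calibration_target < 1.0:
            raise ValueError("calibration_target must lie in (0.5, 1)")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be non-negative")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(str(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))


def _config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _scaled(n_full: int, scale: float, floor: int = 20) -> int:
    return max(floor, int(round(n_full * scale)))


def run(cfg: RunConfig) -> Path:
    """Execute the configured experiment; returns the output directory.

    Results are CSV files; the manifest records everything needed to
    reproduce them byte for byte.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    t0 = time.time()
    files: list[str] = []
    try:
        if cfg.experiment == "fig3":
            df = experiments.figure3_experiment(
                n_patterns=_scaled(1000, cfg.scale), density=cfg.density, rng=rng
            )
            files.append(_write(df, out_dir, "fig3_tuning.csv"))
        elif cfg.experiment == "fig4a":
            grid = experiments.SweepGrid(scale_factor=cfg.scale)
            df = experiments.sweep_density_rf(
                grid.densities, grid.sigmas, grid.n_patterns_scaled, rng,
                dot_radius_deg=cfg.dot_radius_deg,
            )
            files.append(_write(df, out_dir, "fig4a_rnorm.csv"))
        elif cfg.experiment == "fig4b":
            grid = experiments.SweepGrid(scale_factor=cfg.scale)
            df = experiments.sweep_refresh_rf(
                grid.refresh_rates, grid.sigmas, grid.n_trials_scaled,
                duration_s=grid.trial_duration_s * cfg.scale,
                density=cfg.density, rng=rng, dot_radius_deg=cfg.dot_radius_deg,
            )
            files.append(_write(df, out_dir, "fig4b_rnorm.csv"))
        elif cfg.experiment == "fig5":
            df = experiments.figure5_experiment(n_patterns=_scaled(5000, cfg.scale), rng=rng)
            files.append(_write(df, out_dir, "fig5_tuning.csv"))
        elif cfg.experiment == "fig6":
            results = experiments.figure6_experiment(
                n_trials=_scaled(10_000, cfg.scale),
                calib_trials=_scaled(4000, cfg.scale, floor=50),
                rng=rng,
                calibration_target=cfg.calibration_target,
            )
            for key, res in results.items():
                df = res.to_frame()
                fa = experiments.fractional_area(res.x, res.proportion_correct)
                df["fractional_area_fitted"] = fa["fa_fitted"]
                df["fractional_area_raw"] = fa["fa_raw"]
                files.append(_write(df, out_dir, f"fig6_{key}.csv"))
        elif cfg.experiment == "fig7b":
            results = experiments.dot_size_experiment(
                n_trials=_scaled(10_000, cfg.scale),
                calib_trials=_scaled(4000, cfg.scale, floor=50),
                rng=rng,
                calibration_target=cfg.calibration_target,
                include_zero_disparity_control=True,
            )
            for key, res in results.items():
                files.append(_write(res.to_frame(), out_dir, f"fig7b_{key}.csv"))
        elif cfg.experiment == "fig9":
            res = experiments.alternation_experiment(
                n_trials=_scaled(10_000, cfg.scale),
                calib_trials=_scaled(4000, cfg.scale, floor=50),
                kernel_kind=cfg.kernel_kind,
                output_exponent=cfg.output_exponent,
                rng=rng,
                calibration_target=cfg.calibration_target,
            )
            files.append(_write(res.to_frame(), out_dir, "fig9_alternation.csv"))
    except Exception as exc:
        raise RuntimeError(f"experiment {cfg.experiment} failed: {exc}") from exc
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "files": files,
        "wall_clock_s": round(time.time() - t0, 3),
        "versions": {
            "stereobem": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    (out_dir / f"manifest_{cfg.experiment}.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def _write(df, out_dir: Path, name: str) -> str:
    path = out_dir / name
    df.to_csv(path, index=False, float_format="%.10g")
    return name
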