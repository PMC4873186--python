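"""Procedural generation of mixed-correlation random-dot stereograms.

A stereogram is a pair of luminance images (gray background 0, white +1,
black -1).  Black and white circular anti-aliased dots are painted on the
background in a single random order.  Dots inside the central disk carry
the stimulus disparity, split symmetrically between the eyes (+d/2 in the
left image, -d/2 in the right); dots in the surrounding annulus have zero
disparity.  A *matched* (correlated) dot has the same contrast polarity in
both eyes; an *unmatched* (anticorrelated) dot has opposite polarity.  The
``match_level`` parameter sets the proportion of matched dots: 1 is a fully
correlated stereogram, 0 fully anticorrelated, and 0.5 the half-matched
stimulus whose mean binocular correlation is zero.

Dynamic stereograms replace the whole dot pattern with a fresh, independent
pattern at each refresh interval.  Alternating-correlation stereograms
additionally flip the pattern between 100% correlated and 100%
anticorrelated following a square wave.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from ._render import paint_dots

__all__ = [
    "StimulusParams",
    "StereoFramePair",
    "StereoFrameSequence",
    "AlternationParams",
    "make_dot_pattern",
    "make_dynamic_rds",
    "make_alternating_rds",
    "binocular_pixel_correlation",
    "center_disk_mask",
    "render_pattern_batch",
    "save_png_sequence",
    "save_npz",
    "load_npz",
]

_SURROUND_MODES = ("correlated", "same_as_center")
_LAYOUTS = ("disk_annulus", "full")


@dataclass
class StimulusParams:
    """Full parameterization of one random-dot stereogram.

    Geometry is expressed in degrees of visual angle; the image raster has
    ``field_size_px`` pixels per side at ``deg_per_px`` degrees per pixel
    (default 0.03).  ``density`` is coverage proportion: the fraction of
    the stimulus area the dots would occupy if they did not occlude (they
    are allowed to), so values above 1 are legal.  ``layout`` selects the
    standard disk-plus-annulus stimulus or a full-field dot carpet (used
    for single-unit tuning studies, where the whole field plays the role
    of the disparity-defined region).
    """

    field_size_px: int = 292
    deg_per_px: float = 0.03
    dot_radius_deg: float = 0.09
    density: float = 0.24
    disparity_deg: float = 0.0
    match_level: float = 1.0
    disk_diameter_deg: float = 2.5
    annulus_width_deg: float = 1.0
    surround_mode: str = "correlated"
    refresh_rate_hz: float = 21.25
    duration_s: float = 1.5
    layout: str = "disk_annulus"
    uncorrelated: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.field_size_px < 1:
            raise ValueError("field_size_px must be a positive integer")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")
        if self.density < 0:
            raise ValueError(f"density must be non-negative, got {self.density}")
        if self.dot_radius_deg <= 0:
            raise ValueError("dot_radius_deg must be positive")
        if self.disk_diameter_deg <= 0:
            raise ValueError("disk_diameter_deg must be positive")
        if self.annulus_width_deg < 0:
            raise ValueError("annulus_width_deg must be non-negative")
        if not 0.0 <= self.match_level <= 1.0:
            raise ValueError(f"match_level must lie in [0, 1], got {self.match_level}")
        if self.surround_mode not in _SURROUND_MODES:
            raise ValueError(f"surround_mode must be one of {_SURROUND_MODES}")
        if self.layout not in _LAYOUTS:
            raise ValueError(f"layout must be one of {_LAYOUTS}")
        if self.refresh_rate_hz <= 0:
            raise ValueError("refresh_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not np.isfinite(self.disparity_deg):
            raise ValueError("disparity_deg must be finite")
        half_extent = self.field_extent_deg / 2.0
        if abs(self.disparity_deg) / 2.0 > half_extent:
            raise ValueError(
                f"disparity {self.disparity_deg} deg shifts dots beyond the "
                f"{self.field_extent_deg:.2f} deg field"
            )

    @property
    def binocular_correlation(self) -> float:
        """Mean binocular correlation implied by the match level (2m - 1)."""
        return 2.0 * self.match_level - 1.0

    @classmethod
    def from_correlation(cls, correlation: float, **kwargs) -> "StimulusParams":
        """Build params from a binocular correlation in [-1, 1]."""
        if not -1.0 <= correlation <= 1.0:
            raise ValueError("binocular correlation must lie in [-1, 1]")
        return cls(match_level=(correlation + 1.0) / 2.0, **kwargs)

    @property
    def field_extent_deg(self) -> float:
        return self.field_size_px * self.deg_per_px

    def pixel_coords(self) -> np.ndarray:
        """Degree coordinate of each pixel centre along one axis.

        The origin is the field centre; x increases rightward (columns),
        y downward (rows), matching the array layout.
        """
        n = self.field_size_px
        return (np.arange(n) - (n - 1) / 2.0) * self.deg_per_px

    def frame_interval_s(self) -> float:
        return 1.0 / self.refresh_rate_hz


@dataclass
class StereoFramePair:
    """One left/right image pair in [-1, 1] luminance units."""

    left: np.ndarray
    right: np.ndarray
    params: StimulusParams


@dataclass
class StereoFrameSequence:
    """A dynamic stereogram: stacks of frames plus their onset times.

    ``frame_times`` holds the onset of each frame in seconds.  Frame ``i``
    is displayed on [frame_times[i], frame_times[i+1]) and the final frame
    until ``duration_s`` (a trailing partial frame is shown for the
    remaining time).  ``match_levels`` records the per-frame match level
    (constant for plain dynamic stereograms, alternating for
    alternating-correlation ones).
    """

    left: np.ndarray
    right: np.ndarray
    frame_times: np.ndarray
    params: StimulusParams
    match_levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left and right stacks must have identical shape")
        if self.left.shape[0] != len(self.frame_times):
            raise ValueError("one onset time is required per frame")

    @property
    def n_frames(self) -> int:
        return self.left.shape[0]

    @property
    def n_complete_frames(self) -> int:
        """Number of frames displayed for a full refresh interval."""
        return int(math.floor(self.params.duration_s * self.params.refresh_rate_hz + 1e-9))

    def frame_index_on_grid(self, dt: float = 1e-3) -> np.ndarray:
        """Zero-order-hold frame index for each sample of a ``dt`` grid."""
        t = np.arange(int(round(self.params.duration_s / dt))) * dt
        idx = np.searchsorted(self.frame_times, t + 1e-12, side="right") - 1
        return np.clip(idx, 0, self.n_frames - 1)


@dataclass
class AlternationParams:
    """Parameters of an alternating-correlation stereogram.

    The monitor refresh must contain a whole number of frames per
    correlation half-cycle, i.e. ``refresh_rate_hz`` must be an integer
    multiple of ``2 * alternation_rate_hz``.
    """

    base: StimulusParams
    alternation_rate_hz: float = 3.75
    start_phase: str = "random"

    def __post_init__(self) -> None:
        if self.start_phase not in ("correlated_first", "anticorrelated_first", "random"):
            raise ValueError("start_phase must be correlated_first, anticorrelated_first or random")
        if self.alternation_rate_hz <= 0:
            raise ValueError("alternation_rate_hz must be positive")
        ratio = self.base.refresh_rate_hz / (2.0 * self.alternation_rate_hz)
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"refresh rate {self.base.refresh_rate_hz} Hz is not an integer "
                f"multiple of 2 x alternation rate {self.alternation_rate_hz} Hz; "
                "the alternation schedule is not realizable in whole frames"
            )

    @property
    def frames_per_half_cycle(self) -> int:
        return int(round(self.base.refresh_rate_hz / (2.0 * self.alternation_rate_hz)))


def _region_dot_count(density: float, region_area: float, dot_radius: float) -> int:
    return int(round(density * region_area / (math.pi * dot_radius**2)))


def _sample_monocular_dots(params: StimulusParams, rng: np.random.Generator):
    """Dot centres (deg, field-centred), region labels (0 centre, 1 surround)."""
    r = params.dot_radius_deg
    if params.layout == "full":
        # Pad the sampling region so that disparity shifts and dot spill do
        # not deplete the visible field near its edges.
        half = params.field_extent_deg / 2.0 + abs(params.disparity_deg) / 2.0 + r + params.deg_per_px
        area = (2.0 * half) ** 2
        n = _region_dot_count(params.density, area, r)
        xy = rng.uniform(-half, half, size=(n, 2))
        return xy[:, 0], xy[:, 1], np.zeros(n, dtype=np.int64)
    disk_r = params.disk_diameter_deg / 2.0
    outer_r = disk_r + params.annulus_width_deg
    n_center = _region_dot_count(params.density, math.pi * disk_r**2, r)
    n_surround = _region_dot_count(
        params.density, math.pi * (outer_r**2 - disk_r**2), r
    )
    u = rng.uniform(size=n_center)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_center)
    rad = disk_r * np.sqrt(u)
    xc, yc = rad * np.cos(theta), rad * np.sin(theta)
    u = rng.uniform(size=n_surround)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_surround)
    rad = np.sqrt(u * (outer_r**2 - disk_r**2) + disk_r**2)
    xs, ys = rad * np.cos(theta), rad * np.sin(theta)
    x = np.concatenate([xc, xs])
    y = np.concatenate([yc, ys])
    region = np.concatenate(
        [np.zeros(n_center, dtype=np.int64), np.ones(n_surround, dtype=np.int64)]
    )
    return x, y, region


def _matched_flags(n: int, match_level: float, rng: np.random.Generator) -> np.ndarray:
    """Flag match_level * n dots as matched, at random.

    A fractional dot is resolved by randomized rounding, so the expected
    matched fraction equals ``match_level`` exactly.  Deterministic
    rounding would otherwise give e.g. every half-matched frame with an
    odd dot count one extra matched dot, biasing the stimulus's mean
    binocular correlation away from zero.
    """
    exact = match_level * n
    n_matched = int(math.floor(exact))
    if rng.uniform() < exact - n_matched:
        n_matched += 1
    flags = np.zeros(n, dtype=bool)
    flags[:n_matched] = True
    rng.shuffle(flags)
    return flags


def _deg_to_px(x_deg: np.ndarray, params: StimulusParams) -> np.ndarray:
    return x_deg / params.deg_per_px + (params.field_size_px - 1) / 2.0


def _paint_eye(img, x_deg, y_deg, colors, params):
    paint_dots(
        img,
        np.ascontiguousarray(_deg_to_px(x_deg, params)),
        np.ascontiguousarray(_deg_to_px(y_deg, params)),
        np.ascontiguousarray(colors, dtype=np.float64),
        params.dot_radius_deg / params.deg_per_px,
    )


def _render_uncorrelated(params: StimulusParams, rng: np.random.Generator):
    n = params.field_size_px
    left = np.zeros((n, n), dtype=np.float32)
    right = np.zeros((n, n), dtype=np.float32)
    for img in (left, right):
        x, y, _region = _sample_monocular_dots(params, rng)
        colors = rng.choice(np.array([-1.0, 1.0]), size=x.size)
        order = rng.permutation(x.size)
        _paint_eye(img, x[order], y[order], colors[order], params)
    return left, right


def _render_pattern(params: StimulusParams, rng: np.random.Generator):
    """Render one stereo pair; returns (left, right) float32 images."""
    if params.uncorrelated:
        return _render_uncorrelated(params, rng)
    n = params.field_size_px
    left = np.zeros((n, n), dtype=np.float32)
    right = np.zeros((n, n), dtype=np.float32)
    x, y, region = _sample_monocular_dots(params, rng)
    n_dots = x.size
    if n_dots == 0:
        return left, right
    colors = rng.choice(np.array([-1.0, 1.0]), size=n_dots)
    matched = np.ones(n_dots, dtype=bool)
    is_center = region == 0
    matched[is_center] = _matched_flags(int(is_center.sum()), params.match_level, rng)
    is_surround = ~is_center
    if params.surround_mode == "same_as_center" and is_surround.any():
        matched[is_surround] = _matched_flags(
            int(is_surround.sum()), params.match_level, rng
        )
    half_shift = np.where(is_center, params.disparity_deg / 2.0, 0.0)
    color_right = np.where(matched, colors, -colors)
    # One random interleaved paint order shared by both eyes, so occlusion
    # carries no systematic cue about correlation or region.
    order = rng.permutation(n_dots)
    _paint_eye(left, (x + half_shift)[order], y[order], colors[order], params)
    _paint_eye(right, (x - half_shift)[order], y[order], color_right[order], params)
    return left, right


def make_dot_pattern(params: StimulusParams, rng: np.random.Generator | int | None = None) -> StereoFramePair:
    """Generate a single static random-dot stereogram."""
    rng = np.random.default_rng(params.seed if rng is None else rng)
    left, right = _render_pattern(params, rng)
    return StereoFramePair(left=left, right=right, params=params)


def render_pattern_batch(
    params: StimulusParams, n_patterns: int, rng: np.random.Generator
) -> np.ndarray:
    """Render ``n_patterns`` independent pairs, flattened for batched math.

    Returns an array of shape ``(n_patterns, 2, field_size_px**2)`` with the
    left eye at index 0 of the middle axis.
    """
    npix = params.field_size_px**2
    out = np.empty((n_patterns, 2, npix), dtype=np.float32)
    for i in range(n_patterns):
        left, right = _render_pattern(params, rng)
        out[i, 0] = left.ravel()
        out[i, 1] = right.ravel()
    return out


def render_rnorm_triplet(
    params: StimulusParams, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Render paired correlated / half-matched / uncorrelated stereograms.

    The three classes share the same left-eye image, dot layout and paint
    order (the uncorrelated class redraws the right eye's dots); only the
    binocular relation differs.  Pairing the classes this way cancels the
    dominant monocular-content variability when their responses are
    differenced, sharply reducing the Monte-Carlo error of the normalized
    half-matched response at a given number of patterns.

    Returns ``{"correlated": (L, R), "half_matched": (L, R),
    "uncorrelated": (L, R)}`` where the left image object is shared.
    """
    n = params.field_size_px
    left = np.zeros((n, n), dtype=np.float32)
    x, y, region = _sample_monocular_dots(params, rng)
    n_dots = x.size
    colors = rng.choice(np.array([-1.0, 1.0]), size=n_dots)
    is_center = region == 0
    half_shift = np.where(is_center, params.disparity_deg / 2.0, 0.0)
    order = rng.permutation(n_dots)
    _paint_eye(left, (x + half_shift)[order], y[order], colors[order], params)

    right_corr = np.zeros((n, n), dtype=np.float32)
    _paint_eye(right_corr, (x - half_shift)[order], y[order], colors[order], params)

    matched = np.ones(n_dots, dtype=bool)
    matched[is_center] = _matched_flags(int(is_center.sum()), 0.5, rng)
    if params.surround_mode == "same_as_center" and (~is_center).any():
        matched[~is_center] = _matched_flags(int((~is_center).sum()), 0.5, rng)
    hm_colors = np.where(matched, colors, -colors)
    right_hm = np.zeros((n, n), dtype=np.float32)
    _paint_eye(right_hm, (x - half_shift)[order], y[order], hm_colors[order], params)

    right_unc = np.zeros((n, n), dtype=np.float32)
    x2, y2, _ = _sample_monocular_dots(params, rng)
    colors2 = rng.choice(np.array([-1.0, 1.0]), size=x2.size)
    order2 = rng.permutation(x2.size)
    _paint_eye(right_unc, x2[order2], y2[order2], colors2[order2], params)

    return {
        "correlated": (left, right_corr),
        "half_matched": (left, right_hm),
        "uncorrelated": (left, right_unc),
    }


def _frame_onsets(params: StimulusParams) -> np.ndarray:
    n_frames = int(math.ceil(params.duration_s * params.refresh_rate_hz - 1e-9))
    if params.duration_s * params.refresh_rate_hz < 1.0 - 1e-9:
        raise ValueError(
            f"duration {params.duration_s} s is shorter than one frame at "
            f"{params.refresh_rate_hz} Hz"
        )
    return np.arange(n_frames) / params.refresh_rate_hz


def make_dynamic_rds(
    params: StimulusParams, rng: np.random.Generator | int | None = None
) -> StereoFrameSequence:
    """Generate a dynamic stereogram: a fresh pattern at every refresh.

    Every frame is an independent dot pattern with identical disparity and
    match level.  A trailing partial frame, if the duration is not a whole
    number of refresh intervals, is included and shown for the remainder.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    onsets = _frame_onsets(params)
    n = params.field_size_px
    left = np.empty((len(onsets), n, n), dtype=np.float32)
    right = np.empty_like(left)
    for i in range(len(onsets)):
        left[i], right[i] = _render_pattern(params, rng)
    levels = np.full(len(onsets), params.match_level)
    return StereoFrameSequence(
        left=left, right=right, frame_times=onsets, params=params, match_levels=levels
    )


def make_alternating_rds(
    ap: AlternationParams, rng: np.random.Generator | int | None = None
) -> StereoFrameSequence:
    """Generate an alternating-correlation stereogram.

    Every monitor frame is a fresh dot pattern; the match level follows a
    square wave between 1 (correlated) and 0 (anticorrelated) with
    ``frames_per_half_cycle`` frames per half-cycle.  The starting
    correlation is set by ``start_phase`` (randomized per trial when
    requested).
    """
    rng = np.random.default_rng(ap.base.seed if rng is None else rng)
    onsets = _frame_onsets(ap.base)
    if ap.start_phase == "random":
        correlated_first = bool(rng.integers(2))
    else:
        correlated_first = ap.start_phase == "correlated_first"
    half = ap.frames_per_half_cycle
    frame_idx = np.arange(len(onsets))
    is_correlated = (frame_idx // half) % 2 == 0
    if not correlated_first:
        is_correlated = ~is_correlated
    levels = np.where(is_correlated, 1.0, 0.0)
    n = ap.base.field_size_px
    left = np.empty((len(onsets), n, n), dtype=np.float32)
    right = np.empty_like(left)
    for i in range(len(onsets)):
        frame_params = replace(ap.base, match_level=levels[i])
        left[i], right[i] = _render_pattern(frame_params, rng)
    return StereoFrameSequence(
        left=left, right=right, frame_times=onsets, params=ap.base, match_levels=levels
    )


def center_disk_mask(params: StimulusParams) -> np.ndarray:
    """Boolean mask of pixels inside the disparity-defined central disk."""
    coords = params.pixel_coords()
    xx, yy = np.meshgrid(coords, coords)
    if params.layout == "full":
        return np.ones_like(xx, dtype=bool)
    return xx**2 + yy**2 <= (params.disk_diameter_deg / 2.0) ** 2


def binocular_pixel_correlation(
    seq: StereoFrameSequence, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-frame Pearson correlation of left vs right pixels within a mask.

    Frames in which either eye is constant (e.g. all-gray) have undefined
    correlation and are reported as NaN.
    """
    if mask is None:
        mask = center_disk_mask(seq.params)
    if not mask.any():
        raise ValueError("mask must contain at least one pixel")
    out = np.full(seq.n_frames, np.nan)
    for i in range(seq.n_frames):
        l = seq.left[i][mask].astype(np.float64)
        r = seq.right[i][mask].astype(np.float64)
        sl, sr = l.std(), r.std()
        if sl == 0.0 or sr == 0.0:
            continue
        out[i] = ((l - l.mean()) * (r - r.mean())).mean() / (sl * sr)
    return out


def save_png_sequence(seq: StereoFrameSequence, out_dir: str | Path, prefix: str = "rds") -> None:
    """Export a sequence as 8-bit PNG stacks plus a JSON parameter sidecar."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(seq.n_frames):
        for eye, stack in (("L", seq.left), ("R", seq.right)):
            img = np.clip((stack[i] + 1.0) / 2.0 * 255.0, 0, 255).astype(np.uint8)
            iio.imwrite(out_dir / f"{prefix}_{i:04d}_{eye}.png", img)
    sidecar = {
        "params": asdict(seq.params),
        "frame_times": seq.frame_times.tolist(),
        "match_levels": None if seq.match_levels is None else seq.match_levels.tolist(),
    }
    (out_dir / f"{prefix}_params.json").write_text(json.dumps(sidecar, indent=2))


def save_npz(seq: StereoFrameSequence, path: str | Path) -> None:
    """Exact round-trip export of a sequence as a compressed array container."""
    np.savez_compressed(
        path,
        left=seq.left,
        right=seq.right,
        frame_times=seq.frame_times,
        match_levels=np.array([]) if seq.match_levels is None else seq.match_levels,
        params_json=json.dumps(asdict(seq.params)),
    )


def load_npz(path: str | Path) -> StereoFrameSequence:
    with np.load(path) as data:
        params = StimulusParams(**json.loads(str(data["params_json"])))
        levels = data["match_levels"]
        return StereoFrameSequence(
            left=data["left"],
            right=data["right"],
            frame_times=data["frame_times"],
            params=params,
            match_levels=None if levels.size == 0 else levels,
        )
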