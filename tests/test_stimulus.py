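"""Stereogram generator: geometry, correlation structure and frame timing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stereobem.stimulus import (
    AlternationParams,
    StimulusParams,
    _sample_monocular_dots,
    binocular_pixel_correlation,
    load_npz,
    make_alternating_rds,
    make_dot_pattern,
    make_dynamic_rds,
    save_npz,
)


def small_params(**kw):
    defaults = dict(field_size_px=64, layout="full", density=0.24)
    defaults.update(kw)
    return StimulusParams(**defaults)


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"density": -0.1},
            {"dot_radius_deg": 0.0},
            {"match_level": 1.5},
            {"match_level": -0.01},
            {"disk_diameter_deg": -2.0},
            {"surround_mode": "mirror"},
            {"refresh_rate_hz": 0.0},
            {"duration_s": 0.0},
            {"disparity_deg": float("nan")},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            StimulusParams(**kw)

    def test_correlation_match_level_mapping(self):
        assert StimulusParams(match_level=0.5).binocular_correlation == 0.0
        assert StimulusParams.from_correlation(-1.0).match_level == 0.0
        assert StimulusParams.from_correlation(1.0).match_level == 1.0

    def test_dot_counts_at_standard_density(self):
        # density 24%, r = 0.09 deg: the disk holds round(0.24*(1.25/0.09)^2)
        # dots and the annulus round(0.24*(2.25^2-1.25^2)/0.09^2).
        p = StimulusParams(density=0.24, dot_radius_deg=0.09)
        x, y, region = _sample_monocular_dots(p, np.random.default_rng(0))
        assert (region == 0).sum() == round(0.24 * (1.25 / 0.09) ** 2)
        assert (region == 1).sum() == round(0.24 * (2.25**2 - 1.25**2) / 0.09**2)


class TestStaticPattern:
    def test_zero_density_gives_gray(self):
        pair = make_dot_pattern(small_params(density=0.0), 0)
        assert not pair.left.any() and not pair.right.any()

    def test_fully_matched_zero_disparity_identical(self):
        pair = make_dot_pattern(small_params(match_level=1.0), 3)
        assert np.array_equal(pair.left, pair.right)
        assert pair.left.min() >= -1.0 and pair.left.max() <= 1.0

    def test_fully_anticorrelated_is_sign_inverted(self):
        # Alpha compositing preserves the sign inversion exactly, even on
        # anti-aliased edges and where opposite-sign dots occlude.
        pair = make_dot_pattern(small_params(match_level=0.0), 3)
        assert np.array_equal(pair.left, -pair.right)
        assert pair.left.any()

    def test_low_density_coverage_fraction(self):
        # At low density occlusion is negligible, so the fraction of
        # majority-covered pixels (|luminance| >= 0.5, i.e. inside the
        # anti-aliasing ramp) equals the density.
        density, n_rep = 0.04, 60
        fracs = [
            np.count_nonzero(np.abs(make_dot_pattern(small_params(density=density), s).left) >= 0.5)
            / 64**2
            for s in range(n_rep)
        ]
        se = np.std(fracs, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(fracs) - density) < 3 * se + 0.003

    def test_black_white_dots_balanced(self):
        rng = np.random.default_rng(7)
        p = small_params()
        total, white = 0, 0
        for _ in range(200):
            x, _y, _r = _sample_monocular_dots(p, rng)
            colors = rng.choice([-1.0, 1.0], size=x.size)
            total += colors.size
            white += (colors > 0).sum()
        # binomial 3-sigma band around one half
        assert abs(white / total - 0.5) < 3 * 0.5 / np.sqrt(total)

    def test_disparity_moves_half_shift_each_eye(self):
        # Cross-correlating the two eyes' images at match level 1 peaks at
        # the full disparity: +d/2 in one eye, -d/2 in the other.
        d = 0.12  # 4 px
        p = small_params(match_level=1.0, disparity_deg=d, density=0.5)
        rng = np.random.default_rng(5)
        score = np.zeros(9)
        lags = np.arange(-4, 5)
        for _ in range(20):
            pair = make_dot_pattern(p, rng)
            for i, lag in enumerate(lags):
                score[i] += np.sum(
                    np.roll(pair.left, -lag, axis=1)[:, 8:-8] * pair.right[:, 8:-8]
                )
        assert lags[np.argmax(score)] == round(d / p.deg_per_px)

    @given(match=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    def test_images_bounded_and_congruent(self, match, seed):
        pair = make_dot_pattern(small_params(match_level=match, field_size_px=32), seed)
        assert pair.left.shape == pair.right.shape == (32, 32)
        for img in (pair.left, pair.right):
            assert img.min() >= -1.0 and img.max() <= 1.0


class TestDynamic:
    @pytest.mark.parametrize(
        "refresh,interval_ms", [(21.25, 47.06), (120.0, 8.33)]
    )
    def test_frame_interval(self, refresh, interval_ms):
        p = small_params(field_size_px=16, refresh_rate_hz=refresh, duration_s=0.1)
        assert round(p.frame_interval_s() * 1e3, 2) == interval_ms

    def test_complete_frame_count(self):
        p = small_params(field_size_px=16, refresh_rate_hz=21.25, duration_s=1.5, density=0.1)
        seq = make_dynamic_rds(p, 0)
        assert seq.n_complete_frames == 31  # floor(1.5 * 21.25)
        assert seq.n_frames == 32  # trailing partial frame shown for the rest

    def test_duration_shorter_than_one_frame_rejected(self):
        p = small_params(field_size_px=16, refresh_rate_hz=10.0, duration_s=0.05)
        with pytest.raises(ValueError, match="shorter than one frame"):
            make_dynamic_rds(p, 0)

    def test_frames_are_independent_patterns(self):
        p = small_params(field_size_px=32, refresh_rate_hz=20.0, duration_s=0.2)
        seq = make_dynamic_rds(p, 0)
        assert not np.array_equal(seq.left[0], seq.left[1])

    def test_zero_order_hold_index(self):
        p = small_params(field_size_px=16, refresh_rate_hz=20.0, duration_s=0.2, density=0.1)
        seq = make_dynamic_rds(p, 0)
        idx = seq.frame_index_on_grid()
        assert idx.size == 200
        assert idx[0] == 0 and idx[49] == 0 and idx[50] == 1 and idx[-1] == 3

    def test_npz_round_trip(self, tmp_path):
        p = small_params(field_size_px=16, refresh_rate_hz=20.0, duration_s=0.2, density=0.1)
        seq = make_dynamic_rds(p, 0)
        save_npz(seq, tmp_path / "seq.npz")
        back = load_npz(tmp_path / "seq.npz")
        assert np.array_equal(back.left, seq.left)
        assert back.params == seq.params


class TestAlternation:
    def base(self, **kw):
        defaults = dict(
            field_size_px=16, refresh_rate_hz=120.0, duration_s=1.0 / 15.0, density=0.1
        )
        defaults.update(kw)
        return StimulusParams(layout="full", **defaults)

    def test_sign_pattern_60hz(self):
        ap = AlternationParams(self.base(), 60.0, start_phase="correlated_first")
        seq = make_alternating_rds(ap, 0)
        assert list(seq.match_levels[:4]) == [1.0, 0.0, 1.0, 0.0]

    def test_sign_pattern_30hz(self):
        ap = AlternationParams(self.base(duration_s=1.0 / 15.0), 30.0, "correlated_first")
        seq = make_alternating_rds(ap, 0)
        assert list(seq.match_levels[:8]) == [1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0]

    def test_fastest_alternation_flips_every_frame(self):
        ap = AlternationParams(self.base(), 60.0, "anticorrelated_first")
        seq = make_alternating_rds(ap, 0)
        assert np.all(np.diff(seq.match_levels)[::2] != 0)
        assert seq.match_levels[0] == 0.0

    def test_non_divisible_rate_rejected(self):
        with pytest.raises(ValueError, match="not an integer multiple"):
            AlternationParams(self.base(), 25.0)

    def test_random_start_phase_balanced(self):
        rng = np.random.default_rng(0)
        params = self.base(field_size_px=8, density=0.05, duration_s=2.0 / 120.0)
        ap = AlternationParams(params, 60.0, "random")
        n = 800
        first_corr = sum(
            make_alternating_rds(ap, rng).match_levels[0] == 1.0 for _ in range(n)
        )
        assert abs(first_corr / n - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestPixelCorrelation:
    def test_correlated_is_one(self):
        p = small_params(field_size_px=48, match_level=1.0, refresh_rate_hz=20, duration_s=0.2)
        seq = make_dynamic_rds(p, 0)
        corr = binocular_pixel_correlation(seq)
        assert np.allclose(corr, 1.0)

    def test_anticorrelated_is_minus_one(self):
        p = small_params(field_size_px=48, match_level=0.0, refresh_rate_hz=20, duration_s=0.2)
        seq = make_dynamic_rds(p, 0)
        assert np.allclose(binocular_pixel_correlation(seq), -1.0)

    def test_half_matched_averages_to_zero(self):
        p = small_params(
            field_size_px=48, match_level=0.5, refresh_rate_hz=100, duration_s=3.0
        )
        corr = binocular_pixel_correlation(make_dynamic_rds(p, 2))
        se = corr.std(ddof=1) / np.sqrt(corr.size)
        assert abs(corr.mean()) < 3 * se

    def test_gray_frame_is_missing_not_zero(self):
        p = small_params(field_size_px=16, density=0.0, refresh_rate_hz=20, duration_s=0.1)
        corr = binocular_pixel_correlation(make_dynamic_rds(p, 0))
        assert np.all(np.isnan(corr))

    def test_empty_mask_rejected(self):
        p = small_params(field_size_px=16, refresh_rate_hz=20, duration_s=0.1)
        seq = make_dynamic_rds(p, 0)
        with pytest.raises(ValueError):
            binocular_pixel_correlation(seq, np.zeros((16, 16), dtype=bool))
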