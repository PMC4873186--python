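"""Low-level dot painting.

Dots are anti-aliased by a coverage ramp: a pixel whose centre lies at
distance ``d`` (in pixels) from the dot centre receives coverage
``clip(r_px - d + 0.5, 0, 1)``, a linear approximation to the area of the
pixel covered by the circle.  Painting is alpha-compositing in dot order,
so later dots occlude earlier ones while edge pixels blend.
"""

import numpy as np
from numba import njit

__all__ = ["paint_dots", "footprint_gabor_weights"]


@njit(cache=True)
def paint_dots(img, xs_px, ys_px, colors, r_px):
    """Composite circular dots onto ``img`` in the order given.

    ``img`` is modified in place.  ``xs_px``/``ys_px`` are float pixel
    coordinates of dot centres (column, row); ``colors`` are luminance
    values in [-1, 1].  Compositing uses ``new = (1-cov)*old + cov*color``
    so that sign-flipping every color exactly negates the painted image.
    """
    n_rows, n_cols = img.shape
    for i in range(xs_px.shape[0]):
        x = xs_px[i]
        y = ys_px[i]
        c = colors[i]
        lo_r = int(np.floor(y - r_px - 1.0))
        hi_r = int(np.ceil(y + r_px + 1.0))
        lo_c = int(np.floor(x - r_px - 1.0))
        hi_c = int(np.ceil(x + r_px + 1.0))
        if lo_r < 0:
            lo_r = 0
        if lo_c < 0:
            lo_c = 0
        if hi_r > n_rows - 1:
            hi_r = n_rows - 1
        if hi_c > n_cols - 1:
            hi_c = n_cols - 1
        for row in range(lo_r, hi_r + 1):
            dy = row - y
            for col in range(lo_c, hi_c + 1):
                dx = col - x
                d = np.sqrt(dx * dx + dy * dy)
                cov = r_px - d + 0.5
                if cov <= 0.0:
                    continue
                if cov > 1.0:
                    cov = 1.0
                img[row, col] = (1.0 - cov) * img[row, col] + cov * c


@njit(cache=True)
def footprint_gabor_weights(xs_px, ys_px, r_px, transparency, gab0, gab1, b):
    """Per-dot effective Gabor weights under occlusion.

    Because compositing is alpha blending, the painted image is linear in
    the dot colors: pixel = sum_d color_d * w_d(px), where w_d is the
    dot's coverage multiplied by the transparency (1 - cov) of every dot
    painted after it.  This kernel accumulates, per dot d (in paint
    order), the inner products of w_d with two receptive-field arrays
    into ``b[0, d]`` and ``b[1, d]``, by sweeping the dots in reverse
    paint order while maintaining the remaining-transparency buffer.

    ``transparency`` must be all-ones on entry (it is consumed); the
    coverage formula matches ``paint_dots`` exactly.
    """
    n_rows, n_cols = transparency.shape
    for i in range(xs_px.shape[0] - 1, -1, -1):
        x = xs_px[i]
        y = ys_px[i]
        lo_r = int(np.floor(y - r_px - 1.0))
        hi_r = int(np.ceil(y + r_px + 1.0))
        lo_c = int(np.floor(x - r_px - 1.0))
        hi_c = int(np.ceil(x + r_px + 1.0))
        if lo_r < 0:
            lo_r = 0
        if lo_c < 0:
            lo_c = 0
        if hi_r > n_rows - 1:
            hi_r = n_rows - 1
        if hi_c > n_cols - 1:
            hi_c = n_cols - 1
        acc0 = 0.0
        acc1 = 0.0
        for row in range(lo_r, hi_r + 1):
            dy = row - y
            for col in range(lo_c, hi_c + 1):
                dx = col - x
                d = np.sqrt(dx * dx + dy * dy)
                cov = r_px - d + 0.5
                if cov <= 0.0:
                    continue
                if cov > 1.0:
                    cov = 1.0
                w = cov * transparency[row, col]
                acc0 += w * gab0[row, col]
                acc1 += w * gab1[row, col]
                transparency[row, col] *= 1.0 - cov
        b[0, i] = acc0
        b[1, i] = acc1
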