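# Methods

## The model in brief

`stereobem` simulates stereo depth perception in mixed-correlation random-dot
stereograms (RDS) with a single correlation-based mechanism: the binocular
energy model (BEM) of V1 complex cells, extended with a static squaring
output nonlinearity, read out by a small opponent population with a linear
decision rule.

A monocular receptive field is a vertically oriented Gabor

    rho_s(x, y) = exp(-(x - x0 ∓ dx/2)^2 / 2 sigma^2 - (y - y0)^2 / 2 sigma^2)
                  · cos(2 pi f (x - x0 ∓ dx/2) + phi)

with *position* disparity only: the left-eye field is shifted by +dx/2 and
the right-eye field by -dx/2 (no phase disparity).  Two binocular simple
cells S = (V_L + V_R)^2 with quadrature carrier phases (phi, phi + pi/2)
combine into the complex response C = S_1 + S_2, which is invariant to
stimulus phase.  The *binocularly linear* model reads out C; its mean
response is a linear function of the stimulus's binocular correlation, so it
is blind to half-matched RDSs (equal numbers of correlated and
anticorrelated dots, mean correlation 0).  The modified model reads out C².
Because E[X²] = (E[X])² + Var[X], the squaring converts trial-to-trial
*variability* of the local correlation within the receptive field into a
change in mean response: the model becomes disparity-tuned to half-matched
patterns, peaked at its preferred disparity, and its anticorrelated tuning
is attenuated relative to correlated (amplitude ratio < 1), as observed in
V1.

The strength of half-matched tuning is summarized by the normalized
half-matched response

    R_norm = (⟨C²_hm⟩ − ⟨C²_uncorr⟩) / (⟨C²_corr⟩ − ⟨C²_uncorr⟩)

evaluated at the preferred disparity: 1 means half-matched responses equal
correlated ones, 0 means they fall to the uncorrelated baseline.  R_norm
grows with the variability of local correlation, hence it falls as dot
density rises, as the relative receptive-field size sigma/r (Gabor SD over
dot radius) rises, and as the pattern refresh rate rises relative to the
temporal integration window.

Time enters through a separable biphasic temporal kernel

    rho_t(t) = t^(alpha-1) exp(-t/tau) cos(omega t + phase) / (Gamma(alpha) tau^alpha),  t >= 0

with defaults alpha = 2.5, omega = 8 pi rad/s, phase = -pi, tau = 35 ms: a
gamma-density envelope times a cosine, i.e. a bandpass kernel whose on-phase
lasts 125 ms (between the cosine zero crossings at 62.5 and 187.5 ms) and
whose amplitude spectrum peaks at 4.6 Hz on the 1 ms simulation grid (the
asymmetric envelope skews the peak slightly above the 4 Hz carrier).  A
non-oscillatory `lowpass` variant (the same gamma envelope without the
cosine) is provided for comparison.  Monocular drives are the causal
convolution of the kernel with the per-millisecond spatial inner product of
the receptive field and the zero-order-held stimulus frames.

## Stimuli

Dynamic RDSs are fresh, independent dot patterns at every refresh interval:
black and white anti-aliased circular dots (radius 0.09° by default) on a
gray background, luminance coded as −1/0/+1 so that anticorrelation is sign
inversion.  Dots inside the central 2.5° disk carry the disparity, split
±d/2 between the eyes; a 1°-wide surrounding annulus has zero disparity and,
by default, full correlation.  Dot density is coverage proportion (24%
default; dots may occlude, and densities above 1 are legal).  A *matched*
dot has the same polarity in both eyes, an *unmatched* dot opposite
polarity; `match_level` m sets the matched proportion (binocular correlation
2m − 1).  The matched count uses randomized rounding so the expected matched
fraction is exactly m — deterministic rounding would bias every
odd-dot-count half-matched frame by one dot.  Dots are painted in one random
interleaved order shared by both eyes, so occlusion carries no correlation
or region cue; painting is alpha compositing with a linear coverage ramp at
the dot edge (the anti-aliasing scheme).  Alternating-correlation stereograms
refresh the pattern every monitor frame (120 Hz) while the correlation
flips between +1 and −1 as a square wave at 3.75–60 Hz, with the starting
sign randomized per trial; their surround follows the centre's correlation.

Disparities are realized exactly: dot centres are continuous and
anti-aliased, so no grid rounding is applied (rounding half-shifts to the
0.03°/px raster would destroy the ±0.03° condition, whose per-eye shift is
half a pixel).

Simulations use 0.03°/pixel.  Single-unit studies use a "full-field" layout
(a dot carpet covering just the receptive field's ±4 sigma support, sampled
from a padded region so disparity shifts do not deplete the edges);
decision-model runs use the disk-plus-annulus stimulus on a raster trimmed
to the region any unit can see (160 px = 4.8°).  Responses are identical in
distribution to a larger raster because the dots beyond a unit's support
never enter its inner product.

## Decision model

The population holds 40 cells at each preferred disparity in
(−0.48°, −0.03°, +0.03°, +0.48°).  Receptive-field size follows the
size-disparity correlation sigma = 0.023 + 0.41·|dx| (degrees) and the
carrier frequency f = 0.3125/sigma, so all cells have the same bandwidth.
Within a group, centres are placed in the central disk by dart throwing
with minimum spacing 2 sigma ("non-overlapping" receptive fields); where 40
centres cannot be packed at that spacing (the coarse groups), the spacing
relaxes geometrically to the maximum feasible value and is recorded.

Each cell's response is divided by its normalization constant ⟨C̄ᵢ²⟩, the
mean response to fully correlated RDSs at its own preferred disparity
presented at 21.25 Hz (estimated from 100 trials per disparity group), so
every cell peaks near 1 in normalized units.  Gaussian noise is
multiplicative in the normalized response: P_ik = X_ik + kappa·eps_ik with
X_ik = C²_ik/⟨C̄ᵢ²⟩ and eps_ik ~ N(0, X_ik), independent across cells and
1 ms time points (per-frame for static runs).  kappa is the model's only
free parameter.

Each cell is paired with its antineuron (same retinal position, opposite
disparity sign).  The opponent signal R(i) = sum_k (P_ik − N_ik) is summed
over the 80 pairs; the model reports "far" iff the sum is strictly positive
(an exact zero — measure zero under continuous noise — reports "near").
For zero-disparity control conditions, a trial's "correct" target is a coin
flip, so accuracy converges to chance.

Because the decision variable is a sum of independent Gaussians given the
stimulus, `run_psychometric` draws the noise exactly as one Gaussian per
trial with the aggregated variance kappa²·sum(X), and `calibrate_kappa`
takes the noise expectation in closed form (a probit), leaving only
stimulus Monte-Carlo; `decide_trial` draws noise per time point.  These are
distributional identities, not approximations.

kappa is calibrated by bisection on log kappa to a target accuracy of 0.95
on fully correlated stimuli at the experiment's own refresh rate, duration
and fine disparity (matching human ceiling performance), separately per
refresh rate — at fixed duration, faster refresh averages more patterns per
trial, so stimulus-driven variability falls with refresh and a single kappa
cannot fit all rates.  For the dot-size experiment kappa is the largest
value at which *every* dot size reaches the target on correlated stimuli
(the minimum of the per-size calibrations).

The fine/coarse-disparity comparison uses static receptive fields (one time
point per frame); the refresh-rate, dot-size and alternation experiments
use the temporal kernel.  The dot-size experiment probes the model at its
fine preferred disparity (±0.03°): the population encodes only four
disparities, and at intermediate disparities (e.g. ±0.075°, roughly half a
carrier period off-peak for the fine cells) the side lobes of the
disparity-tuning curves produce false-match signals that invert the
readout — a wallpaper-effect limitation of a four-disparity population, not
of the mechanism.

## Monte-Carlo estimation of R_norm

Mean-response surfaces (R_norm vs density, sigma/r, refresh) use two
variance reductions, both exact:

1. **Common random numbers** — the correlated, half-matched and
   uncorrelated stimuli of one draw share the same dot layout and left-eye
   image (the uncorrelated class redraws the right eye), so class
   differences cancel the dominant monocular-content variability.
2. **Exact color averaging** — alpha compositing makes every pixel linear
   in the dot colors, which are independent ±1 variables, even with
   occlusion (a dot's effective footprint is its coverage attenuated by
   later dots' transparency).  Monocular drives are therefore Rademacher
   linear forms, and E[C] and E[C²] given the layout have closed forms in
   the per-dot footprint weights; with the temporal kernel the weights
   factor per frame and the time-resolved moments reduce to sums over
   frames of squared/fourth-power temporal window weights.  Integrating
   the colors out removes roughly two thirds of the sampling variance at a
   given number of layouts.

The closed forms are verified in the test suite against brute-force
enumeration of all color assignments and against the image-rendering
pipeline, which remains the route used by the tuning-curve and decision
code.  R_norm standard errors propagate the full covariance of the three
paired class means (delta method).

## Statistics

* **Exact binomial CIs** (Clopper-Pearson, via beta quantiles) accompany
  every proportion.
* **Monte-Carlo proportion test**: for groups of binomial proportions, the
  across-group variance is compared with its null distribution under a
  common success probability (the mean of the observed proportions), with
  the add-one correction p = (1 + #{null ≥ obs}) / (1 + N); the suite
  verifies the test holds its nominal 5% size under its own null.
* **Fractional area**: the odd-symmetry statistic of a psychometric
  function of correlation, FA = ∫₋₁⁰|fit − 0.5| / ∫₀¹|fit − 0.5|, computed
  on a shape-preserving monotone spline (PCHIP) through the condition means
  (clipped to [0, 1]) — reversed-depth curves are not sigmoids, so no
  parametric family is imposed.  FA = 1 for a curve whose deviations from
  chance are proportionate on both sides; FA = 0 when all
  different-from-chance performance is at positive correlations.  The raw
  trapezoid version is emitted alongside the fitted one.

## Problem sizes

Publication-scale runs (20 000 patterns per tuning point, 10 000 trials per
psychometric point, 10 s sweep trials) are available through the API and
CLI (`--scale 1.0`).  The test suite runs desk-scale versions chosen once:
1000 patterns × 21 disparities for tuning curves; 3×3 sweep subgrids at
1000 patterns/trials per cell with 2 s dynamic trials; 1000 trials per
psychometric point (400 for the linear-model control) with calibrations on
400 cached trials; normalization constants from 100 trials per group.
Every qualitative assertion carries an explicit Monte-Carlo error budget
(3–4 SEs, or the full-span 3-pooled-SE comparisons on sweep grids).

## Known limitations

* Reversed depth to anticorrelated stimuli is stronger in the model than in
  human observers, and its magnitude is sensitive to the tuning-curve
  shapes; a higher output exponent would reduce it.
* The model is local: it cannot express surround-dependent effects
  (abolition of depth with an anticorrelated surround) or mixed-polarity
  benefits.
* The four-disparity population misassigns intermediate disparities via
  tuning side lobes (see above); psychometric claims are made at the
  population's preferred disparities.
* The `lowpass` kernel is a gamma-envelope stand-in with the biphasic
  kernel's time constants, not a fit to any published sustained-channel
  kernel; exact equivalence with previously proposed low-pass kernels is
  not claimed.
* Quadrature phase invariance is only approximate at the default bandwidth
  (the cos/sin Gabor spectra differ by exp(−(2 pi f sigma)²) ≈ 2%).
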