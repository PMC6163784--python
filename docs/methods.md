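# Methods

This note documents the models, parameter choices and numerical conventions
behind `stainquant`, and what the synthetic-data generator does and does not
emulate.

## Imaging model and illumination correction

All images are arrays in [0, 1]; integer files are rescaled by their dtype
maximum on load. Flat-field correction uses the standard two-reference
scheme: a brightfield image of an empty slide (the illumination profile) and
a darkfield image with the light path closed (the sensor offset),

    corrected = (original − darkfield) / (brightfield − darkfield),

applied per channel. The denominator is floored at 1e−6 and the output is
clipped to [0, 1]; clipping is not part of the idealised model but keeps
downstream log transforms defined when calibration is imperfect. Correction
is applied per channel (not on luminance) because color deconvolution needs
corrected colors. Luminance is the Rec. 601 weighting
0.299 R + 0.587 G + 0.114 B. Downscaling is anti-aliased bilinear
(area-averaging behaviour); binary masks are resampled nearest-neighbour so
they stay strictly binary; resized heights are rounded to the nearest
integer.

## Color deconvolution

A pixel of a transmitted-light image of absorbing dyes follows Beer–Lambert:
OD = −log10(I) per channel, and co-localised dyes add, OD = Σ_s c_s v_s with
unit absorption vectors v_s. Unmixing is the per-pixel 3×3 solve
c = OD · M⁻¹, where the rows of M are the stain vectors. Conventions fixed
here: base-10 logarithm, intensity floored at 1e−6 before the log; stain
vectors parametrised in physics polar convention (inclination from the blue
axis, azimuth from the red axis in the red–green plane), restricted to the
nonnegative octant because stains absorb. Two-dye kernels are completed with
the normalised cross product of the two vectors; that residual channel is
reported for diagnostics but never enters assay ratios. Negative unmixed
concentrations are clipped to zero in the returned maps; raw values are kept
for kernel quality control.

Preset kernels ship for the two two-dye stains (Oil Red O / hematoxylin and
Alcian blue / nuclear fast red), built from published histology unmixing
directions where available; they are starting points for estimation, not
ground truth.

## Kernel estimation

Interactive kernel tuning is replaced by a deterministic optimiser. A seeded
3×3 collage of nine images is transformed to OD, lightly Gaussian-smoothed
**in OD space** (σ = 1 px; an OD average of dye mixtures is itself a
nonnegative mixture, so this suppresses noise without biasing the vectors —
smoothing in intensity space does bias them, because the log of an intensity
mixture is not the mixture of the logs), and restricted to pixels with
‖OD‖ > 0.15 (background pixels carry only noise). Coordinate descent over
the per-stain polar angles, with step halving 2.0° → 0.25°, minimises

    50 · mean(negative raw concentrations²)        [all three channels]
  + 0.02 · mean(total clipped stain concentration)
  + 1.0 · mean(residual-channel concentration²)    [two-dye kernels]

The three terms pin the three failure directions: rotating a stain vector
*toward* its partner over-subtracts and drives concentrations negative;
rotating *away* inflates the total concentration needed to explain the same
absorbance (the true vectors give the sparsest nonnegative explanation); and
out-of-plane rotations leak dye signal into the residual channel. A
correlation-based cross-talk penalty was considered and rejected: when dyes
genuinely co-localise, the true kernel's concentration maps are positively
correlated, and minimising that correlation pulls the estimate far from the
truth. On synthetic collages the optimiser recovers the generating angles
exactly (0.0°, at the 0.25° search resolution) without noise and within
≈1° at 20 dB SNR. SNR here is defined on the informative part of the
signal, 10·log10(Var(image)/Var(noise)): the DC level of a brightfield image
is background, not signal.

## Segmentation

Three binarisation rules, matched to three image classes:

* **Local-adaptive cell mask** (adipogenic cultures): the negated luminance
  is downscaled to a 512-px working width, and a pixel is foreground when
  its value exceeds 1.1·μ − 0.3·σ of its square local window (side 30 px for
  10× images, 60 px for 20×, at the working resolution). The window is
  centred (one extra pixel toward lower indices for even sides), borders are
  reflective, σ is the population standard deviation. The mask is upscaled
  nearest-neighbour to the original grid. Note an inherent property of this
  rule: it captures objects *smaller* than the window together with a halo
  of roughly one window reach around them (local σ is inflated wherever the
  window touches a cell), and it hollows out flat objects much larger than
  the window (threshold 1.1·μ exceeds a flat interior). Both are acceptable
  for restricting analysis to generous cell regions, which is the mask's
  purpose; it is not an instance segmenter.
* **Pellet mask** (chondrogenic micromasses): luminance downscaled to a
  third of the original width, negated, thresholded with Otsu's
  between-class-variance criterion (256 uniform bins on [0, 1]; exact
  per-bin value sums rather than bin centres; ties resolved toward the
  lowest threshold; foreground is value ≥ threshold), closed with a disk of
  radius 4 at the working scale, and reduced to the largest 8-connected
  component (size ties broken by scan order), which removes air bubbles and
  debris. The closing radius is interpreted at the downscaled resolution and
  is configurable.
* **Confluency mask** (phase contrast): foreground is every pixel strictly
  above mean(image) + 0.07, with no resizing; the fixed offset is an
  empirically consistent threshold for standardised acquisitions.

## Assay metrics

Adipogenic: cell-area fraction plus the Oil Red O : hematoxylin ratio of
summed concentration mass within the cell mask. Chondrogenic: pellet-area
fraction (and pixel area) plus the Alcian blue : nuclear fast red mass
ratio within the pellet. Mass sums, not means of per-pixel ratios, are used
— per-pixel ratios explode at near-zero denominators. A concentration
percentage, stain-A mass over total two-stain mass, is exported alongside
each ratio. Osteogenic: 1 − mean corrected luminance (the silver deposit
darkens mineralised regions; no deconvolution, as the stain is a single
dye). Confluency: percent of the image in the confluency mask. Undefined
quantities (empty masks, zero denominators) propagate as NaN, never as 0.

Dead cells are counted in the red fluorescence channel: Otsu binarisation,
8-connected components, discard components under 10 px (`min_area`,
configurable). Two guards make the count meaningful: if the Otsu threshold
is at or below 0.2 the frame is spot-free background (thresholding pure
noise at its median would otherwise percolate into large phantom
components) and the count is 0; if the bright foreground exceeds 50% of the
frame the image is saturated and rejected as unanalyzable. Viable (green)
cells are not counted — their morphology is too variable for this detector.
The manual histology score sums three categories — seeded-surface
distribution (0–4), fibre integration (0–3), opposite-surface distribution
(0–3) — to a 0–10 total.

## Statistics

Donors are the blocking factor of a randomized-block design (n = 7).
Condition effects are tested with the Friedman rank test (mid-ranks for
ties; tie-corrected chi-square statistic with df = k − 1; fully tied blocks
yield statistic 0 and p = 1) and paired Wilcoxon signed-rank post-hoc tests
(zero differences dropped, Wilcoxon's original treatment; Pratt available;
exact sign-flip distribution whenever the retained sample is small and
tie-free), two-sided at α = 0.05. No multiple-testing correction is applied
by default, matching common practice for these designs; a Holm step-down
switch exists in the comparison driver. An exact permutation Friedman
p-value (dynamic programming over within-block column-sum distributions) is
available for small cohorts; the chi-square approximation remains the
default because at n = 7, k = 3 its realised level (≈5.1%) is close to
nominal, whereas the exact test at α = 0.05 is conservative (largest
attainable level ≈2.7%). Extreme outliers (beyond 3×IQR from the quartiles)
are excluded from boxplot display only; statistics always use the full
data.

Expression ratios are efficiency-corrected:
ratio = E_t^(Ct_control,t − Ct_sample,t) / E_ref^(Ct_control,ref − Ct_sample,ref),
with efficiencies validated to [1, 2.2] and defaulting to 2.0 (perfect
doubling) when unmeasured. Fold changes divide each ratio by the matched
within-donor control, so control fold changes are exactly 1 and the
normalisation is idempotent. Generation time is
elapsed · ln 2 / (ln n_end − ln n_start), undefined (NaN with a warning)
without growth.

## Synthetic data: what it emulates, and what it does not

The generator renders every input class through the exact forward models the
pipeline inverts: Beer–Lambert composition of disk-shaped stained objects, a
radial quadratic vignette 1 − k·r² (r normalised to the far corner),
optional clipped Gaussian intensity noise; Gaussian-spot LIVE/DEAD fields
with a minimum pairwise separation enforced by capped rejection sampling
(default 5× the spot σ — at ≈4σ the flanks of two spots sum to near the
detection threshold and noise can bridge them, so closer spots are not
resolvable by global thresholding); and cohort tables from a multiplicative
random-effects model, value = baseline · donor · condition · day ·
lognormal noise with log-σ = √ln(1 + CV²), defaulting to 7 donors, the full
nine-condition monolayer design, days 1 and 3, 25% donor log-scale spread
and 20% residual CV. Effects are multiplicative because all assay metrics
are nonnegative.

Passing tests on these renders shows the *inverse* computations are correct
and calibrated; it does not certify performance on real histology, which
additionally contains texture, chromatic aberration, uneven staining,
touching cells and scaffold autofluorescence that the generator deliberately
omits (no photorealistic synthesis, no scaffold fibre texture).

## Problem sizes and verification quantities

`scripts/acceptance.py` recomputes, from scratch at run time: flat-field
recovery RMSE on a 512×512 vignetted scene; deconvolution round-trip RMSE on
128×128 random mixtures; kernel angle recovery (noise-free and 20 dB) on
192×192 collages; oracle agreement of the adaptive mask (100 random 64×64
images against an explicit sliding-window loop) and of Otsu (100 random
images against exhaustive threshold search); the pellet pipeline on a
900×1200 disk with bubbles and holes; the closed-form score/confluency/dye-
ratio values; dead-count recovery for 0/25/40 spots over 20 seeds with 40
speck artifacts each; exact-test oracle deviations and realised type-I
error over 10,000 simulated null cohorts; and detection power for a 2×
effect at 20% CV over 500 replicate cohorts. These sizes keep the full run
around one to two minutes on a single core while leaving every Monte-Carlo
estimate with a standard error well below its acceptance margin.

## Known limitations

* At most three simultaneous stains; no batch stain normalisation.
* The adaptive cell mask is a region restrictor, not a cell segmenter (no
  watershed or learned instance segmentation).
* Kernel presets cannot be validated against the original instrument's
  kernels, which were never published; they are exercised on synthetic data.
* The dead-cell detector's `min_area`/threshold-floor defaults are declared
  choices, configurable per dataset.
* Pellet areas are exported in pixels and as image fractions; no physical
  scale (mm²) is attached because scale bars are not modelled.
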