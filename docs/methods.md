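# Methods

## Problem setting

Mature, high-coverage biofilms imaged with transmitted-light stereomicroscopy
after crystal-violet staining appear as a dark biomass layer on a lighter
substrate. Their morphology is too complex and their contrast too low for the
standard segmentation-first analyses used on sparse bacterial images, which
motivates three complementary pathways: local (not global) thresholding for
coverage, Voronoi regularity of the segmented objects, and — crucially,
because it needs no binarization — structure-tensor orientation analysis of
the raw intensity field, summarized per region of interest (ROI) and compared
across samples statistically.

## Models and procedures

### Niblack local thresholding

The per-pixel threshold is `thr = m + k·S`, with `m` and `S` the mean and
*population* standard deviation of the `(2r+1)²` window centred on the pixel
(computed with uniform-filter moving sums; reflective/symmetric padding).
`radius` is the window half-width. `k` is dimensionless and small-negative
for dark foreground; `-0.1` and `-0.2` are the conventional choices, `-0.2`
the package default. Pixels strictly below (dark foreground) or above
(bright foreground) their threshold are foreground; equality is background.
The best radius is image-dependent — small enough to retain local detail,
large enough that window statistics mix both intensity classes — so the
radius is a required per-image parameter, with `radius_sweep` reporting
coverage stability over a grid rather than silently picking. On the
package's synthetic images (512², sharp class separation, low noise) the
documented setting is radius 128 with `k = -0.1`. A global-Otsu baseline is
provided for contrast only.

### Shape statistics

Connected components (8-connectivity default; border-touching objects kept
but flagged) carry area, perimeter, circularity and aspect ratio.
Circularity is the dimensionless `4πA/P²`, clamped at 1; the perimeter is
the weighted boundary-step estimator (anti-bias weights for diagonal steps,
scikit-image's `perimeter`), which keeps a rasterized r = 20 px disk in
[0.92, 1.0] and a 64-px square near `π/4`. That estimator retains a small
radius-dependent bias on disks (Circ drifts from ~0.98 at r = 10 toward
~0.91 at r = 80 rather than converging to 1); the Crofton alternative
converges better on disks but misestimates axis-aligned rectangles, and the
boundary-step choice is the one whose biases stay inside all documented
bands. Aspect ratio is the major/minor axis ratio of the
moment-equivalent ellipse (1 for a single pixel; +inf flag for collinear
pixel sets). Histograms use the Sturges rule `k = ceil(1 + 3.322·log10 n)`.
The "approximately round" fractions count objects with `|Circ − 1| ≤ tol`
(default tol 0.1, exposed because the informal "~1" class has no canonical
width).

### Voronoi regularity

Object centroids seed a Euclidean Voronoi tessellation clipped exactly to
the image window by the mirror construction (generators reflected across all
four window edges). The regularity index pools, over included cells, the
distances from each cell's polygon centroid to its vertices and returns
mean/SD. Pooled distances (rather than per-cell means) are the default
because heterogeneous patterns then land in the sub-unity regime expected
for irregular biofilm distributions; the per-cell-mean variant and
seed-centred distances are options. Cells touching the window boundary are
excluded by default since clipping distorts their geometry. A perfect
lattice has zero distance spread and returns an +inf sentinel with a
regular-pattern flag.

### Structure tensor, orientation and coherency

Gradients come from central finite differences, derivative-of-Gaussian
(σ_d = 1 px), or the first-order Riesz transform (frequency multipliers
`−i·ω_k/‖ω‖`, DC forced to zero) — the default, being rotation- and
scale-invariant and free of high-frequency amplification. The tensor is the
Gaussian-windowed (σ = 8 px default, exposed) smoothing of the gradient
product images; orientation `θ = ½·atan2(2J_xy, J_yy − J_xx)` in degrees on
[0, 180) and coherency `C` equal to the normalized eigenvalue contrast.
Angle convention: x = columns, y = rows increasing downward; θ is the
structure (isoline) direction counter-clockwise from +x, so horizontal
stripes have θ = 0. Pixels with tensor trace below 1e−12 of the field
maximum get C = 0 and undefined θ (NaN) rather than an arbitrary angle.
Note that the Riesz transform treats the image as periodic: on a
non-periodic grating it picks up mild edge ringing, which is why coherency
comparisons across textures are best made with the local Gaussian operator
or on the interior of the field.

### ROI summaries and angle series

ROIs tile the image deterministically: the grid factorization of the
smallest rows×cols ≥ n whose aspect matches the image, origins evenly
spaced (exact partition when sizes divide; uniform gaps otherwise).
Default 250×250 px, 20 ROIs. Per ROI the tensor entries are summed —
implicit energy weighting, so textureless pixels do not dilute the
estimate — and eigen-decomposed into a dominant angle and an orientation
ellipse (axes ∝ √eigenvalues); elongation ≤ 1.3 flags near-isotropy. Each
ROI also reports up to K modal angles of its coherency·energy-weighted
angle histogram (2° bins, 3-bin circular smoothing, peaks above 1.5× the
uniform level, ties by mass then smaller angle), so an ROI straddling two
subdomains contributes both directions. The angle series records the top 3
peaks per ROI (padded with the dominant angle), giving N = 60 from 20 ROIs;
3 per ROI is the reading consistent with both of those conventional counts,
and it is configurable.

### Cross-sample statistics

Box/violin summaries use linear-interpolation quartiles, 1.5·IQR outlier
fences and a Silverman-bandwidth Gaussian KDE. Pearson and Spearman run on
the paired series. The χ² statistic compares the sorted (quantile-matched)
series with the second as expectation, df = N − 1, two-sided p — one
reasonable construction for "χ² between two angle lists"; a shared-Sturges-
bin histogram variant is available. PCA standardizes every column to mean 0,
SD 1 (correlation-matrix PCA) so each angle variable contributes equally;
components carry a largest-loading-positive sign convention. The separation
report sorts each replicate's angles (aligning them as empirical quantiles),
projects onto the first two components and reports centroid distances, mean
within-sample spread and a silhouette score — descriptive only. Angles are
treated as linear values on [0, 180) by default to mirror common practice;
this is statistically questionable for orientations (0° ≡ 180°), so a
circular option (doubled-angle statistics) exists and is the better
practice. No multiple-testing correction is applied, deliberately.

## Synthetic data: what it emulates and what it does not

`synthgen` generates grayscale biofilm-like images with exact ground truth.
Oriented textures are band-pass-filtered white noise (radial Gaussian band
around 1/wavelength, width half the centre frequency) with a von-Mises
angular spectrum weight whose concentration maps from `anisotropy`
(κ = 10a²/(1−a); a = 1 is an exact sinusoidal grating), normalized to zero
mean and unit variance. The biofilm image thresholds a level field — the
per-subdomain oriented texture plus a smooth colony-scale component
(Gaussian-filtered noise, 24 px correlation length) and dark colony wells —
at the coverage-target quantile, which fixes realized coverage exactly and
independently of texture parameters. Intensity follows a sharp tanh ramp
between the class levels (40/200 by default, dark foreground), with a small
aligned in-class modulation whose amplitude (≤ 6 intensity units) vanishes
at the class midpoint so the noiseless image crosses the midpoint exactly
on the ground-truth mask; Gaussian noise (SD 2.5) comes last. Making the
*structural field itself* oriented — rather than overlaying texture on
isotropic blobs — is deliberate: in stained biofilms the oriented features
are the biomass ridges, and it lets the same image validate both coverage
recovery (bimodal local statistics) and orientation recovery (structures
carry the subdomain angle). Every generator is a pure function of its
spec and seed.

What the synthetic images do not have: three-dimensionality and focus
gradients, uneven illumination/halos, color, cell-scale structure, and the
heavy-tailed texture spectra of real micrographs. Passing tests therefore
demonstrate the correctness of the measurement chain on known ground truth,
not segmentation robustness on arbitrary real images — on real data the
radius sweep and the QC renders remain essential.

Point patterns for regularity validation: square lattice (equal
nearest-neighbour spacing), jittered lattice (i.i.d. Gaussian displacement,
clipped to the window), and binomial/Poisson uniform points.

## Numerical choices

* Window statistics via `uniform_filter` moving sums in float64; agreement
  with the brute-force window oracle is ~1e−13 on 64² frames.
* Reflective (symmetric) padding everywhere a window crosses the border.
* VRI uses population SD; the regular-pattern sentinel triggers when the
  distance SD is below 1e−12 of the mean.
* PCA eigen-decomposes the correlation matrix with `eigh`; ratios are
  eigenvalue fractions (observation-count normalization cancels).
* Channel selection scores channels by intensity SD; ties go to the lower
  channel index (R < G < B).
* Degenerate inputs are flagged, not thrown, wherever a sentinel is
  meaningful (undefined θ, infinite AR, infinite VRI, NaN correlations).

## Problem sizes

Tests and the acceptance script use 256²–512² synthetic frames (one 1024×1280
determinism check), 20-replicate Monte-Carlo for the VRI ordering, and
4 strains × 3 replicates for the separation study; these sizes keep the whole
validation run to a couple of minutes while leaving every statistic far from
its decision boundary.

## Known limitations

* Per-pixel numeric parity with ImageJ/OrientationJ is not claimed; parity
  is asserted against analytic cases and brute-force oracles instead.
* The boundary-step perimeter bias on large disks (above) caps circularity
  accuracy at the few-percent level.
* Linear-angle statistics inherit the wrap-around artefact at 0°/180°; use
  the circular option when regimes sit near the wrap.
* The χ² pairing of two angle lists is one defensible construction among
  several; its p-values should be read comparatively, not inferentially.
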