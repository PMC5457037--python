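# Methods

## Scope and model

The package quantifies *initial* bacterial colonization — a mono-cell layer of
adhered cells, not mature three-dimensional biofilm — on flat material
coupons from tiled single-channel epifluorescence images. The measurement
model is areal: colonization is the fraction of imaged surface covered by
segmented, size-filtered bright objects. Nothing is counted per cell; touching
cells contribute their joint area. This is appropriate as long as cells form
a sparse monolayer (coverages of roughly 0.1–10%); at confluence the area
fraction saturates and the method loses discrimination.

## Segmentation

**Triangle thresholding.** Each field is binarized independently from its own
intensity histogram, so slow illumination differences between tiles never
couple fields. The algorithm assumes a *unimodal* histogram: one dominant
dark background mode with a sparse bright tail of stained cells. The chord is
drawn from the histogram peak to the farthest occupied level on the bright
side, and the threshold is the level maximizing the perpendicular distance
between histogram and chord.

Numerical conventions (all needed to make the argmax well-defined and
bit-depth independent, and matched by the test oracle):

- The intensity axis is normalized so peak → 0 and tail end → 1; the count
  axis is divided by the peak count. The threshold is therefore invariant
  under uniform scaling of the counts and under bit depth.
- Distance is signed (positive below the chord); ties are broken toward the
  peak, the conservative choice that keeps the threshold near the background.
- Polarity is configurable: `dark` objects are handled by reflecting the
  histogram about the range midpoint.
- A histogram occupying fewer than two levels, or with no occupied level on
  the object side of the peak, is *degenerate*: the field is flagged invalid
  rather than silently assigned zero coverage.

**Labeling and size filter.** Connected components use 8-connectivity by
default — diagonal pixels of a thin rod belong to one cell — with
4-connectivity available. The size window is inclusive at both ends: objects
with 6 ≤ area ≤ 400 px are kept; smaller specks (noise, sub-cellular debris)
and larger blobs (aggregates, dust) are removed. At the default pixel pitch
of 0.486 µm these bounds correspond to 1.4 and 94.48 µm². Border-touching
objects are kept (subject to the window): coverage is an area fraction, and
excluding clipped cells would bias it downward.

**Field validity.** A field is excluded from all aggregation when (a) the
operator listed it in the sidecar, (b) its histogram is degenerate, or
(c) its focus metric — the variance of the Laplacian response divided by the
image variance, a dimensionless, contrast-invariant measure of relative
high-frequency content — falls below a threshold (default 0.1; in-focus
noisy fields score well above 1, Gaussian defocus of a few pixels well
below 0.01). Invalid fields remain visible in mosaics (struck through) and
fingerprints (blank), never silently dropped.

## Coverage and sampling effort

Per-field coverage is `A/Aref·100` with `A` the kept-mask pixel sum and
`Aref` the full raster; full float precision is kept until report time.
The coupon-level figure is the pooled ratio `ΣA/ΣAref·100` over valid
fields — the area-true definition — which equals the mean of per-field
percentages when all rasters are equal; both are reported.

The cumulative variation coefficient uses the *sample* standard deviation
(n−1 denominator) over the first k valid fields in acquisition order,
`CV_k = sd/mean · 100`, defined where the running mean is positive (an
all-zero series is an explicit error, zero-prefix entries are NaN). The
minimum image number defaults to the *sustained* rule — the smallest k from
which CV_j ≤ target for every j ≥ k — because a noisy curve can dip below
the target transiently; a first-crossing mode is available and documented as
spurious-prone. Since acquisition order is arbitrary, a seeded order-permuted
envelope (5/50/95% quantiles of CV_k) is provided; CV_n is order-invariant.

## Reporting and position independence

The overview mosaic places thumbnails at their acquisition-grid positions
with kept-object outlines overlaid; its raster is a pure function of grid
shape, thumbnail size and gutter. Display stretching (1–99.9 percentile) is
cosmetic only — quantification never sees it. Fingerprints are positional
matrices of per-field coverage; all coupons in one figure share color limits
so shading is comparable. The acquisition grid defaults to 15 rows × 7
columns (105 fields) along the coupon's long axis and is sidecar-configurable.

Whether colonization depends on coupon position along the flow axis is tested
by a permutation test: Spearman rank correlation between tray slot and pooled
coupon coverage, null distribution from permuting slot labels, two-sided
add-one p-value. This replaces visual inspection of fingerprints with an
assertable statistic; it is calibrated (near-uniform p under a uniform
chamber) and powered against monotone gradients.

## Group statistics

Each group of per-coupon pooled coverages passes a four-test normality
battery: Shapiro–Wilk and the classical Kolmogorov–Smirnov (with sample-
estimated mean/sd against the standard KS null — the textbook variant, known
to be conservative) via scipy; Lilliefors — the same D statistic with a null
calibrated for estimated parameters — via the statsmodels table or an
in-repo seeded Monte-Carlo null; and Anderson–Darling with the Stephens
small-sample correction `A*² = A²(1 + 0.75/n + 2.25/n²)` and the standard
piecewise-exponential p approximation for the composite-normal case. The
joint verdict is "normal" iff no test rejects at α. Because the verdict is a
union of four correlated 5%-level tests, its false-alarm rate on truly normal
data is above 5% (≈10% measured at n=100); this is inherent to a battery and
documented rather than hidden. The gate informs interpretation — flagged
groups still enter the comparisons.

Trials are compared with one-way fixed-effects ANOVA plus Tukey HSD
(pairwise adjusted p and confidence intervals), also reporting the maximum
pairwise mean difference as the practically relevant effect size when nothing
is significant. Materials are compared with a two-sample t-test — Welch by
default, since equal variances are not guaranteed across materials; the
pooled form is available — reporting the mean difference with CI and the
ratio of means. The default significance level is 5%; decisions are also
printed at 0.1%, the stricter level relevant for material-discrimination
claims. Degenerate inputs are explicit: zero-variance samples error in the
battery; two constant equal samples yield p = 1.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
the optics: rod-shaped cells as randomly oriented capsules (length 1.5–4.0 µm,
width 0.7–1.0 µm), bright (default mean 9000 counts, 16-bit) on a dark
unimodal background (Gaussian, mean 900, sd 60), with Poisson-like extra
variance on object pixels. Cells are placed by rejection sampling with a 1-px
exclusion margin, so ground truth is a clean monolayer and no two cells merge
under 8-connected labeling; placement stops at the requested coverage, which
realized coverage overshoots by at most one cell footprint. Optional
ingredients stress specific stages: a linear illumination gradient (per-field
thresholding), speck artefacts of 1–5 px and debris blobs of ≥401 px
(straddling the size window; discretized blob axes are inflated until the
realized pixel count reaches the request, so a nominal super-size blob can
never slip under the filter), and Gaussian defocus blur (the focus gate).
Per-coupon coverage laws: constant, a linear gradient along grid rows
(wave-like colonization), or lognormal per-field variation (patchiness).

What passing on synthetic data does **not** show: robustness to structured
backgrounds (autofluorescent scratches, mounting-medium halos), to dense or
multi-layer growth, to non-rod morphologies or EPS matrix, or to optical
point-spread effects; real acquisitions should always be spot-checked via the
overview mosaics.

One measured caveat: with Gaussian background noise, a noise pixel above
threshold occasionally 8-touches a 5-px speck, forming a 6-px object the
(correctly inclusive) filter keeps. Over a 200-field study this contributes
at most a few parts in 10⁵ of the kept area; artefact removal is therefore
verified as a bound (< 0.01% of kept area) plus an exact deterministic check
on constructed label maps, not as a strict zero on noisy images.

## Problem sizes and defaults

| parameter | default | why |
|---|---|---|
| field raster | 1280 × 960 px | with 0.486 µm/px reproduces the 0.622 × 0.467 mm field and the 400 px ↔ 94.48 µm² equivalence exactly |
| pixel pitch | 0.486 µm | see above; configurable, never inferred from images |
| size window | 6–400 px, inclusive | spans single cells (≈1.4 µm²) up to small clusters (≈94 µm²) |
| connectivity | 8 | thin diagonal rods stay single objects |
| target CV | 13% | the precision level at which ~105 fields suffice |
| alpha | 0.05 (+0.001 reported) | conventional; strict level for discrimination claims |
| fields per coupon | 105 (15 × 7 grid) | 30.5 mm² imaged area per coupon |

The synthetic coverage-recovery study (tests and acceptance script) runs 20
coupons × 10 fields at 480 × 640 px — the raster is free in that study and
the quarter-size field keeps the full suite around a minute while leaving
several thousand cells per field; the full default raster is exercised by the
unit tests and the demo pipeline.

## Known limitations

- Coverage saturates for confluent growth; no cell counting or biovolume.
- The triangle threshold requires a unimodal histogram; strongly bimodal
  images (huge bright debris) shift the threshold and are only caught by the
  size filter and the overview inspection.
- The trend test addresses monotone gradients along one axis; patchy but
  position-locked patterns need the fingerprint matrices themselves.
- Chamber/trial nesting is not modeled (no mixed effects); trials enter the
  ANOVA as independent groups.
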