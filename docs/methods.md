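# Methods

## The counting pipeline

A scanned dish is an 8-bit RGB raster; stained colonies are dark
purple-blue objects on a light dish. The pipeline normalizes this into a
measurement problem in seven stages.

**Channel selection.** The RGB channels are scored by pixel standard
deviation and the highest wins (ties break R→G→B). The standard
deviation measures colony-vs-background contrast; for a purple-blue
stain on a near-white dish the green channel absorbs most and wins. The
alternative rule "lowest mean channel" would usually agree but can
differ on adversarial images; only the standard-deviation rule is
implemented. The rule assumes colony contrast dominates channel
variance; a scan whose surround is much darker than the dish can defeat
it, which is why the synthetic generator (and good scanning practice)
uses a light backing.

**Polarity.** All later stages assume colonies BRIGHT. If the modal
intensity of the selected channel (the background) is above 127.5 the
channel is inverted. One fixed convention keeps every downstream
contract simple.

**Gaussian blur.** Isotropic, reflective boundaries, default
σ = 1.9·10⁻⁶·x² + 6.3·10⁻⁴·x + 1.3 pixels at x DPI. The blur
suppresses sensor noise and makes colony interiors homogeneous; too
little leaves noise that later becomes false detections or watershed
fragments, too much merges neighbours and inflates sizes.

**Background subtraction.** Rolling-ball with default radius 0.025·x
pixels (round-half-up, ≥ 1). The implementation slides a *paraboloid*
of rotation z(d) = d²/(2·radius) under the intensity surface — a
grayscale opening with a parabolic structuring function, computed
exactly by separable min-plus convolution along rows and columns
(O(pixels·reach)). The paraboloid is the standard large-ball
approximation in particle-analysis background subtractors: its
curvature matches a ball of the given radius at the contact point, but
in intensity units it cannot climb fully into a tall stained object, so
colonies several times wider than the radius keep almost all of their
amplitude while constant, linear and gently curved illumination fields
are removed exactly. A strict hard-ball opening with radius smaller
than a colony's diameter would hollow the colony out (our first
implementation did exactly that); the documented failure mode — objects
much wider than the radius losing amplitude — still exists but sets in
far more gently. The estimate is validated in the tests against a
brute-force 2-D paraboloid opening.

**Thresholding.** Foreground = pixels strictly above the cut. "auto"
uses the IsoData/intermeans histogram split (Otsu available as an
option). In the full pipeline the auto threshold is estimated from the
dish interior only, so the dish-edge step cannot skew it, and it is
floored at median + 8·σ̂ of the background-subtracted interior, where
σ̂ is the 84.1th−50th percentile gap. The floor exists because
histogram-splitting thresholds assume two populations: on a blank dish
they land inside the noise and turn the whole plate into specks. The
percentile-gap scale is used instead of the MAD because background
subtraction leaves a half-clipped residual distribution in which most
pixels are exactly zero. With colonies present (a few percent of the
dish area) the floor tracks the noise and sits far below the colony
amplitude. Batch processing resolves the threshold once, on the first
plate, and reuses the numeric value for every plate.

**Region of interest.** A circle of radius (1−margin)·dish_radius about
the dish centre; default margin 0.05, dish geometry defaulting to the
largest circle fitting the image with CLI overrides. The margin keeps
the dish rim — which thresholds as foreground — out of the count.
Colonies touching the ROI boundary are kept (the margin already
excludes the rim) and listed in the diagnostics.

**Watershed and measurement.** Merged colonies are split by
marker-based watershed on the Euclidean distance transform. The
distance map is smoothed (σ = 1 px) to fuse raster plateaus, markers
are its h-maxima (depth ≥ 1 px), and surviving maxima closer than a
minimum separation — default half the median inscribed radius of the
mask's components, floored at 3 px — are merged into one seed. The two
guards attack the same failure mode from different sides: a ragged blob
boundary creates spurious distance maxima that are either shallow
(killed by depth) or clustered (killed by merging), while the deep,
well-separated maxima of genuinely fused colonies survive. Labels
partition the foreground exactly. Per label: area = pixel count
(mm² via (25.4/DPI)² when the resolution is known), perimeter by the
weighted boundary-crack estimator (straight steps 1, diagonal √2, with
corner correction), circularity 4π·area/perimeter² capped at 1.2 to
absorb digital-perimeter bias on small objects (rasterized disks score
≈ 0.9, not 1). Detections are then filtered to
min_area ≤ area ≤ max_area and circ_min ≤ circularity ≤ circ_max;
defaults min_area = 20·(DPI/600)² px², max_area = ∞, circularity
[0.3, 1.2], all logged per run.

## Size-distribution fitting

Areas are binned into equal-width bins spanning [0, max·1.001]
(Freedman–Diaconis bin count by default, clamped to [5, 100]) and
normalized so Σ density·width = 1. The Weibull density
c·(a/bᵃ)·xᵃ⁻¹·exp(−(x/b)ᵃ) and the Gaussian
A/(√(2π)σ)·exp(−((x−µ)/(√2σ))²) are fitted to the bin densities at bin
centres by Levenberg–Marquardt least squares (`scipy.optimize.least_squares`,
`method="lm"`, tolerances 10⁻¹²), i.e. a curve fit to the histogram,
not maximum likelihood. Positive parameters are optimized in log space
so positivity cannot be violated. Initialization is by method of
moments on the binned data: the Weibull shape from inverting the
coefficient of variation (bisection on a ∈ [0.1, 50]), the scale from
the mean; the Gaussian from the binned mean and SD. The amplitude
(c, A) is a free third parameter initialized at 1 — on a proper density
it converges near 1 and absorbs binning artifacts; `fix_c=1` recovers a
strict two-parameter Weibull fit. Fits that fail to converge within
5000 function evaluations are returned flagged, never dropped; group
comparisons exclude flagged groups from the pairwise mean-difference
table. Derived quantities use the closed forms µ = b·Γ(1+1/a),
V = b²·(Γ(1+2/a) − Γ²(1+1/a)); at a = 1 these give µ = σ = b exactly.
Fitting requires ≥ 5 non-empty bins; residuals are unweighted
(least-squares on bin densities).

## The synthetic plate generator

The generator renders what the pipeline actually sees: a light dish
(RGB ≈ 234) on a slightly darker light scanner bed (205), a dark rim
annulus just inside the dish edge, soft-edged (≈ 1.5 px) purple-blue
colony disks whose per-channel absorption is deepest in green, a
seeded-direction linear illumination tilt, and per-pixel Gaussian
sensor noise, quantized to uint8. Colony radii default to
Weibull(shape 3, scale 10) pixels on a 768×768 plate declared at
300 DPI (dish radius 0.49·min(H, W), colonies placed within 0.86 of
the dish radius, non-touching singles separated by ≥ 3 px). A fraction
of colonies is placed as touching pairs at centre distance
0.8·(r₁+r₂), so paired colonies genuinely merge in the mask and
exercise the watershed. Identical spec + seed is bit-identical by
construction.

The four quality presets operationalize the qualitative plate
categories seen in practice (contrast gap in gray levels, fraction of
colonies in touching pairs, noise SD, illumination tilt):

| preset | contrast | overlap | noise | gradient |
|--------|----------|---------|-------|----------|
| #1     | 120      | 0       | 3     | 8        |
| #2     | 120      | 0.30    | 3     | 8        |
| #3     | 35       | 0.36    | 4     | 15       |
| #4     | 25       | 0.50    | 4     | 25       |

The values were chosen once so that detection difficulty increases
monotonically #1→#4 — each step adds or worsens exactly the features
(overlap, then contrast/noise, then both plus tilt) that degrade
counting — and they are all overridable on the spec.

What the generator does *not* emulate: scanner point-spread functions,
colony-interior texture (the central fall-off of over-incubated
colonies), stain intensity variation between colonies, condensation,
writing on the dish, and 6-well-plate geometry. Passing tests on
synthetic plates therefore demonstrate the pipeline's geometric and
photometric correctness under controlled degradation, not performance
on any particular real scanner or cell line; on real data the
resolution-dependent defaults are starting points and the threshold
should be checked visually on one plate per batch, then frozen.

## Problem sizes and numerical choices

Test and acceptance runs use 768×768 plates with 50 colonies, 8–10
seeded plates per category for counting accuracy, 50 random
configurations for watershed geometry, and 20 replicates of n = 2000
samples for fit recovery — sizes at which every quantity of interest is
stable from seed to seed. Ties in channel selection break R→G→B;
round-half-up for the rolling radius; watershed leftover pixels (never
observed in practice) are appended as fresh labels rather than dropped;
degenerate perimeters (isolated pixels) fall back to 4·√area so
circularity stays defined; Weibull moments for extreme shapes where Γ
overflows report infinite variance rather than NaN.

## Known limitations

* Global thresholding: strong uncorrected vignetting or per-plate
  staining differences violate the one-threshold-per-batch assumption.
* Counting by connected regions: colony identity for deeply fused
  clusters (> 2 members) is ambiguous and undercounted by design.
* Areas, not cell numbers: the classical "≥ 50 cells" colony definition
  is not computable from area without a per-cell-line calibration, so
  the minimum-area filter is a geometric stand-in.
* The circularity cap (1.2) and perimeter estimator are conventions;
  circularity values are comparable within this package, not across
  tools using different estimators.
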