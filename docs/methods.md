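# Methods

## Segmentation model

The segmentation assumes rosette morphology: leaf blades wide relative to
the structuring element, petioles narrow, veins appearing as bright ridges
in the Compton scatter raster. The pipeline is deterministic —
identical rasters and parameters give bit-identical label maps.

**Plant mask.** Each metal raster is binarized at the Otsu threshold
computed on a 256-bin histogram (8-bit rasters as-is; 16-bit rasters are
min–max scaled onto 0–255 first). The threshold minimizes the weighted
intra-class intensity variance; ties are broken by the smallest threshold
so the operation is deterministic, and a constant raster yields an empty
mask with a warning rather than an arbitrary split. The plant-foreground
mask is the union of the four metal masks; the Compton raster takes no
part in foreground detection.

**Blade vs petiole.** Morphological opening (erosion then dilation, one
iteration) with a square all-ones element of side `opening_kernel`
(default 15) removes structures narrower than the element — petioles —
leaving the blade. Out-of-image pixels count as foreground during erosion
and background during dilation, so plants cropped at the scan edge neither
lose blade area nor grow artefacts. The petiole is the plant-minus-blade
residual after discarding 8-connected components smaller than
`min_component_fraction` of the image area (default 0.001 %, rounded up to
a whole pixel count). Plants too small for the opening kernel end up
entirely petiole; this known failure mode is logged, not raised.

**Margin.** The internal gradient of the blade: blade minus its erosion
with a square element of side `margin_erosion_kernel`. A side of `2w+1`
produces a band of width `w` on straight edges; the default 7 gives the
intended 3-px band (~100 µm at typical scan resolution). The band width is
the testable contract; the element size is exposed as a parameter.

**Veins.** A second-derivative ridge detector on the Compton raster: the
response is the sum of the two directional second derivatives, each
computed with separable extended-difference kernels of aperture
`laplacian_kernel` (default 7) — the 1-D second-difference `[1,-2,1]`
convolved with a binomial smoothing row, with binomial smoothing across
the other axis and edge-replicated borders. Kernels are unnormalized, so
response magnitudes scale with aperture; bright ridges give strongly
negative responses. Two thresholds convert the response into masks:
`vein1_threshold` (default −2500) captures the thick primary/secondary
vasculature, and the topology-preserving skeleton of the region strictly
below `vein2_threshold` (default 0) captures thin tertiary vasculature.
Both inequalities are strict, which makes the flat-image case exactly
empty. The union is intersected with blade-minus-margin. The threshold
magnitudes are specific to this kernel dialect and intensity scale: on the
default synthetic fixtures (8-bit Compton with veins ~80 counts above
tissue) they give per-class F1 ≥ 0.8 noiselessly; other detectors or
count scales require re-tuning, which is why both thresholds are plain
parameters and the sensitivity sweep covers them.

**Composition.** Tissue is blade minus margin minus vein. Margin, vein and
tissue therefore partition the blade exactly; petiole is disjoint from the
blade; everything else is background. Classes are encoded 0–4
(background, petiole, margin, vein, tissue) in single-channel 8-bit TIFFs.

## Concentration quotient and traits

CQ of a substructure is the substructure mean intensity divided by the
plant-foreground mean. The denominator uses the *classified* plant — all
non-background pixels of the label map — so the pixel-count-weighted mean
of the four substructure CQs is exactly 1 (a conservation law the tests
check to 1e-10). An empty substructure yields a missing value, never 0:
a silent zero would bias downstream variance components. Colocalization is
the Pearson correlation of two metal rasters over plant-foreground pixels,
computed on raw intensities (the concentration interpretation assumes
uniform sample thickness). Z-scored substructure means normalize each
substructure's mean by the plant mean and standard deviation.

Segmentation quality is evaluated on pixels sampled uniformly without
replacement from each *predicted* class (default 1000 per class), shuffled
so an annotator is blind to the prediction. Precision is the confusion
matrix diagonal over column sums, recall over row sums, F1 their harmonic
mean; missing values propagate where a class is absent. Reported scores
are rounded to two decimals only in reports; internal values keep full
precision.

## Heritability

Each trait is modelled as P = µ + G + ε with accession (near-isogenic
line) as a random intercept. The REML criterion is profiled to a
one-dimensional optimization over the variance ratio λ = Var(G)/Var(ε)
(solved by bounded scalar minimization on log λ, with the λ = 0 boundary
checked explicitly), which makes the fit fast, free of convergence
failures, and exact enough to match the balanced-design ANOVA
method-of-moments estimator to better than 1e-6 relative error — the
equivalence the tests enforce. statsmodels' MixedLM serves as an
independent cross-check in the test suite, not as the implementation.
Negative genotype variance is truncated at zero, so H² ∈ [0, 1].
Unbalanced designs (lost replicates) are handled natively. The report adds
an advisory residual-vs-BLUP-fitted Pearson correlation per trait; it is
printed, not gated — assumption violations are expected for the
random-substructure control and nowhere else.

REML was chosen over ML because it is unbiased for the residual variance
with only three replicates per line; on the balanced default design the
two differ negligibly.

## Synthetic data generator

The generator emulates the target study design: 86 accessions × 3
replicates, one five-raster bundle per plant, 208×208 px per plant (the
scale of a per-plant crop from a batch scan). A plant is six elliptical
blades (semi-axes 26×17 px before scaling) around a centre, each with a
5-px-wide petiole strip, a 3-px midrib, 2-px secondary veins, and a 3-px
margin rim. Petioles are narrower and blades wider than the 15-px opening
kernel, so the geometry is separable by construction. Truth masks satisfy
the segmentation partition invariants exactly.

Intensities are multiplicative: pixel value = per-element base ×
substructure multiplier, the multiplier carrying a log-normal accession
effect (sd `sigma_g` = 0.15) and replicate effect (sd `sigma_e` = 0.075).
An overall plant-scale effect on geometry uses the same 4:1 variance split
(sd 0.05 / 0.025). Because *every* latent effect splits its variance
identically, any locally linear derived trait — CQ, plant size,
colocalization — inherits the same broad-sense heritability,
H² = σ_g²/(σ_g²+σ_e²) = 0.8 by default, which the manifest records as
ground truth. Effects are drawn on the log scale to keep intensities
positive; extreme plant-scale draws (≳3 sd) are clamped to the canvas with
a warning. Gaussian detector noise (sd 5 on metal rasters, 2 on the
smoother high-count Compton raster) is added before clipping to the 8-bit
range; a warning flags substructure means near the dynamic-range limits,
where clipping would bias CQ.

A per-leaf log-intensity deviation (sd `sigma_leaf` = 0.15 per element,
drawn per plant) emulates the leaf-age-driven within-plant heterogeneity of
real rosettes. It is essential to the random-substructure control: every
true substructure spans all leaves, so leaf effects nearly cancel in its
CQ, but five random 30×30 squares sample only a few leaves, so their CQ is
dominated by this plant-specific variation and shows near-zero
heritability — the same mechanism that makes random patches a valid
negative control on real scans. The value was chosen together with the
other defaults so that leaf heterogeneity dominates patch CQs while
leaving substructure CQs essentially untouched; it corresponds to a ~15 %
coefficient of variation between leaves, modest for rosettes.

What the generator does **not** emulate: XRF physics (absorption,
thickness effects), photorealistic leaf shape, overlapping neighbour
plants, or annotator error in ground truth. Passing tests therefore
demonstrate the correctness and statistical calibration of the pipeline on
idealized rosettes, not segmentation accuracy on real scans — on real
data the printed per-class scores should be re-derived with the
blind-annotation protocol in `evaluate`.

## Robustness machinery

Random substructures place 5 squares of 30×30 px with centres drawn
uniformly from plant-foreground pixels (guaranteeing overlap with the
plant) and crop them to the plant mask. Label-noise injection redraws the
class of exactly ⌈f·N_plant⌉ plant pixels uniformly over the four
substructure classes; the redraw may repeat the original class, so the
effective corruption rate is 0.75·f. Background is never touched. The
sensitivity sweep re-segments at each grid value while keeping the
ground-truth pixel coordinates fixed, so parameter effects are not
confounded with sampling; default grids run two steps below to two steps
above each default (opening 7→23 step 4, Laplacian aperture 3→11 step 2,
vein1 threshold −3500→−1500 step 500, vein2 threshold −200→200 step 100),
and the base value is flagged in the output.

At complete label randomization (fraction 1.0) every substructure mask
becomes an exchangeable uniform subsample of the plant, so all CQ traits
converge to a common, near-zero heritability; the "substructure CQs
approach the tissue CQ" regime holds at heavy-but-partial noise, where
most mislabelled pixels truly belong to the dominant tissue class. The
tests check both regimes (values converging to tissue CQ at 80 % noise;
common collapse at 100 %).

## Numerical choices and problem sizes

- Otsu ties → smallest threshold; constant rasters → empty mask.
- All stochastic operations accept explicit seeds or `numpy` Generators
  and record them in outputs; panels, sweeps and noise curves are
  bit-reproducible under a fixed seed.
- Connected components use 8-connectivity throughout (diagonal-touching
  leaves belong to one plant).
- The test suite validates H² recovery on one default-scale panel
  (258 plants) against the panel's realized ground-truth heritability, and
  estimator calibration (mean bias < 0.02) across 20 independent panel
  replicates — about 5,000 segmented plants in total, a size chosen to
  keep Monte-Carlo error on the mean well below the bias bound.

## Known limitations

- Vein thresholds are dialect- and scale-specific; the defaults are
  calibrated for this package's Laplacian on 8-bit Compton rasters.
- CQ is undefined for empty substructures and for zero plant mean; such
  plants contribute missing values that REML fitting drops (logged).
- The 3-px margin contract holds on straight edges; on strongly curved
  rims the band is locally wider.
- The generator's H² calibration is exact only to first order
  (multiplicative effects enter CQ through a ratio); at the default effect
  sizes the nonlinearity contributes bias well below the Monte-Carlo
  noise, which the 20-replicate calibration test bounds.
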