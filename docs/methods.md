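# Methods

## The NOTCH3 score

CADASIL is caused by NOTCH3 mutations that make the receptor's
extracellular domain aggregate in the walls of small arteries. In
brightfield immunohistochemistry with a DAB chromogen, these aggregates
appear as dark granular deposits on a lighter vessel wall. The NOTCH3
score quantifies this accumulation load from a micrograph:

1. convert the image to 8-bit grayscale (unweighted channel mean by
   default; weights configurable),
2. apply an unsharp mask, `out = (I − w·G_σ(I)) / (1 − w)` with σ = 1
   px and w = 0.60,
3. threshold at intensity 150, dark pixels positive,
4. group positive pixels into particles (8-connectivity),
5. keep particles with area 0–30 px² and circularity 0.50–1.00
   (both windows inclusive),
6. report the total retained area in px² as the per-image score.

Per mouse, the score is the mean over its fields (10 in the reference
design); per strain-age cell, statistics run on the per-mouse values.

The human variant scores NOTCH3 positivity inside a manually drawn
CD31-defined vessel region: positive pixels are those at or below
intensity 100, and the score is reported as the percentage of the
vessel area that is positive (the raw positive area is always reported
too; the percentage makes the score independent of how generously the
ROI was drawn). No unsharp mask and no particle filter are applied by
default in this variant; both can be switched on for sensitivity
analyses.

## Numerical conventions

- **Rounding.** All float→uint8 conversions round half-up
  (`floor(x + 0.5)` after clipping to [0, 255]); 76.5 → 77. This is the
  convention of interactive image tools; numpy's default half-to-even
  would differ on exact .5 values.
- **Unsharp mask.** Gaussian kernel is the sampled, normalized Gaussian
  truncated at 3σ (half-width ≥ 1 px); edges are replicate-padded so
  borders do not acquire dark halos that would cross the threshold.
  Whether the original analysis rounded or truncated after filtering is
  unknowable; we round, and oracle tests carry a ±1 intensity
  tolerance to absorb it.
- **Polarity.** DAB-positive staining is dark on light background, so
  "threshold 150" means member iff intensity ≤ 150. A
  `bright_positive` flag is available since the direction is a
  convention, not a law.
- **Perimeter.** The crack boundary: the exact count of exposed unit
  pixel edges, including edges facing interior holes
  (`4·area − 2·#4-adjacent same-label pairs`). This is exact and
  testable against a brute-force edge count, but it runs longer than
  the weighted boundary approximation of common interactive tools, so
  circularities here are systematically lower for the same blob (a
  1-px particle: 0.785; a digital disc of 13 px: 0.41). The
  circularity window is an explicit parameter for this reason.
- **Determinism.** Component labels follow raster-scan order of each
  component's first pixel; particles touching the border are kept;
  holes are not filled. Outputs are byte-stable for fixed inputs and
  seeds.
- **Degenerate inputs.** Empty vessel masks, groups with n < 2,
  all-identical ages, and empty designs raise typed errors rather than
  returning NaNs silently.
- **16-bit images are rejected**, not rescaled: the fixed thresholds
  150/100 are defined on the 0–255 scale and silent rescaling would
  change their meaning.

## Statistical layer

- "Unpaired Student's t-test" = pooled-variance two-sample t
  (df = n₁ + n₂ − 2), the common default of interactive statistics
  packages; Welch is available as an option. On the reference 20-month
  group summaries (659 ± 51 vs 1150 ± 107, n = 3 per group) the pooled
  test gives t = 7.17, df 4, p = 0.0020.
- Fisher's LSD p-values are unadjusted — that is what LSD is — using
  the ANOVA pooled error term and its df; output flags carry the MSE
  df so multiplicity can be handled downstream.
- Slope comparison fits the common model
  `score ~ age + group + age:group` by OLS and tests the interaction
  coefficient (two-sided t on pooled residual variance), equivalent to
  the classic equal-slopes test.
- Sample size for a fractional treatment effect on progression uses
  the normal-approximation start
  `n = 2(z_{1−α/2} + z_{1−β})²·sd²/Δ²` refined by exact noncentral-t
  power iteration to the smallest qualifying integer. Defaults
  α = 0.05 two-sided and power = 0.80 are conventions (the output says
  so), since the underlying study states neither; every input (effect
  fraction, baseline progression, SD, α, power) is an explicit
  parameter rather than a guess.

## Synthetic fields and cohorts

The generator renders the geometry the score was designed for — a light
background (mean 235), a vessel-wall ring (intensity 210, radii 70–95
px in a 256×256 field), and dark deposits (mean intensity 60, clipped
to ≤ 120) placed uniformly on the wall without overlap (minimum 2-px
gap keeps deposits 8-disconnected) — plus optional additive Gaussian
intensity noise (default SD 8), with exact per-deposit ground truth.

Deposits are discs of integer radius 1 or 2, rasterized as all pixels
whose centers lie within r + 0.5 of the deposit center: areas 9 and 21
px², crack-boundary circularities 0.785 and 0.66. Both shapes pass the
default filter, which is the point: on noise-free fields the pipeline
score equals the true deposit area *exactly*, making truth-vs-score
tests sharp rather than approximate. Radius-3 discs are excluded from
the default range because their 37 px² rasterization exceeds the 30 px²
size cap (and the alternative 29-px rasterization fails the 0.50
circularity floor).

Cohorts follow a piecewise-linear onset model: the expected deposit
count per field is `L(age, e) = rate · e · max(0, age − onset(e))`,
with expression multipliers e ∈ {1.0, 1.5, 2.0, 3.5} and onset ages
{52, 22, 13, 6} weeks respectively — higher expression, earlier onset
and faster accumulation, matching the observed ordering. Actual counts
are Poisson draws; per-field seeds derive from one cohort seed through
a SeedSequence, so cohorts are reproducible end to end. The default
rate of 0.4 deposits·week⁻¹ per unit multiplier keeps the densest cell
(≈ 106 expected deposits at e = 3.5, 82 weeks) well below the wall's
packing capacity while keeping neighbouring cells' expected loads
separated by several standard errors of a 30-field cell mean, so rank
comparisons across the 16 strain-age cells are stable.

The Poisson-count and linear-onset choices are modeling conveniences:
the generator reproduces only the qualitative accumulation structure
(ordering and monotonicity in age and expression), which is all the
progression tests assert. It does **not** emulate real histology —
stain color variation, out-of-focus fields, vessel-shape diversity,
overlapping or irregular deposits, section artifacts — so passing
tests demonstrate correctness of the *measurement chain*, not
segmentation performance on real slides. The printed absolute scores
from real tissue (e.g. 659 and 1150 at 20 months) are consequently not
reproducible here; only the procedures and the published test
statistics on the printed summaries are.

## Verification set-up and problem sizes

- Particle chain: 200 random binary masks up to 64×64 checked
  bit-for-bit against a brute-force flood-fill/edge-count oracle.
- Unsharp mask: random ≤ 32×32 images against an explicitly summed
  dense convolution, within ±1 intensity unit.
- Recovery: 3 noise-free fields (exact equality) and 3 simulated mice
  × 10 fields at noise SD 8 (per-mouse mean within 10% of truth;
  observed ≈ 4% upward bias from noise-flipped pixels forming small
  retained particles).
- Progression: the full 4-strain × 4-age cohort, 3 mice × 10 fields
  per cell, run noise-free so the six pre-onset cells tie at exactly
  zero in both the programmed loads and the measured scores; Spearman
  rank correlation across the 16 cell means is then exactly 1.0 and
  within-age ordering by expression holds.
- Statistics: 10,000-rep vectorized null simulation for the t-test
  type-I error at n = 3 (target band 0.04–0.06); ANOVA-vs-t² identity
  to machine precision; slope-equality null on duplicated data and a
  2× slope alternative at low noise; 20,000-rep Monte-Carlo
  confirmation of the sample-size routine and a cross-check against an
  independent power solver.

## Known limitations

- Circularity values differ from tools using smoothed perimeter
  estimators; calibrate `circ_min` before comparing absolute scores
  across implementations.
- Sizes are uncalibrated px²; no physical pixel size is applied.
- The human variant requires an externally supplied vessel mask; CD31
  segmentation and stain unmixing are out of scope.
- Whether the original per-mouse value was the mean or the sum of the
  10 fields is not determinable; both are implemented (mean default).
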