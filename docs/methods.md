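# Methods

## The measurement model

`isletmorph` treats a stained pancreas section as three aligned 8-bit
channels — insulin, a second marker, DAPI — with a single µm/px calibration
supplied by the cohort manifest (TIFF resolution tags are ignored as
unreliable). All internal lengths are µm and areas µm².

**Channel positivity.** Each channel is binarized either by Otsu's method
or by a fixed threshold (strict `intensity > t`). Objects smaller than
`min_object_px` (default 9 px) are removed and holes smaller than
`min_hole_px` (default 64 px) filled, so perinuclear gaps in the
cytoplasmic hormone stain do not fragment the masks.

**Islet candidates.** The union of the two hormone masks is morphologically
closed with radius `r_close_um` (default 5 µm) and hole-filled; connected
components of the result are the candidates. The closing deliberately
bridges the small gap between an islet's β core and its α mantle while
leaving islets tens of µm apart separate.

**Cell counting.** Nuclei are split by a distance-transform watershed
seeded at local maxima with minimum separation `nucleus_min_sep_um`
(default 4 µm). A nucleus belongs to a β cell when at least
`insulin_overlap_fraction` (default 0.5) of its pixels lie in the insulin
mask. An overlap rule is used instead of centroid-in-insulin because the
hormone stain is cytoplasmic/perinuclear: the centroid of a β-cell nucleus
can fall in a hormone-free core, while the overlap fraction separates β
nuclei (~0.9+) cleanly from adjacent α-mantle nuclei (≤ ~0.3 cross-talk).
The same rule with `marker_overlap_fraction` (default 0.5) decides
marker⁺ β cells for apoptosis/proliferation markers.

**Exclusion filter.** A candidate is an islet iff it holds ≥ 1 insulin⁺
DAPI⁺ cell, its area strictly exceeds 50 µm², it is in focus, and it is not
an ambiguous micro-cluster. Rules are evaluated in a fixed priority so each
exclusion carries exactly one, maximally informative flag:

1. `nonbeta_only` — second-marker signal with no insulin signal at all;
2. `no_insulin_dapi_cell` — insulin signal but no qualifying cell;
3. `subthreshold_area` — area ≤ 50 µm²;
4. `ambiguous_microclusters` — before closing, the candidate decomposes
   into ≥ 2 hormone components, each with at most `microcluster_max_cells`
   (default 3) insulin⁺ DAPI⁺ cells and pairwise boundary gaps below
   `microcluster_max_gap_um` (default 10 µm): impossible to call one islet
   versus a group of tiny ones;
5. `out_of_focus` — focus score below `focus_fraction` (default 0.2) times
   the median score of the section's provisional islets.

The priority matters: a hormone blob without nuclei has a featureless DAPI
channel and would otherwise also be flagged blurred. The focus score is the
variance of the DAPI Laplacian inside the region divided by the squared
mean intensity; squaring the mean makes the score invariant to global
intensity scaling, so dim-but-sharp regions rank with bright ones.

**Brightness rescaling.** Sections with suboptimal signal/noise are
linearly stretched per channel between the 1st and 99.9th percentile. The
automatic trigger requires the bright tail (99.9th percentile) to be below
128 *and* at least 3× the channel median: on a whole section stained tissue
covers a few percent of the frame, so the 99th percentile is background and
would misfire, and a channel whose bright tail sits at background level has
no signal to stretch. Rescaling is monotone per channel and idempotent up
to 8-bit quantization.

## Shape metrics

- **Area** is pixel count × (µm/px)².
- **Feret's diameter** is the diameter of the convex hull of boundary-pixel
  centres — identical to the maximum pairwise boundary distance (verified
  against a brute-force O(n²) oracle in the tests) at hull cost.
- **Circularity** is 4πa/p². The perimeter estimator is the subpixel
  marching-squares contour simplified by Douglas–Peucker (tolerance 1 px):
  raw pixel-edge counting overestimates smooth boundaries (a digital disc
  scores ≈ 0.85), and the 4-direction Crofton estimator — available via
  `perimeter_method="crofton"` — underestimates square perimeters by ~5%,
  biasing their circularity to ≈ 0.88. The contour estimator puts large
  digital discs at 0.98–1.00 and large squares within ~2% of π/4.
  Circularity is not clamped; discretization can push it slightly above 1.

## The synthetic tissue generator

The generator emulates exactly the features the analysis assumes, with
exact ground truth, and nothing more.

**Cells.** Each islet cell is a DAPI nucleus disc (radius 3 µm) plus a
hormone cytoplasm annulus (outer radius 6 µm, inner radius 1 µm — in 8-µm
projected sections the hormone signal overlays most of the nucleus). Cell
centres sit on an 8-µm-pitch layout (≈ 55 µm²/cell): a hexagonal interior
lattice plus a boundary ring placed at equal arc length on the islet
ellipse, jittered by ±0.5 µm so nuclei never touch. The ring construction
makes the rendered outline the Minkowski offset of the ellipse, so by the
Steiner formula the rendered footprint tracks the requested target area
(within 1–4% for mid/large islets) and round islets render at circularity
0.93–0.97. Under the `core_mantle` architecture all α (and δ) cells occupy
the outermost positions and β cells the interior, reproducing the
core–mantle organisation of rodent islets.

**Ground truth.** Truth areas are measured on the rendered masks (pixel
count × pixel size²), never taken from the nominal spec. The truth islet
outline smooths the scalloped disc union with the same 5-µm closing radius
the segmentation applies, and truth hormone areas use hole-filled full cell
footprints — truth and measurement thereby share a single definition of
the tissue boundary, and on clean sections the pipeline reproduces the
truth masks pixel-for-pixel. That exactness is what makes the
50-islet validation harness (paired t test) meaningful: any systematic
pipeline bias, however small, would reject at n = 50.

**Confounders.** One renderer per exclusion kind: an insulin blob with no
nuclei; an α-cells-only cluster; a single ~40 µm² insulin⁺ DAPI⁺ speck; a
normal islet Gaussian-blurred (σ 3 px) before compositing; and ≥ 2
micro-clusters of 1–3 β cells with 4-µm boundary gaps.

**Cohorts.** Per-islet areas are lognormal (default median 1800 µm²,
log-sd 0.5 — islet size distributions are right-skewed; the lognormal shape
is an assumption), multiplied by the group's area effect and clipped to the
renderable range 150–40 000 µm². Islets per section are Poisson (default
mean 30); four sections per mouse; cell counts derive from the lattice
capacity of the drawn area with an α-cell fraction of 0.2. A group's
β-count multiplier scales the β-cell number with the islet growing to hold
the extra cells — β-cell hyperplasia enlarges islets rather than crowding
them. The default marker⁺ β-cell fraction is 0 (the plain hormone-stain
slide series); marker planting is an explicit condition because the marker
and glucagon share the red channel. Sections are 1600 × 1600 µm at 1 µm/px
with background 10 and Gaussian noise σ 4; signal intensities are 200
(hormones) and 230 (DAPI). Identical designs and seeds give bit-identical
files.

`sample_cohort_truth` and `sample_mouse_mean_areas` draw from the same
sampling path without rasterizing, for replicate-scale simulations
(power, type-I calibration) where only summaries matter.

**What is not emulated.** Acinar/ductal background tissue and texture,
uneven illumination, staining gradients, 3-D structure, cell-size
heterogeneity, and segmentation-hostile artefacts beyond the five planted
confounder kinds. Passing the synthetic benchmarks therefore demonstrates
the correctness of the measurement rules, not robustness to every real
staining pathology; real cohorts should still spot-check the per-candidate
exclusion table.

## Cohort metrics

Relative islet (β) area, β-cell mass and islet density follow the standard
4-section conventions given in the README. β-cell mass uses the
pancreas-plus-spleen weight exactly as recorded in the manifest — a
dissection proxy, documented as such. Mice with zero retained islets
produce NaN-flagged summaries; islets without counted β cells are omitted
from the β-cell-size mean. Size-class histograms use left-closed bins of
configurable width with an open-ended last class; the default widths
(5000 / 2500 / 2000 µm² for adult / juvenile / neonate schemes) are
configuration, and display labels are deliberately separate from the
internal µm² unit so published bin labels in other units can be reproduced
without changing the arithmetic.

## Statistics

- **Unequal variance.** Before a t test, an F test (2 groups) or
  median-centred Levene test (> 2) at α = 0.05 decides whether to apply the
  natural log to *all* groups; non-positive values block the transform with
  a warning. The transform is recorded in the result.
- **Two-way ANOVA** uses type-II sums of squares (appropriate for factorial
  designs whose imbalance is not interaction-driven); the post hoc method
  (Bonferroni or Tukey, applied to the factor-cell means) must be named
  explicitly — there is no silent default. A constant response returns
  F = 0, p = 1 for every term: the F ratios are 0/0 and floating-point
  noise would otherwise fabricate signal.
- **Repeated-measures two-way ANOVA** is a mixed design (between = group,
  within = size class, subject = mouse) requiring every subject at every
  within level; post hoc per-level group contrasts are Bonferroni-adjusted
  over level × pair count.
- **Grubbs outlier removal** is two-sided and iterative — remove the most
  extreme point while its studentized deviation exceeds the critical value
  G(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) t-quantile on
  n−2 df — capped at ⌊n/5⌋ removals of the original sample size so the
  iteration cannot eat a small sample. n < 3 or zero spread returns the
  data unchanged.
- Significance categories: p < 0.05 significant, 0.05 ≤ p < 0.1 trend.

Ordinary fits are delegated to scipy, statsmodels (OLS ANOVA, Tukey HSD)
and pingouin (mixed ANOVA); the variance-check policy, Grubbs procedure and
all conventions above are this package's own. The tests hold every routine
to hand-written textbook-formula oracles (≤ 1e-8) and to seeded null
simulations (type-I error 0.05 ± 0.01 at ≥ 2000 replicates).

## Validation harness

Mirroring program-vs-manual accuracy checks, `sample_validation_islets`
draws a seeded, tercile-stratified sample (default n = 50, ≥ 10 per
tercile, so all sizes are represented) and `compare_to_reference` compares
pipeline and reference measurements per metric: a metric passes when the
paired two-tailed t test gives p ≥ 0.05 *and* the mean relative deviation
is ≤ 5%. These two thresholds quantify "the two strategies showed similar
results"; both are configurable. The reference may be generator truth or
manual tracings supplied as CSV.

## Problem sizes

The test suite and `scripts/acceptance.py` exercise: analytic fixtures
(discs r ≥ 30 px, an 80-px square, 20 random blobs against the O(n²) Feret
oracle); one section with 3 islets plus all 5 confounder kinds; a rendered
cohort of 2 groups × 5 mice × 4 sections at ~30 islets/section (~1200
islets, ~2000+ β cells/mouse) for ground-truth recovery and the 50-islet
validation; 100 replicate cohorts (summary mode) for power at a 1.5× area
effect and 1000 for null calibration; and ≥ 2000-replicate null simulations
for the t test and ANOVA. These sizes were chosen to give the property
checks the precision they claim (binomial/SE arithmetic in the tests) while
remaining single-CPU friendly.

## Known limitations

- Per-cell typing inside islets is binary (β vs non-β); α and δ cells are
  quantified by area only, and a single second-marker channel cannot carry
  glucagon and a nuclear marker simultaneously without biasing the α-area
  readout.
- The micro-cluster rule is a parametric approximation of what was, in
  manual practice, investigator judgment; its parameters are exposed rather
  than claimed universal.
- The focus criterion is relative to the section's own provisional islets
  and needs a handful of in-focus islets per section to anchor the median.
- Whole-slide pyramidal formats, stitching and illumination correction are
  out of scope; inputs are flat 8-bit RGB TIFF/PNG.
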