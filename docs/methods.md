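# Methods

This note documents the models implemented in `vinevigor`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
study can and cannot show about real field data.

## Study design being emulated

A biparental grapevine F1 progeny (two heterozygous parents, so each locus
segregates four parental-haplotype classes ac/ad/bc/bd) of 209 genotypes is
laid out in a randomized complete 2-block design, one 3-plant elementary
plot per genotype per block, together with 6 replicated control plots of a
reference variety per block. Vines are trained on a vertical shoot
positioning system with 1.7 m between rows and 1.4 m between plants. Traits:
apparent canopy volume at véraison (L·plant⁻¹, summer LiDAR), apparent
pruning-wood volume (L·plant⁻¹, winter LiDAR before/after pruning), exposed
leaf area (m²·plant⁻¹, row images), plus scalar traits such as pruning fresh
weight and leaf chlorophyll that enter the statistics as plain columns.

## Point clouds and apparent volumes

Scenes are voxelized on a half-open regular grid anchored at the plot
origin: point *p* falls in cell ⌊(*p* − origin)/*s*⌋ per axis, so every
point maps to exactly one cell. A cell is "vine" when it holds at least
`min_hits` returns (default 1; the single-hit rule is a known source of
overestimation, which is why the outputs are called *apparent* volumes).
Voxel edges: 10 mm for canopy scenes, 5 mm for wood scenes. Volume is
|occupied| · *s*³ in litres.

Scene cleaning removes points within `soil_margin` (default 0.05 m) of the
registered ground plane, points beyond `y_halfwidth` (default 0.85 m,
half the row spacing) across-row, optional wire z-bands, and the overlap
between the two stacked scanners by giving each scanner an exclusive
vertical band split at the midpoint of the scanner heights (defaults 0.8
and 1.5 m). The plot's along-row extent is divided into equal half-open
zones, one per plant; each occupied voxel is attributed by its cell-centre
x, and zone counts always partition the total.

Per plant, the lower and upper scanner grids are pooled per row side, and
the sides combined by voxel-set union in the shared grid (default). The
union is used because a voxel seen from both sides is one piece of canopy;
`sum` and `mean` are provided as configuration options for sensitivity
analyses, since per-plant merging of sides admits several defensible
conventions. Pruning-wood volume is
(N<sub>before</sub> − N<sub>after</sub>) · *s*³ on a common 5-mm grid with a
shared origin; negative differences (registration noise) are floored at
zero with a warning. Because wires and permanent wood occupy the same cells
in both scans, they cancel exactly in the subtraction.

## Images and exposed leaf area

Foliage is segmented in HSV space: hue within 70°–170°, saturation ≥ 0.2,
value ≥ 0.1 (the thresholds of the original manual workflow are not public;
these defaults separate vegetation green from a blue curtain background
with a wide margin and are configurable). FC is the green-pixel fraction of
the analysis window — by default the canopy band between the trellis
wires. ELA = D·FC·S with S = W + 1.25·H; for the default geometry
(D = 1.40, W = 0.3, H = 1.40) S = 2.05 and a full-cover window gives
2.87 m²·plant⁻¹.

## Heritability estimators

Both target broad-sense H² = σ_g²/(σ_g² + σ_e²); sample variances use the
n − 1 denominator throughout.

* **Control-based** (single clean block): σ_t² is the variance of the
  progeny genotype means in the block, σ_e² the variance among the
  replicated control-plot means, and H² = (σ_t² − σ_e²)/σ_t². Estimates are
  clamped to [0, 1] and flagged; the raw value is retained
  (`VarianceDecomposition.H2_raw`) because the clamped estimator is biased
  upward when averaged over replicate simulations — with only 6 control
  plots the raw estimate is noisy (its sampling sd is ≈ 0.63·(1 − H²)), so
  truncation at 0 matters at low heritability.
* **ANOVA** (two complete blocks): plot means enter a two-way additive
  layout; σ_g² = (MS_genotype − MS_error)/r with r blocks, floored at 0,
  σ_e² = MS_error. Balanced layouts use closed-form sums of squares;
  unbalanced tables fall back to a least-squares fit with a warning.

Block-adjusted genotype means subtract block effects referenced to the
first block (so they are exactly invariant to additive offsets applied to
other blocks) and, by default, shrink genotype deviations toward the mean
by σ_g²/(σ_g² + σ_e²/r) — the BLUP factor under the fitted model.
Trait–trait association is reported as squared Pearson correlation over the
genotypes present in both series.

Applying the control-based estimator to the published progeny/control
variance pairs reproduces the published H² values at two decimals for
chlorophyll (0.69, 0.93), canopy volume (0.79, 0.66), wood volume year 1
(0.83) and pruning weight (0.33, 0.89). Two published rows are knowingly
not reproducible from their printed variances: the ELA rows (printed at 1–2
significant figures, so the quotient is rounding-limited) and the
wood-volume year-2 row, where (1.13 − 0.113)/1.13 = 0.90 against a printed
0.79 — the estimator behind that figure is ambiguous. These are documented
exceptions, not assertions.

## QTL machinery

* **Genotype-class probabilities.** Observed classes give indicator rows.
  Missing entries are reconstructed per parent from the nearest informative
  flanking markers via the Haldane map function
  r = ½(1 − e^(−2d/100)); with flanks at distances d_L, d_R the allele
  probability follows from the two-interval recombination events,
  P(x | l, r) ∝ P(l→x)·P(x→r), and the class probability is the outer
  product over the two parents. This exact flanking computation replaces
  multiple-imputation draws: on dense maps with ≤ 10% missingness it is the
  expectation of the imputation distribution, deterministic, and testable
  against brute-force enumeration. Markers with more than 10% missing data
  are rejected (the cap is configurable).
* **Scan.** At each marker the trait is regressed on the four class
  probabilities (3 model d.f.) against the intercept-only model;
  LOD = (n/2)·log₁₀(RSS₀/RSS₁). Scans run at markers only — the simulated
  maps are dense enough (default 0.25 cM spacing) that a pseudomarker grid
  adds nothing. Residuals below 10⁻¹² of RSS₀ are treated as perfect fits
  (LOD = ∞, flagged). Internally each marker's design matrix is QR-factored
  once, making a scan one matrix product per marker; this is what keeps
  1,000-permutation thresholds at sub-second cost for a ~450-marker genome.
* **Permutation threshold.** Genome-wide max-LOD over n_perm phenotype
  shuffles; threshold is the empirical (1 − α) quantile with linear
  (type-7) interpolation. QTLs are declared on strict exceedance.
* **Credible intervals.** Marker weights 10^LOD are normalized per
  chromosome; markers are accumulated in decreasing weight order until the
  target coverage (default 0.95) and the interval spans the accumulated
  set, reported at marker positions in cM and bp (positions are embedded in
  marker names, `<chrom>_<bp>`).
* **Multi-QTL models.** Additive joint regression over all loci; each locus
  is summarised by drop-one (type III) LOD and
  %var = 100·(RSS_reduced − RSS_full)/TSS, the model by overall LOD and
  %var against intercept-only. The stepwise search scans current-model
  residuals, adds the best candidate if its drop-one LOD exceeds the
  threshold, and refines every locus to the best marker on its chromosome
  holding the others fixed. Interactions are not searched: the automatic
  model is purely additive, and epistasis scans are out of scope.

Measured behaviour at the default simulation scale (19 chromosomes ≈ 54 cM,
2.5-cM test spacing, n = 200): genome-wide type-I error 0.05 ± 0.02, two
unlinked QTLs of 12–15% variance each recovered in ≥ 80% of replicates,
0.95-interval coverage ≈ 95–97%, and genome-wide thresholds around
LOD ≈ 4.2–4.3, the magnitude expected for a genome of this size.

## The synthetic generator

The generator's defaults are the study conditions: 209 progeny + 6 control
plots per block, 2 blocks, 3 plants per plot, 19 chromosomes of 53.5 cM
(≈ 1,017 cM genome, 0.5 Mb/cM), default marker spacing 0.25 cM (≈ 4,100
markers, the scale of a duplicate-pruned consensus GBS map). Phenotypes are
plant value = trait mean + Σ QTL class effects + polygenic deviation +
block effect + plant noise. QTL `fraction_variance` is the share of total
plant-level variance (σ_g² + σ_e²) the locus explains; effects are placed
at the marker nearest the requested cM position (keeping marker-regression
scans exact), centered and scaled assuming equal class frequencies; the
polygenic variance absorbs the remainder of σ_g² and the configuration is
rejected if the QTLs claim more than the declared genetic variance. The
control genotype carries no genetic term, so its between-plot variance is
pure environment — making the control estimator's target analytically
known. Canopy-trait defaults (mean 365 L, σ_g² = 1450, σ_e² = 1200 at plant
level) give plot-mean heritabilities in the 0.7–0.8 range typical of the
LiDAR traits; the plot/plant split of environmental noise is a free knob of
the simulator, as the within-genotype decomposition is not identified by
the published summaries.

Physical scenes are deliberately simple generative stand-ins:

* **Summer canopy**: points uniform in a per-plant box (width W, height H,
  along-row length D − 2·trigger_offset = 0.9 m, so the 0.25-m acquisition
  trigger cut never clips a plant's box), point count proportional to the
  target volume (default 80 points/L). Occupancy is then monotone in the
  target, which is the property the pipeline tests rely on; apparent volume
  is *not* equal to the target (it is a sampling-density proxy), exactly as
  real apparent volumes are not true volumes. Occlusion is modelled only as
  a density-thinning factor — no ray casting. Soil points, two wires (at
  0.7 and 1.2 m, offset 0.18 m across-row so they never share cells with
  vine points) and per-point scanner/side labels complete the scene.
* **Winter scenes**: the after-pruning scene holds trunk and cordon points
  plus wires; the before scene adds canes as vertical runs on a 5-mm
  voxel-aligned lattice occupying exactly round(target/s³) cells above the
  cordon band, so the subtraction recovers the planted wood volume
  essentially exactly (the ±10% recovery tests pass with large margin).
  Wood targets beyond the lattice capacity of the canopy box are rejected.
* **Row images**: orthographic projection of canopy points at 5 mm/pixel,
  green on curtain-blue, with optional multiplicative per-pixel brightness
  jitter. The jitter knob exists to reproduce the qualitative finding that
  image-based cover is less repeatable under uncontrolled lighting: FC
  variance across renders is non-decreasing in the noise level, and zero
  noise renders are bit-identical.

What passing tests therefore show: the measurement chain (filtering,
voxelization, zone attribution, side pooling, subtraction, segmentation,
the estimators and the scan machinery) is correct on scenes whose ground
truth is known by construction. What they do not show: robustness to real
LiDAR artefacts (occlusion geometry, beam divergence, registration error,
wind), real canopy architecture, or real linkage-disequilibrium structure —
the published field QTLs and correlations depend on the real progeny and
are not reproducible from simulation.

## Numerical conventions and edge cases

Seeds are explicit everywhere; the pipeline derives per-stage, per-plot
substreams from one root seed, and a rerun with the same configuration is
byte-identical. Voxel grids must share size and origin to be combined
(union rejects mismatches). Zone splitting warns and assigns to the nearest
end zone if a voxel centre falls outside the plot extent. Constant
phenotypes scan to all-zero LOD with a warning; flat-zero LOD profiles
yield whole-chromosome credible intervals with a warning. Duplicate-marker
removal matches missing values literally (no wildcard), keeping the result
order-stable and deterministic. Plots with fewer than 2 productive plants
are dropped before statistics, and the filter is idempotent.

## Problem sizes used in the checks

The statistical test battery runs at a reduced marker density (2.5 cM
spacing, ≈ 440 markers) and n = 200 progeny — chosen so the full property
suite (including 1,000-permutation thresholds inside 50-replicate power
loops and ≈ 1,500 null-trait calibration scans) completes in a couple of
minutes while keeping every rate estimate's sampling error well inside the
asserted bands. Replicate counts per check are stated in the tests
themselves; rates are averaged over independent threshold draws because a
single 1,000-permutation quantile is the dominant noise source in a
calibration estimate.

## Known limitations

No alpha-shape or convex-hull volumes, tree-area index, transmittance-based
leaf area, or shoot segmentation; no linkage-map construction, SNP calling
or parental-map handling; no epistasis search; no GPS/acquisition error
model; LAS I/O requires the optional `laspy` dependency. The ELA analysis
window and green thresholds are configurable because the original image
workflow's numeric choices are unpublished.
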