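# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `tmefib`, what the synthetic generator does and does not emulate, and
the known limitations.

## 1. Lesion-level prevalence analysis

The unit is the lesion; the outcomes are binary presence of any TLS and of a
primary-stage TLS.  For each factor level against its referent we form the
2×2 table (a = exposed & outcome, b = exposed without, c = referent &
outcome, d = referent without) and report

- odds ratio `OR = ad/bc`,
- Wald interval `exp(ln OR ± z_{0.975} · √(1/a + 1/b + 1/c + 1/d))`,
- two-sided Fisher exact p (hypergeometric tail sum with fixed margins).

A zero cell triggers the Haldane–Anscombe +0.5 correction on all cells,
always flagged in the output.  Age is compared with a pooled-variance
Student t-test (Welch available) run only when both groups pass Shapiro–Wilk
at α = 0.05; raw p-values throughout — no multiplicity adjustment, matching
the single-cohort reporting style (a Benjamini–Hochberg switch exists in
`stats` but defaults off).

**Packaged cohort fixture.** `tmefib/data/table1_lesions.csv` carries 30
lesions from 22 patients.  Covariates (age, gender, body site, subtype
components, ulceration) are transcribed from the published patient listing.
Per-lesion TLS status is *not* published — only the marginal
cross-tabulations are — so the two outcome columns were reconstructed by
integer programming to satisfy every published margin simultaneously
(including the group age sums).  Any statistic that depends only on those
margins (every OR, CI, Fisher p, group mean age) is therefore exact; the age
t-statistic depends on within-group dispersion, which the margins do not
pin down, and is reproduced in direction and non-significance only.

## 2. Geometry

All coordinates are pixel-space, origin top-left; polygons (shapely) live in
image (x, y) coordinates, distances are converted to µm by the raster
calibration.  The rules:

- **Stromal band**: `(dilate(tumor, w) − tumor) ∩ stroma` with Euclidean
  dilation radius `w = 30 µm` (distance transform, radius rounded to
  pixels).  An empty band is a warning, not an error.
- **Proximity**: minimum *edge-to-edge* distance from tumor to any TLS;
  proximal iff ≤ 500 µm, distal otherwise, control when the lesion has no
  TLS.  Edge-to-edge was chosen because the staging rule is phrased from
  the TLS edge.  A `strict_farthest_distal` helper reproduces the manual
  one-farthest-tumor convention when wanted.
- **Control field**: a uniformly sampled 500 × 500 µm² axis-aligned square
  fully inside tissue containing at least one tumor pixel, deterministic
  per seed.

## 3. Stain separation

Beer–Lambert optical density `OD = −log10((I + 1)/white)` per channel
(ε = 1 intensity unit guards the log; saturated pixels clamp at 0).  Stain
concentrations solve `OD = C · M` for the 3×3 stain matrix `M` of unit OD
row vectors; negatives are clamped to zero and the clamped fraction is
reported.  Defaults are the published H&E calibration triplets
(hematoxylin (0.644, 0.717, 0.267), eosin (0.093, 0.954, 0.283)); an H-DAB
set is included and any matrix may be supplied.  With two stains the third
row is the unit orthogonal residual (cross product, sign-fixed, negatives
clamped).  No blind stain estimation or cross-slide normalization.

## 4. Pixel classification

A random forest (default 60–100 trees, fixed seed, single-threaded for
determinism) on a multiscale filter bank of the eosin channel: raw plus,
per scale σ ∈ {1, 2, 4} px, Gaussian smooth, gradient magnitude, Laplacian
of Gaussian, both Hessian eigenvalues and local variance (6·n_scales + 1
bands, `mode="nearest"` borders).  Classes: background, fibrillary matrix
(collagen/elastin/reticulin merged — not separable on H&E), nuclei, mucin,
amyloid; ≥ 50 scribbled pixels per class, training rows canonically ordered
so scribble order cannot change the model.  One classifier artifact per
project, applied to all images.  Image QC: variance-of-Laplacian blur gate
(threshold 1e-4 on [0,1]-scaled intensities, calibrated once on sharp
synthetic renders) and a 64-px minimum resolution.

## 5. Fiber morphometrics

The fibrillary mask is thinned (`skimage.morphology.skeletonize`), spurs
shorter than 5 µm are pruned iteratively, and the skeleton is decomposed
into a graph: endpoints (1 neighbor), branchpoints (≥ 3 neighbors; adjacent
branch pixels cluster into one node), and traced pixel paths; chain length
counts 1 px per orthogonal and √2 px per diagonal step.  Pure cycles are
traced as closed paths.  8-chain length slightly overestimates smooth
curves (a circle measures ~4–5% long), which is inside the tolerance used
everywhere a length is asserted.

Metric definitions and choices:

- `avg_fiber_length` is the mean *path* (junction-to-junction segment)
  length — individual fibers are not traced across junctions.
- `hyphal_growth_unit = total_length / n_endpoints` (undefined when no
  endpoints); the identity `HGU × endpoints = total_length` is exact by
  construction and preserved by the combination rule.
- `curvature`: mean absolute turn between successive 20-µm chords resampled
  along each path (degrees per chord step); paths shorter than two chords
  contribute nothing.
- `alignment`: structure-tensor coherence `(λ1 − λ2)/(λ1 + λ2)` of the mask,
  tensor components summed over the region (σ = 2 px); rotation-invariant
  by construction.
- `fractal_dimension`: least-squares slope of log box count vs log(1/s)
  over dyadic boxes from 2 px to min(dim)/4.
- `lacunarity`: gliding-box `1 + var/mean²` of box occupancy, averaged over
  the same box sizes; 1 for a filled mask.  Both box metrics are computed
  on the ROI bounding-box crop with the mask restricted to the ROI (the
  rectangular-field convention of fiber-pattern tools); for narrow annular
  ROIs this mixes in empty corners, which is uniform across compared
  regions at fixed geometry.
- `hdm`: fraction of ROI pixels whose eosin concentration exceeds a
  threshold (config; Otsu on the ROI when unset) — the intensity-based
  density notion, kept separate from the mask-fraction `density`.
- `mean_gap_diameter`: 2 × mean local maximum of the distance transform of
  ROI∖mask.

**Combining stromal regions of one tumor**: per-fiber additive quantities
(endpoints, branchpoints, total length, path count) are summed; ratio
metrics are *recomputed from the combined sums* (so the HGU identity holds
for the combined record — averaging ratios would break it); global pattern
metrics are averaged weighted by fibrillary-mask area.  The combination is
permutation-invariant and associative; with zero total mask area the
pattern metrics are flagged missing.

The 13-metric set (11 named in the morphology literature for this tool
class plus fractal dimension and mean gap diameter) is fixed in
`METRIC_NAMES`; the exact composition of published 13-metric panels varies,
so the set is declared rather than asserted as identical to any one source.

## 6. Lymphocyte quantification

Positive pixels are classified in HSV: hue within a closed circular
interval (center ± width), saturation ≥ minimum, intensity ≤ maximum;
classes are exclusive with brown (T) precedence on ties — brown pigments
such as melanin contaminate the T channel, and an optional exclusion mask
is supported.  Defaults are calibrated against the renderer's fixed
chromogen constants (brown hue ≈ 0.075, pink ≈ 0.94, blue ≈ 0.64) and held
constant across a project.  Counts = round(integrated positive area /
nominal cell area), nominal area 38 µm² (a 7-µm lymphocyte disk); the
constant is configurable and cancels in every fraction and ratio.  TLS
records carry stage (an annotation input — the `suggest_stage` heuristic
never overrides it), area (mm²), T/B counts, B fraction and relative size
(TLS area / tissue area); tumor records carry TIL count (T + B inside the
tumor polygon), area and the proximity class.

## 7. Mixed models and other inference

The random-intercept model `y = Xβ + Zb + ε` is fitted by REML profiled
over θ = σ_g²/σ_e²: for fixed θ the GLS solution, the residual quadratic
form and both log-determinants have closed forms via per-group sums, so the
REML criterion is a smooth 1-D function minimized over log θ on [−12, 12]
(bounded scalar optimization), with the θ = 0 boundary checked explicitly.
σ_e² = r'V⁻¹r/(n−p), σ_g² = θσ_e², SEs from (X'V⁻¹X)⁻¹σ_e², Wald z against
the standard normal.  The implementation agrees with an independent REML
fit (statsmodels MixedLM) to ~1e-4 on coefficients in the test suite.
Box-Cox selects λ̂ by profile likelihood on the grid [−2, 2] step 0.01; a
+0.5 shift is applied when zero counts are present (documented; count IQRs
below 1 make a shift unavoidable).  Mann-Whitney U is exact for pooled
n ≤ 20 without ties, otherwise normal with tie correction.  Spearman
matrices use pairwise-complete rows and average ranks; significance masks
use the unadjusted per-pair α.

## 8. PCA and HCPC

Metrics are standardized before PCA by default: the 13 metrics mix µm,
counts and unit-free fractions, and an unscaled decomposition would be
dominated by total length.  (R's `prcomp` defaults to unscaled; the
`standardize=False` flag reproduces that behavior.)  Loading signs are
fixed so each component's largest-magnitude entry is positive.  Sample
clustering is Ward linkage on Euclidean distances in the retained-PC space
(default 7 PCs, or a cumulative-variance threshold); cluster labels are
canonicalized by decreasing cluster size with ties broken by lowest row
index, making the pipeline equivariant to row permutation.  Cluster
characterization is computed on the *original* metric scale: per metric a
one-way ANOVA across clusters (η² = between-SS/total-SS, F-test p assuming
homoscedasticity) and per cluster the standardized difference from the
grand mean with its direction.  No k-means consolidation after the tree
cut; k defaults to 3 with the linkage heights available for elbow
inspection.  A correlation-distance mode exists for metric dendrograms
only, never for sample clustering.

## 9. The synthetic generator

**Fibers** are correlated random walks: initial direction von Mises
(κ = 0 isotropic), turn angle per µm `N(0, step_angle_sd)`, gamma-distributed
lengths (CV configurable), optional branching (per-100-µm rate), optional
crosslink seeding of new fibers from points of existing ones, optional
anastomosis (walks truncate on contact).  Polylines are rasterized with a
circular brush until the target ROI coverage is reached; the fiber budget
exhausting first raises an error naming the limiting parameter.  Ground
truth polylines are returned in µm, so orientation statistics and nested-
mask constructions have an oracle independent of the raster.

Two presets span the phenotype contrast the clustering must detect:
**A** — long (150 µm), thin (2 µm), sparse (12% coverage), isotropic;
**B** — long generated fibers (200 µm) in a thick (6 µm), dense (25%),
aligned (κ = 6), crosslinked mesh whose *measured* segments are short
(junction-limited) and whose tips are often absorbed, giving high HGU with
low endpoint counts.  These were calibrated once against the qualitative
cluster fingerprints (A: ↑ average/total fiber length, ↑ lacunarity,
↓ alignment, ↓ density; B: ↑ HGU, ↑ density, ↓ segment length,
↓ endpoints) and then frozen.

**Cohort**: covariates are independent Bernoulli draws at the study
frequencies (nodular 25/30, superficial 10/30, infiltrative 5/30,
ulceration 21/30); TLS presence is logistic in the nodular flag (intercept
logit(0.2), slope ln 10.29); stage is Bernoulli(11/19) per TLS; TIL counts
are gamma-Poisson with log-mean
`ln 17.6 + 0.7·[primary-proximal] + 0.8·[phenotype A] + u_lesion`,
`u ~ N(0, 0.5²)`, dispersion 0.6 (the wide count IQRs demand strong
overdispersion); killing is Bernoulli with logit linear in ln(TIL + 0.5).
No quantitative TIL-generating model is published; these effect sizes
reproduce the reported group means qualitatively and are the package's
declared study conditions.

**Scenes** render cohort rows into 512×512 px (default; any size ≥ ~256)
images at 1 µm/px: elliptical tumor nests, disk TLS (primary larger),
per-tumor annular stromal neighborhoods carrying their phenotype's fiber
network, mucin/amyloid blobs, scattered nuclei; H&E via the Beer–Lambert
forward model (5% multiplicative concentration noise), IHC with planted
cell disks placed with spacing (and capped at ~45% regional coverage) so
positive-pixel areas remain additive and planted counts are recoverable.
Distal tumors require a canvas wider than the 500-µm cutoff.

**What the generator does not emulate** — and hence what green tests do not
establish about real slides: realistic chromogen variation and stain
overlap, melanin confounding (an optional contamination toggle exists, off
by default), nucleus-level texture, section-to-section registration error
between IHC and H&E (annotations are per-image by construction), 3-D tissue
context, and scanner artifacts.  Segmentation Dice near 1.0 on these
renders reflects their controlled noise, not expected performance on real
H&E.

## 10. Experiment scales

The packaged experiments run at desk scale on one CPU: phenotype recovery
uses 32–40 regions per arm at 256² px; mixed-model recovery uses 200
lesions averaged over 10 simulated cohorts; null calibration uses 1000
cohorts of 200 lesions; Monte-Carlo odds-ratio recovery uses 10⁴ lesions.
The pipeline default renders images for 6 of 30 simulated lesions (tables
cover all 30).

## 11. Known limitations

- Fibers are not traced across junctions; `avg_fiber_length` is a segment
  statistic, which differs from per-fiber length when networks are dense.
- Chain-code lengths bias long smooth curves upward by a few percent.
- The gliding-box metrics use the bounding-box crop of non-rectangular
  ROIs (uniform across compared regions, but not a per-shape exact value).
- The Wald z reference for mixed-model fixed effects ignores small-sample
  degrees of freedom; calibration is verified at ~200 groups, and p-values
  at very few groups will be anti-conservative.
- Reconstructed TLS columns in the packaged cohort are one of several
  margin-consistent assignments; only margin-determined statistics are
  exact (see §1).
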