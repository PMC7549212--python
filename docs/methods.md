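# Methods

This note records the models, conventions and design choices behind
`salipheno`, in the order the pipeline runs. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Synthetic plant model

Real photograph archives for this kind of study are rarely distributable, so
the package ships a generator whose output has the statistical structure the
analysis assumes and whose ground truth is exact.

**Design.** Two populations — C (natural saline site) and I (industrial
saline site, programmed as the more salt-tolerant) — × five NaCl treatments
(0, 200, 400, 800, 1000 mM) × 12 replicates = 120 plants. Every random draw
is keyed on `(seed, population, treatment, replicate)` through a
`numpy` `SeedSequence`, so identical configs give bit-identical cohorts.

**Geometry.** A plant is a vertical beaded stem with first-order laterals
and recursive children, rasterised with PIL and then hole-filled (the
silhouette is the region "inside the borderline", exactly as the area trait
and the segmentation post-processing treat it):

* stem: height and width drawn from treatment-dependent Gaussian curves
  (height unimodal, peak 400 mM; width — succulence — monotone increasing);
* laterals: `branch_count` per plant (CV ≈ 20–35 % between replicates,
  realistic for branched halophytes), attached between 0.45 and 0.92 of the
  stem height, lower laterals steeper (30–60° from the vertical) so
  same-side laterals diverge instead of crossing;
* recursion: `branching_depth` counts sub-branching orders beyond the
  first-order laterals (depth 0 = plain laterals). Children fan outward on
  the parent's side of the vertical, never back across the stem; children
  drooping past 90° are shortened so neighbouring crowns do not fuse;
* beads: every stroke carries periodic bulges (period 2.0× width, amplitude
  1.32×) emulating the articulated succulent segments of the shoot and
  giving the silhouette its fine-scale boundary texture.

These constraints are not cosmetic: they keep each generative parameter
recoverable from the rendered mask (laterals that fuse or cross become
uncountable in any 2-D projection — the same occlusion problem a human
counter faces with a real bush).

**Colour.** Foreground pixels are sampled around a treatment-dependent
CIELab centre (per-pixel sd 2.0) and converted to sRGB; the background is
pure white, emulating light-box photography. Centres drift monotonically
with salinity — L\* up (70 → 78), a\* up towards 0 (−20 → −6), b\* up
(27 → 39) — with population C's excursion scaled ×1.35 (it shows the larger
ΔE). The centres are light enough that plant pixels stay inside the
135–240 greyscale band with dropout < 0.1 % even at −2 sd plant-level
draws; this was checked by Monte Carlo when the defaults were set.

**Population contrast.** The I population's biomass traits (height,
branches, stem width, spread) carry a multiplicative advantage that is
smallest at the shared 400 mM optimum (×1.07) and largest at 1000 mM
(×1.40), so the populations' trait profiles converge at the optimum and
separate most under severe stress. I also accumulates more proline (×1.15)
and keeps slightly more pigment (×1.06); C's H₂O₂ rises earlier (×1.10).

**Biochemistry.** True assay concentrations (proline in µg/ml, H₂O₂ in mM,
both inside their 0–40 calibration ranges at most treatments) are drawn
from treatment curves and pushed through the printed linear standard curves
plus small read noise (sd 0.002 absorbance); pigment absorbances are drawn
directly, declining with salinity. With all noise at zero the measurement
model inverts exactly (checked to 1e-9 relative).

**RAPD.** Three primers with 5+3, 6+6 and 6+6 monomorphic+polymorphic bands
(15 polymorphic in total). Monomorphic bands are present in every
individual; polymorphic bands get per-population frequencies in (0.1, 0.9),
half of them strongly divergent between populations. A designated
polymorphic band that happens to be sampled fixed-and-identical everywhere
has one individual flipped so the designed count is always realised.
`private_bands_per_population` (default 0) adds population-diagnostic bands
for strongly structured fixtures.

## Measurement conventions

**Segmentation.** Deterministic band thresholding (inclusive 135–240 on the
BT.601 greyscale), keep-largest-component and hole-fill both on by default.
The original workflow this replaces was manual; determinism is the point.
Whether the threshold band should capture the plant or the background on
*real* photographs depends on the camera and lighting — for the synthetic
images the plant falls inside the band by construction, and both thresholds
are exposed.

**Shoot diameter S.** Rows spanning the middle third of the vertical
extent; in each row the contiguous run that intersects the main-stem column
(the column foreground in the most band rows); S = the 0.15 quantile of the
run lengths. Two deliberate deviations from the more obvious choices, both
forced by bushy crowns: a centroid-based stem column is dragged off a
narrow stem by one-sided laterals, and the *median* run length reads crown
width, not stem width, once junction rows dominate the band (on the default
cohort the median overestimated S by ~25 px at 400 mM; the low quantile
reads the bare-stem rows and recovers S essentially exactly). On a
branch-free stem every row has the same width, so any quantile returns it.

**Branch count B.** Skeletonise; prune terminal twigs shorter than 5 px;
main path = geodesic from the basal-most to the apical-most skeleton point
(anchoring the apex rather than taking the longest geodesic keeps the main
path on the stem when a branch-plus-descendants chain is geodesically
longer than the remaining stem); B = number of connected lateral subtrees
off that path whose geodesic reach exceeds the prune length (the reach test
removes junction nubs whose degree is inflated by diagonal adjacency).

**Fractal dimension.** Boxes are anchored at the top-left origin (no origin
search); the mask is cropped to its bounding box and padded to the next
power-of-2 square; the default box series is powers of 2 from 2 px up to a
quarter of the padded side, **capped at 64 px**. The cap mirrors the
fine-scale default series of the standard box-count plugin in mainstream
image-analysis software and is load-bearing: beyond ≈ 1/8 of the frame any
branched silhouette degenerates towards its skeleton and the local slope
falls to ~1.5 regardless of crown texture, which would cap every cohort
mean near 1.78. Saturated scales (every grid box occupied) are excluded
from the OLS fit unless fewer than four scales survive, in which case the
unfiltered series is used — a fully plane-filling mask is then fit over all
scales and correctly returns FD = 2. Natural logarithms; the slope is
base-invariant.

**Colour.** sRGB → linear RGB → XYZ (sRGB/D65 primaries) → Lab with the
D65 white point, as implemented by scikit-image; per-plant summary is the
arithmetic mean over the mask (median behind a flag). The ΔE reference is
the **per-population mean of the 0 mM controls** — populations differ at
0 mM, and ΔE is reported per population — so control plants themselves get
small positive ΔE while their mean per-axis deviation is zero. sRGB
primaries are an assumption about the camera; for synthetic images they are
exact, for real photographs they are the weakest link of the colour path.

**Biochemical units.** Content conversions are explicit parameters with the
extraction protocol as defaults: proline mg/g FW = x µg/ml × 2.5 ml extract
/ 0.5 g / 1000; H₂O₂ nmol/g FW = x mM × 6 (assay dilution, 0.5 ml in
3.0 ml) × 5 ml extract / 0.5 g × 1000. The chlorophyll-b coefficient pair
(20.13, 2.81) is implemented exactly as the source workflow uses it, even
though it differs slightly from the canonical 80 %-acetone coefficient set
— deliberately not "corrected". Inside the carotenoid equation the
mass-scaled Cha/Chb values are used (the typography of the source formula
is ambiguous on this; the choice is recorded here and in the config
header). Negative pigment values are flagged with a warning, never clamped;
inversions outside a standard curve's calibrated range are flagged, never
rejected.

## Statistical layer

* **PCA** on the correlation matrix (the 12 variables have incommensurate
  units, and the Kaiser eigenvalue > 1 rule presumes unit-variance input);
  covariance PCA behind a flag. Loading columns are oriented so their
  largest-magnitude entry is positive — score signs are then reproducible
  across eigensolvers, and the score distances are sign-invariant anyway.
* **Distances** between the populations' factorial scores use the first
  three components regardless of the Kaiser count, matching the 3-D
  factorial-score plot convention.
* **Pearson matrix** significance by the exact t transform with n−2 df;
  zero-variance variables propagate NaN and are never flagged significant.
* **ANOVA**: full factorial (population × treatment) per trait; pairwise
  simple effects use the pooled residual mean square; Holm–Šidák
  step-down (adjusted pᵢ = 1 − (1 − pᵢ)^(m−i+1), running max) applied
  within each comparison family — the ten treatment pairs within each
  population, and the five population contrasts across treatments. Compact
  letters by insert-and-absorb with treatments ordered 0 < 200 < 400 <
  800 < 1000.
* **UPGMA** is the classic size-weighted average linkage with merge height
  d/2 and ties broken by the smallest cluster-index pair; output is
  ultrametric by construction and reproduces an ultrametric input exactly.
  Jaccard distance ignores shared absences (the standard convention for
  dominant markers; some software variants differ, hence the explicit
  statement). Band calling from gel images is out of scope — the module
  starts at the 0/1 matrix.

## Calibration of the defaults

The generator's defaults are the study conditions, fixed once: the joint
requirements were (a) cohort mean FD ≈ 1.85 at 400 mM, (b) all silhouette
FDs inside [1, 2] with mean FD strictly increasing in branching depth, and
(c) ground truth recoverable from the rendered masks (Spearman ≥ 0.95 for
H and A, ≥ 0.9 for S and B over the default cohort). These pull against
each other: the FD target needs ~20 % crown fill, and filled crowns hide
laterals from any silhouette-based counter. The resolved operating point —
few, thin, well-spaced laterals carrying dense beaded child crowns,
measured with the fine-scale box series — was selected by a sweep over
several seeds and then frozen; on the default cohort it delivers mean FD at
400 mM of ≈ 1.80–1.82, FD range ≈ [1.33, 1.87], and recovery correlations
H ≈ 0.996, A ≈ 1.00, S ≈ 0.99, B ≈ 0.91–0.93.

## Problem sizes

The default cohort (120 plants at 512 × 512) generates and measures in
about 7 s. The test suite runs the full default cohort once, a
200-silhouette depth sweep, and a 100-run repetition of the
population-distance experiment at 3 replicates per cell — the reduced
replicate count keeps that experiment at ~2.5 minutes while leaving the
programmed effects untouched. The acceptance script measures 224
silhouettes end to end.

## What passing tests do and do not show

The synthetic cohort validates the *machinery*: segmentation, trait
extraction, FD estimation, colour scoring, the algebra of the biochemical
equations and the statistical layer, against exact ground truth and
independent oracles. It does not validate camera colour management,
lighting inhomogeneity, soil/pot occlusion, perspective, overlapping
plants, or any biology beyond the programmed response shapes; conclusions
about real photographs need the measurement half applied to real,
calibrated images. Axis conventions are fixed (row 0 at the top, base =
bottom-most foreground row): the height of a horizontal bar is its stroke
width, by design.

## Known limitations

* B saturates on very dense crowns (laterals occluded in the 2-D
  projection are uncountable in principle); the generator's defaults keep
  occlusion mild, real bushes may not.
* FD depends on the box-series convention; values are comparable only
  within one convention. The 64 px cap is documented and overridable.
* The ΔE reference choice (per-population control mean vs per-plant or
  pooled references) changes control-group ΔE; alternatives are exposed as
  parameters.
* UPGMA tie-breaking is deterministic but arbitrary where distances tie
  exactly; topology among tied merges is convention, not signal.
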