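# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a user may want to audit.

## Micrograph quantification

**Segmentation.** Images are percentile contrast-stretched, inverted (cells
are iodine-dark on a light background), and globally thresholded (Otsu by
default). The lower stretch percentile defaults to 0 because cells typically
cover well under 1% of a settling-chamber field; a higher lower percentile
would clip them out of the dynamic range. Otsu has a known failure mode on
nearly object-free frames — it splits the background-noise mode in half —
so a threshold is rejected (no ROIs returned) when the foreground/background
class means are separated by less than 0.35 of the stretched range; genuine
cell/background splits separate by ~0.9. Connected components smaller than
an area floor are dropped. The floor corresponds to a 4 μm cell, the
smallest resolvable by this method, minus a 15% margin so that a genuine
4 μm cell straddling the rasterization boundary is retained.

**Axis measurement.** Axes come from the ellipse with the same normalized
second central moments as the binary mask; axis length = 4·√eigenvalue of
the pixel-coordinate covariance, with no +1/12 pixel-area correction — the
convention of common `regionprops` implementations, stated here so results
are bit-reproducible. Quantization error scales inversely with axis length
in pixels: below ~20 px the minor axis can be off by 1–3%, which is why the
synthetic benchmarks image small cells at high magnification (0.125 μm/px)
and large cells at 0.5 μm/px, as a microscopist would.

**Cilia correction.** Automated thresholding includes cilia in ciliate
outlines, inflating the measured major axis (the generators emulate a 12%
extension). The correction is a regression of manually measured (cilia-free)
lengths on automated lengths, zero-intercept by default — a pure correction
factor; a free-intercept fit is available and recorded in the result. The
correction is applied to the major axis only; the minor axis is unaffected
by cilia along the cell's long axis. Applying it twice is a state error.
Dinoflagellates pass through untouched.

**Biovolume and carbon.** Cells are treated as prolate spheroids,
V = (π/6)·a·b². Carbon uses the non-diatom protist allometry
pg C = 0.216·V^0.939 for both groups by default; coefficients live in a
`CarbonModel` so diatom-type values (0.288·V^0.811) or group-specific
updates are configuration, not code. Biomass per sample is
Σ carbon / settled volume converted to μg C L⁻¹ (1 pg mL⁻¹ = 10⁻³ μg L⁻¹).
Cells labelled *Tripos* are tallied separately and excluded from the four
group totals: their sporadic, massive cells would otherwise dominate
dinoflagellate biomass. Samples with fewer than 80 cells are flagged as
low-count. The size-class boundary assigns exactly 20 μm to the large class.

## Two-point dilution rates

The model is exponential chlorophyll growth with grazing mortality diluted
by the fraction x of whole seawater: k(x) = μ − x·g. With the 100% and ~20%
levels, g = (k_dil − k_WSW)/(1 − x). Classification: the amended dilution
and amended WSW bottle rates are compared with Welch's t-test (α = 0.05);
if not significantly different, g = 0; if WSW growth is significantly
*higher*, grazing is undetermined and no number is reported. Welch was
chosen because bottle replication is 2–3 and variances need not be equal; a
paper using this design names no test, so the choice is documented here.
The replication unit is the bottle — chlorophyll subsample triplicates are
averaged first to avoid pseudo-replication — and the two WSW treatments'
initial readings are pooled because both sets of bottles are filled from the
same carboy. The realized dilution x is estimated from initial chlorophyll
(diluted/WSW) rather than taken as the nominal 0.2, with a warning when it
strays 0.05 or more from nominal, and a fallback to nominal when initial
diluted readings are missing. μ pairs with the unamended bottles (in situ
growth), μ_n with the amended ones; nutrient limitation is a one-sided Welch
comparison of the two.

Monte-Carlo behaviour under the survey design (duplicate bottles, triplicate
subsamples, 5% reading CV): the median |ĝ − g| over μ ∈ [0, 1.5],
g ∈ [0, 1] is ≈ 0.04–0.05 d⁻¹. Two structural effects are worth knowing.
First, with duplicate bottles the Welch test has ~2 degrees of freedom, so
true grazing below ≈ 0.2 d⁻¹ is often classified zero; those cases re-enter
the error distribution with error = g. Second, conditioning on a significant
difference selects slightly high ĝ among "measured" cases (≈ +0.01 d⁻¹).
Both are properties of the published classification rule at this
replication, not of the implementation.

## Environmental derivations

**MLD.** The surface reference is the mean temperature over bins at or above
5 m (configurable); the mixed layer depth is the shallowest *sampled* depth
whose absolute temperature difference from that reference exceeds 0.5 °C.
The absolute difference handles winter inversions. No interpolation between
bins by default — the rule then returns an actual sampled depth and is exact
against step-profile fixtures — with a linear-interpolation variant behind a
flag. Profiles never exceeding the threshold return an explicit unresolved
result rather than a number.

**K_d.** Ordinary least squares of ln(PAR) on depth; K_d is minus the slope,
with r² reported. The default window runs from the surface to the 1%-light
depth, since no deeper reading should inform a surface attenuation estimate;
non-positive PAR readings are dropped with a warning and at least three
points are required. Night casts use a linear calibration of K_d against
mean 0–10 m beam attenuation fitted on daytime casts; predictions outside
the calibrated beam range are flagged as extrapolations.

**I_m.** The depth-mean of exponentially attenuated surface irradiance over
the mixed layer, I₀(1 − e^(−K_d·MLD))/(K_d·MLD). A three-term series branch
is used when K_d·MLD < 10⁻⁶ to avoid 0/0; in that optically thin limit
I_m → I₀.

**Chlorophyll size fractions.** Small-fraction chlorophyll is the GF/F total
minus the >10 μm reading (filter-type means first), clamped at zero with a
flag when the large-fraction reading exceeds the total, as can happen with
triplicate noise.

## Community statistics

**ANOSIM.** Clarke's statistic on a Bray-Curtis matrix:
R = (mean between-group rank − mean within-group rank)/(n(n−1)/4), average
ranks for ties. This denominator makes R = 1 at complete separation.
Permutation p-values use the add-one convention (1 + count)/(1 + n_perm), so
the smallest attainable p at 999 permutations is 1/1000. An exact mode
enumerates all label orderings (feasible for small n) and is verified
against an independently coded brute-force oracle.

**Type-III ANOVA.** Season × region with interaction under sum-to-zero
contrasts, marginal (type-III) sums of squares via statsmodels — appropriate
for the unbalanced designs that arise once outliers are excluded. Terms made
inestimable by empty cells surface as NaN rows, not exceptions. The
implementation is tested against an explicit full-vs-reduced projection
oracle and against R's `car::Anova`.

**Pearson screen.** Explanatory pairs with |r| > 0.70 and p < 0.05 (complete
cases) form co-correlation clusters (connected components); each cluster
keeps the member with the highest cumulative |r| against the four response
columns, ties broken by column order. This guarantees the explanatory matrix
passed to the RDA is not collinear by construction.

**RDA.** Responses (relative biomass) are centered; explanatory variables
are z-scored (sample SD) before entry. Fitted values from the multivariate
least-squares projection are SVD-decomposed; the constrained fraction is
trace(Ŷ'Ŷ)/trace(Y'Y) — the multivariate R², invariant to any invertible
affine recoding of the explanatory columns. The global permutation test
permutes rows of X and recomputes that statistic. Site scores are the
centered responses projected on the constrained axes (weighted-average-style
scores), so a sample's position reflects its actual composition; linear
combination scores and explanatory-axis correlations (biplot loadings) are
also returned.

**Outlier rule.** Distances are Euclidean in RDA space over all constrained
axes by default (the number of axes is a parameter; analyses of the first
two axes can be requested). A sample is an outlier if d_opp < 0.5·d_own
("more than 50% closer" read strictly; the alternative reading is reachable
via the ratio parameter) or if d_own exceeds its season's mean centroid
distance by more than 2.5 standard deviations *of those distances* — the
distance-SD reading of "2.5 standard deviations from the centroid", chosen
because it is scale-free across axes. Flags are invariant to rigid rotation
of the scores.

**Summaries and correlations.** Per-(season, region) means, SDs and SEs of
each group and the total, overall group shares, and winter:summer total
ratios, all computed after excluding flagged outliers (reported means should
not be dragged by anomalous events). Grazing–biomass relationships are
two-sided Pearson correlations per season stratum, with undetermined-grazing
samples dropped and strata under three pairs skipped.

## Synthetic generators

The generators emulate the study conditions, not photorealism:

- **Micrographs**: filled dark ellipses (Lugol's-like contrast 140 on a
  background of 200) with 4×4 supersampled partial-pixel coverage at the
  boundary — moment measurement is boundary-sensitive, so sub-pixel
  rendering matters. Ciliates get a fringe ellipse extending the major axis
  by the cilia fraction (default 0.12) at 75% of the cell contrast, dark
  enough that a global threshold absorbs it — reproducing the
  over-measurement mechanism the correction exists for. Non-overlapping
  placement is enforced by bounding-circle rejection. Not emulated: texture,
  vacuoles, touching cells, debris, uneven illumination; passing closed-loop
  tests therefore demonstrates correctness of the measurement chain, not
  robustness to curation-stage ambiguity, which the manual include/exclude
  table handles in real use.
- **Community tables**: one sample per (year, season, region) over six years,
  three regions, two seasons. Default stratum means (total μg C L⁻¹: winter
  11/13/7, summer 9/4/5.4 for inner/mid/outer) and group proportions encode
  the canonical shelf pattern — winter dominated by large dinoflagellates,
  a summer shift to small dinoflagellates, aseasonal ciliates at roughly a
  quarter of biomass, small ciliates always minor. Noise is mean-one
  lognormal (σ = 0.45) because biomass is positive and right-skewed; the
  lognormal choice is an assumption, not an inference from data. Outlier
  events are planted by swapping a sample's composition to the opposite
  season's proportions.
- **Dilution experiments**: Chl₂₄ = Chl₀·e^(μ−x·g) with mean-one lognormal
  reading noise (CV 0.05 by default), duplicate bottles, triplicate
  subsamples, 20% target dilution — the field design.
- **CTD profiles**: step thermocline at a known MLD (plus a slow gradient
  below), exactly exponential PAR with known K_d, constant beam attenuation;
  optional noise on each.
- **Grazing rates**: winter rates are linear in total biomass with noise set
  to hit a target correlation; summer rates are drawn independently. The
  default target (r = 0.75) is set by power: with ~18 winter samples the 5%
  detection threshold is r ≈ 0.47, and 0.75 makes the winter dependence
  detectable in ≈95% of realizations, so the seasonal contrast — a real
  winter correlation, a null summer one — is reproducible rather than a
  coin flip.

All generators are deterministic under a seed, and every zero-noise
generator inverts exactly through its analysis counterpart.

## Problem sizes used in the test and acceptance runs

Closed-loop imaging uses 200 cells (log-uniform 4–200 μm) rendered in
magnification batches; cilia fitting uses 120 ciliates; dilution recovery
uses 500 experiments; null calibration uses 500 replicates of n = 24 with
199 permutations per test (the add-one convention makes the nominal size
exactly 0.05 at that count); the end-to-end study is the full 36-sample
design with 999 permutations. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Known limitations

- Group labels (dinoflagellate / ciliate / Tripos) are inputs: the package
  models the manual-curation step as an include/exclude + label table and
  does not attempt taxonomic identification.
- Whether ciliate biovolume should also use a corrected minor axis is
  untestable from the available description; the correction applies to the
  major axis only.
- The RDA permutation test permutes raw rows of X (appropriate for a global
  test without covariates); partial RDA and variance partitioning are out of
  scope.
- Multiple-testing correction across the correlation grid is deliberately
  not applied, matching the analysis style this pipeline reproduces.
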