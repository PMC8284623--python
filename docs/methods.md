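# Methods

## The pipeline model

A field of view is a set of co-registered 2-D intensity rasters, one per
marker, with a physical pixel size in µm (default 0.5 µm/px, a typical
slide-scanner resolution). The panel always contains the pan-myeloid
marker Iba1 and exactly one microglial-specific marker (P2RY12 or
TMEM119); optionally one TAM-enriched marker (CD14 or CD163).

**Segmentation.** Each channel is binarised by one of three methods —
fixed intensity, Otsu, or an intensity quantile (default Otsu; the
threshold actually applied is always recorded for audit). The per-marker
masks are unioned into a *master mask*; every connected component of the
master mask is one cell. Touching cells therefore merge into one object —
this is deliberate fidelity to the object-based design rather than a
defect, and no watershed/declumping is attempted. Components below
`min_area_px` (default 20 px at 0.5 µm/px, roughly a soma cross-section)
are removed as size debris; connectivity defaults to 8. Mean intensity of
every marker is measured over each object's pixels, with unweighted pixel
centroids (0-based, x = column) and areas in both px and µm².

Cell densities are normalised by the stained-tissue area. Default: the
full field area in mm². For slides containing empty glass an alternative
estimates tissue as the hole-filled Otsu foreground of the summed
channels. The method used is recorded on the table. Intensities are not
background-subtracted; the gates operate on relative intensities.

**Gating.** Gates are half-open intervals [lo, hi) in 1-D intensity space
(a cell exactly on a threshold goes to the *upper* region — documented and
tested), with optional 2-D simple-polygon gates (boundary inclusive) for
parity with manually drawn regions. The hierarchy is: Iba1 master gate
(debris vs total cells), then the microglial-marker split gate (inside →
microglia, outside → TAM; the two regions partition the master-gated
space by construction), then an optional CD14/CD163 high/low gate.
Epilepsy tissue carries its own gate set, looked up before the shared
"all" scope, because control and tumor staining patterns differ.

CD14/CD163 do not split bimodally; their positivity threshold is instead
calibrated from negative-control (epilepsy) tissue as a quantile of the
pooled control cells' marker means — default 0.99, linear-interpolation
quantile convention (so controls are, by construction, ≈1% cd_high). A
two-component Gaussian-mixture helper can *suggest* a microglia/TAM split
threshold from a pooled bimodal sample; it is an automation convenience,
always overridable, and its output should be recorded in the scheme
provenance rather than trusted blindly.

**Population metrics.** Per case: counts, proportions of total gated
cells, densities (count / tissue area), and the microglia:TAM count
ratio. Zero-TAM cases would make the ratio infinite; the default
convention is a +inf sentinel with a `ratio_degenerate` flag (excluded
from ratio statistics), with a continuity-corrected alternative
((mg+0.5)/(tam+0.5)) by option. The global expression index for a
microglial marker is defined as the per-case integrated intensity (sum
over non-debris cells of mean intensity × area in px) divided by total
myeloid density; the per-case rather than pooled normalisation is a
design choice, locked in code. Repeated-staining replicates of one case
must be averaged (`collapse_replicates`) before any cross-case statistic.

Comparisons: Mann–Whitney U (scipy, exact for small samples), two-way
ANOVA via OLS with type-II sums of squares (robust to unequal cell sizes)
with Tukey HSD or Sidak-corrected pairwise post-hocs, paired t for
matched cases, and a normality gate (Shapiro–Wilk per group; two-sided
F-test of variances for two groups, Bartlett for more) that recommends
the nonparametric route whenever an assumption fails or is untestable.

**Survival.** Times are months throughout. A per-case metric is
median-split: values strictly above the median are "high"; ties at the
exact median go to "low" by default (switchable), so group labels depend
only on ranks and are invariant to monotone transforms. Kaplan–Meier
estimation, the log-rank test and Cox regression are delegated to
lifelines (Efron tie handling); the KM median is the earliest time with
S(t) ≤ 0.5 and is reported as undefined if never reached. Rule-based
exclusion (pandas query expressions, e.g. `idh1_mutant == 1`) is applied
and logged before modelling. AIC selection searches all covariate subsets
(including the null model) for ≤10 candidates and backward-stepwise
otherwise, logging the full trace; perfectly collinear candidates are
dropped with a warning. The null model's Efron partial log-likelihood is
computed directly (each of d tied events at a time with risk-set size n
contributes −log(n−j), j=0..d−1) so the null AIC is on the same scale as
the fitted models. Degenerate fits (constant covariate, non-convergence)
return flagged results rather than raising mid-pipeline. An
events-per-variable warning fires below 10.

## The synthetic generators

**Images.** Cells are rendered as disks (radius uniform on 4–7 px by
default): real microglia are ramified and TAMs amoeboid, but disks are
sufficient to exercise masking, object detection and measurement while
keeping ground truth analytic. Per cell, each marker's foreground mean is
drawn from the population's intensity model and added onto a constant
background, the image is blurred by a Gaussian PSF (σ = 1 px default) and
corrupted by additive Gaussian noise (sd 200). Intensities are arbitrary
16-bit-range floats with no camera model — the pipeline uses only
relative intensities. Defaults: Iba1 bright in both populations
(18 000/20 000 ± ~1 500–1 800), the microglial marker strongly bimodal
(14 000 ± 1 200 in microglia vs 2 500 ± 1 200 in TAMs — the separation
the gating relies on, and a spec invariant), and CD14/CD163 as
*overlapping log-normals* (median 900 vs 2 800, σ_log 0.9) so the CD axis
is a continuum, not a split. These distributions are declared defaults,
not fits to any measured data.

Placement is rejection sampling; with the default overlap budget of 0 a
2-px inter-disk gap is enforced so connected components are one-to-one
with cells (a positive budget gives a "clumped" mode that exercises the
known touching-cells-merge limitation). Unplaceable requests raise an
error naming the budget. Tissue presets fix the composition: epilepsy
≈98% microglia with the few CD⁺ cells placed along a simulated vessel
path and near-background CD expression elsewhere (quasi-steady-state,
perivascular-macrophage control); meningioma/low-grade 10–15% microglia
(TAM-dominated); grade IV 40%. Everything is deterministic for a fixed
seed.

What the simulator does *not* emulate: ramified morphology,
autofluorescence/lipofuscin, illumination gradients, stitching artefacts,
out-of-focus light beyond the Gaussian PSF, or spectral spillover.
Passing tests therefore demonstrate the correctness of the computational
pipeline on its stated model, not robustness to every property of real
tissue.

**Cohorts.** Per patient: a microglia:TAM ratio drawn log-normal (µ=0,
σ=1 by default), MGMT methylation Bernoulli (p=0.45, near the commonly
reported methylated fraction), rare IDH1 mutation (p configurable,
default 0). Survival time is exponential with hazard
`baseline × exp(β_ratio·1[high] + β_mgmt·mgmt)` where 1[high] indicates
being above the realized median ratio — the effect is attached to the
group indicator itself so the downstream median split recovers the
generating groups exactly. Censoring is an independent exponential
clock. Baseline hazard 0.05/month puts the null median survival at
ln2/0.05 ≈ 13.9 months, the right scale for glioblastoma.

## Separation convention for gating fidelity

"Separation" between the two populations on the microglial marker is
defined as the distance from each population mean to the midpoint
threshold, in pooled-SD units. With Gaussian per-cell means and a
midpoint threshold the analytic misclassification rate at separation d is
Φ(−d): ≈2.3% at d=2, ≈1×10⁻⁹ at d=6 (effectively zero errors at any
realistic cell count). Tests compare empirical error to Φ(−d) within
binomial tolerance.

## Numerical and testing choices

Quantiles use numpy's linear-interpolation convention. Gate intervals are
closed-left/open-right everywhere, including the high/low gate (≥
threshold → cd_high). Empty tables are legal (zero-row CellTable, all-zero
gate report); empty scenes are not (at least one cell must be requested).
Test problem sizes are chosen so ground truth is exact or tolerances are
binomial: 20 clean 1024×1024 images for count recovery; 6 000 cells per
gating-fidelity scenario; 500 null replicates for log-rank calibration;
100 replicates × 4 hazard ratios at n=300 for Cox bias/coverage; 100
replicates at n=300 for the directional protective-effect check. Oracles
in the test suite (flood-fill component counting, exhaustive Mann–Whitney
rank enumeration, empirical survival, permutation log-rank, closed-form
exponential medians and generating hazard ratios) are implemented
independently of the libraries they check.

## Known limitations

- Touching cells merge; counts are only identifiable in the non-touching
  regime (enforced by the simulator's default, violated by design in the
  clumped mode).
- Gate coordinates for real tissue are user-supplied or helper-suggested;
  nothing in the package claims to reconstruct any particular manual
  gating session.
- The two-way ANOVA wrapper requires ≥2 observations per factor cell.
- The cohort simulator's exponential baseline has constant hazard; it
  validates estimator calibration, not clinical realism of the survival
  shape.
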