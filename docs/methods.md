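# Methods

This note documents the statistical model behind each stage of `episig`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Scales: beta values and M values

Methylation at a CpG is measured as a beta value β ∈ [0, 1] (methylated
signal over total signal).  Betas are bounded and heteroskedastic, so all
linear modeling is done on M values, M = log2(β / (1 − β)), where the
distribution is approximately Gaussian; effect sizes are reported and
thresholded on the beta scale, where "a 10% methylation difference" has a
direct biological meaning.  Betas are clipped to [10⁻³, 1 − 10⁻³] before the
logit to avoid infinities; inside that range the transform pair is exact to
better than 10⁻¹² and strictly increasing.

## Quality control

Probe filters run in a fixed order, and each removed probe is attributed to
the first rule that claims it: (1) detection p > 0.01 in any sample (the
strictest reading of a per-probe detection rule; a maximum failing-fraction
is configurable), (2) probes flagged on chromosomes X/Y, (3) probes
overlapping SNPs, (4) cross-reactive probes, (5) probes with any missing
beta.  Filtering is idempotent.

Two sample-level checks flag (never silently drop) samples:

* **Sex concordance.** X inactivation leaves a large share of chrX CpGs at
  intermediate methylation in females, while males sit at the bimodal
  extremes.  A sample is predicted female when ≥ 20% of its chrX betas fall
  in [0.25, 0.75].  The three thresholds are heuristics chosen for
  transparency and are configurable; this check must run before chrX probes
  are filtered.
* **Density bimodality.** A healthy methylome concentrates near 0 and 1; a
  sample is flagged when more than 35% of its betas fall in (0.3, 0.7).  A
  simple mid-fraction rule was preferred over a dip test because it is
  directly interpretable and has no tuning beyond the two bounds.

**Cell composition.** Whole blood is a mixture of cell types whose
proportions vary between people and can confound case/control comparisons.
Given reference beta profiles of K cell types at marker probes, per-sample
fractions are estimated by constrained least squares (fractions ≥ 0,
summing to 1; Houseman-style constrained projection), solved per sample
with SLSQP.  The reference profiles are an input; a synthetic six-type
reference (neutrophil, CD4 T, CD8 T, B, monocyte, NK at realistic base
proportions) ships with the generator.

## Differential methylation (DMP)

Each probe's M values are regressed on an intercept, a patient/control
indicator, and K − 1 cell-fraction covariates (one type dropped against the
intercept).  Residual variances s²_g with d_g degrees of freedom are
moderated toward a scaled inverse-chi-square prior (d₀, s₀²) estimated by
the method of moments on log s²_g (digamma/trigamma inversion); the
posterior variance is s²_post = (d₀ s₀² + d_g s²_g) / (d₀ + d_g) and the
moderated t has d₀ + d_g degrees of freedom (capped at 10⁶ when d₀ = ∞,
which legitimately occurs when probe variances are homogeneous — e.g. in
simulations with a single global noise level).  Probes with s_g = 0 take
their variance entirely from the prior; there is no ad-hoc floor.  The
implementation is cross-checked in the test suite against Bioconductor
limma on a fixture.

P values are two-sided (both hypo- and hypermethylation are biologically
expected) and Benjamini–Hochberg adjusted.  A probe enters the epi-signature
when adjusted p < 0.01 **and** |Δβ| > 0.10, where Δβ is the difference of
group mean betas (not a back-transformed coefficient — the simplest
definition consistent with reporting effects on the beta scale).

The signature's ability to separate groups is summarized by two-way
hierarchical clustering (Euclidean distance, average linkage) purity over
patients and controls; carriers are reported by cluster assignment but kept
out of the purity.

## Region detection (DMR)

Probes are grouped per chromosome into clusters with inter-probe gaps of at
most 500 bp (a gap of exactly 500 stays in the cluster).  Candidate regions
are maximal same-sign runs of at least three consecutive probes with
|Δβ| > 0.10; no smoothing is applied to the per-probe effects (planted and
biological regional effects are locally coherent, and the raw-effect rule is
reproducible).  Each region carries its probe count, signed mean difference,
and area (Σ|Δβ| over members).

Significance is a family-wise error rate from a residual bootstrap with
B = 1000: residuals are taken from the **full** model fit (they are
exchangeable under the null and carry no group effect — taking them from the
null fit would leak the group effect into the resampled noise and inflate
the null at signal probes), resampled over samples with one shared resample
per iteration, and added to the null-model fitted values; group beta
differences and candidate regions are recomputed and the maximum region
area recorded.  Then fwer = (#{max null area ≥ observed area} + 1) / (B + 1),
so the smallest attainable value at B = 1000 is 1/1001 ≈ 0.001.  Regions are
reported at fwer < 0.01 with ≥ 3 probes and |mean difference| > 0.10.  The
area was chosen over probe count as the null statistic because it combines
width and amplitude; both the statistic and B are configurable.

Coordinates are 1-based inclusive internally (width = end − start + 1);
BED output converts to 0-based half-open.  Gene annotation is optional and
driven by a user-supplied BED (overlap, or a TSS within 2 kb downstream);
CpG-island distance is the distance to the nearest island-annotated probe.

## Classification

From the epi-signature, feature selection first keeps probes whose
direction-folded ROC AUC for patients vs controls is 1 (complete
separation); carriers are deliberately excluded from this step, entering
only at model training.  Redundant probes are then pruned: while any pair
has |Pearson r| > √0.8 ≈ 0.894, the member of the most-correlated pair with
the larger mean absolute correlation to the remaining probes is dropped
(ties resolved toward keeping the earlier probe id), leaving a deterministic
non-redundant panel.

A three-class RBF-SVM is trained on the standardized beta values of the
surviving probes.  Hyperparameters are chosen over C ∈ {0.1, 1, 10, 100}
and γ ∈ {1/p, 0.01, 0.001} by stratified tenfold cross-validation scored as
pooled held-out accuracy; ties prefer the smallest C, then the smallest γ.
Because the carrier class (n = 6) is smaller than the fold count, folds are
built by per-class round-robin assignment: the fold count stays at 10, some
folds simply contain no carrier, and a warning is emitted.  Probability
scores come from one-vs-one decision values with sigmoid (Platt)
calibration coupled into class probabilities; they lie in [0, 1] and sum to
1 per sample.  The predicted class is the argmax, and samples whose top
score falls below 0.5 are flagged ambiguous.  Features are beta values by
default (M values are configurable); class imbalance (56 controls) is left
unweighted by default.

Specificity is evaluated by scoring an external cohort (controls plus
samples carrying an unrelated methylation disturbance) and reporting the
percentage predicted control.

## Cohort splitting

Patients and carriers are split 75% / 25% into training and testing by
stratified random draw with floor rounding — floor(0.75 · 10) = 7 training
patients and floor(0.75 · 8) = 6 training carriers — and all matched
controls stay in training.  Control matching itself is out of scope here
(simulated cohorts are matched by construction); a greedy nearest-age
matcher would slot in where the sample sheet carries ages.

## The synthetic-data generator

The generator's defaults are the study conditions: 7 patients, 6 carriers,
56 controls; planted per-probe effects and nine planted regions whose
spans, signed differences (eight hypo-, one hypermethylated, magnitudes
0.245–0.333) and probe counts (3–8, consistent with the spans under the
500 bp gap rule) mirror the reported region geometry; carriers express
exactly half the patient effect by default (the carrier factor λ is a
modeling choice — the underlying gene escapes X inactivation, so a
heterozygous carrier plausibly expresses an intermediate dosage — and is
configurable in [0, 1]).

Control methylation per probe is drawn from a bimodal mixture (45% low
mode near 0.1, 45% high mode near 0.9, 10% intermediate), which passes the
QC bimodality check by construction.  Sample betas are logit-normal:
β = logistic₂(M_group + ε), ε ~ N(0, noise_sd²) in M units, with
noise_sd = 0.35 by default.  The logit-normal choice keeps β↔M transforms
exact (at noise 0 the sample equals its group mean bit for bit) and makes
the carrier invariant — carrier shift = λ × patient shift on the beta
scale — hold exactly.  Blood mixing is emulated at dedicated marker probes
where the six cell-type profiles differ; per-sample fractions are
Dirichlet-drawn around realistic blood proportions (concentration 60), and
an optional confounded mode correlates fractions with case status to
exercise the adjustment.  chrX probes get sex-specific means so the sex
check has signal.  All draws derive from one seed through fixed per-stage
substreams; identical configurations are bitwise reproducible.

External cohorts reuse the same per-probe ground state and add an
"other-disorder" signature planted on background probes disjoint from both
the trained signature and the cohort's own planted probes (magnitudes
0.15–0.35, directions toward mid-methylation).

**What the generator does not emulate** — probe-chemistry differences
(Infinium type I/II), batch and chip effects, age- or family-structure
effects, spatial correlation of background noise, and real genomic
annotation.  Passing tests therefore demonstrate correctness of the
pipeline's logic and its recovery behavior under the stated noise model,
not performance on real arrays; in particular, real per-probe biological
variance is larger and more heterogeneous than the single logit-normal
noise scale used here.

## Problem sizes and numerical choices

The acceptance script uses the full stated problem sizes — a 20 000-probe
genome for region detection with B = 1000 bootstraps, 21 769 probes for
per-probe recovery, 1 087 external samples — and completes in well under a
minute; module tests use smaller genomes (300–4 000 probes) and B = 150–200
where only the logic, not the resolution, is under test.  A power note on
per-probe recovery: at noise_sd 0.35 and n = 7 vs 56, the patient group
mean of β has a standard error near 0.02, so planted probes at the bottom
of the magnitude range (|Δβ| = 0.12) occasionally miss the strict
|Δβ| > 0.10 observed-effect gate; recovery of a 1 769-probe planted
signature is therefore expected around 99%, with essentially no false
positives (the dual gate makes the background contribution negligible).

Other numerical details: the trigamma inversion in the prior fit uses
Newton iteration to relative 10⁻¹⁰; BH adjustment delegates to statsmodels
and is property-tested against a literal step-up oracle; the constrained
projection runs SLSQP to ftol 10⁻¹²; SVM probability calibration is seeded,
making training and scoring deterministic; model JSON serialization stores
the fitted support vectors, dual coefficients and calibration constants and
reproduces predictions exactly on reload.

## Known limitations

* The bimodality and sex heuristics use fixed thresholds appropriate for
  genome-wide 450k-like data; small targeted panels would need retuning.
* The moderated-t prior assumes a common residual d.f. across probes (true
  here, where one design fits all probes).
* The bootstrap FWER is valid for the maximum-area statistic under the
  fitted linear model; strong unmodeled covariates would require extending
  the design.
* With very small carrier classes the Platt-calibrated probabilities are
  crude (few calibration points); argmax predictions are robust but the
  0.5 ambiguity cutoff should be read conservatively.
* Feature pruning on strongly group-structured data can collapse hundreds
  of separating probes to a small panel; this is by design (the retained
  panel carries the non-redundant information) but the panel size is not a
  stable quantity across noise levels.
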