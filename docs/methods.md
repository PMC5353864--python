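# Methods

This note records the models, numerical choices, and design decisions behind
each stage of the pipeline, and what the synthetic cohorts do and do not
emulate.

## Synthetic cohorts

**Concentrations.** Each cohort group draws every metabolite independently
from a zero-truncated Gaussian with the group's published mean and SD
(nmol/mg). The truncated density is sampled exactly through the probability
transform rather than by clamping, which would pile probability mass at
zero. A Gaussian copula option adds within-pathway correlation (default 0:
the source tables report no covariance). Tissue weights are uniform on
15–20 mg, the analytic range of the emulated protocol. The packaged designs
transcribe the published group tables verbatim, including their internal
inconsistencies (the survivor table duplicates the chemotherapy table's
columns; two tables disagree on a few PA values); the design files flag
this in comments but do not "correct" it.

**Spectra.** Each resonance contributes a Lorentzian at its assigned shift
with integrated area `response_factor · nmol · n_protons`; glucose is split
over its anomer peaks at the α:β = 0.36:0.64 aqueous equilibrium. Defaults:
half-width at half-maximum 0.001 ppm (0.5 Hz at 500 MHz — an idealized,
resolution-enhanced line), 262 144 points over 0.20–8.00 ppm (≈ 4 points
per half-width, enough for accurate trapezoidal peak integrals), optional
smooth Gaussian-hump baseline and white noise. By default only the
designated quantification peaks are rendered; `quantify_peaks_only=False`
renders all 61 assigned groups, which reintroduces the real-world overlap
(e.g. creatine CH₂ and a glycerophosphocholine resonance share 3.93 ppm)
that the designated-peak selection exists to avoid. The generator does not
simulate J-coupling multiplets, phase/shim artifacts, water residuals, or
T₂ attenuation — so passing recovery tests show correctness of the
quantification arithmetic under the stated line model, not robustness to
those real-data effects.

**Survival.** Exponential times per outcome group (defaults: mean 60 months
for long-term, 8 for short-term, censoring probability 0.1). Because the
long/short labels are by definition assigned from the observed outcome
(> 3 years / < 1 year), labelled draws are truncated to the defining window
(long via memorylessness, short via inverse CDF); unlabeled samples get the
plain exponential, which is what the closed-form median check exercises.

## Bucketing

Trapezoidal integration on the native grid over left-closed 0.01-ppm
buckets between 0.70 and 7.50 ppm (680 buckets; the final bucket is closed).
Implementation inserts the bucket boundaries into the grid and differences
the cumulative trapezoid, so the bucket sum telescopes exactly to the
whole-range integral. Only weight normalization is applied — no total-area
scaling, phasing, alignment, or solvent exclusion, since the emulated
processing chain reports none.

## Peak integration and PULCON quantification

Windows are centered on the assigned shift with half-width 0.004 ppm. A
local linear baseline through two anchor points just outside the peak core
is subtracted; each anchor is the average of the median-smoothed (5-point
running median) intensities in a ±0.0025 ppm slice around the window edge.
Averaging, rather than taking the slice median outright, keeps the anchor
unbiased under point noise: the slice overlaps the skewed inner tail of the
peak, and a median of skewed-signal-plus-noise is pulled toward the tail
mean, which measurably biased small metabolites at realistic noise levels.
The anchor lies exactly on any locally linear signal, so constant offsets
and linear drifts integrate to zero.

The window captures a fixed fraction of a Lorentzian's area and the
baseline subtracts a fixed fraction of its own tails; both fractions cancel
in the PULCON ratio because the reference peak has the same lineshape. The
half-width and linewidth defaults were chosen together, from closed-form
Lorentzian tail integrals, so that the closest pair of designated peaks
(lactate CH at 4.13 vs phosphorylcholine CH₂-O at 4.11, 0.02 ppm apart)
cross-contaminate by well under 1 % at typical concentration ratios; wider
windows or broader lines break this (at 0.01 ppm half-width the
phosphorylcholine error reaches tens of percent). Because the leak is a
fixed absolute amount proportional to the lactate peak, the *relative*
error on phosphorylcholine is unbounded as its concentration approaches
zero — recovery bounds are therefore stated at the published mean profiles
and, for random cohorts, as median errors. Negative window integrals clamp
to zero with a warning (concentrations are physical). The known ~20 %
underestimation of intact-tissue quantification versus extraction is
documented here and deliberately not corrected; reported values follow the
uncorrected convention. Proton counts per group are fixed from chemical
structure (they are not printed in assignment tables); the bold-group
count, not a per-metabolite total, enters the correction.

## OPLS-DA

Unit-variance scaling by default (Pareto and centering available — the
emulated software's default is UV and the source does not state it); the
encoded class is centered. Orthogonal components are removed sequentially
by the standard orthogonal-filtering construction (w ∝ Xᵀy; w_o ∝ p −
(wᵀp)w), then a single predictive PLS component is fitted; "bi-component"
is read as 1 predictive + 1 orthogonal, the default. Orthogonal scores are
uncorrelated with the class by construction (asserted to 1e-8). With no
orthogonal components the model is exactly single-component PLS1 (verified
against an independent implementation). Q² uses stratified, seeded 7-fold
cross-validation, with PRESS over held-out encoded labels and the global
class variance as denominator; folds re-stratify with a shifted seed in the
degenerate case of a one-class training split. The predictive weight is
oriented so positive loadings mean "higher in the class encoded 1"
(adenocarcinoma in the tissue contrast).

## Univariate tables

Two-sided Mann-Whitney U per metabolite, U reported as min(U₁, U₂). Exact
enumeration for tie-free comparisons with combined n ≤ 20 — covering the
9-vs-8 survivor and chemotherapy contrasts, the regime where the emulated
analysis (R's wilcox.test) is also exact — and the tie- and
continuity-corrected normal approximation otherwise. Means ± SD print with
4 decimals to mirror the published tables. No multiple-testing correction
is applied, mirroring the emulated analysis; the output carries an explicit
"uncorrected" column.

## Network direction analysis

The unit of inference is the pathway group, not the single metabolite: the
12 packaged group comparisons are scored by the mutual information between
the group's joint concentrations and the binary condition. The estimator is
the k-nearest-neighbor estimator for continuous-vs-discrete data (distance
to the k-th same-class neighbor, neighbor counts in the pooled sample,
digamma formula; k = 3), computed on column ranks so it is near-invariant
under monotone transforms. Integer ranks tie heavily under the Chebyshev
metric, so a deterministic sub-rank perturbation (10⁻⁶·tanh of the
z-score) breaks ties as a function of the data alone — making estimates
exactly invariant to sample order and to swapping the case/control labels.
Significance is a label-permutation p-value (default 1000 shuffles,
α = 0.05), vectorized over permutations. A metabolite belonging to at least
one significant group is called "increase"/"decrease" when its case–control
mean difference exceeds 0.1 pooled SD, else "stable". The source algorithm
is specified only through its inputs and outputs; these concrete choices
(estimator, permutation null, mean-difference direction rule) are this
package's reimplementation decisions, not a claim about the original's
internals. The packaged network adjacency is a minimal literature-style
pathway graph, connected over the 18 quantified metabolites, shipped as an
editable text file; the group list, not the adjacency, drives the
analysis.

## Survival biomarker

The ROC positive class is the short-term survivor; for ethanolamine high
values predict it (equivalently, low ethanolamine predicts long-term
survival). AUC is the trapezoidal integral over the threshold sweep and
equals the tie-half-weighted pair count exactly; its standard error uses
the Hanley–McNeil formula (reported, not targeted). "Optimal threshold"
means Youden-J maximization with ties broken toward higher specificity and
the cut reported as the midpoint between adjacent observed values;
predictive values are computed at the sample prevalence. Kaplan-Meier
estimation and the log-rank test are delegated to lifelines behind this
module's interface and cross-checked in the tests against a hand-rolled
hypergeometric risk-table oracle. Stratum "superiority" in the simulation
checks is judged by restricted mean survival time (area under the KM curve
to the common follow-up horizon): strict pointwise dominance at every event
time is fragile to a single misclassified sample at realistic biomarker
separations, while RMST captures the clinically meaningful ordering.
Degenerate strata (fewer than 2 samples) produce a report with a warning
and no log-rank p.

## Problem sizes

The simulation suites run at the study's own group sizes (9 vs 44 tissue
samples, 8 vs 9 survivors). Replicate counts — 500 for test calibration,
power, and the pair-count identities; 200 for noisy-recovery cohorts and
biomarker detection; 100 for the OPLS gate; 50 for planted-signal network
recovery — were chosen to estimate the corresponding rates to a few
percent while keeping the full acceptance run within a few minutes on one
CPU.

## Known limitations

Quantification assumes resolved designated peaks; it does not deconvolve
overlapping multiplets, and rendering all assigned resonances (rather than
the designated peaks only) degrades creatine and phosphorylcholine recovery
by design. Published patient-level endpoints (Table-level p-values, the
printed R²Y/Q², AUC 0.861, the 0.740 nmol/mg ethanolamine threshold) are
non-recomputable without the undeposited spectra; the published sensitivity
77.8 % and specificity 75.0 % correspond to a 7/9–6/8 confusion structure,
which the threshold logic reproduces on a fixture built to it, and the
published PPV/NPV pair is arithmetically inconsistent with those rates at
the study prevalence and is not reproduced. The ¹³C shifts are carried as
annotations but unused.
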