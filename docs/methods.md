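# Methods

## The classification model

A tumor's CMS-resembling label is assigned hierarchically.  The
mismatch-repair gate fires first: dMMR (loss of any of MLH1, MSH2,
PMS2, MSH6, consumed as a boolean input — the package does not
interpret MMR stains) maps to CMS1-like regardless of the marker
panel.  Remaining tumors are voted spot by spot: each evaluable TMA
spot's five-marker panel is scored by a logistic model

P(epithelial) = logistic(β₀ + Σⱼ βⱼ xⱼ)

over the integer intensities (CDX2, FRMD6, HTR2B, KER; 0–3), the exact
percentages (CDX2, FRMD6, KER; 0–100) and a ZEB1 presence indicator
(percent ≥ 2; sub-threshold staining is treated as a potential false
positive and suppressed, and the boundary value 2.0 counts as
present).  The majority call over the 1–4 spots decides CMS2/3-like
vs CMS4-like; an exact tie leaves the patient unclassified rather than
forcing a call.  Patients with 1–3 evaluable spots are voted over what
is available — only ties and missing data exclude.  Finally, the
β-catenin consensus (per-spot positive iff nuclear intensity ≥ 2 or
percentage category ≥ 2, majority over spots, tie → unclassified)
splits CMS2-like (positive) from CMS3-like (negative).

The source classification tool for the epithelial/mesenchymal step is
an external web calculator whose fitted coefficients are not public.
The model here is therefore *pluggable* (`ClassifierModel`): the
default fixes the biologically determined signs — CDX2 and KER push
epithelial; FRMD6, HTR2B and ZEB1 push mesenchymal — with magnitudes
(intensity coefficients ~1, percentage coefficients ~0.03, ZEB1
presence −2, intercept 0) calibrated once against the synthetic
generator's well-separated phenotypes and then frozen.  Decision
threshold 0.5; a spot probability exactly at the threshold is called
epithelial (deterministic, documented, configurable).

Continuous intensities are rounded to integer scores with the scoring
convention 0–0.499 → 0, 0.5–1.499 → 1, 1.5–2.499 → 2, 2.5–3 → 3;
rounding happens at classification time so the regression-then-round
flow is exercised explicitly.

## Image quantification

Spot images are modeled as two-stain Beer–Lambert absorbers: per-pixel
optical density OD = −log₁₀(I/255) decomposes in least squares onto
fixed hematoxylin (0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776)
unit vectors, clipped at zero.  Epithelium is segmented by thresholding
the hematoxylin density at 0.45 OD (between the generator's stromal
0.25 and epithelial 0.70), OR-ing in DAB-positive pixels (DAB can mask
hematoxylin), followed by binary closing/opening and removal of
components under 32 px.  Intensity is the mean DAB density over
*positive* pixels only (density > 0.12 OD) divided by the calibration
constant 0.35 OD per intensity unit, clipped to [0, 3] — averaging over
positive pixels keeps intensity independent of the positive fraction.
Percent positive is the fraction of the compartment above the same
0.12 OD cutoff.  Both the 0–3 calibration and the positivity cutoff
are contract choices (the original cloud models' internal scaling is
not published); they are shared with the generator so the round trip
is exact in the noiseless limit.

Exact recovery of the rounded score is only well-posed away from the
half-integer bin boundaries: at a true level of exactly 1.5 an
arbitrarily small quantization bias flips the bin.  The default
synthetic level is therefore mid-bin (2.0).

Marker conventions: CDX2 and FRMD6 report intensity + percent, HTR2B
intensity only, ZEB1 percent only (presence is decided downstream),
KER intensity + percent over the epithelium estimate, β-catenin
nuclear intensity + percent.

## The synthetic cohort generator

The generator defines the study conditions for every test; its
defaults are fixed once:

* **Prevalence** (0.158, 0.349, 0.385, 0.108) for CMS1–4-like — the
  classified-cohort distribution of the reference association table.
* **Marker distributions**: truncated normals on the 0–3 / 0–100
  scales.  CMS1/2/3-like share the epithelial phenotype (CDX2
  2.4 ± 0.35, 82 ± 8 %; KER 2.3 ± 0.35, 80 ± 8 %; FRMD6 0.6 ± 0.35,
  15 ± 8 %; HTR2B 0.5 ± 0.3; ZEB1 0.5 ± 0.5 %), CMS4-like the converse
  (CDX2 0.7, 20 %; KER 1.2, 40 %; FRMD6 2.3, 70 %; HTR2B 2.2; ZEB1
  12 ± 6 %).  A patient-level latent draw plus independent per-spot
  noise (intensity SD 0.2, percent SD 4) is the simplest mechanism
  that produces discordant spots and exercises the majority vote and
  its ties.  No real-data estimate of inter-spot discordance exists,
  so these noise levels are calibration choices.
* **β-catenin**: per-subtype categorical distributions giving a
  per-spot positive probability ≈ 0.96 for CMS2-like and ≈ 0.10
  elsewhere, so the positive consensus concentrates on CMS2-like and
  tied consensuses stay rare (a per-spot probability near 0.3 would
  make one patient in four inconclusive with four spots — unrealistic
  against a ~90 % classified fraction).
* **MMR deficiency**: probability 1 for CMS1-like, 0 otherwise by
  default (degenerate gate); configurable for misclassification
  studies.
* **Covariates** (age group, sex, stage, pT, pN, grade, location,
  histology) are drawn from cohort-level marginals *independently of
  subtype*, so association scans are null by construction and their
  size can be checked; pM = 1 iff stage IV is enforced.
* **Survival**: Weibull proportional hazards (default shape 1 =
  exponential), baseline hazard 0.08 / year for the CMS2-like
  reference (≈ 67 % five-year survival), per-subtype log hazard ratios
  (0.45, 0, 0.37, 0.37) matching the magnitude of reported
  univariable effects, follow-up horizon 15 years.  `censoring_rate`
  is a *target marginal censored fraction* (default 0.15): an
  independent exponential censoring rate is solved numerically
  (Brent) to achieve it, plus administrative censoring at the
  horizon.  A value ≥ 1 withdraws every subject uniformly before any
  event — the degenerate all-censored cohort.  Disease-specific
  events are a Bernoulli(0.7) subset of deaths; no competing-risks
  mechanism is claimed.

Synthetic images are a circular tissue disc (radius 0.9 of the half
frame, 200 nm/pixel nominal) with stromal hematoxylin 0.25 OD,
epithelial blobs at 0.70 OD, and a smooth random sub-region of the
epithelium thresholded at the exact quantile that realizes the target
positive fraction; DAB OD is 0.35 × level on positive pixels, plus
Gaussian RGB noise (SD 2 of 255 by default).  Annotator variation is
emulated by adding a smooth unit-variance field scaled by the jitter
(pixels) to the mask's signed distance transform and re-thresholding;
jitter 0 is the identity.

What the generator does **not** emulate: nuclei, texture, scanner
artifacts, stain variation between laboratories, spatially correlated
marker heterogeneity, subtype-covariate association, or informative
censoring.  Tests passing on this generator demonstrate that the
pipeline's arithmetic and decision rules are correct under the stated
model — not that the classifier would reach any particular accuracy on
real tissue.

## Association testing

Conditional tests on r×c tables with both margins fixed.  Table
probabilities are multivariate hypergeometric (computed in log space
via gammaln).  Two two-sided orderings are implemented:

* **probability-mass** (Freeman–Halton): p sums probabilities of
  tables no more probable than observed — the classical r×c
  generalization of Fisher's exact test and the package default;
* **pearson**: p sums probabilities of tables whose Pearson X² is at
  least the observed — the ordering used by the chi-square row of
  common clinical statistics software's exact/Monte-Carlo modules.

The packaged reference association table is reproduced by the Pearson
ordering, not by the probability-mass ordering, so the reporting
routines (`table1_report`, the CLI, the acceptance script) default to
`ordering="pearson"`; both remain available.

Exact enumeration covers 2×c (and r×2 via transposition, p being
transpose-invariant) within a 10⁸-candidate guard; larger tables use
Monte-Carlo with tables sampled by the Patefield algorithm
(`scipy.stats.random_table`), 10⁶ replicates and a fixed seed by
default, with an add-one estimator keeping p in (0, 1].  Probability
and statistic comparisons carry a 10⁻⁷ relative tie slack so float
ties do not make p platform-dependent.  Degenerate tables (a single
non-empty row or column) return p = 1.

## Survival analysis

*Kaplan–Meier*: product-limit estimates at distinct event times;
Greenwood variance; 95 % CIs as S·exp(±1.96·√Σd/(n(n−d))) (log scale)
clipped to [0, 1].

*Log-rank*: k-sample observed-minus-expected statistic over pooled
event times with the hypergeometric covariance, chi-square with k−1
degrees of freedom; for k = 2 this equals the squared standardized
O−E statistic.  Undefined (NaN) when no events exist.

*Cox*: Newton–Raphson with step-halving on the Efron-corrected partial
likelihood (registry survival times in years carry ties; Efron is the
accepted default of modern software).  Covariates are centered for
numerical stability; constant covariates and designs with more
covariates than events are rejected; |β| > 15 triggers a separation
warning; non-convergence within 100 iterations is flagged and warned.
Inference is Wald (HR with 95 % CI and p per level), matching the
HR (CI) + p presentation convention.  The implementation is verified
against a brute-force partial-likelihood grid oracle on ≤ 20-subject
data (10⁻⁴ agreement) and cross-checked against lifelines on tied
data (10⁻⁶ agreement).

*Enter method*: every candidate covariate is fit alone (categoricals
reference-coded; the subtype factor uses CMS2-like — the
best-prognosis group — as reference); a covariate with **any** level
at Wald p ≤ 0.05 enters the joint multivariable fit, which is not
further refined.  An empty selection skips the multivariable step.

*Schoenfeld diagnostics*: scaled residuals β̂ + m·V̂·(xᵢ − x̄(tᵢ)) at
the m event times (Efron-consistent risk-set means), Pearson
correlation of each covariate's residuals against transformed time
with its p-value.  The default time transform is 1 − S_KM(t⁻)
(left-continuous KM), which is robust to heavy censoring; raw time is
available.  Plot helpers render KM curves and residual scatters.

## Problem sizes used in the checks

Acceptance-level checks run at: exact enumeration or 10⁶ Monte-Carlo
tables per contingency table; Cox recovery at n = 2000 with ≈ 30 %
censoring (single designated fit plus 100-simulation CI coverage);
log-rank size at 1000 null simulations of 100 + 100 subjects;
Schoenfeld calibration at 100 simulations of n = 300; image round
trips over 50 seeded 256×256 spots; end-to-end recovery on a 1000-
patient cohort; association-scan calibration over 200 cohorts of 200
patients.  These sizes make every stochastic bound a ≥ 3-standard-
error statement under the stated model.

## Known limitations

* The epithelial/mesenchymal model is sign-faithful but not the
  original fitted calculator; absolute spot probabilities are not
  comparable to the source tool's.
* The reported association p-values of the reference table are
  reproduced by the Pearson-ordered exact test for seven of nine
  covariates at printed precision; the stage and grade rows match the
  asymptotic Pearson p instead and differ from any exact ordering by
  ~0.001–0.006 — consistent with the original analysis printing
  asymptotic chi-square values for some rows.
* Cohort-level survival figures (five-year OS percentages, cohort
  hazard ratios) require patient-level data that are not deposited;
  the survival machinery is validated by parameter recovery and
  calibration on synthetic cohorts instead.
* Disease-specific survival uses a configurable cause-attribution
  probability, not a competing-risks model.
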