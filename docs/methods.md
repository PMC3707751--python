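# Methods

## Model

All survival modelling uses the Cox proportional-hazards model
λ(t|x) = λ₀(t)·exp(Σⱼ xⱼβⱼ) with an unspecified baseline hazard and
coefficients estimated from the log partial likelihood l(β). Two
right-censored outcomes are handled throughout: overall survival (time
from diagnosis to breast-cancer death) and disease-free survival (time
to recurrence). Patients recorded as never disease-free are excluded
from recurrence models but retained for mortality; no value is ever
imputed (complete-case analysis per model).

### Ties

Unpenalized fits default to the Efron approximation for tied event
times, the standard in general-purpose survival software; penalized
fits use Breslow, matching the convention of the penalized-Cox software
family this pipeline's selection stage mirrors. Both are selectable for
unpenalized fits, and the two agree exactly on tie-free data. Expected
differences on hazard ratios at this cohort scale are within ±0.02.

### Unpenalized fitting

Newton–Raphson with step-halving on the log partial likelihood;
convergence when the log-likelihood change falls below 1e-9 (at most 50
iterations). Standard errors come from the inverse observed
information; hazard ratios are exp(β) with exp(β ± 1.96·SE) intervals.
Monotone likelihood (perfect separation of event order by a covariate)
is made visible, not looped on: coefficients are capped at |β| ≤ 15 and
flagged per-coefficient as divergent. Constant covariates and singular
information matrices raise errors.

### L1-penalized fitting

The penalized objective is l(β) − λΣⱼ|βⱼ| (unnormalized likelihood, so
λ is on the score scale; λ_max = max |score at β=0| is the smallest
penalty with an all-zero solution). It is maximized by proximal Newton:
each outer iteration forms the exact quadratic model of l (gradient and
observed information), an inner cyclic coordinate descent with
soft-thresholding solves the penalized quadratic, and step-halving
against the true penalized objective makes the outer sequence
monotone. Convergence is declared when the largest coefficient change
over an outer iteration falls below 1e-7 (inner sweeps capped at 1000
in total); a fixed point satisfies the exact KKT conditions, which the
test suite checks directly and against a generic convex optimizer. The
earlier diagonal-curvature (working-response) formulation was dropped
because its linear convergence was impractically slow on the strongly
intercorrelated expression block; the exact-Hessian version is cheap at
panel sizes of tens of genes.

Covariates are not standardized internally by default — the expression
matrix is already on a common log2 scale — but a flag standardizes and
back-transforms.

### Penalty choice

10-fold cross-validation with folds stratified on the event indicator
(a fold with zero events is re-drawn once, then an error). The
criterion is the Verweij–van Houwelingen cross-validated partial
log-likelihood, Σₖ [l_full(β̂₋ₖ) − l_train,₋ₖ(β̂₋ₖ)], evaluated on a
descending 50-point log-spaced grid from λ_max to λ_max·10⁻³; the
chosen λ maximizes it (ties resolve to the larger penalty). On null
data this maximum-CV rule is known to admit small spurious models with
appreciable frequency, increasingly so as the panel grows — at p = 5
the null model wins in well over 80% of runs, at p = 32 in roughly
three quarters. That liberality is intrinsic to predictive CV and is
precisely what the permutation threshold of the stability-selection
stage corrects at the signature level.

## Stability selection and the permutation threshold

Each replicate splits the cohort 70/30, stratified so train and test
match on tumor-stage composition: per stratum (missing stage is its own
stratum), training counts are allocated by largest-remainder rounding
toward a total of round(0.7·n); strata of size one go wholly to
training with a warning. On the training half a CV-tuned L1 Cox fit is
made and the genes with nonzero coefficients recorded with their
coefficients. Counts are tabulated over (by default) 1000 splits.

The null reference repeats the identical procedure — permute, one
split, one CV, one fit — on data whose (time, event) outcome pairs have
been jointly shuffled across patients (for recurrence, the
never-disease-free flag travels with the pair so the exclusion rule
stays coherent). Patients keep their stage, so the stratified split
structure is preserved under permutation. Running the permutation as
one fit per replicate keeps observed and null counts on the same scale;
a full-pipeline-per-permutation variant would be three orders of
magnitude costlier for the same threshold estimand. The significance
threshold is the highest per-gene total count across permuted
replicates, and observed counts must be *strictly greater* — with 32
genes this corresponds to an empirical per-gene error rate of about
1/32. An alternative null that shuffles whole expression rows instead
of outcomes is available as a switch.

Signature assembly removes significant genes with inconsistent
coefficient signs: a gene is ambiguous when neither sign accounts for
at least 90% of its nonzero retained coefficients. The 90% fraction is
a package choice (no numeric rule exists in the literature the
procedure descends from); it is configurable.

## Model comparison

The comparison stage uses fixed covariate sets with no re-selection:
the gene signature, the clinical set (stage as a 1 / 2 / 3-or-4
three-level factor, ER and PR negativity as binary indicators), and
their union. Rows are restricted up front to complete cases on the
outcome and the clinical covariates, so the three models see identical
patients and per-split C-index differences are paired. Per split, each
model is fitted to the training half and evaluated on the test half by
Harrell's C for right-censored data: over pairs in which one subject
demonstrably fails first (earlier time is an event, or tied times with
exactly one event — the event subject is taken to fail first),
concordant risk orderings score 1, tied risk scores 1/2. Summaries are
medians with empirical 2.5th/97.5th-percentile intervals; paired
differences get percentile intervals of the per-split differences.
ER+/ER− subgroup C-indexes reuse the all-patient training fits. Test
patients are classed low/high risk at the median training linear
predictor (scores strictly above the median are high), and per-class
Kaplan–Meier curves (delegated to lifelines) are retained for the
overlay figures. A random-gene comparator draws size-k gene sets anew
at each split as a reference distribution, and a probe-collapse utility
(keep the most variable probe per gene; ties keep the first in input
order) prepares microarray-style external cohorts.

## Synthetic cohorts

The generator emulates the cohort structure the pipeline assumes, not
any particular dataset's joint distribution.

- **Expression.** 32 genes, means set to the observed per-gene log2
  medians and SDs to observed IQR/1.349 (median SD ≈ 1.8, mean IQR ≈
  3.0). Correlation is a single-factor block model: PGR, ESR1, NAT1,
  SLC39A6, TBC1D9, LRBA load 0.60–0.80 on a latent factor (pairwise
  correlations ≈ 0.39–0.64), GABRP loads −0.35 (≈ −0.28 to −0.21
  against the block). Any |loading| < 1 keeps the implied covariance
  positive definite, which is why the factor form was chosen over a
  free correlation matrix. The factor is partly determined by ER status
  (weight 0.7), so block genes shift up in ER+ patients and GABRP in
  ER− patients (e.g. corr(ER, NAT1) ≈ 0.56, corr(ER, GABRP) ≈ −0.24).
- **Outcomes.** Event times are exponential with rate
  λ₀·exp(linear predictor); censoring is the minimum of an exponential
  (rate 0.007/month) and a 180-month administrative horizon. Baseline
  rates (0.0013/month mortality, 0.0015 recurrence) were calibrated
  once so the defaults hit the design conditions: ≈30% events and
  ≈60-month median follow-up (62.5 and 55.5 months for the two outcomes
  at large n), with the event fraction staying within 0.2–0.4 across
  seeds at n = 225.
- **Planted effects.** Default per-log2-unit log-hazards: PGR −0.10,
  GABRP −0.07, TBC1D9 −0.08, SLC39A6 −0.10 (recurrence additionally
  NAT1 −0.08) — hazard ratios ≈ 0.90–0.93 per doubling. LRBA is
  deliberately constructed as 0.6·factor + residual, with the
  *residual* carrying +0.18: marginally LRBA looks null (its protective
  correlation with the block cancels the hazardous residual) while the
  residual-adjusted Cox fit recovers HR > 1 — the sign-flip phenomenon
  the diagnostics module exists to expose.
- **Clinical covariates.** Stage (0.22/0.62/0.12/0.03), ER/PR joint
  (0.57/0.07/0.13/0.23), node positivity increasing with stage, grade,
  treatments, age and size with cohort-like moments; stage and ER/PR
  additionally contribute log-hazards (0/0.6/1.2/1.5 by stage;
  0/0.45/0.45/0.6 by ER/PR class) so clinical-only models are genuinely
  prognostic. Missingness is sporadic and cohort-like (1.8% stage,
  6.2% size, 7.1% nodes, ~3% never disease-free, ~1% recurrence
  records).
- **Randomness.** One master seed; every stage derives child seeds
  through a fixed `SeedSequence([master, purpose, index])` tree, so any
  stage can be regenerated independently and all outputs are
  reproducible byte-for-byte.

What passing tests on these cohorts do *not* show: robustness to batch
effects, non-proportional hazards, non-normal expression margins,
informative censoring, or misrecorded outcomes — none of which the
generator simulates.

## Diagnostics

- **Residual Cox.** OLS of the target gene on the adjusters (with
  intercept; collinear adjusters are an error), residuals into a
  univariate Cox fit, HR per unit residual log2 expression. Residuals
  are exactly zero-mean and sample-orthogonal to adjusters; with no
  adjusters the fit equals the ordinary univariate fit.
- **Interaction scan.** Per gene: main effects plus gene×level product
  terms, Wald chi-square on the interaction block (chosen over a
  likelihood-ratio test for speed and because the two agree at these
  sample sizes; selectable in principle), BH adjustment across genes.
- **Power.** The minimal detectable hazard ratio implements
  log HR = √[(z₁₋α + z₁₋β)² / (D·σ²)] literally, one-sided z₁₋α by
  default (as the formula is printed) with a two-sided option. With
  α = 0.05/32, β = 0.2, D = 68, σ = 1.8 the literal evaluation gives
  HR ≈ 1.29 (one-sided) or 1.31 (two-sided) — not the 1.116 reported
  alongside the formula in the study this design descends from; that
  printed value is not reproducible from the printed inputs under
  either sidedness convention, so it is documented here and not used as
  a reference value anywhere.

## Problem sizes

Resampling defaults are 1000 splits and 1000 permutation replicates.
The shipped tests and the acceptance script use scaled-down runs —
100–200 splits/permutations — which this package treats as its standard
verification sizes; selection percentages and C-index medians at those
sizes carry Monte-Carlo noise of roughly ±3–5 percentage points and
±0.01–0.02 respectively, which the test tolerances reflect.
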