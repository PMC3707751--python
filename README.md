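# coxsig

Discovery and validation of small prognostic gene-expression signatures
for right-censored breast-cancer outcomes.

Given a cohort of breast-carcinoma patients with log2 relative expression
of a candidate gene panel (here 32 genes measured by qRT-PCR), two
censored outcomes — overall survival (time to disease-related death) and
disease-free survival (time to recurrence) — and standard clinical
covariates, the package answers three questions:

1. **Which genes are individually prognostic?** Univariate Cox
   proportional-hazards screening, λ(t|x) = λ₀(t)·exp(xβ), with
   false-discovery-rate control: Benjamini–Yekutieli for the (highly
   intercorrelated) genes, Benjamini–Hochberg for clinical covariates.
2. **Which subset forms a stable multivariable signature?** The log
   partial likelihood is penalized with an L1 term, l(β) − λΣⱼ|βⱼ|, so
   that unimportant coefficients shrink exactly to zero; λ is chosen by
   10-fold cross-validated partial likelihood. This selection is
   repeated over many 70/30 train/test splits stratified on tumor
   stage, counting how often each gene is retained. A significance
   threshold comes from a permutation null: the same split/CV/fit
   procedure applied to outcome-shuffled data, with the highest
   permuted per-gene count as the cut-off (strictly-greater-than rule,
   roughly a 1/32 empirical error rate). Genes whose retained
   coefficient flips sign across splits are dropped.
3. **Does the signature beat clinical information?** Gene-only,
   clinical-only (stage, ER, PR), and combined Cox models are re-fitted
   over repeated stratified splits with *fixed* covariate sets and
   compared by Harrell's C-index on held-out data, with empirical 95%
   percentile intervals of the paired per-split C differences, plus
   low/high risk classes cut at the median training linear predictor.

A synthetic-cohort generator reproduces the data structure this design
assumes — a positively intercorrelated estrogen-receptor-associated gene
block (PGR, ESR1, NAT1, SLC39A6, TBC1D9, LRBA), GABRP anti-correlated
with it, proportional-hazards outcomes at ~30% events and ~60-month
median follow-up, Table-1-style clinical marginals, and sporadic
missingness — so every stage is testable end to end. Residual-adjustment
diagnostics (regress a target gene on a block of correlated genes, feed
the residual to a univariate Cox model) explain sign flips between
marginal and multivariable fits, and a power utility reports the minimal
detectable hazard ratio, log HR = √[(z₁₋α + z₁₋β)² / (D·σ²)].

## Worked example

```python
from coxsig import (SimConfig, generate_cohort, univariate_screen,
                    selection_frequencies, permutation_null, compare_models)

cohort = generate_cohort(SimConfig(seed=7))      # 225 patients, 67 deaths

screen = univariate_screen(cohort, "os")         # per-gene Cox + BY FDR
print(screen[screen["class"] == "gene"].head())

profile = selection_frequencies(cohort, "os", n_splits=100, master_seed=7)
_, threshold = permutation_null(cohort, "os", n_perm=100, master_seed=7)

result = compare_models(cohort, "os", n_splits=100, master_seed=7)
```

The screen reports hazard ratios per unit (i.e. per doubling) of log2
expression; on this cohort the top rows are

```
variable    HR  ci_low  ci_high     p  adj_p
  TBC1D9 0.795   0.737    0.857 0.000  0.000
     PGR 0.835   0.779    0.894 0.000  0.000
    NAT1 0.833   0.777    0.893 0.000  0.000
```

i.e. TBC1D9 over-expression associates with a ~20% drop in mortality
hazard per doubling, significant after dependence-robust FDR
adjustment. Stability selection at 100 splits/100 permutations gives a
permutation threshold of 23 retentions; the planted signature genes
(TBC1D9 100%, PGR 99%, NAT1 99%, GABRP 93%, LRBA 74%) all clear it. The
model comparison prints

```
genes     median C = 0.74  (95% CI 0.61-0.83)
combined  median C = 0.74  (95% CI 0.63-0.82)
clinical  median C = 0.64  (95% CI 0.54-0.74)
combined - clinical: +0.10 (95% CI -0.04 to 0.18)
```

median held-out concordance of each model with its empirical 95%
interval, and the paired difference showing what expression adds over
stage/ER/PR alone on this synthetic cohort.

The same workflow is available from the shell:

```bash
coxsig run --seed 7 --n-splits 200 --n-perm 200 --out results/
coxsig report results/
```

which writes delimited-text tables, JSON summaries, a manifest, and
regenerable figures (C-index boxplots, Kaplan–Meier risk-class overlays
for actual vs permuted data, per-gene coefficient boxplots).

## Layout

- `src/coxsig/cohort.py` — cohort table I/O, ΔΔCt utility, complete-case
  filtering
- `src/coxsig/simulate.py` — synthetic cohort generator and outcome
  permutation
- `src/coxsig/cox.py` — Cox partial likelihood, Newton and L1 coordinate
  descent fitting, CV penalty choice, Kaplan–Meier (sklearn-style
  estimators `CoxPH`, `CoxLasso`, `CoxLassoCV`)
- `src/coxsig/screening.py` — univariate screen with BY/BH adjustment
- `src/coxsig/stability.py` — stratified splits, `StabilitySelector`,
  permutation threshold
- `src/coxsig/evaluation.py` — Harrell's C, risk classes, model
  comparison, probe collapsing
- `src/coxsig/diagnostics.py` — residual Cox analysis, power formula,
  interaction scan
- `src/coxsig/report.py`, `src/coxsig/cli.py` — pipeline orchestration,
  figures, `coxsig` command

See `docs/methods.md` for the statistical details and design choices.
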