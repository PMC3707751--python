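"""Residual-adjustment Cox analysis, study-power formula, and the
gene-by-clinical interaction scan.

The residual analysis explains sign flips between univariate and
multivariable penalized fits: a gene that is marginally null can carry a
real hazard signal once its correlation with a protective gene block is
regressed out (LRBA being the motivating case — marginal HR ~ 1 but
residual over-expression associated with increased risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, complete_cases
from .cox import CoxFit, CoxPH, fit_cox
from .screening import adjust_pvalues, clinical_design

__all__ = ["residual_cox", "PowerParams", "detectable_hr",
           "interaction_scan"]


def residual_cox(cohort: CohortTable, target_gene: str, adjustment_genes,
                 outcome: str) -> CoxFit:
    """Univariate Cox fit of the component of ``target_gene`` not
    explained by ``adjustment_genes``.

    The target is regressed on the adjusters (OLS with intercept); the
    residuals — zero-mean and sample-orthogonal to every adjuster —
    enter a univariate Cox model. The hazard ratio is per unit residual
    log2 expression. With no adjusters this reduces to the ordinary
    univariate fit of the (centered) target.
    """
    adjustment_genes = list(adjustment_genes)
    cc = complete_cases(cohort, outcome, [target_gene] + adjustment_genes)
    y = cc.data[target_gene].to_numpy(float)
    if adjustment_genes:
        A = np.column_stack([np.ones(len(y)),
                             cc.data[adjustment_genes].to_numpy(float)])
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            raise ValueError(
                f"collinear adjusters among {adjustment_genes}")
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
    else:
        resid = y - y.mean()
    t, e = cc.survival(outcome)
    X = pd.DataFrame({f"{target_gene}_residual": resid})
    return fit_cox(X, t, e)


@dataclass
class PowerParams:
    """Parameters of the minimal-detectable-hazard-ratio formula.

    alpha is the per-test type-I error (default Bonferroni 0.05/32 for
    the 32-gene panel), type_ii_error is 1 - power, n_events the number
    of observed events D, covariate_sd the covariate standard deviation
    sigma (log2-expression units). ``sidedness`` chooses z_{1-alpha}
    (one-sided, the formula as printed) or z_{1-alpha/2}.
    """

    alpha: float = 0.05 / 32
    type_ii_error: float = 0.2
    n_events: int = 68
    covariate_sd: float = 1.8
    sidedness: str = "one"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.type_ii_error < 1:
            raise ValueError("type_ii_error must be in (0, 1)")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.covariate_sd <= 0:
            raise ValueError("covariate_sd must be positive")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")


def detectable_hr(params: PowerParams) -> tuple[float, float]:
    """Minimal detectable hazard ratio (and its reciprocal) per unit of
    the covariate: ``log HR = sqrt((z_{1-a} + z_{1-b})^2 / (D sigma^2))``.

    Implements the formula literally; see the methods note for the
    discrepancy between this evaluation and the value printed in the
    originating study.
    """
    a = params.alpha / 2 if params.sidedness == "two" else params.alpha
    za = stats.norm.ppf(1 - a)
    zb = stats.norm.ppf(1 - params.type_ii_error)
    log_hr = np.sqrt((za + zb) ** 2 /
                     (params.n_events * params.covariate_sd ** 2))
    return float(np.exp(log_hr)), float(np.exp(-log_hr))


def interaction_scan(cohort: CohortTable, genes=None, clinical_var: str =
                     "stage", outcome: str = "os",
                     adjust: str = "BH") -> pd.DataFrame:
    """Per-gene Wald test of gene-by-clinical-variable interaction.

    For each gene, a Cox model with main effects for the gene and the
    clinical variable's indicator contrasts plus their product terms is
    fitted; the interaction block is tested with a Wald chi-square on
    the corresponding coefficients, and p-values are FDR-adjusted across
    genes (BH by default). Genes whose model cannot be fitted (e.g. too
    few events within a stratum) are skipped with a warning.
    """
    genes = list(cohort.panel.genes) if genes is None else list(genes)
    rows = []
    for g in genes:
        base = clinical_design(cohort, clinical_var)
        cc_mask = (base.notna().all(axis=1)
                   & cohort.data[g].notna()
                   & cohort.data[f"{outcome}_months"].notna()
                   & cohort.data[f"{outcome}_event"].notna())
        if outcome == "dfs":
            cc_mask &= ~(cohort.data["never_disease_free"].fillna(0) == 1)
        df = cohort.data.loc[cc_mask]
        Z = base.loc[cc_mask]
        X = pd.DataFrame({g: df[g].astype(float)})
        for col in Z.columns:
            X[col] = Z[col].astype(float)
        inter_cols = []
        for col in Z.columns:
            name = f"{g}x{col}"
            X[name] = X[g] * Z[col].astype(float)
            inter_cols.append(name)
        try:
            est = CoxPH().fit(X, (df[f"{outcome}_months"].to_numpy(float),
                                  df[f"{outcome}_event"].to_numpy(float)))
            names = list(est.feature_names_in_)
            idx = [names.index(c) for c in inter_cols]
            beta = est.coef_[idx]
            # Wald block statistic beta' V^{-1} beta ~ chi2(k)
            V = np.linalg.inv(est.information_)[np.ix_(idx, idx)]
            stat = float(beta @ np.linalg.solve(V, beta))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"interaction scan skipped {g}: {exc}")
            continue
        p = float(stats.chi2.sf(stat, df=len(idx)))
        rows.append({"gene": g, "wald_chi2": stat, "df": len(idx), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = adjust_pvalues(out["p"], adjust)
    return out
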