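"""Univariate Cox screening of genes and clinical covariates with
false-discovery-rate control.

Each variable is screened by its own univariate Cox model on that
variable's complete cases (so each row of the output can use a different
n, as in cohort summary tables whose denominators differ by variable).
Gene p-values are adjusted jointly by Benjamini-Yekutieli — valid under
the arbitrary dependence induced by the correlated expression block —
while clinical covariates use plain Benjamini-Hochberg. Gene hazard
ratios are per unit (i.e. per doubling) of log2 expression.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable, complete_cases
from .cox import fit_cox

log = logging.getLogger(__name__)

__all__ = ["adjust_pvalues", "univariate_screen", "clinical_design"]


def adjust_pvalues(pvals, method: str = "BY") -> np.ndarray:
    """FDR-adjust p-values (input order preserved).

    ``method="BH"``: Benjamini-Hochberg step-up ``p_(i) * m / i`` with a
    cumulative minimum from the largest p, capped at 1. ``method="BY"``:
    the BH values additionally multiplied by ``c(m) = sum_{i<=m} 1/i``,
    valid under arbitrary dependence. Delegates to statsmodels.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


#: Clinical screening design: (variable, kind, reference, levels).
#: References mirror the study's summary table (stage 1, nodes positive,
#: ER+/PR+ as baseline classes; note the node-negative hazard ratio is
#: reported *relative to node-positive*, reproducing the table's
#: printed convention).
CLINICAL_DESIGN = (
    ("age", "numeric", None, None),
    ("tumor_size_mm", "numeric", None, None),
    ("nodes", "categorical", "pos", ("neg",)),
    ("hormone_therapy", "numeric", None, None),
    ("chemotherapy", "numeric", None, None),
    ("radiation", "numeric", None, None),
    ("grade", "categorical", "1", ("2", "3-4")),
    ("stage", "categorical", 1.0, (2.0, 3.0, 4.0)),
    ("er_pr", "categorical", "+/+", ("+/-", "-/+", "-/-")),
)


def clinical_design(cohort: CohortTable, variable: str) -> pd.DataFrame:
    """Indicator-contrast design matrix for one clinical variable
    (complete cases only; column per non-reference level)."""
    df = cohort.data
    if variable == "er_pr":
        series = df["er_status"].astype(str) + "/" + df["pr_status"].astype(str)
        series[df["er_status"].isna() | df["pr_status"].isna()] = np.nan
    else:
        series = df[variable]
    spec = {v: (kind, ref, levels) for v, kind, ref, levels in CLINICAL_DESIGN}
    if variable not in spec:
        raise KeyError(f"no clinical design for {variable!r}")
    kind, ref, levels = spec[variable]
    if kind == "numeric":
        return pd.DataFrame({variable: pd.to_numeric(series)})
    out = pd.DataFrame(index=df.index)
    valid = series.notna()
    for lev in levels:
        col = (series == lev).astype(float)
        col[~valid] = np.nan
        out[f"{variable}={lev}"] = col
    return out


def _screen_one(cohort, outcome, name, design: pd.DataFrame) -> list[dict]:
    """Fit one univariate Cox model; one output row per contrast."""
    mask = design.notna().all(axis=1).to_numpy()
    mask &= cohort.data[f"{outcome}_months"].notna().to_numpy()
    mask &= cohort.data[f"{outcome}_event"].notna().to_numpy()
    if outcome == "dfs":
        mask &= ~(cohort.data["never_disease_free"].fillna(0) == 1).to_numpy()
    X = design.loc[mask]
    t = cohort.data.loc[mask, f"{outcome}_months"].to_numpy(float)
    e = cohort.data.loc[mask, f"{outcome}_event"].to_numpy(float)
    if e.sum() == 0:
        raise ValueError(f"zero events after filtering for {name}")
    if (X.std() == 0).any():
        warnings.warn(f"zero-variance variable skipped: {name}")
        return []
    fit = fit_cox(X, t, e)
    rows = []
    for j, contrast in enumerate(fit.names):
        rows.append({
            "variable": name, "contrast": contrast,
            "HR": fit.hazard_ratios[j], "ci_low": fit.ci_low[j],
            "ci_high": fit.ci_high[j], "p": fit.p_values[j],
            "outcome": outcome, "n": fit.n, "events": fit.n_events,
        })
    return rows


def univariate_screen(cohort: CohortTable, outcome: str,
                      genes=None, clinical=None,
                      fdr_genes: str = "BY",
                      fdr_clinical: str = "BH") -> pd.DataFrame:
    """Screen genes and clinical covariates one variable at a time.

    Returns a table with one row per contrast: hazard ratio, 95% CI, raw
    and FDR-adjusted p-value, and the n/events actually used. Gene rows
    come first, sorted by raw p; gene and clinical p-values are adjusted
    within their own families (BY and BH respectively by default).
    """
    if outcome not in ("os", "dfs"):
        raise ValueError(f"unknown outcome {outcome!r}")
    genes = list(cohort.panel.genes) if genes is None else list(genes)
    if clinical is None:
        clinical = [v for v, _, _, _ in CLINICAL_DESIGN]
    missing = set(genes) - set(cohort.data.columns)
    if missing:
        raise KeyError(f"genes not in cohort: {sorted(missing)}")

    gene_rows: list[dict] = []
    for g in genes:
        gene_rows += _screen_one(cohort, outcome, g,
                                 cohort.data[[g]].astype(float))
    clin_rows: list[dict] = []
    for v in clinical:
        clin_rows += _screen_one(cohort, outcome, v,
                                 clinical_design(cohort, v))

    gene_df = pd.DataFrame(gene_rows)
    if len(gene_df):
        gene_df["adj_p"] = adjust_pvalues(gene_df["p"], fdr_genes)
        gene_df["class"] = "gene"
        gene_df = gene_df.sort_values("p", kind="stable")
    clin_df = pd.DataFrame(clin_rows)
    if len(clin_df):
        clin_df["adj_p"] = adjust_pvalues(clin_df["p"], fdr_clinical)
        clin_df["class"] = "clinical"
    out = pd.concat([gene_df, clin_df], ignore_index=True)
    log.info("screened %d gene and %d clinical contrasts for %s",
             len(gene_df), len(clin_df), outcome)
    return out
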