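"""Concordance-based comparison of gene, clinical, and combined models
over repeated stratified train/test splits.

For each split, Cox models with *fixed* covariate sets (no re-selection)
are fitted to the training half and scored on the held-out half with
Harrell's C-index for right-censored data; test patients are divided
into low/high risk classes at the median training linear predictor.
Summaries are medians with empirical 95% percentile intervals, and
model contrasts use percentile intervals of the paired per-split
C-index differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._survdata import check_survival
from .cohort import CohortTable, complete_cases
from .cox import CoxFit, CoxLassoCV, fit_cox, linear_predictor
from .stability import _cohort_xy, _stratified_indices, stratified_split

log = logging.getLogger(__name__)

__all__ = ["harrell_c", "classify_risk", "compare_models",
           "random_gene_comparator", "collapse_probes", "EvaluationResult",
           "clinical_model_matrix", "lasso_c_distribution"]


def harrell_c(times, events, risk_scores) -> float:
    """Harrell's concordance index for right-censored data.

    The probability that, of a comparable pair, the subject with the
    higher risk score fails first. Comparable pairs: the earlier time is
    an event and the times differ, or the times are tied with exactly
    one event (the event subject is taken to fail first). Tied risk
    scores contribute 1/2.
    """
    t, e = check_survival((times, events))
    s = np.asarray(risk_scores, float)
    if s.shape != t.shape:
        raise ValueError("risk_scores length mismatch")
    # ordered pairs (i, j) where i demonstrably fails before j
    dt = t[:, None] - t[None, :]
    i_first = ((dt < 0) & (e[:, None] == 1)) | \
              ((dt == 0) & (e[:, None] == 1) & (e[None, :] == 0))
    n_comparable = int(i_first.sum())
    if n_comparable == 0:
        raise ValueError("no comparable pairs")
    ds = s[:, None] - s[None, :]
    concordant = int((i_first & (ds > 0)).sum())
    tied = int((i_first & (ds == 0)).sum())
    return (concordant + 0.5 * tied) / n_comparable


def classify_risk(train_scores, test_scores) -> np.ndarray:
    """Low/high labels for test scores, cut at the median training
    linear predictor (scores strictly above the median are high)."""
    train_scores = np.asarray(train_scores, float)
    if train_scores.size == 0:
        raise ValueError("empty training scores")
    cut = np.median(train_scores)
    test_scores = np.asarray(test_scores, float)
    return np.where(test_scores > cut, "high", "low")


def clinical_model_matrix(df: pd.DataFrame,
                          variables=("stage", "er_status", "pr_status")
                          ) -> pd.DataFrame:
    """Design matrix for the standard clinical model: disease stage as a
    three-level factor (1, 2, 3-or-4 pooled), ER and PR negativity as
    binary indicators. Only the requested variables are included."""
    out = pd.DataFrame(index=df.index)
    if "stage" in variables:
        stage = df["stage"]
        out["stage=2"] = (stage == 2).astype(float).where(stage.notna())
        out["stage=3-4"] = (stage >= 3).astype(float).where(stage.notna())
    for col, name in (("er_status", "er=-"), ("pr_status", "pr=-")):
        if col in variables:
            s = df[col]
            out[name] = (s == "-").astype(float).where(s.notna())
    return out


@dataclass
class EvaluationResult:
    """Per-split test C-indexes and risk classes for each model variant."""

    per_split: pd.DataFrame         # split, model, c, c_er_pos, c_er_neg,
                                    # n_low, n_high
    risk_curves: list               # per split: {model: (t, e, labels)}
    models: list[str]
    master_seed: int | None = None

    def median_c(self, model: str) -> float:
        return float(self._c(model).median())

    def _c(self, model: str) -> pd.Series:
        return self.per_split.loc[self.per_split["model"] == model, "c"]

    def ci_c(self, model: str, level: float = 0.95) -> tuple[float, float]:
        q = (1 - level) / 2
        c = self._c(model)
        return float(c.quantile(q)), float(c.quantile(1 - q))

    def difference(self, model_a: str, model_b: str,
                   level: float = 0.95) -> dict:
        """Median and percentile CI of the paired per-split C-index
        difference (a minus b)."""
        a = self._c(model_a).to_numpy()
        b = self._c(model_b).to_numpy()
        d = a - b
        q = (1 - level) / 2
        return {"median": float(np.median(d)),
                "ci": (float(np.quantile(d, q)),
                       float(np.quantile(d, 1 - q)))}

    def median_class_sizes(self, model: str) -> tuple[float, float]:
        rows = self.per_split[self.per_split["model"] == model]
        return (float(rows["n_low"].median()), float(rows["n_high"].median()))

    def summary(self) -> dict:
        out = {"n_splits": int(self.per_split["split"].nunique()),
               "master_seed": self.master_seed, "models": {}}
        for m in self.models:
            lo, hi = self.ci_c(m)
            nl, nh = self.median_class_sizes(m)
            rows = self.per_split[self.per_split["model"] == m]
            out["models"][m] = {
                "median_c": self.median_c(m), "ci": (lo, hi),
                "median_c_er_pos": float(rows["c_er_pos"].median()),
                "median_c_er_neg": float(rows["c_er_neg"].median()),
                "median_n_low": nl, "median_n_high": nh,
            }
        out["differences"] = {
            f"{a}-{b}": self.difference(a, b)
            for a, b in [(x, y) for x in self.models for y in self.models
                         if x < y]}
        return out


def _fit_and_score(train_df, test_df, design_fn, t_col, e_col):
    """Fit on train, return (C, C_er+, C_er-, labels, test t/e)."""
    Xtr = design_fn(train_df)
    Xte = design_fn(test_df)
    fit = fit_cox(Xtr, train_df[t_col].to_numpy(float),
                  train_df[e_col].to_numpy(float))
    lp_tr = linear_predictor(fit, Xtr)
    lp_te = linear_predictor(fit, Xte)
    t = test_df[t_col].to_numpy(float)
    e = test_df[e_col].to_numpy(float)
    c = harrell_c(t, e, lp_te)
    labels = classify_risk(lp_tr, lp_te)
    cs_sub = {}
    for er, key in (("+", "pos"), ("-", "neg")):
        sub = (test_df["er_status"] == er).to_numpy()
        try:
            cs_sub[key] = harrell_c(t[sub], e[sub], lp_te[sub])
        except ValueError:
            cs_sub[key] = np.nan
    return c, cs_sub["pos"], cs_sub["neg"], labels, t, e


def compare_models(cohort: CohortTable, outcome: str, gene_set=None,
                   clinical_spec=("stage", "er_status", "pr_status"),
                   n_splits: int = 1000, master_seed: int = 0,
                   train_fraction: float = 0.7, strata: str = "stage"
                   ) -> EvaluationResult:
    """Gene / clinical / combined model comparison over repeated splits.

    Models use fixed covariate sets (the signature genes by default) with
    no per-split re-selection; subgroup C-indexes for ER+/ER- test
    subsets use the all-patient training fits. Rows are restricted up
    front to complete cases on the outcome and the clinical covariates so
    that per-split C-differences are paired.
    """
    if gene_set is None:
        gene_set = list(cohort.panel.signature(outcome))
    gene_set = list(gene_set)
    clin_cols = [c for c in clinical_spec]
    cc = complete_cases(cohort, outcome, clin_cols + gene_set)

    t_col, e_col = f"{outcome}_months", f"{outcome}_event"
    designs = {
        "genes": lambda df: df[gene_set].astype(float),
        "combined": lambda df: pd.concat(
            [df[gene_set].astype(float),
             clinical_model_matrix(df, clin_cols)], axis=1),
    }
    if clin_cols:  # an empty clinical spec drops the clinical-only model
        designs["clinical"] = lambda df: clinical_model_matrix(df, clin_cols)
    models = list(designs)

    rows, curves = [], []
    done = 0
    attempt_idx = 0
    while done < n_splits and attempt_idx < 2 * n_splits + 10:
        seed = np.random.SeedSequence([master_seed, 1, attempt_idx])
        attempt_idx += 1
        train, test = stratified_split(cohort=cc,
                                       train_fraction=train_fraction,
                                       strata=strata, seed=seed)
        try:
            curve = {}
            for m in models:
                c, cp, cn, labels, t, e = _fit_and_score(
                    train.data, test.data, designs[m], t_col, e_col)
                rows.append({"split": done, "model": m, "c": c,
                             "c_er_pos": cp, "c_er_neg": cn,
                             "n_low": int((labels == "low").sum()),
                             "n_high": int((labels == "high").sum())})
                curve[m] = (t, e, labels)
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows = [r for r in rows if r["split"] != done]
            warnings.warn(f"split re-drawn after degenerate fit: {exc}")
            continue
        curves.append(curve)
        done += 1
    if done == 0:
        raise ValueError("all splits failed")
    if done < n_splits:
        warnings.warn(f"only {done}/{n_splits} splits succeeded")
    return EvaluationResult(pd.DataFrame(rows), curves, models, master_seed)


def random_gene_comparator(cohort: CohortTable, outcome: str, k: int,
                           n_splits: int = 1000, master_seed: int = 0,
                           train_fraction: float = 0.7,
                           strata: str = "stage") -> np.ndarray:
    """Test C-index distribution for size-k gene sets drawn uniformly
    anew at each split (reference for the fixed signature)."""
    genes = list(cohort.panel.genes)
    if k > len(genes):
        raise ValueError("k exceeds panel size")
    cc = complete_cases(cohort, outcome, [])
    t_col, e_col = f"{outcome}_months", f"{outcome}_event"
    cs = []
    for i in range(n_splits):
        seed = np.random.SeedSequence([master_seed, 2, i])
        rng = np.random.default_rng(np.random.SeedSequence(
            [master_seed, 3, i]))
        subset = list(rng.choice(genes, size=k, replace=False))
        train, test = stratified_split(cc, train_fraction=train_fraction,
                                       strata=strata, seed=seed)
        try:
            c, *_ = _fit_and_score(train.data, test.data,
                                   lambda df: df[subset].astype(float),
                                   t_col, e_col)
        except (ValueError, np.linalg.LinAlgError):
            continue
        cs.append(c)
    if not cs:
        raise ValueError("all splits failed")
    return np.asarray(cs)


def lasso_c_distribution(cohort: CohortTable, outcome: str,
                         n_splits: int = 1000, master_seed: int = 0,
                         train_fraction: float = 0.7, strata: str = "stage",
                         cv: int = 10, n_alphas: int = 50,
                         genes=None) -> np.ndarray:
    """Per-split test C-indexes of CV-tuned L1-penalized Cox fits.

    For each stratified 70/30 split, a Cox LASSO model (penalty chosen
    by cross-validated partial likelihood on the training half) scores
    the held-out half; applied to outcome-permuted data, this is the
    negative control whose C distribution centers on 0.5. An all-zero
    fitted model ties every risk score, scoring exactly 0.5.
    """
    X, t, e, strata_arr = _cohort_xy(cohort, outcome, genes)
    cs = []
    for i in range(n_splits):
        c = np.nan
        for attempt in range(2):
            rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, 4, i, attempt]))
            mask = _stratified_indices(strata_arr, train_fraction, rng)
            if e[mask].sum() < 2 or e[~mask].sum() < 1:
                continue
            est = CoxLassoCV(cv=cv, n_alphas=n_alphas,
                             random_state=np.random.SeedSequence(
                                 [master_seed, 5, i]))
            est.fit(X.loc[mask], (t[mask], e[mask]))
            lp = X.loc[~mask].to_numpy(float) @ est.coef_
            c = harrell_c(t[~mask], e[~mask], lp)
            break
        if np.isnan(c):
            warnings.warn(f"split {i} skipped")
            continue
        cs.append(c)
    if not cs:
        raise ValueError("all splits failed")
    return np.asarray(cs)


def collapse_probes(expression: pd.DataFrame, probe_to_gene: dict
                    ) -> pd.DataFrame:
    """Collapse a probe-level matrix (rows = probes, columns = samples)
    to gene level, keeping the most variable probe per gene.

    Ties in variance keep the first probe in input order. Every probe
    must be covered by the map.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene map")
    missing = [p for p in expression.index if p not in probe_to_gene]
    if missing:
        raise KeyError(f"probes missing from map: {missing[:5]}")
    variances = expression.var(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probe in expression.index:
        gene = probe_to_gene[probe]
        if gene not in best or variances[probe] > variances[best[gene]]:
            best[gene] = probe
    out = expression.loc[list(best.values())].copy()
    out.index = list(best.keys())
    return out
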