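"""Synthetic breast-cancer cohorts with the statistical structure the
analysis pipeline assumes.

The generator emulates the study cohort it stands in for: 225 patients,
32 log2 relative expression variables with a positively intercorrelated
estrogen-receptor-associated block (PGR, ESR1, NAT1, SLC39A6, TBC1D9,
LRBA; pairwise correlations ~0.3-0.7) and one gene (GABRP) negatively
correlated with that block, right-censored mortality and recurrence
outcomes from a proportional-hazards model with exponential baseline
(~30% events, ~60-month median follow-up), clinical covariates with the
study's marginal frequencies, and sporadic missingness in clinical
fields.

Correlation structure is realized as a single-factor block model: block
genes load positively on a latent factor, the anti-gene negatively,
which guarantees a positive-definite covariance for any loading in
(-1, 1). The factor itself is partly determined by ER status, so block
genes are shifted up in ER+ patients and the anti-gene in ER- patients.
LRBA is deliberately constructed as factor loading plus an independent
residual that carries a *positive* hazard coefficient while the block
carries protective effects: marginally LRBA then looks null (HR ~ 1)
although its residual over-expression increases risk — the sign-flip
phenomenon the residual-adjustment diagnostics recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import CLINICAL_COLUMNS, CohortTable
from .panel import ANTI_GENE, ER_BLOCK, GenePanel

__all__ = ["SimConfig", "generate_cohort", "permute_outcomes",
           "TABLE_MEDIANS"]

#: Observed per-gene log2 medians in the study cohort (used as default
#: simulated means).
TABLE_MEDIANS: dict[str, float] = {
    "RABEP1": -0.27, "PGR": 0.38, "NAT1": 2.15, "PTP4A2": -0.35,
    "SLC39A6": -0.38, "ESR1": 4.27, "EVL": 0.68, "TBC1D9": 0.15,
    "FUT8": -0.51, "SCUBE2": 2.04, "GATA3": 0.87, "MELK": -2.53,
    "TCEAL1": 0.45, "XBP1": 2.69, "PLK1": -2.5, "IL6ST": -2.94,
    "DSC2": 0.31, "CX3CL1": 0.86, "ATAD2": -1.18, "BUB1": -3.1,
    "CENPA": -2.18, "CKS2": -1.89, "GABRP": 3.08, "GMPS": -1.4,
    "LRBA": -1.71, "MAPRE2": -1.84, "MCM6": -2.27, "PFKP": -2.45,
    "ST8SIA1": -0.67, "TPBG": 0.68, "TRIM29": -0.71, "YBX1": -1.72,
}

#: Observed per-gene interquartile ranges (Q75 - Q25) in the study
#: cohort; default per-gene SDs are IQR/1.349 (normal margins), giving a
#: median SD of ~1.8 and a mean IQR of ~3.0 across the panel.
TABLE_IQRS: dict[str, float] = {
    "RABEP1": 2.48, "PGR": 5.39, "NAT1": 5.31, "PTP4A2": 2.35,
    "SLC39A6": 4.14, "ESR1": 6.80, "EVL": 2.87, "TBC1D9": 4.18,
    "FUT8": 2.37, "SCUBE2": 5.13, "GATA3": 3.97, "MELK": 1.93,
    "TCEAL1": 2.69, "XBP1": 2.93, "PLK1": 1.76, "IL6ST": 4.39,
    "DSC2": 2.23, "CX3CL1": 2.29, "ATAD2": 1.31, "BUB1": 1.88,
    "CENPA": 1.90, "CKS2": 2.37, "GABRP": 4.98, "GMPS": 1.58,
    "LRBA": 3.94, "MAPRE2": 1.99, "MCM6": 1.84, "PFKP": 1.96,
    "ST8SIA1": 2.17, "TPBG": 1.86, "TRIM29": 3.77, "YBX1": 1.30,
}

DEFAULT_SDS: dict[str, float] = {g: iqr / 1.349
                                 for g, iqr in TABLE_IQRS.items()}

#: Factor loadings: pairwise block correlations are products of
#: loadings, spanning ~0.39-0.64; GABRP correlates -0.28..-0.21 with
#: the block.
DEFAULT_LOADINGS: dict[str, float] = {
    "PGR": 0.80, "ESR1": 0.75, "NAT1": 0.80, "SLC39A6": 0.70,
    "TBC1D9": 0.65, "LRBA": 0.60, ANTI_GENE: -0.35,
}

#: Planted log-hazard coefficients per log2 unit (protective block
#: effects on the scale of the study's univariate hazard ratios).
DEFAULT_BETA_OS: dict[str, float] = {
    "PGR": -0.10, "GABRP": -0.07, "TBC1D9": -0.08, "SLC39A6": -0.10,
}
DEFAULT_BETA_DFS: dict[str, float] = {
    "PGR": -0.10, "GABRP": -0.07, "TBC1D9": -0.08, "SLC39A6": -0.10,
    "NAT1": -0.08,
}


@dataclass
class ClinicalMarginals:
    """Marginal frequencies of the clinical covariates (study Table-1
    like)."""

    stage_probs: tuple = (0.22, 0.62, 0.12, 0.03)           # stages 1-4
    er_pr_probs: tuple = (0.57, 0.07, 0.13, 0.23)           # ++, +-, -+, --
    grade_probs: tuple = (0.06, 0.42, 0.52)                 # 1, 2, 3-4
    nodes_pos_prob_by_stage: tuple = (0.40, 0.55, 0.72, 0.85)
    hormone_prob: float = 0.30
    chemo_prob: float = 0.35
    radiation_prob: float = 0.18
    age_mean: float = 59.8
    age_sd: float = 15.4
    size_mean_by_stage: tuple = (18.0, 29.0, 42.0, 50.0)    # millimeters
    size_sd: float = 10.0
    #: additive log-hazard for stage 1-4 and ER/PR class ++/+-/-+/--
    stage_log_hrs: tuple = (0.0, 0.6, 1.2, 1.5)
    er_pr_log_hrs: tuple = (0.0, 0.45, 0.45, 0.6)


@dataclass
class Censoring:
    """Censoring = min(administrative horizon, exponential censoring
    time); defaults target ~30% events and ~60-month median follow-up
    together with the baseline hazard."""

    rate: float = 0.007         # exponential censoring rate per month
    horizon: float = 180.0      # administrative horizon, months


@dataclass
class Missingness:
    """Sporadic missingness rates for clinical fields (study fractions:
    4/225 stage, 14/225 size, 16/225 nodes, 2 recurrence values)."""

    stage: float = 0.018
    tumor_size_mm: float = 0.062
    nodes: float = 0.071
    dfs: float = 0.009
    never_disease_free: float = 0.031


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int = 225
    panel: GenePanel = field(default_factory=GenePanel)
    mean_vector: dict = field(default_factory=lambda: dict(TABLE_MEDIANS))
    marginal_sd: float | dict = field(
        default_factory=lambda: dict(DEFAULT_SDS))
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    er_factor_weight: float = 0.7
    true_beta_os: dict = field(default_factory=lambda: dict(DEFAULT_BETA_OS))
    true_beta_dfs: dict = field(default_factory=lambda: dict(DEFAULT_BETA_DFS))
    lrba_residual_beta: float = 0.18
    clinical: ClinicalMarginals = field(default_factory=ClinicalMarginals)
    baseline_hazard_os: float = 0.0013   # events per month
    baseline_hazard_dfs: float = 0.0015
    censoring: Censoring = field(default_factory=Censoring)
    missingness: Missingness = field(default_factory=Missingness)
    use_clinical_hazard: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name, probs in (("stage_probs", self.clinical.stage_probs),
                            ("er_pr_probs", self.clinical.er_pr_probs),
                            ("grade_probs", self.clinical.grade_probs)):
            if abs(sum(probs) - 1.0) > 0.05:
                raise ValueError(f"{name} must sum to ~1")
        for g, l in self.loadings.items():
            if not -1.0 < l < 1.0:
                raise ValueError(
                    f"loading for {g} is {l}; |loading| >= 1 makes the "
                    "implied covariance non-positive-definite")
        unknown = (set(self.loadings) | set(self.true_beta_os)
                   | set(self.true_beta_dfs)) - set(self.panel.genes)
        if unknown:
            raise ValueError(f"genes not in panel: {sorted(unknown)}")

    def sd_of(self, gene: str) -> float:
        if isinstance(self.marginal_sd, dict):
            return float(self.marginal_sd.get(gene, 1.8))
        return float(self.marginal_sd)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = {"genes": list(self.panel.genes),
                      "os_signature": list(self.panel.os_signature),
                      "dfs_signature": list(self.panel.dfs_signature)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "panel" in d and isinstance(d["panel"], dict):
            d["panel"] = GenePanel(
                genes=tuple(d["panel"]["genes"]),
                os_signature=tuple(d["panel"].get("os_signature", ())),
                dfs_signature=tuple(d["panel"].get("dfs_signature", ())))
        for key, typ in (("clinical", ClinicalMarginals),
                         ("censoring", Censoring),
                         ("missingness", Missingness)):
            if key in d and isinstance(d[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in d[key].items()}
                d[key] = typ(**sub)
        return cls(**d)


def _rng(config: SimConfig, purpose: int) -> np.random.Generator:
    # per-purpose child seeds: SeedSequence([master, purpose_counter])
    return np.random.default_rng(np.random.SeedSequence([config.seed, purpose]))


def _draw_survival(rng, base_rate, lp, cens: Censoring):
    n = len(lp)
    event_time = rng.exponential(1.0 / (base_rate * np.exp(lp)))
    cens_time = np.minimum(rng.exponential(1.0 / cens.rate, n), cens.horizon)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(float)
    return np.round(time, 4), event


def generate_cohort(config: SimConfig) -> CohortTable:
    """Draw a synthetic cohort; fully reproducible from ``config.seed``."""
    n = config.n_patients
    genes = list(config.panel.genes)
    cl = config.clinical

    rng_clin = _rng(config, 1)
    rng_expr = _rng(config, 2)
    rng_os = _rng(config, 3)
    rng_dfs = _rng(config, 4)
    rng_miss = _rng(config, 5)

    # clinical covariates -------------------------------------------------
    stage_p = np.asarray(cl.stage_probs, float)
    stage = rng_clin.choice(4, n, p=stage_p / stage_p.sum()) + 1
    erpr_p = np.asarray(cl.er_pr_probs, float)
    erpr = rng_clin.choice(4, n, p=erpr_p / erpr_p.sum())  # ++ +- -+ --
    er_pos = np.isin(erpr, (0, 1))
    pr_pos = np.isin(erpr, (0, 2))
    grade_p = np.asarray(cl.grade_probs, float)
    grade_idx = rng_clin.choice(3, n, p=grade_p / grade_p.sum())
    nodes_pos = rng_clin.random(n) < np.asarray(
        cl.nodes_pos_prob_by_stage)[stage - 1]
    age = rng_clin.normal(cl.age_mean, cl.age_sd, n).clip(18, 100)
    size = rng_clin.normal(np.asarray(cl.size_mean_by_stage)[stage - 1],
                           cl.size_sd, n).clip(1, None)
    hormone = (rng_clin.random(n) < cl.hormone_prob).astype(float)
    chemo = (rng_clin.random(n) < cl.chemo_prob).astype(float)
    radiation = (rng_clin.random(n) < cl.radiation_prob).astype(float)

    # expression: single-factor block model shared with ER status ---------
    p_er = erpr_p[0] + erpr_p[1]
    z_er = (er_pos.astype(float) - p_er) / np.sqrt(p_er * (1 - p_er))
    c = config.er_factor_weight
    factor = c * z_er + np.sqrt(1 - c * c) * rng_expr.normal(size=n)
    expr = {}
    lrba_residual = np.zeros(n)
    for g in genes:
        load = config.loadings.get(g, 0.0)
        eps = rng_expr.normal(size=n)
        u = load * factor + np.sqrt(1 - load * load) * eps
        sd = config.sd_of(g)
        expr[g] = config.mean_vector.get(g, 0.0) + sd * u
        if g == "LRBA":
            lrba_residual = sd * np.sqrt(1 - load * load) * eps

    # proportional-hazards outcomes ---------------------------------------
    def lin_pred(betas: dict) -> np.ndarray:
        lp = np.zeros(n)
        for g, b in betas.items():
            lp += b * (expr[g] - config.mean_vector.get(g, 0.0))
        lp += config.lrba_residual_beta * lrba_residual
        if config.use_clinical_hazard:
            lp += np.asarray(cl.stage_log_hrs)[stage - 1]
            lp += np.asarray(cl.er_pr_log_hrs)[erpr]
        return lp

    os_months, os_event = _draw_survival(
        rng_os, config.baseline_hazard_os, lin_pred(config.true_beta_os),
        config.censoring)
    dfs_months, dfs_event = _draw_survival(
        rng_dfs, config.baseline_hazard_dfs, lin_pred(config.true_beta_dfs),
        config.censoring)

    # missingness ----------------------------------------------------------
    miss = config.missingness
    stage_f = stage.astype(float)
    stage_f[rng_miss.random(n) < miss.stage] = np.nan
    size[rng_miss.random(n) < miss.tumor_size_mm] = np.nan
    nodes = np.where(nodes_pos, "pos", "neg").astype(object)
    nodes[rng_miss.random(n) < miss.nodes] = np.nan
    ndf = (rng_miss.random(n) < miss.never_disease_free).astype(float)
    dfs_missing = (rng_miss.random(n) < miss.dfs) | (ndf == 1)
    dfs_months = np.where(dfs_missing, np.nan, dfs_months)
    dfs_event = np.where(dfs_missing, np.nan, dfs_event)

    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "os_months": os_months, "os_event": os_event,
        "dfs_months": dfs_months, "dfs_event": dfs_event,
        "never_disease_free": ndf,
        "age": np.round(age, 1), "tumor_size_mm": np.round(size, 1),
        "nodes": nodes,
        "grade": np.asarray(["1", "2", "3-4"], object)[grade_idx],
        "stage": stage_f,
        "er_status": np.where(er_pos, "+", "-"),
        "pr_status": np.where(pr_pos, "+", "-"),
        "hormone_therapy": hormone, "chemotherapy": chemo,
        "radiation": radiation,
    })
    for g in genes:
        df[g] = expr[g]
    return CohortTable(df[list(CLINICAL_COLUMNS) + genes], config.panel)


def permute_outcomes(cohort: CohortTable, outcome: str, seed: int,
                     what: str = "outcomes") -> CohortTable:
    """Break the covariate-outcome association for a permutation null.

    With ``what="outcomes"`` (default) the (time, event) pairs of the
    chosen outcome — plus the never-disease-free flag for DFS, so the
    exclusion rule travels with the outcome — are jointly shuffled
    across patients; covariates and the other outcome are untouched.
    ``what="expression"`` instead shuffles whole expression rows,
    leaving both outcomes and clinical covariates in place.
    """
    if outcome not in ("os", "dfs"):
        raise ValueError(f"unknown outcome {outcome!r}")
    rng = np.random.default_rng(seed)
    out = cohort.data.copy()
    perm = rng.permutation(len(out))
    if what == "outcomes":
        cols = [f"{outcome}_months", f"{outcome}_event"]
        if outcome == "dfs":
            cols.append("never_disease_free")
        out[cols] = out[cols].to_numpy()[perm]
    elif what == "expression":
        gcols = list(cohort.panel.genes)
        out[gcols] = out[gcols].to_numpy()[perm]
    else:
        raise ValueError(f"unknown permutation target {what!r}")
    return CohortTable(out, cohort.panel)
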