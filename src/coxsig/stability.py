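"""Stability selection with a permutation-derived significance threshold.

The selection procedure: repeatedly split the cohort into training
(70%) and test (30%) halves stratified on tumor stage, fit an
L1-penalized Cox model to each training set (penalty chosen by 10-fold
cross-validated partial likelihood), and count how often each gene is
retained with a nonzero coefficient. The null reference repeats the
identical split/CV/fit procedure on outcome-permuted data; the
significance threshold is the highest per-gene total count across the
permuted replicates, and genes whose observed counts are *strictly
greater* are declared significant (an empirical per-gene error rate of
roughly 1/#genes).

Genes whose retained coefficients flip sign across splits (neither sign
reaching the configured consistency fraction, default 90%) are flagged
as ambiguous and dropped from the final signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortTable, complete_cases
from .cox import CoxLassoCV

log = logging.getLogger(__name__)

__all__ = ["stratified_split", "StabilitySelector", "SelectionProfile",
           "selection_frequencies", "permutation_null", "significant_genes"]


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def _stratified_indices(strata: np.ndarray, train_fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Boolean training mask; per-stratum largest-remainder allocation
    toward a total training size of round(fraction * n)."""
    n = len(strata)
    codes, _ = pd.factorize(pd.Series(strata), use_na_sentinel=False)
    groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    total_train = int(round(train_fraction * n))

    floors, remainders = [], []
    for g in groups:
        if len(g) == 1:
            warnings.warn("stratum of size 1 assigned wholly to training")
            floors.append(1)
            remainders.append(-np.inf)  # excluded from top-up
            continue
        target = train_fraction * len(g)
        floors.append(int(np.floor(target)))
        remainders.append(target - np.floor(target))
    floors = np.array(floors)
    deficit = total_train - int(floors.sum())
    order = np.argsort(-np.asarray(remainders), kind="stable")
    for gi in order:
        if deficit <= 0:
            break
        if floors[gi] < len(groups[gi]):
            floors[gi] += 1
            deficit -= 1
    mask = np.zeros(n, dtype=bool)
    for g, k in zip(groups, floors):
        take = rng.permutation(g)[:k]
        mask[take] = True
    return mask


def stratified_split(cohort: CohortTable, train_fraction: float = 0.7,
                     strata: str = "stage", seed=None
                     ) -> tuple[CohortTable, CohortTable]:
    """Split into train/test balanced on the composition of ``strata``
    (missing stratum values form their own stratum)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if strata not in cohort.data.columns:
        raise KeyError(f"stratum variable not in cohort: {strata}")
    rng = np.random.default_rng(seed)
    mask = _stratified_indices(cohort.data[strata].to_numpy(),
                               train_fraction, rng)
    return cohort.subset(mask), cohort.subset(~mask)


# ---------------------------------------------------------------------------
# Selection profile
# ---------------------------------------------------------------------------

@dataclass
class SelectionProfile:
    """Per-gene selection counts across resampling splits, with the
    permutation null and derived threshold."""

    genes: list[str]
    n_splits: int                      # successful splits counted
    counts: pd.Series                  # per-gene selection count
    split_models: list[dict]           # per split: {gene: coef} (nonzero)
    perm_matrix: pd.DataFrame | None = None   # genes x permutation reps
    threshold: int | None = None       # highest permuted per-gene count
    master_seed: int | None = None
    sign_consistency: float = 0.9

    @property
    def percentages(self) -> pd.Series:
        return 100.0 * self.counts / self.n_splits

    @property
    def significant(self) -> list[str]:
        """Genes with observed count strictly above the threshold,
        by descending selection percentage."""
        if self.threshold is None:
            raise ValueError("no permutation threshold available")
        sig = self.counts[self.counts > self.threshold]
        return list(sig.sort_values(ascending=False).index)

    def sign_fractions(self) -> pd.Series:
        """Per gene, the fraction of its nonzero retained coefficients
        sharing the majority sign (NaN if never retained)."""
        out = {}
        for g in self.genes:
            coefs = np.array([m[g] for m in self.split_models if g in m])
            if len(coefs) == 0:
                out[g] = np.nan
            else:
                pos = (coefs > 0).mean()
                out[g] = max(pos, 1 - pos)
        return pd.Series(out)

    @property
    def ambiguous(self) -> list[str]:
        """Significant genes whose coefficient sign is inconsistent."""
        frac = self.sign_fractions()
        return [g for g in self.significant
                if frac[g] < self.sign_consistency]

    @property
    def signature(self) -> list[str]:
        """Final signature: significant genes minus ambiguous-sign genes."""
        amb = set(self.ambiguous)
        return [g for g in self.significant if g not in amb]

    def to_dict(self) -> dict:
        d = {
            "n_splits": self.n_splits,
            "counts": {g: int(c) for g, c in self.counts.items()},
            "percentages": {g: float(p) for g, p in self.percentages.items()},
            "master_seed": self.master_seed,
        }
        if self.threshold is not None:
            d.update({
                "threshold": int(self.threshold),
                "threshold_percent": 100.0 * self.threshold / self.n_splits,
                "significant": self.significant,
                "ambiguous_sign": self.ambiguous,
                "signature": self.signature,
            })
        return d


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class StabilitySelector(BaseEstimator):
    """Feature selector: genes stably retained by CV-tuned Cox LASSO
    across stratified resampling splits, thresholded by a permutation
    null.

    ``fit(X, y, strata=...)`` expects X as a DataFrame of expression
    values and y as (times, events); ``transform`` keeps the final
    signature columns. Fitted attributes: ``counts_``, ``threshold_``,
    ``significant_``, ``ambiguous_``, ``signature_``, ``profile_``.
    """

    def __init__(self, n_splits: int = 1000, n_perm: int = 1000,
                 train_fraction: float = 0.7, cv: int = 10,
                 n_alphas: int = 50, sign_consistency: float = 0.9,
                 random_state: int = 0):
        self.n_splits = n_splits
        self.n_perm = n_perm
        self.train_fraction = train_fraction
        self.cv = cv
        self.n_alphas = n_alphas
        self.sign_consistency = sign_consistency
        self.random_state = random_state

    # tags in the seed tree: 1 = splits, 2 = CV folds, 3 = permutations,
    # 4 = redraws
    def _seed(self, *path) -> np.random.SeedSequence:
        return np.random.SeedSequence([int(self.random_state), *path])

    def _one_model(self, X, times, events, strata, split_seed, cv_seed):
        """One stratified split + CV-LASSO training fit.

        Returns {gene: nonzero coef} or None if the training half is
        unusable (< 2 events)."""
        rng = np.random.default_rng(split_seed)
        mask = _stratified_indices(strata, self.train_fraction, rng)
        if events[mask].sum() < 2:
            return None
        est = CoxLassoCV(cv=self.cv, n_alphas=self.n_alphas,
                         random_state=cv_seed)
        est.fit(X.loc[mask], (times[mask], events[mask]))
        nz = np.flatnonzero(est.coef_)
        return {X.columns[j]: float(est.coef_[j]) for j in nz}

    def _run_splits(self, X, times, events, strata, tag, n, permute=False,
                    outcome_cols=None):
        """``n`` replicates; for the permutation null each replicate
        first jointly shuffles the outcome pairs."""
        models = []
        for i in range(n):
            t_i, e_i = times, events
            if permute:
                prng = np.random.default_rng(self._seed(3, i))
                perm = prng.permutation(len(times))
                t_i, e_i = times[perm], events[perm]
            model = None
            for attempt in range(2):  # one re-draw with a derived seed
                model = self._one_model(
                    X, t_i, e_i, strata,
                    self._seed(tag, i, 4 + attempt),
                    self._seed(tag, i, 2))
                if model is not None:
                    break
            if model is None:
                warnings.warn(f"split {i} skipped: training half has "
                              "fewer than 2 events")
                continue
            models.append(model)
        return models

    def fit(self, X, y, strata=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
        times = np.asarray(y[0] if isinstance(y, (tuple, list)) else
                           y[:, 0], float)
        events = np.asarray(y[1] if isinstance(y, (tuple, list)) else
                            y[:, 1], float)
        if strata is None:
            strata = np.zeros(len(X))
        strata = np.asarray(strata, object)

        obs_models = self._run_splits(X, times, events, strata, 1,
                                      self.n_splits)
        if not obs_models:
            raise ValueError("all splits failed")
        genes = list(X.columns)
        counts = pd.Series({g: sum(g in m for m in obs_models)
                            for g in genes})

        perm_matrix = None
        threshold = None
        if self.n_perm > 0:
            perm_models = self._run_splits(X, times, events, strata, 3,
                                           self.n_perm, permute=True)
            if not perm_models:
                raise ValueError("all permutation replicates failed")
            mat = np.zeros((len(genes), len(perm_models)), dtype=int)
            for r, m in enumerate(perm_models):
                for g in m:
                    mat[genes.index(g), r] = 1
            perm_matrix = pd.DataFrame(mat, index=genes)
            threshold = int(mat.sum(axis=1).max())

        self.profile_ = SelectionProfile(
            genes, len(obs_models), counts, obs_models, perm_matrix,
            threshold, self.random_state, self.sign_consistency)
        self.counts_ = counts
        self.threshold_ = threshold
        if threshold is not None:
            self.significant_ = self.profile_.significant
            self.ambiguous_ = self.profile_.ambiguous
            self.signature_ = self.profile_.signature
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = len(genes)
        return self

    def transform(self, X):
        if not hasattr(self, "signature_"):
            raise ValueError("selector not fitted with a permutation null")
        return X[self.signature_]


# ---------------------------------------------------------------------------
# Functional interface over CohortTable
# ---------------------------------------------------------------------------

def _cohort_xy(cohort: CohortTable, outcome: str, genes):
    genes = list(cohort.panel.genes) if genes is None else list(genes)
    cc = complete_cases(cohort, outcome, genes)
    t, e = cc.survival(outcome)
    X = cc.data[genes]
    strata = cc.data["stage"].to_numpy(object)
    return X, t, e, strata


def selection_frequencies(cohort: CohortTable, outcome: str, genes=None,
                          n_splits: int = 1000, master_seed: int = 0,
                          **kwargs) -> SelectionProfile:
    """Observed per-gene selection counts (no permutation null)."""
    X, t, e, strata = _cohort_xy(cohort, outcome, genes)
    sel = StabilitySelector(n_splits=n_splits, n_perm=0,
                            random_state=master_seed, **kwargs)
    sel.fit(X, (t, e), strata=strata)
    return sel.profile_


def permutation_null(cohort: CohortTable, outcome: str, genes=None,
                     n_perm: int = 1000, master_seed: int = 0,
                     **kwargs) -> tuple[pd.DataFrame, int]:
    """Permutation-null count matrix and its threshold (the highest
    per-gene total count across replicates)."""
    X, t, e, strata = _cohort_xy(cohort, outcome, genes)
    sel = StabilitySelector(n_splits=1, n_perm=n_perm,
                            random_state=master_seed, **kwargs)
    sel.fit(X, (t, e), strata=strata)
    return sel.profile_.perm_matrix, sel.profile_.threshold


def significant_genes(profile: SelectionProfile) -> list[tuple[str, float]]:
    """Genes above the permutation threshold with their selection
    percentages, by descending percentage."""
    pct = profile.percentages
    return [(g, float(pct[g])) for g in profile.significant]
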