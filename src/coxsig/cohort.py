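"""Cohort table: per-patient clinical covariates, censored outcomes, and
log2 relative gene-expression values.

A :class:`CohortTable` wraps a single :class:`pandas.DataFrame` whose
columns are the standard clinical/outcome fields plus one column per
panel gene. Two right-censored outcomes are carried: overall survival
(``os_*``, time to breast-cancer death) and disease-free survival
(``dfs_*``, time to recurrence). Patients who were never disease-free
have no meaningful recurrence time and are excluded from DFS modelling
but kept for mortality.

Expression values are consumed already log2-transformed (log2 fold
change versus a calibrator RNA); :func:`ddct_log2_relative` is provided
as an upstream utility for computing them from raw qPCR Ct values and is
never applied automatically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import GenePanel

log = logging.getLogger(__name__)

#: Missing-value tokens accepted on input; "NA" is emitted on output.
NA_TOKENS = ("NA", "", "NaN")

#: Required clinical/outcome columns (expression columns come from the panel).
CLINICAL_COLUMNS = (
    "patient_id", "os_months", "os_event", "dfs_months", "dfs_event",
    "never_disease_free", "age", "tumor_size_mm", "nodes", "grade",
    "stage", "er_status", "pr_status", "hormone_therapy", "chemotherapy",
    "radiation",
)

_NUMERIC_CLINICAL = (
    "os_months", "os_event", "dfs_months", "dfs_event", "never_disease_free",
    "age", "tumor_size_mm", "stage", "hormone_therapy", "chemotherapy",
    "radiation",
)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ParseError(ValueError):
    """A cell could not be parsed (row/column reported in the message)."""


def _normalize_grade(value):
    """Collapse grades 3 and 4 into the single '3-4' level."""
    if pd.isna(value):
        return np.nan
    s = str(value).strip()
    if s in ("3", "4", "3.0", "4.0", "3 or 4"):
        return "3-4"
    if s in ("1", "1.0", "2", "2.0", "3-4"):
        return s.rstrip(".0") if s.endswith(".0") else s
    raise ParseError(f"unrecognized grade value {value!r}")


@dataclass
class CohortTable:
    """Validated per-patient cohort with expression columns from ``panel``."""

    data: pd.DataFrame
    panel: GenePanel

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.panel.genes)

    @property
    def expression(self) -> pd.DataFrame:
        """Log2 expression matrix, one column per panel gene."""
        return self.data[list(self.panel.genes)]

    def survival(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) arrays for outcome 'os' or 'dfs'."""
        if outcome not in ("os", "dfs"):
            raise ValueError(f"unknown outcome {outcome!r}")
        t = self.data[f"{outcome}_months"].to_numpy(float)
        e = self.data[f"{outcome}_event"].to_numpy(float)
        return t, e

    def subset(self, mask) -> "CohortTable":
        """Row-subset copy (boolean mask or positional indices)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            sub = self.data.loc[mask].reset_index(drop=True)
        else:
            sub = self.data.iloc[mask].reset_index(drop=True)
        return CohortTable(sub, self.panel)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.panel)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col}")
        for gene in self.panel.genes:
            if gene not in df.columns:
                raise SchemaError(f"missing expression column: {gene}")
        if df["patient_id"].duplicated().any():
            dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise SchemaError(f"duplicate patient_id values: {dupes}")
        expr = df[list(self.panel.genes)].to_numpy(float)
        present = ~np.isnan(expr)
        if not np.isfinite(expr[present]).all():
            raise ParseError("non-finite expression value")
        for col in ("os_months", "dfs_months"):
            t = df[col].to_numpy(float)
            if np.nanmin(t, initial=0.0) < 0:
                raise ValueError(f"negative time in {col}")
        ev = df["os_event"].to_numpy(float)
        t = df["os_months"].to_numpy(float)
        if np.any((ev == 1) & ~np.isfinite(t)):
            raise ValueError("os_event=1 requires finite os_months")


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def ddct_log2_relative(ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal):
    """Log2 relative expression from quadruplet Ct values (delta-delta-Ct).

    Computes ``-[(Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator]``,
    i.e. log2 of the 2^-ddCt fold change of the target gene in the sample
    relative to the calibrator, normalized to a reference gene (ACTB in the
    originating assay). Accepts scalars or broadcastable arrays.
    """
    args = [np.asarray(a, dtype=float) for a in
            (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal)]
    for a in args:
        if not np.isfinite(a).all():
            raise ValueError("non-finite Ct value")
    ddct = (args[0] - args[1]) - (args[2] - args[3])
    out = -ddct
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _resolve_column_map(path: Path, column_map) -> dict:
    """standard name -> file-specific name mapping (JSON sidecar or dict)."""
    if column_map is None:
        sidecar = path.with_suffix(path.suffix + ".columns.json")
        if sidecar.exists():
            column_map = sidecar
        else:
            return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = json.load(fh)
    return dict(column_map)


def read_cohort(path, panel: GenePanel | None = None, column_map=None) -> CohortTable:
    """Read a delimited cohort file (tab or comma) into a CohortTable.

    Missing values may be encoded as "NA", an empty field, or "NaN".
    ``column_map`` (dict, or JSON file mapping standard -> file column
    names; a ``<path>.columns.json`` sidecar is picked up automatically)
    lets files with non-standard headers be ingested.
    """
    path = Path(path)
    panel = panel or GenePanel()
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=list(NA_TOKENS))
    if df.shape[1] == 1:  # wrong delimiter guess; try the other one
        df = pd.read_csv(path, sep="," if sep == "\t" else "\t", dtype=str,
                         keep_default_na=False, na_values=list(NA_TOKENS))
    cmap = _resolve_column_map(path, column_map)
    if cmap:
        df = df.rename(columns={v: k for k, v in cmap.items()})

    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    for gene in panel.genes:
        if gene not in df.columns:
            raise SchemaError(f"missing expression column: {gene}")

    out = pd.DataFrame()
    out["patient_id"] = df["patient_id"].astype(str)
    for col in _NUMERIC_CLINICAL:
        try:
            out[col] = df[col].astype(float)  # numpy parse: exact round-trip
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric value in column {col}: {exc}") from exc
    out["nodes"] = df["nodes"].where(df["nodes"].notna(), np.nan)
    out["grade"] = df["grade"].map(_normalize_grade)
    for col in ("er_status", "pr_status"):
        bad = ~df[col].isin(["+", "-"]) & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(f"invalid {col} value at row {row}: "
                             f"{df[col].iloc[row]!r} (expected '+' or '-')")
        out[col] = df[col]
    for gene in panel.genes:
        try:
            out[gene] = df[gene].astype(float)
        except (ValueError, TypeError):
            vals = pd.to_numeric(df[gene], errors="coerce")
            bad = vals.isna() & df[gene].notna()
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric expression entry at row {row}, column {gene}: "
                f"{df[gene].iloc[row]!r}") from None

    cohort = CohortTable(out, panel)
    log.info("read %d patients, %d expression columns from %s",
             len(cohort), len(panel), path)
    return cohort


def write_cohort(cohort: CohortTable, path, sep: str = "\t") -> None:
    """Write a cohort file in the dialect :func:`read_cohort` accepts."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        sep = ","
    cols = list(CLINICAL_COLUMNS) + list(cohort.panel.genes)
    # %.17g guarantees bit-for-bit float round-trips through the text file
    cohort.data[cols].to_csv(path, sep=sep, index=False, na_rep="NA",
                             float_format="%.17g")


# ---------------------------------------------------------------------------
# Complete-case filtering
# ---------------------------------------------------------------------------

def complete_cases(cohort: CohortTable, outcome: str,
                   covariates: Iterable[str] = ()) -> CohortTable:
    """Complete cases on the outcome and the requested covariates.

    Drops rows missing the outcome time or event, rows missing any
    requested covariate, and — for the recurrence outcome only — the
    never-disease-free patients (they have no meaningful recurrence time
    but do contribute to mortality analyses). No imputation anywhere.
    """
    if outcome not in ("os", "dfs"):
        raise ValueError(f"unknown outcome {outcome!r}")
    covariates = list(covariates)
    df = cohort.data
    missing = set(covariates) - set(df.columns)
    if missing:
        raise KeyError(f"covariates not in cohort: {sorted(missing)}")

    keep = df[f"{outcome}_months"].notna() & df[f"{outcome}_event"].notna()
    n_missing_outcome = int((~keep).sum())
    n_ndf = 0
    if outcome == "dfs":
        ndf = df["never_disease_free"].fillna(0).astype(float) == 1
        n_ndf = int((keep & ndf).sum())
        keep &= ~ndf
    n_missing_cov = 0
    for cov in covariates:
        miss = keep & df[cov].isna()
        n_missing_cov += int(miss.sum())
        keep &= ~miss
    log.info("complete_cases(%s): kept %d/%d (dropped %d missing outcome, "
             "%d never-disease-free, %d missing covariates)", outcome,
             int(keep.sum()), len(df), n_missing_outcome, n_ndf, n_missing_cov)
    if not keep.any():
        raise ValueError("no complete cases")
    return cohort.subset(keep.to_numpy())
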