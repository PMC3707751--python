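"""End-to-end pipeline orchestration and report/figure generation.

``run_pipeline`` executes the requested stages — simulate (or load a
cohort file), univariate screening, stability selection, model
evaluation (optionally repeated on outcome-permuted data as a negative
control), and diagnostics — writing delimited-text tables and JSON
summaries plus a manifest listing every artifact with the master seed
and a config hash. ``render_report`` regenerates figures and a summary
document purely from those stored per-split results, so the expensive
resampling never needs re-running to re-plot.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, read_cohort, write_cohort
from .cox import kaplan_meier
from .diagnostics import PowerParams, detectable_hr, residual_cox
from .evaluation import EvaluationResult, compare_models
from .panel import ER_BLOCK, GenePanel
from .screening import univariate_screen
from .simulate import SimConfig, generate_cohort, permute_outcomes
from .stability import StabilitySelector, _cohort_xy

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report"]


@dataclass
class RunConfig:
    """Pipeline configuration (serializable to/from a YAML mapping)."""

    cohort_path: str | None = None        # None -> synthesize a cohort
    outcome: str = "os"
    n_splits: int = 200
    n_perm: int = 200
    seed: int = 0
    out_dir: str = "results"
    gene_set: list | None = None          # None -> stability signature
    clinical_spec: tuple = ("stage", "er_status", "pr_status")
    stages: tuple = ("simulate", "screen", "select", "evaluate", "diagnose")
    evaluate_permuted: bool = True
    sim: dict = field(default_factory=dict)   # SimConfig overrides

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("clinical_spec", "stages"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=str) + "\n")


def _km_rows(curves, models) -> pd.DataFrame:
    """Flatten per-split risk-class Kaplan-Meier curves to rows."""
    rows = []
    for split, curve in enumerate(curves):
        for model in models:
            t, e, labels = curve[model]
            for cls in ("low", "high"):
                sub = labels == cls
                if sub.sum() == 0 or e[sub].sum() == 0:
                    continue
                km = kaplan_meier(t[sub], e[sub])
                for tt, ss in zip(km.event_times, km.survival):
                    rows.append({"split": split, "model": model,
                                 "risk_class": cls, "time": tt, "surv": ss})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> tuple[int, dict]:
    """Execute the configured stages; returns (exit_status, manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "outputs": [], "stages": {},
    }

    def record(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    def finish(status: int) -> tuple[int, dict]:
        _json_dump(manifest, out / "manifest.json")
        return status, manifest

    # ---- cohort ----------------------------------------------------------
    try:
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
            manifest["stages"]["load"] = {"n": len(cohort)}
        else:
            sim_cfg = SimConfig.from_dict({"seed": config.seed,
                                           **config.sim})
            cohort = generate_cohort(sim_cfg)
            if "simulate" in config.stages:
                path = out / "cohort.tsv"
                write_cohort(cohort, path)
                record(path)
            t, e = cohort.survival(config.outcome)
            manifest["stages"]["simulate"] = {
                "n": len(cohort), "events": int(np.nansum(e))}
    except Exception as exc:  # noqa: BLE001 - manifest must flag the stage
        manifest["stages"]["load" if config.cohort_path else "simulate"] = \
            {"error": str(exc)}
        log.error("cohort stage failed: %s", exc)
        return finish(1)

    gene_set = config.gene_set

    # ---- screen ----------------------------------------------------------
    if "screen" in config.stages:
        try:
            table = univariate_screen(cohort, config.outcome)
            path = out / "screen.tsv"
            table.to_csv(path, sep="\t", index=False, na_rep="NA")
            record(path)
            sig = table[(table["class"] == "gene")
                        & (table["adj_p"] < 0.05)]
            _json_dump({"seed": config.seed,
                        "significant_genes": sig["variable"].tolist()},
                       out / "screen_summary.json")
            record(out / "screen_summary.json")
            manifest["stages"]["screen"] = {
                "n_significant_genes": int(len(sig))}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["screen"] = {"error": str(exc)}
            return finish(1)

    # ---- select ----------------------------------------------------------
    if "select" in config.stages:
        try:
            X, t, e, strata = _cohort_xy(cohort, config.outcome, None)
            sel = StabilitySelector(n_splits=config.n_splits,
                                    n_perm=config.n_perm,
                                    random_state=config.seed)
            sel.fit(X, (t, e), strata=strata)
            prof = sel.profile_
            freq = pd.DataFrame({"gene": prof.genes,
                                 "count": prof.counts.values,
                                 "percent": prof.percentages.values})
            freq.to_csv(out / "selection_frequencies.tsv", sep="\t",
                        index=False)
            record(out / "selection_frequencies.tsv")
            prof.perm_matrix.to_csv(out / "permutation_matrix.tsv",
                                    sep="\t")
            record(out / "permutation_matrix.tsv")
            coef_rows = [{"split": i, "gene": g, "coef": c}
                         for i, m in enumerate(prof.split_models)
                         for g, c in m.items()]
            pd.DataFrame(coef_rows).to_csv(
                out / "split_coefficients.tsv", sep="\t", index=False)
            record(out / "split_coefficients.tsv")
            _json_dump({"seed": config.seed, **prof.to_dict()},
                       out / "selection_summary.json")
            record(out / "selection_summary.json")
            manifest["stages"]["select"] = {
                "threshold": prof.threshold,
                "signature": prof.signature}
            if gene_set is None and prof.signature:
                gene_set = prof.signature
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["select"] = {"error": str(exc)}
            return finish(1)

    if gene_set is None:
        gene_set = list(cohort.panel.signature(config.outcome))

    # ---- evaluate --------------------------------------------------------
    if "evaluate" in config.stages:
        try:
            def _evaluate(coh: CohortTable, subdir: Path):
                subdir.mkdir(parents=True, exist_ok=True)
                res = compare_models(coh, config.outcome, gene_set,
                                     config.clinical_spec,
                                     n_splits=config.n_splits,
                                     master_seed=config.seed)
                res.per_split.to_csv(subdir / "per_split_c.tsv", sep="\t",
                                     index=False, na_rep="NA")
                record(subdir / "per_split_c.tsv")
                _km_rows(res.risk_curves, res.models).to_csv(
                    subdir / "km_curves.tsv", sep="\t", index=False)
                record(subdir / "km_curves.tsv")
                _json_dump({"seed": config.seed, "gene_set": gene_set,
                            **res.summary()},
                           subdir / "evaluation_summary.json")
                record(subdir / "evaluation_summary.json")
                return res

            res = _evaluate(cohort, out)
            manifest["stages"]["evaluate"] = {
                "median_c": {m: res.median_c(m) for m in res.models}}
            if config.evaluate_permuted:
                permuted = permute_outcomes(
                    cohort, config.outcome,
                    seed=np.random.SeedSequence(
                        [config.seed, 99]).generate_state(1)[0] % (2**31))
                res_p = _evaluate(permuted, out / "permuted")
                manifest["stages"]["evaluate"]["median_c_permuted"] = {
                    m: res_p.median_c(m) for m in res_p.models}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["evaluate"] = {"error": str(exc)}
            return finish(1)

    # ---- diagnose --------------------------------------------------------
    if "diagnose" in config.stages:
        try:
            diag: dict = {"seed": config.seed}
            hr, hr_inv = detectable_hr(PowerParams())
            diag["detectable_hr"] = {"hr": hr, "reciprocal": hr_inv}
            adjusters = [g for g in ER_BLOCK if g != "LRBA"
                         and g in cohort.genes]
            for target in ("LRBA", "GABRP"):
                if target not in cohort.genes:
                    continue
                fit = residual_cox(cohort, target, adjusters,
                                   config.outcome)
                diag[f"residual_{target}"] = fit.to_dict()
            _json_dump(diag, out / "diagnostics.json")
            record(out / "diagnostics.json")
            manifest["stages"]["diagnose"] = {"ok": True}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["diagnose"] = {"error": str(exc)}
            return finish(1)

    return finish(0)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _plot_km_overlay(ax, km: pd.DataFrame, title: str):
    colors = {"low": "tab:blue", "high": "tab:red"}
    for (split, cls), grp in km.groupby(["split", "risk_class"]):
        ax.step(np.r_[0, grp["time"].to_numpy()],
                np.r_[1.0, grp["surv"].to_numpy()], where="post",
                color=colors[cls], alpha=0.05, lw=0.8)
    for cls, col in colors.items():
        ax.plot([], [], color=col, label=f"{cls} risk")
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("months")
    ax.set_ylabel("S(t)")
    ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)


def render_report(results_dir) -> Path:
    """Regenerate figures and a summary document from stored results.

    Never modifies numeric result files; missing stage outputs are
    skipped with a notice in the report.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(results_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Analysis report", ""]
    notices = []

    per_split = out / "per_split_c.tsv"
    if per_split.exists():
        df = pd.read_csv(per_split, sep="\t")
        models = sorted(df["model"].unique())
        data = [df.loc[df["model"] == m, "c"].dropna() for m in models]
        labels = list(models)
        perm_file = out / "permuted" / "per_split_c.tsv"
        if perm_file.exists():
            dfp = pd.read_csv(perm_file, sep="\t")
            for m in models:
                data.append(dfp.loc[dfp["model"] == m, "c"].dropna())
                labels.append(f"{m}\n(permuted)")
        fig, ax = plt.subplots(figsize=(1.6 * len(labels) + 1, 4))
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.5, color="gray", ls="--", lw=0.8)
        ax.set_ylabel("test C-index")
        fig.tight_layout()
        fig.savefig(out / "c_index_boxplot.png", dpi=150)
        plt.close(fig)
        lines += ["## Test-set C-indexes", ""]
        for m in models:
            med = df.loc[df["model"] == m, "c"].median()
            lines.append(f"- {m}: median C = {med:.3f}")
        lines += ["", "![C-index boxplots](c_index_boxplot.png)", ""]
    else:
        notices.append("no evaluation results; C-index panel skipped")

    km_file = out / "km_curves.tsv"
    if km_file.exists():
        km = pd.read_csv(km_file, sep="\t")
        perm_km_file = out / "permuted" / "km_curves.tsv"
        layers = [("actual", km)]
        if perm_km_file.exists():
            layers.append(("permuted", pd.read_csv(perm_km_file, sep="\t")))
        models = sorted(km["model"].unique())
        fig, axes = plt.subplots(len(layers), len(models),
                                 figsize=(4 * len(models), 3.5 * len(layers)),
                                 squeeze=False)
        for r, (name, frame) in enumerate(layers):
            for cidx, m in enumerate(models):
                _plot_km_overlay(axes[r][cidx],
                                 frame[frame["model"] == m],
                                 f"{m} ({name})")
        fig.tight_layout()
        fig.savefig(out / "km_overlays.png", dpi=150)
        plt.close(fig)
        lines += ["## Risk-class survival curves", "",
                  "![KM overlays](km_overlays.png)", ""]
    else:
        notices.append("no KM curves; survival panel skipped")

    coef_file = out / "split_coefficients.tsv"
    sel_file = out / "selection_summary.json"
    if coef_file.exists() and sel_file.exists():
        coefs = pd.read_csv(coef_file, sep="\t")
        summary = json.loads(sel_file.read_text())
        top = summary.get("significant") or \
            list(coefs["gene"].value_counts().head(7).index)
        if top and len(coefs):
            series = [coefs.loc[coefs["gene"] == g, "coef"] for g in top]
            fig, ax = plt.subplots(figsize=(1.2 * len(top) + 1.5, 4))
            ax.boxplot(series, tick_labels=top)
            ax.axhline(0.0, color="gray", ls="--", lw=0.8)
            ax.set_ylabel("retained coefficient")
            fig.tight_layout()
            fig.savefig(out / "coefficient_boxplot.png", dpi=150)
            plt.close(fig)
            lines += ["## Retained LASSO coefficients", "",
                      "![coefficients](coefficient_boxplot.png)", ""]
            if "threshold_percent" in summary:
                lines.append(
                    f"Permutation threshold: {summary['threshold']} "
                    f"({summary['threshold_percent']:.1f}%); signature: "
                    f"{', '.join(summary.get('signature', [])) or 'none'}")
                lines.append("")
    else:
        notices.append("no selection results; coefficient panel skipped")

    if notices and len(notices) == 3:
        lines += ["", "**No results found in this directory.**", ""]
    for msg in notices:
        lines.append(f"_Notice: {msg}_")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
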