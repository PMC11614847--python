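"""Single-command orchestration of the full DE workflow.

``run_pipeline`` reads counts and metadata, filters, runs every engine,
fuses the results, and writes all tables, diagnostics, plots, a JSON run
summary, and a narrated report to one output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import combine as comb
from .data import CountMatrix, SampleSheet, align, read_counts, read_metadata
from .engines import ENGINE_ORDER, run_all_engines
from .plots import plot_heatmap, plot_norm_factors, plot_ordination, plot_volcano
from .prep import (
    cooks_distance,
    cpm,
    filter_by_expression,
    filter_by_variance,
    filter_rowsums,
    median_of_ratios,
    tmm_factors,
)
from .report import render_report

logger = logging.getLogger("decombine")

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_COMBINERS = ["lancaster"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    counts: str = ""
    metadata: str = ""
    condition_col: str = "condition"
    contrast: tuple[str, str] = ("c1", "c2")
    filter_method: str = "rowsums"
    min_total: int = 10
    variance_top_n: int | None = None
    min_variance: float | None = None
    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    combiners: list[str] = field(default_factory=lambda: list(DEFAULT_COMBINERS))
    lancaster_weights: list[float] | None = None
    wilkinson_r: int = 1
    include_wilcoxon: bool = True
    cooks_filter: bool = False
    seed: int = 0
    outdir: str = "decombine_out"

    def __post_init__(self) -> None:
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if not 1 <= self.wilkinson_r <= len(ENGINE_ORDER):
            raise ValueError(f"wilkinson_r must be in [1, {len(ENGINE_ORDER)}]")
        if self.filter_method not in ("rowsums", "by_expression", "variance"):
            raise ValueError(f"unknown filter_method {self.filter_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)


def _apply_filter(cfg: RunConfig, cm: CountMatrix, sheet: SampleSheet) -> CountMatrix:
    if cfg.filter_method == "rowsums":
        return filter_rowsums(cm, cfg.min_total)
    if cfg.filter_method == "by_expression":
        return filter_by_expression(cm, sheet)
    return filter_by_variance(cm, min_variance=cfg.min_variance, top_n=cfg.variance_top_n)


def run_pipeline(
    cfg: RunConfig,
    cm: CountMatrix | None = None,
    sheet: SampleSheet | None = None,
) -> Path:
    """Execute the workflow and return the output directory.

    Inputs may be passed in memory; otherwise they are read from the paths
    in the config.  On failure, partial outputs are kept and a ``FAILED``
    marker file records the error.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    steps: list[dict] = []
    state: dict = {"config": asdict(cfg), "version": _version, "steps": steps}
    try:
        if cm is None:
            cm = read_counts(cfg.counts)
        if sheet is None:
            sheet = read_metadata(cfg.metadata, cfg.condition_col, cfg.contrast)
        cm = align(cm, sheet)
        steps.append(
            {
                "step": "load",
                "genes": cm.n_genes,
                "samples": cm.n_samples,
                "contrast": list(cfg.contrast),
            }
        )

        filtered = _apply_filter(cfg, cm, sheet)
        steps.append(
            {
                "step": "filter",
                "method": cfg.filter_method,
                "genes_before": cm.n_genes,
                "genes_after": filtered.n_genes,
            }
        )

        tmm = tmm_factors(filtered)
        mor = median_of_ratios(filtered)
        tmm.as_frame().to_csv(outdir / "norm_factors_tmm.tsv", sep="\t")
        mor.as_frame().to_csv(outdir / "norm_factors_median_of_ratios.tsv", sep="\t")
        plot_norm_factors(tmm.as_frame(), outdir, "tmm")
        plot_norm_factors(mor.as_frame(), outdir, "median_of_ratios")
        steps.append({"step": "normalize", "methods": ["tmm", "median_of_ratios"]})

        results = run_all_engines(
            filtered, sheet, include_wilcoxon=cfg.include_wilcoxon, seed=cfg.seed
        )
        for name, res in results.items():
            res.table.to_csv(outdir / f"engine_{name}.tsv", sep="\t", index_label="gene")
        steps.append({"step": "engines", "engines": list(results)})

        # screen against the trend dispersion: a gross count outlier inflates
        # its own gene's dispersion estimate and would otherwise mask itself
        disp = results["nb_wald"].extras["dispersion_trend"]
        cooks = cooks_distance(filtered, mor, disp, sheet)
        cooks.distances.round(4).to_csv(outdir / "cooks_distance.tsv", sep="\t")
        steps.append(
            {
                "step": "cooks",
                "threshold": cooks.threshold,
                "flagged_genes": len(cooks.flagged_genes()),
            }
        )

        core = {k: results[k].table for k in ENGINE_ORDER}
        weights = (
            None if cfg.lancaster_weights is None else np.asarray(cfg.lancaster_weights)
        )
        combined = comb.combine_all(
            core,
            combiners=cfg.combiners,
            padj_thr=cfg.padj_threshold,
            lfc_thr=cfg.lfc_threshold,
            lancaster_weights=weights,
            wilkinson_r=cfg.wilkinson_r,
        )
        combined.to_csv(outdir / "combined.tsv", sep="\t", index_label="gene")
        call_counts = {
            m: int(combined[f"de_call_{m}"].sum()) for m in cfg.combiners
        }
        call_counts["max_p"] = int(combined["max_p_member"].sum())
        for name, res in results.items():
            calls = comb.call_de(
                res.table["padj"], res.table["log2_fc"], cfg.padj_threshold, cfg.lfc_threshold
            )
            call_counts[name] = int(np.sum(calls))
        steps.append({"step": "combine", "combiners": cfg.combiners, "calls": call_counts})

        logcpm = cpm(filtered, tmm, log=True)
        plot_ordination(logcpm, sheet, "mds", outdir)
        plot_ordination(logcpm, sheet, "pca", outdir)
        primary = cfg.combiners[0]
        plot_volcano(
            combined.rename(
                columns={f"padj_{primary}": "padj", "mean_log2_fc": "log2_fc"}
            ),
            outdir,
            primary,
            padj_thr=cfg.padj_threshold,
            lfc_thr=cfg.lfc_threshold,
        )
        de_genes = list(combined.index[combined[f"de_call_{primary}"]])
        logcpm_df = pd.DataFrame(
            logcpm, index=filtered.counts.index, columns=filtered.counts.columns
        )
        plot_heatmap(logcpm_df, de_genes, sheet, outdir)
        steps.append({"step": "plots", "de_genes_plotted": len(de_genes)})

        state["call_counts"] = call_counts
        with open(outdir / "summary.json", "w") as fh:
            json.dump(state, fh, indent=2, default=str)
        render_report(state, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return outdir
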