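"""Confusion-matrix benchmarking of DE approaches on synthetic data.

Each simulated dataset is pushed through the full pipeline — expression
filter, the four engines, every p-value combiner and the Max-P
intersection — and each approach's calls are scored against ground truth
with sensitivity, specificity, precision, F1 and Matthews correlation.
Evaluation is restricted to the genes surviving the filter; a DE call on a
truly-DE gene counts as a true positive regardless of direction (a
direction-aware mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import combine as comb
from .data import CountMatrix, SampleSheet
from .engines import run_all_engines
from .prep import filter_by_expression
from .simulate import SimConfig, SimTruth, simulate_dataset

__all__ = [
    "MetricsRecord",
    "confusion",
    "metrics",
    "evaluate_dataset",
    "run_benchmark",
    "COMBINER_APPROACHES",
]

COMBINER_APPROACHES = (
    "lancaster",
    "fisher",
    "stouffer",
    "wilkinson",
    "bonferroni_holm",
    "tippett",
)


@dataclass
class MetricsRecord:
    """Confusion counts and derived scores for one (approach, dataset)."""

    approach: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float


def confusion(calls: np.ndarray, truth: SimTruth) -> tuple[int, int, int, int]:
    """Tally (TP, FP, TN, FN) of boolean calls against the truth table.

    ``calls`` must align with ``truth.table`` row for row.
    """
    calls = np.asarray(calls, dtype=bool)
    is_de = truth.is_de.to_numpy(dtype=bool)
    if calls.shape != is_de.shape:
        raise ValueError(
            f"calls ({calls.shape}) and truth ({is_de.shape}) lengths differ"
        )
    tp = int(np.sum(calls & is_de))
    fp = int(np.sum(calls & ~is_de))
    tn = int(np.sum(~calls & ~is_de))
    fn = int(np.sum(~calls & is_de))
    return tp, fp, tn, fn


def metrics(approach: str, tp: int, fp: int, tn: int, fn: int) -> MetricsRecord:
    """Derive sensitivity/specificity/precision/F1/MCC; 0/0 ratios are 0."""

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricsRecord(
        approach=approach,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        f1=ratio(2 * tp, 2 * tp + fp + fn),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0,
    )


def evaluate_dataset(
    cm: CountMatrix,
    sheet: SampleSheet,
    truth: SimTruth,
    padj_thr: float = 0.05,
    lfc_thr: float = 1.0,
    include_wilcoxon: bool = False,
    direction_aware: bool = False,
    seed: int | None = None,
) -> tuple[dict[str, MetricsRecord], dict]:
    """Score every approach on one dataset.

    Returns the per-approach metrics plus a dict of intermediate results
    (engine tables and the combined table) for inspection.
    """
    filtered = filter_by_expression(cm, sheet)
    truth_eval = truth.restrict(filtered.gene_ids)
    results = run_all_engines(filtered, sheet, include_wilcoxon=include_wilcoxon, seed=seed)
    tables = {name: r.table for name, r in results.items()
              if name in ("nb_exact", "voom_limma", "nb_wald", "score_test")}
    combined = comb.combine_all(
        tables, combiners=list(COMBINER_APPROACHES), padj_thr=padj_thr, lfc_thr=lfc_thr
    )

    def score(name: str, calls: np.ndarray, lfc: np.ndarray) -> MetricsRecord:
        if direction_aware:
            dirs = truth_eval.table["direction"].to_numpy()
            ok_dir = (dirs == 0) | (np.sign(lfc) == dirs)
            calls = calls & ok_dir
        return metrics(name, *confusion(calls, truth_eval))

    out: dict[str, MetricsRecord] = {}
    for name, r in results.items():
        t = r.table
        calls = comb.call_de(t["padj"], t["log2_fc"], padj_thr, lfc_thr)
        out[name] = score(name, calls.to_numpy() if hasattr(calls, "to_numpy") else calls,
                          t["log2_fc"].to_numpy())
    mean_lfc = combined["mean_log2_fc"].to_numpy()
    for name in COMBINER_APPROACHES:
        calls = combined[f"de_call_{name}"].to_numpy(dtype=bool)
        out[name] = score(name, calls, mean_lfc)
    out["max_p"] = score("max_p", combined["max_p_member"].to_numpy(dtype=bool), mean_lfc)
    return out, {"engines": tables, "combined": combined, "filtered_genes": filtered.gene_ids}


def run_benchmark(
    presets: list[int | str],
    n_per_group: int = 3,
    n_replicates: int = 10,
    n_genes: int | None = None,
    seed: int = 0,
    padj_thr: float = 0.05,
    lfc_thr: float = 1.0,
    include_wilcoxon: bool = False,
) -> pd.DataFrame:
    """Run the simulation grid and return a long-format metrics table.

    One row per (approach, preset, replicate) with confusion counts and
    derived metrics.
    """
    rows = []
    for preset in presets:
        cfg = SimConfig.from_preset(preset, n_per_group=n_per_group, seed=seed, n_genes=n_genes)
        for rep in range(n_replicates):
            try:
                cm, sheet, truth = simulate_dataset(cfg, rep)
                scored, _ = evaluate_dataset(
                    cm, sheet, truth, padj_thr, lfc_thr, include_wilcoxon, seed=seed
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"benchmark failed at preset={preset}, replicate={rep}: {exc}"
                ) from exc
            for rec in scored.values():
                rows.append(
                    {
                        "preset": preset,
                        "n_per_group": n_per_group,
                        "replicate": rep,
                        "approach": rec.approach,
                        "tp": rec.tp,
                        "fp": rec.fp,
                        "tn": rec.tn,
                        "fn": rec.fn,
                        "sensitivity": rec.sensitivity,
                        "specificity": rec.specificity,
                        "precision": rec.precision,
                        "f1": rec.f1,
                        "mcc": rec.mcc,
                    }
                )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of every metric over replicates, per approach and preset."""
    metrics_cols = ["sensitivity", "specificity", "precision", "f1", "mcc"]
    grouped = table.groupby(["preset", "n_per_group", "approach"])[metrics_cols]
    summary = grouped.agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()
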