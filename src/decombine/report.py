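"""Narrated run report.

The report is a human-readable Markdown view over the tables the pipeline
already wrote — every number in it is re-derivable from those TSVs.
"""

from __future__ import annotations

from pathlib import Path

_STEP_PROSE = {
    "load": (
        "Counts and metadata were loaded and aligned: {genes} genes x "
        "{samples} samples, contrast {contrast} (second level is the test "
        "class whose mean is the log2FC numerator)."
    ),
    "filter": (
        "Low-expression filtering ({method}) reduced the matrix from "
        "{genes_before} to {genes_after} genes.  All engines receive this "
        "same filtered gene set."
    ),
    "normalize": (
        "Between-sample normalization factors were computed with both TMM "
        "and median-of-ratios (see norm_factors_*.tsv and the factor "
        "plots); each engine uses its native method."
    ),
    "engines": (
        "DE engines executed on the filtered counts: {engines}.  Each "
        "engine's per-gene table (base_mean, log2_fc, stat, p_value, "
        "padj) is in engine_<name>.tsv."
    ),
    "cooks": (
        "Cook's distances were computed from the NB GLM fit for every "
        "(gene, sample) cell (cooks_distance.tsv); {flagged_genes} genes "
        "have at least one cell above the F-based threshold {threshold:.2f}. "
        "Flags are reported, not applied."
    ),
    "combine": (
        "Engine p-values were fused per gene with: {combiners}; BH "
        "adjustment was applied per combiner over the full filtered gene "
        "universe, and DE calls use the configured padj and |log2FC| "
        "thresholds.  The Max-P intersection (genes called by all four "
        "engines, carrying their least significant p) is included.  Call "
        "counts: {calls}."
    ),
    "plots": (
        "Diagnostic plots were produced: MDS and PCA ordination of the "
        "samples, a volcano plot of the primary combiner, and a clustered "
        "heatmap of the {de_genes_plotted} called genes."
    ),
    "simulate": (
        "A synthetic dataset was generated (preset {preset}, {n_per_group} "
        "samples per group, {n_genes} genes, {n_de} truly-DE)."
    ),
    "metrics": (
        "Calls were scored against the simulated ground truth; the "
        "confusion-matrix metrics per approach are tabulated below."
    ),
}


def render_report(state: dict, outdir) -> Path:
    """Write report.md narrating every executed step, in order."""
    lines = [
        "# Differential expression run report",
        "",
        f"Software version: {state.get('version', '?')}; "
        f"seed: {state.get('config', {}).get('seed', '?')}.",
        "",
        "## Steps executed",
        "",
    ]
    for i, step in enumerate(state.get("steps", []), start=1):
        name = step.get("step", "?")
        prose = _STEP_PROSE.get(name, "")
        try:
            prose = prose.format(**step)
        except (KeyError, IndexError):
            pass
        lines.append(f"{i}. **{name}** — {prose}")
        lines.append("")
    if "call_counts" in state:
        lines += ["## DE call counts per approach", "", "| approach | calls |", "|---|---|"]
        for name, n in state["call_counts"].items():
            lines.append(f"| {name} | {n} |")
        lines.append("")
    if "metrics_table" in state:
        lines += ["## Truth-based metrics", "", state["metrics_table"], ""]
    lines += [
        "## Notes",
        "",
        "Combined p-values treat the four engines' results as exchangeable "
        "evidence; because the engines analyse the same data their "
        "p-values are correlated and combined significance is "
        "anti-conservative in absolute terms.  The Max-P intersection is "
        "the conservative counterpart.",
        "",
    ]
    path = Path(outdir) / "report.md"
    path.write_text("\n".join(lines))
    return path
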