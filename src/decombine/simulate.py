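"""Negative-binomial count simulation with ground truth for benchmarking.

The generator produces two-condition bulk RNA-seq count matrices whose
genes follow ``NB(mu_g, phi_g)`` with a canonical mean-dispersion decay,
a configurable number of truly-DE genes with exact direction proportions,
per-sample sequencing-depth variation, and optional outlier injection
(single influential counts or scattered random ones).

Nine study presets cover the standard benchmark grid — a null dataset,
balanced and one-sided DE at two DE fractions, and outlier variants — plus
a ``large`` preset with asymmetric direction split.  DE gene counts and
direction splits are exact (not Bernoulli draws), so configured settings
are machine-checkable on the emitted truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CountMatrix, SampleSheet

__all__ = [
    "PRESETS",
    "SimConfig",
    "SimTruth",
    "sample_base_expression",
    "simulate_dataset",
    "inject_outliers",
    "write_truth",
]


#: preset -> (n_de, fraction of DE genes upregulated in the test class, outliers)
PRESETS: dict[int, tuple[int, float, str]] = {
    1: (0, 0.0, "none"),
    2: (1250, 0.5, "none"),
    3: (1250, 1.0, "none"),
    4: (4000, 0.5, "none"),
    5: (4000, 1.0, "none"),
    6: (0, 0.0, "single"),
    7: (1250, 0.5, "single"),
    8: (0, 0.0, "random"),
    9: (1250, 0.5, "random"),
}

LARGE_PRESET_ID = 10  # RNG stream index for the "large" preset


@dataclass
class SimConfig:
    """Settings of one synthetic study arm.

    ``preset`` 1-9 selects the benchmark grid row (12,500 genes); the
    string ``"large"`` selects the big asymmetric design (100 samples per
    group, 20,000 genes, 10% DE split 40/60 between directions).
    """

    preset: int | str = 2
    n_per_group: int = 3
    n_genes: int = 12500
    n_de: int = 1250
    frac_up: float = 0.5
    outlier_mode: str = "none"
    n_replicates: int = 10
    seed: int = 0

    @classmethod
    def from_preset(
        cls,
        preset: int | str,
        n_per_group: int = 3,
        seed: int = 0,
        n_genes: int | None = None,
        n_replicates: int = 10,
    ) -> "SimConfig":
        if preset == "large":
            cfg = cls(
                preset="large",
                n_per_group=100,
                n_genes=20000,
                n_de=2000,
                frac_up=0.4,
                outlier_mode="none",
                n_replicates=n_replicates,
                seed=seed,
            )
        else:
            preset = int(preset)
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset}")
            n_de, frac_up, mode = PRESETS[preset]
            cfg = cls(
                preset=preset,
                n_per_group=n_per_group,
                n_genes=12500,
                n_de=n_de,
                frac_up=frac_up,
                outlier_mode=mode,
                n_replicates=n_replicates,
                seed=seed,
            )
        if n_genes is not None:
            # scaled-down variant: DE fraction preserved
            scale = n_genes / cfg.n_genes
            cfg = replace(cfg, n_genes=n_genes, n_de=int(round(cfg.n_de * scale)))
        if cfg.n_de > cfg.n_genes:
            raise ValueError("n_de exceeds n_genes")
        return cfg

    @property
    def preset_id(self) -> int:
        return LARGE_PRESET_ID if self.preset == "large" else int(self.preset)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``table`` has one row per gene: ``is_de`` flag, ``direction`` (+1 up in
    the test class, -1 down, 0 for non-DE), ``true_log2_fc``, the base mean
    ``mu`` and dispersion ``phi``.  ``outlier_cells`` records every count
    multiplied during outlier injection as ``(gene, sample, factor)``.
    """

    table: pd.DataFrame
    outlier_cells: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def is_de(self) -> pd.Series:
        return self.table["is_de"]

    def restrict(self, genes) -> "SimTruth":
        return SimTruth(self.table.loc[list(genes)], self.outlier_cells)


def sample_base_expression(
    n_genes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-gene baseline means and dispersions.

    ``log2 mu ~ Normal(6, 2.5)`` truncated to ``mu >= 1``; the dispersion
    follows the canonical decay ``0.05 + 2.5 / mu`` with multiplicative
    LogNormal(0, 0.3) jitter, reproducing the mean-dispersion scatter of
    bulk RNA-seq.
    """
    log2_mu = rng.normal(6.0, 2.5, size=n_genes)
    bad = log2_mu < 0.0
    while bad.any():
        log2_mu[bad] = rng.normal(6.0, 2.5, size=int(bad.sum()))
        bad = log2_mu < 0.0
    mu = 2.0**log2_mu
    phi = (0.05 + 2.5 / mu) * rng.lognormal(0.0, 0.3, size=n_genes)
    return mu, phi


def inject_outliers(
    cm: CountMatrix,
    truth: SimTruth,
    mode: str,
    rng: np.random.Generator,
    gene_fraction: float = 0.10,
    cell_probability: float = 0.05,
    factor_range: tuple[float, float] = (5.0, 10.0),
) -> tuple[CountMatrix, SimTruth]:
    """Multiply selected counts by Uniform(5, 10) and record them in truth.

    ``single``: 10% of genes get exactly one affected sample each;
    ``random``: every cell independently with probability 5%.
    """
    if mode == "none":
        return cm, truth
    counts = cm.counts.to_numpy().astype(float)
    genes, samples = cm.gene_ids, cm.sample_ids
    cells: list[tuple[int, int]] = []
    if mode == "single":
        n_pick = int(round(gene_fraction * cm.n_genes))
        picked = rng.choice(cm.n_genes, size=n_pick, replace=False)
        cols = rng.integers(0, cm.n_samples, size=n_pick)
        cells = list(zip(picked.tolist(), cols.tolist()))
    elif mode == "random":
        mask = rng.random(counts.shape) < cell_probability
        cells = [tuple(idx) for idx in np.argwhere(mask)]
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    recorded = list(truth.outlier_cells)
    for g, s in cells:
        f = rng.uniform(*factor_range)
        counts[g, s] = np.rint(counts[g, s] * f)
        recorded.append((genes[g], samples[s], float(f)))
    out = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=cm.counts.index, columns=cm.counts.columns)
    )
    return out, SimTruth(truth.table, recorded)


def simulate_dataset(
    cfg: SimConfig, replicate: int = 0
) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Generate one replicate: counts, metadata, and ground truth.

    The RNG stream is derived from ``(seed, preset, replicate)`` so
    replicates are mutually independent yet exactly reproducible.  The
    test-class mean of an upregulated gene is multiplied by
    ``S = 1.5 + Exp(1)`` (divided for downregulated genes); per-sample
    depth factors are Uniform(0.7, 1.4).
    """
    if cfg.n_de > cfg.n_genes:
        raise ValueError("n_de exceeds n_genes")
    rng = np.random.default_rng([cfg.seed, cfg.preset_id, replicate])
    n_genes, n = cfg.n_genes, cfg.n_per_group
    mu, phi = sample_base_expression(n_genes, rng)

    de_idx = rng.choice(n_genes, size=cfg.n_de, replace=False)
    n_up = int(round(cfg.frac_up * cfg.n_de))
    up_idx = de_idx[rng.permutation(cfg.n_de)[:n_up]]
    direction = np.zeros(n_genes, dtype=int)
    direction[de_idx] = -1
    direction[up_idx] = 1

    s_factor = 1.5 + rng.exponential(1.0, size=cfg.n_de)
    true_lfc = np.zeros(n_genes)
    true_lfc[de_idx] = direction[de_idx] * np.log2(s_factor)

    mu1 = mu.copy()
    mu2 = mu * 2.0**true_lfc

    depth = rng.uniform(0.7, 1.4, size=2 * n)
    means = np.concatenate(
        [mu1[:, None] * depth[None, :n], mu2[:, None] * depth[None, n:]], axis=1
    )
    r = 1.0 / phi[:, None]
    counts = rng.negative_binomial(r, r / (r + means))

    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"c1_s{i + 1}" for i in range(n)] + [f"c2_s{i + 1}" for i in range(n)]
    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples))
    sheet = SampleSheet(
        pd.DataFrame(
            {"condition": ["c1"] * n + ["c2"] * n}, index=pd.Index(samples, name="sample_id")
        ),
        condition_col="condition",
        ref_level="c1",
        test_level="c2",
    )
    truth = SimTruth(
        pd.DataFrame(
            {
                "is_de": direction != 0,
                "direction": direction,
                "true_log2_fc": true_lfc,
                "base_mean": mu,
                "dispersion": phi,
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    cm, truth = inject_outliers(cm, truth, cfg.outlier_mode, rng)
    return cm, sheet, truth


def write_truth(truth: SimTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")
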