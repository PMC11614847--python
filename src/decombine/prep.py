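"""Low-expression filtering, between-sample normalization, and outlier screening.

Three filters (total-count, expression-aware, variance), two normalization
schemes (trimmed mean of M-values and median-of-ratios size factors), CPM
transforms, and per-cell Cook's distance screening from a negative-binomial
GLM fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountMatrix, SampleSheet
from .glm import fit_nb_glm

logger = logging.getLogger("decombine")

__all__ = [
    "NormFactors",
    "CooksTable",
    "filter_rowsums",
    "filter_by_expression",
    "filter_by_variance",
    "tmm_factors",
    "median_of_ratios",
    "cpm",
    "cooks_distance",
]


@dataclass
class NormFactors:
    """Per-sample normalization factors.

    For ``method='tmm'`` the factor is the classic multiplicative scaling
    whose geometric mean is 1, and the effective library size is
    ``library size x factor``.  For ``method='median_of_ratios'`` the factor
    is the size factor itself (it absorbs sequencing depth) and the
    effective library size is ``factor x geometric-mean library size`` so
    CPM values stay on a comparable scale across methods.
    """

    method: str
    sample_ids: list[str]
    factors: np.ndarray
    library_sizes: np.ndarray
    effective_lib_sizes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factors,
                "library_size": self.library_sizes,
                "effective_lib_size": self.effective_lib_sizes,
            },
            index=pd.Index(self.sample_ids, name="sample"),
        )


@dataclass
class CooksTable:
    """Cook's distances per (gene, sample) with the flagging threshold.

    Cells with ``D > threshold`` are influential observations (potential
    count outliers).  Flags are reported, never silently applied.
    """

    distances: pd.DataFrame
    threshold: float

    def flagged(self) -> pd.DataFrame:
        return self.distances > self.threshold

    def flagged_genes(self) -> list[str]:
        mask = self.flagged().any(axis=1)
        return [str(g) for g in self.distances.index[mask]]


# ---------------------------------------------------------------------------
# filters


def filter_rowsums(cm: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Keep genes whose total count across all samples is >= ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = cm.counts.sum(axis=1)
    kept = cm.counts.loc[totals >= min_total]
    if kept.shape[0] == 0:
        raise ValueError(
            f"no gene reaches a total of {min_total} counts; lower the threshold"
        )
    return CountMatrix(kept)


def filter_by_expression(
    cm: CountMatrix,
    sheet: SampleSheet,
    min_count: float = 10.0,
    min_total: float = 15.0,
    large_n: int = 10,
    min_prop: float = 0.7,
) -> CountMatrix:
    """Expression-aware filter in the style of edgeR's filterByExpr.

    A gene is kept iff its CPM exceeds ``min_count / median library size
    (in millions)`` in at least ``k`` samples — ``k`` being the smallest
    group size, softened beyond ``large_n`` — and its total count is at
    least ``min_total``.
    """
    lib = cm.library_sizes()
    median_lib = float(np.median(lib))
    if median_lib <= 0:
        raise ValueError("zero median library size")
    cutoff = min_count / (median_lib / 1e6)
    ref, tst = sheet.group_masks()
    k = float(min(ref.sum(), tst.sum()))
    if k > large_n:
        k = large_n + (k - large_n) * min_prop
    cpm_raw = cm.values() / lib * 1e6
    tol = 1e-14
    keep = (np.sum(cpm_raw >= cutoff, axis=1) >= k - tol) & (
        cm.counts.sum(axis=1).to_numpy() >= min_total - tol
    )
    return CountMatrix(cm.counts.loc[keep])


def filter_by_variance(
    cm: CountMatrix,
    min_variance: float | None = None,
    top_n: int | None = None,
) -> CountMatrix:
    """Keep genes by variance of log2-CPM (+0.5 pseudo-count).

    Exactly one of ``min_variance`` (keep genes at or above it) or
    ``top_n`` (keep the n most variable; ties broken by gene id) applies.
    """
    if (min_variance is None) == (top_n is None):
        raise ValueError("give exactly one of min_variance or top_n")
    logcpm = cpm(cm, None, log=True)
    variances = pd.Series(np.var(logcpm, axis=1, ddof=1), index=cm.counts.index)
    if min_variance is not None:
        keep = variances[variances >= min_variance].index
    else:
        if top_n > cm.n_genes:
            logger.warning(
                "top_n=%d exceeds gene count %d; keeping all genes", top_n, cm.n_genes
            )
            top_n = cm.n_genes
        order = variances.sort_index().sort_values(ascending=False, kind="stable")
        keep = order.index[:top_n]
    mask = cm.counts.index.isin(keep)
    return CountMatrix(cm.counts.loc[mask])


# ---------------------------------------------------------------------------
# normalization


def tmm_factors(
    cm: CountMatrix, logratio_trim: float = 0.30, abs_trim: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile.  For each sample, log2 expression ratios (M)
    against the reference are doubly trimmed — ``logratio_trim`` of the M
    distribution and ``abs_trim`` of the average-abundance (A)
    distribution — and averaged with inverse asymptotic-binomial-variance
    weights.  Factors are rescaled to geometric mean 1.
    """
    y = cm.values().astype(float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    cpm_raw = y / lib * 1e6
    uq = np.percentile(cpm_raw, 75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(cm.n_samples)
    yr, nr = y[:, ref], lib[ref]
    for s in range(cm.n_samples):
        ys, ns = y[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            logger.warning(
                "sample %s shares no expressed gene with the reference; factor set to 1",
                cm.sample_ids[s],
            )
            continue
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = m.size
        # rank-based double trimming, matching the classic implementation
        lo_m, hi_m = np.floor(n * logratio_trim / 2) + 1, n + 1 - (np.floor(n * logratio_trim / 2) + 1)
        lo_a, hi_a = np.floor(n * abs_trim / 2) + 1, n + 1 - (np.floor(n * abs_trim / 2) + 1)
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        inv_w = 1.0 / w[keep]
        factors[s] = 2.0 ** (np.sum(m[keep] * inv_w) / np.sum(inv_w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        method="tmm",
        sample_ids=cm.sample_ids,
        factors=factors,
        library_sizes=lib,
        effective_lib_sizes=lib * factors,
    )


def median_of_ratios(cm: CountMatrix) -> NormFactors:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Genes with any zero count are excluded from the pseudo-reference.
    """
    y = cm.values().astype(float)
    lib = y.sum(axis=0)
    all_pos = (y > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios is undefined (consider TMM normalization)"
        )
    sub = y[all_pos]
    pseudo = np.exp(np.mean(np.log(sub), axis=1))
    sf = np.median(sub / pseudo[:, None], axis=0)
    gm_lib = np.exp(np.mean(np.log(lib))) if np.all(lib > 0) else float(lib.mean())
    return NormFactors(
        method="median_of_ratios",
        sample_ids=cm.sample_ids,
        factors=sf,
        library_sizes=lib,
        effective_lib_sizes=sf * gm_lib,
    )


def cpm(
    cm: CountMatrix,
    factors: NormFactors | None = None,
    log: bool = False,
    prior: float = 0.5,
) -> np.ndarray:
    """Counts per million of effective library size (genes x samples).

    The log variant is ``log2((count + prior) / (effective lib + 2 prior) * 1e6)``.
    """
    y = cm.values().astype(float)
    eff = factors.effective_lib_sizes if factors is not None else y.sum(axis=0)
    if np.any(eff <= 0):
        raise ValueError("zero effective library size")
    if log:
        return np.log2((y + prior) / (eff + 2.0 * prior) * 1e6)
    return y / eff * 1e6


# ---------------------------------------------------------------------------
# Cook's distance


def cooks_distance(
    cm: CountMatrix,
    factors: NormFactors,
    dispersions: np.ndarray,
    sheet: SampleSheet,
) -> CooksTable:
    """Cook's distance of every count under the per-gene NB GLM fit.

    ``D = (r_pearson^2 / p) * h / (1 - h)^2`` with ``p = 2`` coefficients;
    the flag threshold is the 99th percentile of ``F(p, m - p)``.  With no
    residual degrees of freedom the screen is skipped (threshold = inf).
    """
    y = cm.values().astype(float)
    m = cm.n_samples
    p = 2
    if m - p <= 0:
        logger.warning("m - p <= 0; Cook's screening skipped")
        dist = pd.DataFrame(np.zeros_like(y), index=cm.counts.index, columns=cm.counts.columns)
        return CooksTable(dist, threshold=np.inf)
    x = sheet.indicator()
    offset = np.log(factors.factors if factors.method == "median_of_ratios"
                    else factors.effective_lib_sizes / np.exp(np.mean(np.log(factors.effective_lib_sizes))))
    fit = fit_nb_glm(y, x, offset, np.asarray(dispersions, dtype=float))
    phi = np.asarray(dispersions, dtype=float)[:, None]
    var = fit.mu + phi * fit.mu**2
    r2 = (y - fit.mu) ** 2 / np.maximum(var, 1e-300)
    d = (r2 / p) * fit.hat / (1.0 - fit.hat) ** 2
    threshold = float(stats.f.ppf(0.99, p, m - p))
    dist = pd.DataFrame(d, index=cm.counts.index, columns=cm.counts.columns)
    return CooksTable(dist, threshold=threshold)
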