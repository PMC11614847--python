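"""Fusing per-gene evidence from several DE engines into one unified call.

Six p-value combination methods (Fisher, Stouffer, Lancaster, Wilkinson,
Bonferroni-Holm, Tippett), the Max-P intersection rule, mean log2 fold
change, Benjamini-Hochberg adjustment, and thresholded DE calling.

All combiners take the engines' two-sided p-values as exchangeable evidence
(no direction alignment before fusion); sign discordance between engines is
surfaced as a per-gene count rather than invalidating the combined p-value.
Because the engines run on the same data their p-values are positively
correlated, so combined p-values are anti-conservative in absolute terms —
a property of this family of pipelines that users should keep in mind when
interpreting call counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COMBINERS",
    "fisher_combine",
    "stouffer_combine",
    "lancaster_combine",
    "wilkinson_combine",
    "bonferroni_holm_combine",
    "tippett_combine",
    "bh_adjust",
    "call_de",
    "mean_log2fc",
    "max_p_intersect",
    "combine_all",
]

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


def _clip(p: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.clip(p, P_FLOOR, P_CEIL)


def fisher_combine(p: np.ndarray) -> np.ndarray:
    """Fisher's method: ``-2 sum(ln p) ~ chi2(2k)`` under the null."""
    p = _clip(p)
    k = p.shape[1]
    x = -2.0 * np.log(p).sum(axis=1)
    return stats.chi2.sf(x, 2 * k)


def stouffer_combine(p: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Stouffer's method: weighted sum of normal quantiles.

    ``Z = sum(w_i z_i) / sqrt(sum w_i^2)`` with ``z_i = Phi^{-1}(1 - p_i)``.
    This is a one-sided fusion of the engines' two-sided p-values.
    """
    p = _clip(p)
    k = p.shape[1]
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    z = stats.norm.isf(p)
    big_z = (z * w).sum(axis=1) / np.sqrt((w**2).sum())
    return stats.norm.sf(big_z)


def lancaster_combine(p: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Lancaster's generalization of Fisher: per-test chi-square weights.

    ``T = sum Q_{w_i}(1 - p_i)`` with ``Q_w`` the chi2(w) quantile function;
    the null reference is chi2(sum w_i).  Weights of 2 everywhere reduce to
    Fisher's method.
    """
    p = _clip(p)
    k = p.shape[1]
    w = np.full(k, 2.0) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("Lancaster weights must be positive")
    t = np.zeros(p.shape[0])
    for i in range(k):
        t += stats.chi2.isf(p[:, i], w[i])
    return stats.chi2.sf(t, w.sum())


def wilkinson_combine(p: np.ndarray, r: int = 1) -> np.ndarray:
    """Wilkinson's r-th order statistic method.

    The r-th smallest of k null p-values is Beta(r, k - r + 1); the
    combined p is that Beta's CDF at the observed order statistic.
    """
    p = _clip(p)
    k = p.shape[1]
    if not 1 <= r <= k:
        raise ValueError(f"r must be in [1, {k}]")
    p_r = np.sort(p, axis=1)[:, r - 1]
    return stats.beta.cdf(p_r, r, k - r + 1)


def bonferroni_holm_combine(p: np.ndarray) -> np.ndarray:
    """Holm's step-down bound as a single combined p-value."""
    p = _clip(p)
    k = p.shape[1]
    ps = np.sort(p, axis=1)
    mult = np.arange(k, 0, -1, dtype=float)
    return np.minimum(1.0, (ps * mult).min(axis=1))


def tippett_combine(p: np.ndarray) -> np.ndarray:
    """Tippett's minimum-p method: ``1 - (1 - min p)^k``."""
    p = _clip(p)
    k = p.shape[1]
    return 1.0 - (1.0 - p.min(axis=1)) ** k


COMBINERS = {
    "fisher": fisher_combine,
    "stouffer": stouffer_combine,
    "lancaster": lancaster_combine,
    "wilkinson": wilkinson_combine,
    "bonferroni_holm": bonferroni_holm_combine,
    "tippett": tippett_combine,
}


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the number of tests and propagate as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def call_de(
    padj: np.ndarray, log2_fc: np.ndarray, padj_thr: float = 0.05, lfc_thr: float = 1.0
) -> np.ndarray:
    """DE call: ``padj <= padj_thr`` and ``|log2FC| >= lfc_thr`` (inclusive)."""
    if not 0 < padj_thr < 1:
        raise ValueError("padj threshold must be in (0, 1)")
    if lfc_thr < 0:
        raise ValueError("lfc threshold must be >= 0")
    padj = np.asarray(padj, dtype=float)
    lfc = np.asarray(log2_fc, dtype=float)
    with np.errstate(invalid="ignore"):
        return (padj <= padj_thr) & (np.abs(lfc) >= lfc_thr)


def mean_log2fc(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean log2 fold change across engines, plus a sign-discordance count.

    Averaging on the log2 scale equals a geometric mean of the linear fold
    changes.  The discordance count is the number of engines whose log2FC
    sign differs from the majority sign.
    """
    lfc = pd.DataFrame({eng: t["log2_fc"] for eng, t in tables.items()})
    mean = lfc.mean(axis=1, skipna=True)
    signs = np.sign(lfc)
    n_pos = (signs > 0).sum(axis=1)
    n_neg = (signs < 0).sum(axis=1)
    discord = np.minimum(n_pos, n_neg)
    out = pd.DataFrame({"mean_log2_fc": mean, "discordance_count": discord})
    return out.dropna(subset=["mean_log2_fc"])


def max_p_intersect(
    tables: dict[str, pd.DataFrame], padj_thr: float = 0.05, lfc_thr: float = 1.0
) -> pd.DataFrame:
    """Intersection of per-engine DE calls, carrying the largest raw p.

    A gene qualifies only if every engine calls it DE at the given
    thresholds; it is then assigned its least significant (maximum) raw
    p-value across engines.  An empty result is a valid outcome.
    """
    calls = []
    for t in tables.values():
        calls.append(pd.Series(call_de(t["padj"], t["log2_fc"], padj_thr, lfc_thr), index=t.index))
    all_de = pd.concat(calls, axis=1).fillna(False).all(axis=1)
    genes = all_de.index[all_de]
    raw = pd.DataFrame({eng: t["p_value"] for eng, t in tables.items()}).loc[genes]
    return pd.DataFrame({"p_max": raw.max(axis=1)}, index=genes)


def combine_all(
    tables: dict[str, pd.DataFrame],
    combiners: list[str] | None = None,
    padj_thr: float = 0.05,
    lfc_thr: float = 1.0,
    lancaster_weights: np.ndarray | None = None,
    wilkinson_r: int = 1,
) -> pd.DataFrame:
    """Unified per-gene output across engines.

    For every requested combiner the engines' raw p-values are fused,
    BH-adjusted over the full filtered gene universe, and thresholded into
    a DE call against the mean log2FC.  The Max-P intersection membership
    is always included (column ``max_p_member`` with its ``p_max`` /
    ``padj_max_p`` where defined).
    """
    if combiners is None:
        combiners = ["lancaster"]
    unknown = set(combiners) - set(COMBINERS)
    if unknown:
        raise ValueError(f"unknown combiners: {sorted(unknown)}")

    genes = next(iter(tables.values())).index
    pmat = pd.DataFrame({eng: t["p_value"].reindex(genes) for eng, t in tables.items()})
    n_avail = pmat.notna().sum(axis=1)
    if (n_avail == 0).any():
        pmat = pmat.loc[n_avail > 0]
        genes = pmat.index

    base = mean_log2fc(tables).reindex(genes)
    out = pd.DataFrame(index=genes)
    out["mean_log2_fc"] = base["mean_log2_fc"]
    out["discordance_count"] = base["discordance_count"]

    p_arr = pmat.to_numpy()
    avail = ~np.isnan(p_arr)
    patterns = {tuple(row) for row in avail}
    for name in combiners:
        comb = np.full(len(genes), np.nan)
        for pat in patterns:
            mask = (avail == np.array(pat)).all(axis=1)
            cols = [i for i, a in enumerate(pat) if a]
            sub = p_arr[np.ix_(mask, cols)]
            if len(cols) == 1:
                # a single contributing engine: its p is passed through
                comb[mask] = sub[:, 0]
            elif name == "lancaster":
                w = None if lancaster_weights is None else np.asarray(lancaster_weights)[cols]
                comb[mask] = lancaster_combine(sub, w)
            elif name == "wilkinson":
                comb[mask] = wilkinson_combine(sub, min(wilkinson_r, len(cols)))
            else:
                comb[mask] = COMBINERS[name](sub)
        out[f"p_{name}"] = comb
        out[f"padj_{name}"] = bh_adjust(comb)
        out[f"de_call_{name}"] = call_de(
            out[f"padj_{name}"], out["mean_log2_fc"], padj_thr, lfc_thr
        )

    maxp = max_p_intersect(tables, padj_thr, lfc_thr)
    out["max_p_member"] = out.index.isin(maxp.index)
    out["p_max_p"] = maxp["p_max"].reindex(out.index)
    return out
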