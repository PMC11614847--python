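"""Four interchangeable two-group differential-expression engines.

Each engine is a self-contained, simplified implementation of one of the
canonical statistical approaches to bulk RNA-seq DE testing:

``nb_exact``
    Negative-binomial exact conditional test with empirical-Bayes tagwise
    dispersion shrinkage toward a common value (the classic count-based
    exact-test approach).
``voom_limma``
    Log-CPM linear modelling with mean-variance precision weights and an
    empirical-Bayes moderated t-statistic.
``nb_wald``
    NB GLM Wald test with median-of-ratios size factors and MAP dispersion
    shrinkage toward a parametric mean-dispersion trend.
``score_test``
    Variance-component score test on centered log-CPM, with an optional
    permutation null.
``wilcoxon``
    Two-sided rank-sum test on CPM values (non-parametric alternative,
    reported alongside the four engines).

All engines accept the same filtered count matrix and return the same
table layout (one row per input gene, same order):
``base_mean, log2_fc, stat, p_value, padj``.  Bit-parity with the R
ecosystem tools is not a goal; distributional behaviour (null uniformity,
power ordering, fold-change recovery) is the contract.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar
from statsmodels.nonparametric.smoothers_lowess import lowess

from .combine import bh_adjust
from .data import CountMatrix, SampleSheet
from .glm import fit_nb_glm
from .prep import NormFactors, cpm, median_of_ratios, tmm_factors

logger = logging.getLogger("decombine")

ENGINE_ORDER = ("nb_exact", "voom_limma", "nb_wald", "score_test")

__all__ = [
    "ENGINE_ORDER",
    "DEResult",
    "run_nb_exact",
    "run_voom_t",
    "run_nb_wald",
    "run_score_test",
    "run_wilcoxon",
    "run_all_engines",
    "fit_dispersion_trend",
]

LOG2FC_PRIOR = 0.125  # pseudo-count wherever ratios of means are formed


@dataclass
class DEResult:
    """One engine's per-gene output plus nuisance estimates."""

    engine: str
    table: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.table["p_value"].to_numpy()
        ok = ~np.isnan(p)
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError(f"engine {self.engine}: p-values outside [0, 1]")
        if self.table.index.duplicated().any():
            raise ValueError(f"engine {self.engine}: duplicated gene ids")


def _finish(engine: str, genes, base_mean, log2_fc, stat, p, extras=None) -> DEResult:
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "stat": stat,
            "p_value": p,
            "padj": bh_adjust(p),
        },
        index=genes,
    )
    return DEResult(engine=engine, table=table, extras=extras or {})


# ---------------------------------------------------------------------------
# NB exact conditional test


def _conditional_loglik(phi: float, y1: np.ndarray, y2: np.ndarray) -> float:
    """Summed NB conditional log-likelihood over genes (terms in phi only)."""
    r = 1.0 / max(phi, 1e-10)
    total = 0.0
    for y in (y1, y2):
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(special.gammaln(y + r))
            - np.sum(special.gammaln(z + n * r))
            + y.shape[0] * special.gammaln(n * r)
            - y.size * special.gammaln(r)
        )
    return total


def _moment_dispersion(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Per-gene pooled moment estimate of the NB dispersion."""
    num = np.zeros(y1.shape[0])
    den = np.zeros(y1.shape[0])
    for y in (y1, y2):
        n = y.shape[1]
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        num += (n - 1) * (v - m)
        den += (n - 1) * np.maximum(m, 1e-8) ** 2
    return np.clip(num / den, 0.0, 20.0)


def _exact_nb_pvalue(s1: int, t: int, r1: float, r2: float) -> float:
    """Two-sided exact conditional p for a split (s1, t - s1) of the total.

    Conditional on the total, the first group's sum follows a
    beta-binomial(t, r1, r2) law; the two-sided p sums the probabilities of
    all outcomes no more likely than the observed one.  Large totals use a
    moment-matched normal approximation.
    """
    if t == 0:
        return 1.0
    if t <= 5000:
        s = np.arange(t + 1)
        logf = (
            special.gammaln(t + 1)
            - special.gammaln(s + 1)
            - special.gammaln(t - s + 1)
            + special.betaln(s + r1, t - s + r2)
            - special.betaln(r1, r2)
        )
        f = np.exp(logf - logf.max())
        f /= f.sum()
        return float(np.minimum(1.0, f[f <= f[s1] * (1.0 + 1e-10)].sum()))
    ab = r1 + r2
    mean = t * r1 / ab
    var = t * r1 * r2 * (ab + t) / (ab**2 * (ab + 1.0))
    sd = np.sqrt(var)
    lower = stats.norm.cdf((s1 + 0.5 - mean) / sd)
    upper = stats.norm.sf((s1 - 0.5 - mean) / sd)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _binom_exact_pvalue(s1: int, t: int, prob: float) -> float:
    """Poisson limit of the exact test: conditional binomial, mass ordering."""
    if t == 0:
        return 1.0
    if t <= 20000:
        s = np.arange(t + 1)
        f = stats.binom.pmf(s, t, prob)
        return float(min(1.0, f[f <= f[s1] * (1.0 + 1e-10)].sum()))
    lower = stats.binom.cdf(s1, t, prob)
    upper = stats.binom.sf(s1 - 1, t, prob)
    return float(min(1.0, 2.0 * min(lower, upper)))


def run_nb_exact(
    cm: CountMatrix,
    sheet: SampleSheet,
    factors: NormFactors | None = None,
    prior_df: float = 10.0,
) -> DEResult:
    """NB exact conditional test with tagwise dispersion shrinkage.

    Counts are scaled to a common (geometric-mean) effective library size;
    a common dispersion maximizes the conditional NB likelihood across all
    genes, per-gene moment estimates are shrunk toward it with
    ``prior_df`` prior degrees of freedom, and the two-group comparison
    conditions on each gene's total.
    """
    if factors is None:
        factors = tmm_factors(cm)
    y = cm.values().astype(float)
    eff = factors.effective_lib_sizes
    common_lib = np.exp(np.mean(np.log(eff)))
    pseudo = y * (common_lib / eff)

    ref, tst = sheet.group_masks()
    n1, n2 = int(ref.sum()), int(tst.sum())
    y1, y2 = pseudo[:, ref], pseudo[:, tst]

    expressed = pseudo.sum(axis=1) > 0
    opt = minimize_scalar(
        lambda lg: -_conditional_loglik(np.exp(lg), y1[expressed], y2[expressed]),
        bounds=(np.log(1e-6), np.log(5.0)),
        method="bounded",
    )
    common_phi = float(np.exp(opt.x))

    moment = _moment_dispersion(y1, y2)
    d = max(cm.n_samples - 2, 1)
    tagwise = (d * moment + prior_df * common_phi) / (d + prior_df)

    s1 = np.rint(y1.sum(axis=1)).astype(np.int64)
    s2 = np.rint(y2.sum(axis=1)).astype(np.int64)
    totals = s1 + s2
    p = np.ones(cm.n_genes)
    for g in range(cm.n_genes):
        phi = tagwise[g]
        if phi < 1e-8:
            p[g] = _binom_exact_pvalue(int(s1[g]), int(totals[g]), n1 / (n1 + n2))
        else:
            p[g] = _exact_nb_pvalue(int(s1[g]), int(totals[g]), n1 / phi, n2 / phi)

    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    log2_fc = np.log2((m2 + LOG2FC_PRIOR) / (m1 + LOG2FC_PRIOR))
    base_mean = pseudo.mean(axis=1)
    stat = np.sign(log2_fc) * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    return _finish(
        "nb_exact",
        cm.counts.index,
        base_mean,
        log2_fc,
        stat,
        p,
        extras={"common_dispersion": common_phi, "tagwise_dispersion": tagwise},
    )


# ---------------------------------------------------------------------------
# voom + moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to sample variances.

    Returns ``(d0, s0^2)``: the prior degrees of freedom and prior value.
    ``d0 = inf`` when the observed variances show no heterogeneity beyond
    chi-square sampling noise.
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / max(n - 1, 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar <= 0:
        # no heterogeneity beyond sampling noise: the prior degenerates to
        # the pooled (geometric-mean) observed variance, so moderation is a
        # fixed point when every gene shows the same variance
        return np.inf, float(np.exp(np.mean(z)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def run_voom_t(
    cm: CountMatrix,
    sheet: SampleSheet,
    factors: NormFactors | None = None,
    lowess_frac: float = 0.5,
) -> DEResult:
    """Mean-variance precision weights plus an EB-moderated t-test.

    Log2-CPM values are modelled linearly per gene; a lowess trend of
    sqrt(residual sd) versus average log2 count supplies inverse-trend^4
    observation weights; residual variances are squeezed toward a common
    prior estimated by method of moments, and the moderated t gains the
    prior degrees of freedom.
    """
    if factors is None:
        factors = tmm_factors(cm)
    m = cm.n_samples
    d_resid = m - 2
    if d_resid < 1:
        raise ValueError("need at least one residual degree of freedom")
    eff = factors.effective_lib_sizes
    logcpm = cpm(cm, factors, log=True, prior=0.5)
    x = sheet.indicator()
    ref, tst = sheet.group_masks()

    # first pass: unweighted two-group fit
    mu1 = logcpm[:, ref].mean(axis=1)
    mu2 = logcpm[:, tst].mean(axis=1)
    fitted = np.where(x[None, :] > 0, mu2[:, None], mu1[:, None])
    resid = logcpm - fitted
    s2 = (resid**2).sum(axis=1) / d_resid
    sx = logcpm.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(s2))

    smooth = lowess(sy, sx, frac=lowess_frac, return_sorted=True)
    trend_x, trend_y = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)
    fitted_cnt = fitted + np.log2(eff + 1.0)[None, :] - np.log2(1e6)
    w = np.interp(fitted_cnt, trend_x, trend_y) ** -4

    # weighted two-group fit, closed form for the [1, x] design
    A = w.sum(axis=1)
    B = (w * x).sum(axis=1)
    D = (w * x * x).sum(axis=1)
    r0 = (w * logcpm).sum(axis=1)
    r1 = (w * x * logcpm).sum(axis=1)
    det = A * D - B * B
    b0 = (D * r0 - B * r1) / det
    b1 = (A * r1 - B * r0) / det
    fit_vals = b0[:, None] + b1[:, None] * x
    s2_w = (w * (logcpm - fit_vals) ** 2).sum(axis=1) / d_resid
    var_unscaled = A / det

    d0, s0 = _fit_f_dist(s2_w, d_resid)
    if np.isinf(d0):
        s2_mod = np.full_like(s2_w, s0)
        df_total = 1e6
    else:
        s2_mod = (d0 * s0 + d_resid * s2_w) / (d0 + d_resid)
        df_total = d0 + d_resid
    t = b1 / np.sqrt(s2_mod * var_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    base_mean = cpm(cm, factors).mean(axis=1)
    return _finish(
        "voom_limma",
        cm.counts.index,
        base_mean,
        b1,
        t,
        p,
        extras={
            "s2": s2_w,
            "s2_moderated": s2_mod,
            "d0": d0,
            "s0_sq": s0,
            "weights": w,
            "logcpm": logcpm,
        },
    )


# ---------------------------------------------------------------------------
# NB GLM Wald test


def _nb_loglik_grid(
    y: np.ndarray, mu: np.ndarray, log_phi: np.ndarray, x: np.ndarray | None = None
) -> np.ndarray:
    """Per-gene NB log-likelihood at gene-specific dispersions (vectorized).

    With ``x`` given, the Cox-Reid adjustment ``-0.5 log det(X'WX)`` for
    the two-column design is included, correcting the downward bias of the
    plain dispersion MLE.
    """
    r = np.exp(-log_phi)[:, None]
    mu = np.maximum(mu, 1e-10)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    out = ll.sum(axis=1)
    if x is not None:
        w = mu / (1.0 + mu / r)
        w_test = (w * x).sum(axis=1)
        w_ref = (w * (1.0 - x)).sum(axis=1)
        out -= 0.5 * (np.log(np.maximum(w_ref, 1e-300)) + np.log(np.maximum(w_test, 1e-300)))
    return out


def _maximize_log_phi(
    objective,
    n_genes: int,
    lo: float = np.log(1e-8),
    hi: float = np.log(20.0),
    n_iter: int = 45,
) -> np.ndarray:
    """Golden-section search over log-dispersion, elementwise across genes.

    Every gene shares the initial bracket but shrinks it independently, so
    one vectorized objective evaluation advances all genes at once.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_genes, lo)
    b = np.full(n_genes, hi)
    for _ in range(n_iter):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        left = objective(c) > objective(d)
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    return np.exp((a + b) / 2.0)


def fit_dispersion_trend(base_mean: np.ndarray, disp: np.ndarray, n_iter: int = 10) -> tuple[float, float]:
    """Fit the parametric dispersion trend ``alpha(mu) = a0 + a1 / mu``.

    Iteratively reweighted least squares with gamma-style weights
    (1 / fitted^2); genes whose dispersion is implausibly far from the
    current fit are dropped between iterations.
    """
    mu = np.asarray(base_mean, dtype=float)
    d = np.asarray(disp, dtype=float)
    use = (d > 1e-7) & (mu > 0)
    mu, d = mu[use], d[use]
    if mu.size < 10:
        return float(np.median(d)) if d.size else 0.1, 0.0
    a0, a1 = max(float(np.median(d)), 1e-4), 1.0
    for _ in range(n_iter):
        fitted = np.maximum(a0 + a1 / mu, 1e-8)
        ratio = d / fitted
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.sum() < 10:
            break
        w = 1.0 / fitted[keep] ** 2
        x1 = 1.0 / mu[keep]
        dd = d[keep]
        A = w.sum()
        B = (w * x1).sum()
        C = (w * x1 * x1).sum()
        r0 = (w * dd).sum()
        r1 = (w * x1 * dd).sum()
        det = A * C - B * B
        if det <= 0:
            break
        new_a0 = (C * r0 - B * r1) / det
        new_a1 = (A * r1 - B * r0) / det
        new_a0 = max(new_a0, 1e-6)
        new_a1 = max(new_a1, 0.0)
        if abs(new_a0 - a0) < 1e-8 and abs(new_a1 - a1) < 1e-8:
            a0, a1 = new_a0, new_a1
            break
        a0, a1 = new_a0, new_a1
    return float(a0), float(a1)


def run_nb_wald(
    cm: CountMatrix,
    sheet: SampleSheet,
    factors: NormFactors | None = None,
    cooks_filter: bool = False,
    cooks_flags: pd.DataFrame | None = None,
) -> DEResult:
    """NB GLM Wald test with MAP dispersion shrinkage toward a trend.

    Median-of-ratios size factors; per-gene dispersion MLE; a parametric
    trend ``a0 + a1/mu`` fit across genes; MAP shrinkage of log-dispersion
    toward the trend with a prior width estimated from the spread of the
    gene-wise values (dispersion outliers more than 2 log2 units above the
    trend keep their MLE); Wald z on the condition coefficient.

    With ``cooks_filter=True`` and a table of Cook's-flagged cells, flagged
    genes get ``p = NaN`` (excluded from BH).  Default is flags only.
    """
    if factors is None:
        factors = median_of_ratios(cm)
    y = cm.values().astype(float)
    sf = factors.factors
    offset = np.log(sf)
    x = sheet.indicator()
    ref, tst = sheet.group_masks()
    q = y / sf
    base_mean = q.mean(axis=1)

    # moment fitted means per sample (group means on the normalized scale)
    mu_hat = np.where(x[None, :] > 0, q[:, tst].mean(axis=1)[:, None], q[:, ref].mean(axis=1)[:, None]) * sf
    mu_hat = np.maximum(mu_hat, 1e-8)

    def mle_objective(log_phi: np.ndarray) -> np.ndarray:
        return _nb_loglik_grid(y, mu_hat, log_phi, x)

    disp_mle = _maximize_log_phi(mle_objective, cm.n_genes)

    a0, a1 = fit_dispersion_trend(base_mean, disp_mle)
    disp_trend = np.maximum(a0 + a1 / np.maximum(base_mean, 1e-8), 1e-8)

    log_resid = np.log(np.maximum(disp_mle, 1e-8)) - np.log(disp_trend)
    m, p_coef = cm.n_samples, 2
    sampling_var = float(special.polygamma(1, max(m - p_coef, 1) / 2.0))
    mad = float(np.median(np.abs(log_resid - np.median(log_resid)))) * 1.4826
    prior_var = max(mad**2 - sampling_var, 0.25)

    log_trend = np.log(disp_trend)

    def map_objective(log_phi: np.ndarray) -> np.ndarray:
        return _nb_loglik_grid(y, mu_hat, log_phi, x) - (log_phi - log_trend) ** 2 / (
            2.0 * prior_var
        )

    disp_map = _maximize_log_phi(map_objective, cm.n_genes)
    outlier = log_resid > 2.0 * np.log(2.0)
    disp_final = np.where(outlier, disp_mle, disp_map)
    disp_final = np.maximum(disp_final, 1e-8)

    fit = fit_nb_glm(y, x, offset, disp_final)
    if not fit.converged.all():
        bad = cm.counts.index[~fit.converged]
        logger.warning(
            "NB GLM did not fully converge for %d gene(s), e.g. %s; "
            "last IRLS iterate used",
            len(bad),
            list(bad[:5]),
        )
    z = fit.beta1 / fit.se_beta1
    p = 2.0 * stats.norm.sf(np.abs(z))
    log2_fc = fit.beta1 / np.log(2.0)

    if cooks_filter and cooks_flags is not None:
        flagged = cooks_flags.reindex(cm.counts.index).fillna(False).any(axis=1).to_numpy()
        p = np.where(flagged, np.nan, p)

    return _finish(
        "nb_wald",
        cm.counts.index,
        base_mean,
        log2_fc,
        z,
        p,
        extras={
            "dispersion_mle": disp_mle,
            "dispersion_map": disp_final,
            "dispersion_trend": disp_trend,
            "trend_a0": a0,
            "trend_a1": a1,
            "prior_var": prior_var,
            "mu": fit.mu,
            "size_factors": sf,
        },
    )


# ---------------------------------------------------------------------------
# variance-component score test


def run_score_test(
    cm: CountMatrix,
    sheet: SampleSheet,
    factors: NormFactors | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> DEResult:
    """Score test for association between log2-CPM and the condition.

    ``Q = (sum y x)^2 / (sigma^2 sum x^2)`` on centered quantities, with an
    asymptotic chi-square(1) null; with ``n_perm > 0`` the null is taken
    over label permutations instead (all distinct reassignments when there
    are at most 10,000, otherwise sampled).
    """
    if factors is None:
        factors = tmm_factors(cm)
    logcpm = cpm(cm, factors, log=True, prior=0.5)
    m = cm.n_samples
    x_raw = sheet.indicator()
    xc = x_raw - x_raw.mean()
    yc = logcpm - logcpm.mean(axis=1, keepdims=True)

    def score_stat(xcv: np.ndarray) -> np.ndarray:
        num = (yc * xcv).sum(axis=1) ** 2
        beta = (yc * xcv).sum(axis=1) / (xcv**2).sum()
        resid = yc - beta[:, None] * xcv
        sig2 = (resid**2).sum(axis=1) / max(m - 2, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = num / (sig2 * (xcv**2).sum())
        return np.where(sig2 <= 0, 0.0, q)

    q_obs = score_stat(xc)
    constant = yc.std(axis=1) == 0

    if n_perm <= 0:
        p = stats.chi2.sf(q_obs, 1)
    else:
        n1 = int(x_raw.sum())
        from math import comb

        n_distinct = comb(m, n1)
        if n_distinct <= 10000:
            perms = []
            for idx in itertools.combinations(range(m), n1):
                v = np.zeros(m)
                v[list(idx)] = 1.0
                perms.append(v - v.mean())
            ge = np.zeros(cm.n_genes)
            for v in perms:
                ge += score_stat(v) >= q_obs - 1e-12
            p = ge / len(perms)
        else:
            rng = np.random.default_rng(seed)
            ge = np.zeros(cm.n_genes)
            for _ in range(n_perm):
                v = np.zeros(m)
                v[rng.choice(m, n1, replace=False)] = 1.0
                ge += score_stat(v - v.mean()) >= q_obs - 1e-12
            p = (1.0 + ge) / (1.0 + n_perm)

    p = np.where(constant, 1.0, p)
    ref, tst = sheet.group_masks()
    log2_fc = logcpm[:, tst].mean(axis=1) - logcpm[:, ref].mean(axis=1)
    log2_fc = np.where(constant, 0.0, log2_fc)
    base_mean = cpm(cm, factors).mean(axis=1)
    return _finish("score_test", cm.counts.index, base_mean, log2_fc, q_obs, p)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def run_wilcoxon(
    cm: CountMatrix, sheet: SampleSheet, factors: NormFactors | None = None
) -> DEResult:
    """Two-sided rank-sum test per gene on CPM values.

    Exact null distribution when both groups have at most 25 samples and a
    gene has no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    if factors is None:
        factors = tmm_factors(cm)
    vals = cpm(cm, factors)
    ref, tst = sheet.group_masks()
    a, b = vals[:, tst], vals[:, ref]
    n1, n2 = a.shape[1], b.shape[1]

    has_ties = np.array(
        [np.unique(row).size < row.size for row in np.concatenate([a, b], axis=1)]
    )
    small = n1 <= 25 and n2 <= 25
    p = np.ones(cm.n_genes)
    u = np.zeros(cm.n_genes)
    exact_mask = small & ~has_ties
    if exact_mask.any():
        res = stats.mannwhitneyu(
            a[exact_mask], b[exact_mask], alternative="two-sided", method="exact", axis=1
        )
        p[exact_mask] = res.pvalue
        u[exact_mask] = res.statistic
    approx_mask = ~exact_mask
    if approx_mask.any():
        res = stats.mannwhitneyu(
            a[approx_mask],
            b[approx_mask],
            alternative="two-sided",
            method="asymptotic",
            use_continuity=True,
            axis=1,
        )
        p[approx_mask] = res.pvalue
        u[approx_mask] = res.statistic
    p = np.minimum(p, 1.0)

    log2_fc = np.log2((a.mean(axis=1) + LOG2FC_PRIOR) / (b.mean(axis=1) + LOG2FC_PRIOR))
    base_mean = vals.mean(axis=1)
    return _finish("wilcoxon", cm.counts.index, base_mean, log2_fc, u, p)


# ---------------------------------------------------------------------------
# orchestration


def run_all_engines(
    cm: CountMatrix,
    sheet: SampleSheet,
    include_wilcoxon: bool = False,
    seed: int | None = None,
    n_perm: int = 0,
) -> dict[str, DEResult]:
    """Run the four engines (plus optionally Wilcoxon) on one filtered matrix.

    Filtering is shared; normalization is per engine (TMM for the exact,
    voom and score engines, median-of-ratios for the Wald engine).  Any
    engine failure aborts the run with the engine named.
    """
    tmm = tmm_factors(cm)
    runners = {
        "nb_exact": lambda: run_nb_exact(cm, sheet, tmm),
        "voom_limma": lambda: run_voom_t(cm, sheet, tmm),
        "nb_wald": lambda: run_nb_wald(cm, sheet),
        "score_test": lambda: run_score_test(cm, sheet, tmm, n_perm=n_perm, seed=seed),
    }
    if include_wilcoxon:
        runners["wilcoxon"] = lambda: run_wilcoxon(cm, sheet, tmm)
    results: dict[str, DEResult] = {}
    for name, runner in runners.items():
        try:
            results[name] = runner()
        except Exception as exc:  # noqa: BLE001 - re-raise with engine context
            raise RuntimeError(f"engine {name!r} failed: {exc}") from exc
    gene_sets = {tuple(r.table.index) for r in results.values()}
    if len(gene_sets) != 1:
        raise RuntimeError("engines returned differing gene sets")
    return results
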