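"""Activity calling: median-of-ratios normalization and a negative-binomial
Wald test of RNA barcode counts against the plasmid input.

The model for oligo i in sample j is

    K_ij ~ NB(mu_ij, alpha_i),    mu_ij = s_j * q_i * 2^{beta_i * 1[RNA_j]}

with size factors s_j from median-of-ratios normalization (computed within a
library batch, across that batch's DNA and RNA samples jointly), per-oligo
baseline abundance q_i, log2 fold change beta_i of RNA over plasmid, and NB
dispersion alpha_i (variance mu + alpha*mu^2).

Because the RNA indicator partitions the samples into two groups, the
likelihood in (q_i, beta_i) separates into two one-parameter group-mean
problems, each solved by a damped Newton iteration vectorized across oligos.
The dispersion recipe is: per-oligo profile MLE of alpha on a refined log
grid, then shrinkage of log alpha toward a rolling-median trend over oligos
of similar base mean.  A sequence is called "MPRA active" when its BH
q-value is below 1% AND beta > 0 (activation, not depletion).

The standard-culture condition is tested only against the batch-1 plasmid
input, DMSO/Tg only against batch-2: the two library preparations are never
compared directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .samples import condition_batch, dna_samples, rna_samples, validate_sample_sheet

__all__ = [
    "bh_adjust",
    "element_activity",
    "fit_nb",
    "size_factors",
    "test_activity",
]

_ALPHA_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame, samples: pd.DataFrame | None = None) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over reference oligos i of K_ij / geomean_i(K_i.), where the
    reference set is the oligos with all-positive counts across the involved
    samples.  When a sample sheet is given, factors are computed per batch
    over that batch's DNA and RNA samples jointly; otherwise over all columns.
    """
    if samples is None:
        return _size_factors_block(counts)
    validate_sample_sheet(samples)
    out = pd.Series(index=counts.columns, dtype=float)
    for batch, grp in samples.groupby("batch"):
        cols = [c for c in grp["sample_id"] if c in counts.columns]
        if not cols:
            continue
        out[cols] = _size_factors_block(counts[cols])
    return out


def _size_factors_block(counts: pd.DataFrame) -> pd.Series:
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no oligo has positive counts in every sample; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference fallback)")
    sub = mat[positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    sf = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (``method="fdr_by"`` for the
    Benjamini-Yekutieli variant)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized across oligos)
# ---------------------------------------------------------------------------

def _solve_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                      n_iter: int = 40) -> np.ndarray:
    """MLE of the group mean m in mu_j = s_j * m for NB(mu, alpha) counts.

    ``y`` is (n_oligos, n_samples); ``s`` (n_samples,); ``alpha`` (n_oligos,).
    Damped Newton on t = log m; the score is strictly decreasing in t, so the
    iteration is globally stable.  Rows with all-zero counts return 0.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    a = np.maximum(np.asarray(alpha, dtype=float), _ALPHA_FLOOR)[:, None]
    tot = y.sum(axis=1)
    zero = tot == 0
    with np.errstate(divide="ignore"):
        t = np.log(np.maximum((y / s).mean(axis=1), 1e-12))
    for _ in range(n_iter):
        mu = s * np.exp(t)[:, None]
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + a * y) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        np.clip(step, -3.0, 3.0, out=step)
        t = t + step
        if np.max(np.abs(step)) < 1e-12:
            break
    m = np.exp(t)
    m[zero] = 0.0
    return m


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; alpha per row."""
    a = np.maximum(alpha, _ALPHA_FLOOR)[:, None]
    r = 1.0 / a
    mu = np.maximum(mu, 1e-300)
    return (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))).sum(axis=1)


def _profile_alpha_mle(y_dna, y_rna, s_dna, s_rna,
                       grid: np.ndarray | None = None) -> np.ndarray:
    """Per-oligo profile MLE of the dispersion over a refined log-alpha grid.

    For each candidate alpha the two group means are re-solved (profiling out
    q and beta), the profiled log-likelihood is evaluated, and the grid
    maximum is refined once by a local parabolic step in log alpha.
    """
    n = y_dna.shape[0]
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(8.0), 49))
    lls = np.empty((len(grid), n))
    for g, a in enumerate(grid):
        av = np.full(n, a)
        m_d = _solve_group_mean(y_dna, s_dna, av)
        m_r = _solve_group_mean(y_rna, s_rna, av)
        ll = _nb_loglik(y_dna, s_dna * m_d[:, None], av)
        ll += _nb_loglik(y_rna, s_rna * m_r[:, None], av)
        lls[g] = ll
    best = np.argmax(lls, axis=0)
    log_grid = np.log(grid)
    alpha = log_grid[best].copy()
    # one parabolic refinement where the maximum is interior
    interior = (best > 0) & (best < len(grid) - 1)
    if interior.any():
        i = best[interior]
        x0, x1, x2 = log_grid[i - 1], log_grid[i], log_grid[i + 1]
        f0 = lls[i - 1, np.flatnonzero(interior)]
        f1 = lls[i, np.flatnonzero(interior)]
        f2 = lls[i + 1, np.flatnonzero(interior)]
        denom = (f0 - 2 * f1 + f2)
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (f0 - f2) / np.where(np.abs(denom) > 1e-12, denom, 1.0), 0.0)
        np.clip(shift, -1.0, 1.0, out=shift)
        alpha[interior] = x1 + shift * (x2 - x1)
    return np.maximum(np.exp(alpha), _ALPHA_FLOOR)


def _dispersion_trend(base_mean: np.ndarray, alpha_mle: np.ndarray,
                      window: int = 50) -> np.ndarray:
    """Rolling-median trend of log alpha over oligos ordered by base mean."""
    order = np.argsort(base_mean, kind="stable")
    la = pd.Series(np.log(alpha_mle[order]))
    trend = la.rolling(window, center=True, min_periods=1).median().to_numpy()
    out = np.empty_like(trend)
    out[order] = trend
    return np.exp(out)


def fit_nb(y_dna, y_rna, s_dna=None, s_rna=None, alpha: float | None = None):
    """Fit one oligo: returns dict with beta (log2FC RNA vs plasmid), its
    standard error (log2 scale), baseline q (DNA-scale mean), and alpha.

    With ``alpha=None`` the dispersion is the joint (profile) MLE; otherwise
    it is held fixed.  Counts are 1-D arrays; size factors default to 1.
    """
    y_d = np.atleast_2d(np.asarray(y_dna, dtype=float))
    y_r = np.atleast_2d(np.asarray(y_rna, dtype=float))
    s_d = np.ones(y_d.shape[1]) if s_dna is None else np.asarray(s_dna, dtype=float)
    s_r = np.ones(y_r.shape[1]) if s_rna is None else np.asarray(s_rna, dtype=float)
    if y_d.sum() == 0 and y_r.sum() == 0:
        raise ValueError("all counts are zero; oligo is untestable")
    if alpha is None:
        a = _profile_alpha_mle(y_d, y_r, s_d, s_r)
        # single-oligo path: polish the grid estimate with a bounded scalar
        # maximization of the profiled likelihood in log alpha
        from scipy.optimize import minimize_scalar

        def negprof(la):
            av = np.array([np.exp(la)])
            m_d = _solve_group_mean(y_d, s_d, av)
            m_r = _solve_group_mean(y_r, s_r, av)
            ll = (_nb_loglik(y_d, s_d * m_d[:, None], av)
                  + _nb_loglik(y_r, s_r * m_r[:, None], av))
            return -float(ll[0])

        la0 = np.log(a[0])
        res = minimize_scalar(negprof, bounds=(la0 - 1.5, la0 + 1.5),
                              method="bounded", options={"xatol": 1e-8})
        if res.fun <= negprof(la0):
            a = np.array([np.exp(res.x)])
    else:
        a = np.full(y_d.shape[0], float(alpha))
    beta, se, q, _, _ = _wald_stats(y_d, y_r, s_d, s_r, a)
    return {"beta": float(beta[0]), "se": float(se[0]),
            "q": float(q[0]), "alpha": float(a[0])}


def _wald_stats(y_dna, y_rna, s_dna, s_rna, alpha):
    """Vectorized group-mean fits and Wald statistics.

    Returns (beta_log2, se_log2, m_dna, m_rna, info) arrays.  In the
    (log m_dna, log m_rna) parametrization the Fisher information is
    diagonal, so var(log m_rna - log m_dna) = 1/I_dna + 1/I_rna with
    I_g = sum_j mu_j / (1 + alpha*mu_j).
    """
    a = np.maximum(np.asarray(alpha, dtype=float), _ALPHA_FLOOR)
    m_d = _solve_group_mean(y_dna, s_dna, a)
    m_r = _solve_group_mean(y_rna, s_rna, a)
    # continuity correction: an all-zero group gets a half-count mean so the
    # contrast stays finite (conservatively large SE from the tiny info)
    m_d = np.maximum(m_d, 0.5 / s_dna.sum())
    m_r = np.maximum(m_r, 0.5 / s_rna.sum())
    ln2 = np.log(2.0)

    def group_info(s, m):
        mu = s * m[:, None]
        return (mu / (1.0 + a[:, None] * mu)).sum(axis=1)

    i_d = group_info(s_dna, m_d)
    i_r = group_info(s_rna, m_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (np.log(m_r) - np.log(m_d)) / ln2
        var = 1.0 / np.maximum(i_d, 1e-300) + 1.0 / np.maximum(i_r, 1e-300)
    se = np.sqrt(var) / ln2
    return beta, se, m_d, m_r, (i_d, i_r)


# ---------------------------------------------------------------------------
# Activity test
# ---------------------------------------------------------------------------

def test_activity(counts: pd.DataFrame, samples: pd.DataFrame, condition: str,
                  fdr: float = 0.01, shrink: float = 0.5,
                  one_sided: bool = False, sf: pd.Series | None = None,
                  fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Call MPRA-active oligos in one culture condition.

    Tests the condition's RNA replicates against the plasmid input of the
    same library batch.  Oligos with zero counts everywhere, or zero plasmid
    counts in every DNA sample, are flagged untested (no silent NA p-values).
    ``shrink`` is the weight of the rolling-median dispersion trend in the
    final log-dispersion (0 = per-oligo MLE only, 1 = trend only).

    Returns a per-oligo DataFrame: oligo_id, condition, base_mean, log2fc,
    alpha, stat, pvalue, qvalue, active, tested.
    """
    validate_sample_sheet(samples)
    batch = condition_batch(condition)
    dna_cols = dna_samples(samples, batch)
    rna_cols = rna_samples(samples, condition)
    if len(rna_cols) < 2:
        raise ValueError(f"condition {condition!r} has <2 RNA replicates")
    if sf is None:
        sf = size_factors(counts[dna_cols + rna_cols])
    s_d = sf[dna_cols].to_numpy()
    s_r = sf[rna_cols].to_numpy()
    y_d = counts[dna_cols].to_numpy(dtype=float)
    y_r = counts[rna_cols].to_numpy(dtype=float)

    norm = np.hstack([y_d / s_d, y_r / s_r])
    base_mean = norm.mean(axis=1)
    tested = (y_d.sum(axis=1) > 0) & ((y_d.sum(axis=1) + y_r.sum(axis=1)) > 0)

    n = len(counts)
    beta = np.full(n, np.nan)
    se = np.full(n, np.nan)
    alpha = np.full(n, np.nan)
    stat = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    qval = np.full(n, np.nan)

    if tested.any():
        ix = np.flatnonzero(tested)
        a_mle = _profile_alpha_mle(y_d[ix], y_r[ix], s_d, s_r)
        a_trend = _dispersion_trend(base_mean[ix], a_mle)
        a_final = np.exp((1.0 - shrink) * np.log(a_mle) + shrink * np.log(a_trend))
        a_final = np.maximum(a_final, _ALPHA_FLOOR)
        b, s_e, m_d, m_r, _ = _wald_stats(y_d[ix], y_r[ix], s_d, s_r, a_final)
        z = b / s_e
        p = 2.0 * stats.norm.sf(np.abs(z))
        if one_sided:
            p = stats.norm.sf(z)
        beta[ix], se[ix], alpha[ix], stat[ix], pval[ix] = b, s_e, a_final, z, p
        qval[ix] = bh_adjust(pval[ix], method=fdr_method)

    active = np.zeros(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        active[tested] = (qval[tested] < fdr) & (beta[tested] > 0)
    return pd.DataFrame({
        "oligo_id": counts.index,
        "condition": condition,
        "base_mean": base_mean,
        "log2fc": beta,
        "alpha": alpha,
        "stat": stat,
        "pvalue": pval,
        "qvalue": qval,
        "active": active,
        "tested": tested,
    }).reset_index(drop=True)


def element_activity(activity: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Element-level roll-up: an element is active in a condition if >=1 of
    its allele oligos is active there.  Accepts results from one or several
    conditions (concatenated); also emits the any-condition union."""
    lib = library[["oligo_id", "element_id"]]
    merged = activity.merge(lib, on="oligo_id", how="left")
    per_cond = (merged.groupby(["element_id", "condition"])["active"]
                .any().rename("active").reset_index())
    union = (per_cond.groupby("element_id")["active"].any()
             .rename("active_any_condition").reset_index())
    return per_cond.merge(union, on="element_id")
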