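"""Single-SNP association tests, candidate orderings, and the
single-marker + Benjamini-Hochberg comparator.

Conventions
-----------
The Cochran-Armitage trend test is reported by default with the classical
conditional (finite-population-corrected) variance, giving the statistic
``(N - 1) * r^2`` for the genotype/status correlation ``r``.  The
model-based variant ``N * r^2`` (``variance="model"``) coincides exactly
with the logistic Rao score test at the unpenalized intercept-only model;
the two conventions differ by the factor ``N / (N - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, log_expit
from statsmodels.stats.multitest import multipletests

from .datasets import GenotypeDataset
from .firth import ModelFit, _design

__all__ = [
    "SnpOrdering",
    "cochran_armitage",
    "score_test",
    "order_snps",
    "benjamini_hochberg",
    "single_marker_scan",
]


@dataclass
class SnpOrdering:
    """Candidate SNPs ranked by a test statistic (descending, ties by index)."""

    order: np.ndarray
    statistics: np.ndarray


def _trend_statistics(ds: GenotypeDataset, variance: str = "conditional") -> np.ndarray:
    """Vectorized trend chi-square statistic for every SNP (0 if constant)."""
    if variance not in ("conditional", "model"):
        raise ValueError("variance must be 'conditional' or 'model'")
    g = ds.genotypes
    y = np.asarray(ds.phenotype, dtype=float)
    n = ds.n
    ybar = y.mean()
    u = g.T @ (y - ybar)
    sxx = np.einsum("ij,ij->j", g, g) - n * g.mean(axis=0) ** 2
    syy = np.sum((y - ybar) ** 2)
    scale = float(n if variance == "model" else n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where((sxx > 0) & (syy > 0), scale * u**2 / (sxx * syy), 0.0)
    return stat


def cochran_armitage(
    ds: GenotypeDataset, snp: int, variance: str = "conditional"
) -> tuple:
    """Cochran-Armitage additive trend test with scores (0, 1, 2).

    Returns ``(statistic, p)`` with the upper-tail chi-square(1) p-value.
    Raises ``ValueError`` for a constant SNP.
    """
    x = ds.genotypes[:, snp]
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError(f"SNP column {snp} is constant")
    stat = float(_trend_statistics(ds, variance=variance)[snp])
    return stat, float(stats.chi2.sf(stat, df=1))


def _score_statistics(
    ds: GenotypeDataset, fit: ModelFit, candidates: np.ndarray, efficient: bool = True
) -> np.ndarray:
    """Rao score statistic for adding each candidate SNP to ``fit``.

    ``U^2 / V`` with ``U = x'(y - pi)`` and, by default, ``V`` the efficient
    information of the candidate column after projecting out the fitted
    design under weights ``pi (1 - pi)``.  Collinear candidates get 0.
    """
    X = _design(ds, fit.snp_indices)
    y = np.asarray(ds.phenotype, dtype=float)
    pi = expit(X @ fit.beta)
    w = pi * (1.0 - pi)
    G = ds.genotypes[:, candidates]
    u = G.T @ (y - pi)
    v_raw = np.einsum("ij,ij->j", G * w[:, None], G)
    v = v_raw
    if efficient:
        b = X.T @ (G * w[:, None])  # (m, c)
        xtwx = (X * w[:, None]).T @ X
        v = v_raw - np.einsum("ij,ij->j", b, np.linalg.solve(xtwx, b))
    # candidates (near-)collinear with the fitted design carry no information
    ok = v > np.maximum(1e-12, 1e-8 * v_raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        statv = np.where(ok, u**2 / np.where(ok, v, 1.0), 0.0)
    return statv


def score_test(
    ds: GenotypeDataset, fit: ModelFit, snp: int, efficient: bool = True
) -> float:
    """Score statistic for adding one SNP to a fitted logistic model."""
    if snp in fit.snp_indices:
        raise ValueError(f"SNP {snp} is already in the model")
    return float(_score_statistics(ds, fit, np.array([snp]), efficient=efficient)[0])


def order_snps(ds: GenotypeDataset, fit: ModelFit, method: str = "marginal") -> SnpOrdering:
    """Rank the non-model SNPs for the stepwise search.

    ``marginal`` ranks by the Cochran-Armitage trend statistic; ``conditional``
    by the score statistic given ``fit``.  Descending, ties broken by
    ascending SNP index; constant SNPs rank last with statistic 0.
    """
    in_model = set(fit.snp_indices)
    candidates = np.array([j for j in range(ds.p) if j not in in_model], dtype=int)
    if method == "marginal":
        statv = _trend_statistics(ds)[candidates]
    elif method == "conditional":
        statv = _score_statistics(ds, fit, candidates)
    else:
        raise ValueError("method must be 'marginal' or 'conditional'")
    perm = np.lexsort((candidates, -statv))
    return SnpOrdering(order=candidates[perm], statistics=statv[perm])


def benjamini_hochberg(pvals, q: float = 0.05) -> np.ndarray:
    """Indices rejected by the Benjamini-Hochberg step-up rule at level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=int)
    if pvals.min() < 0 or pvals.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return np.flatnonzero(reject)


def _batch_logistic_lrt(C: np.ndarray, G: np.ndarray, y: np.ndarray):
    """LRT p-value per column of G for logistic y ~ C + g, fitted by Newton.

    Returns ``(pvals, converged)``; non-converged columns carry NaN p-values.
    """
    n, m = C.shape
    p = G.shape[1]

    def loglik_and_fit(Xd):
        beta = np.zeros(Xd.shape[1])
        for _ in range(50):
            eta = Xd @ beta
            pi = expit(eta)
            w = np.clip(pi * (1 - pi), 1e-10, None)
            score = Xd.T @ (y - pi)
            xtwx = (Xd * w[:, None]).T @ Xd
            try:
                step = np.linalg.solve(xtwx, score)
            except np.linalg.LinAlgError:
                return -np.inf, False
            beta = beta + step
            if np.max(np.abs(step)) < 1e-8:
                eta = Xd @ beta
                return float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta))), True
        eta = Xd @ beta
        return float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta))), False

    ll_null, ok = loglik_and_fit(C)
    if not ok:
        return np.full(p, np.nan), np.zeros(p, dtype=bool)

    # batched Newton over all SNPs at once
    md = m + 1
    Xb = np.empty((p, n, md))
    Xb[:, :, :m] = C[None, :, :]
    Xb[:, :, m] = G.T
    beta = np.zeros((p, md))
    converged = np.zeros(p, dtype=bool)
    for _ in range(40):
        eta = np.einsum("pnm,pm->pn", Xb, beta)
        pi = expit(eta)
        w = np.clip(pi * (1 - pi), 1e-10, None)
        score = np.einsum("pnm,pn->pm", Xb, y[None, :] - pi)
        xtwx = np.einsum("pnm,pn,pnk->pmk", Xb, w, Xb)
        xtwx += 1e-12 * np.eye(md)[None, :, :]
        try:
            step = np.linalg.solve(xtwx, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        active = ~converged
        beta[active] += step[active]
        converged |= np.max(np.abs(step), axis=1) < 1e-8
        if converged.all():
            break
    eta = np.einsum("pnm,pm->pn", Xb, beta)
    ll_full = np.sum(y[None, :] * log_expit(eta) + (1 - y)[None, :] * log_expit(-eta), axis=1)
    lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    pvals = stats.chi2.sf(lrt, df=1)
    pvals[~converged] = np.nan
    return pvals, converged


def genotype_pcs(ds: GenotypeDataset, n_pcs: int) -> np.ndarray:
    """Leading principal components of the column-standardized genotype matrix."""
    if n_pcs == 0:
        return np.empty((ds.n, 0))
    g = ds.genotypes
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    z = (g - mu) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def single_marker_scan(
    ds: GenotypeDataset, q: float = 0.05, n_pcs: int = 4, return_table: bool = False
):
    """Single-marker comparator: per-SNP logistic LRT + Benjamini-Hochberg.

    Each SNP is tested by the likelihood-ratio test of an ordinary logistic
    regression of status on the SNP plus the leading ``n_pcs`` principal
    components of the standardized genotype matrix (population-structure
    adjustment).  Separated / non-converged SNPs fall back to the trend-test
    p-value.  Returns the BH-rejected SNP indices at level ``q`` (and, when
    ``return_table`` is set, a DataFrame with per-SNP statistics).
    """
    if not 0 <= n_pcs < ds.n:
        raise ValueError("n_pcs must be >= 0 and < n")
    pcs = genotype_pcs(ds, n_pcs)
    C = np.column_stack([np.ones(ds.n), pcs])
    y = np.asarray(ds.phenotype, dtype=float)
    pvals, converged = _batch_logistic_lrt(C, ds.genotypes, y)
    trend = _trend_statistics(ds)
    fallback = stats.chi2.sf(trend, df=1)
    pvals = np.where(np.isnan(pvals), fallback, pvals)
    selected = benjamini_hochberg(pvals, q=q)
    if not return_table:
        return selected
    import pandas as pd

    table = pd.DataFrame(
        {
            "snp_id": ds.snps["snp_id"],
            "p": pvals,
            "converged": converged,
            "rejected": np.isin(np.arange(ds.p), selected),
        }
    )
    return selected, table
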