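"""Per-trait association of a gene score, on a common N(0,1) scale.

For a quantitative trait the score enters an ordinary least-squares
regression adjusted for covariates; the t statistic of its coefficient is
mapped through the central-t CDF to a standard-normal quantile
(Z = Phi^-1(F_t(t; df))), a sign-preserving, monotone transform.  For a
binary trait the score enters a maximum-likelihood logistic regression and
the Wald z of its coefficient is used directly (it is already
asymptotically standard normal, so the transform is the identity).

Permutation machinery
---------------------
The combined tests need the same statistics recomputed under many
permutations of the phenotype rows (all traits and covariates moving as
one unit, genotypes fixed).  Because a regression is invariant to row
order, permuting the phenotype block by ``pi`` equals permuting the score
by ``pi^-1`` with the phenotype block fixed.  The batch engines below
exploit this: the covariate design is factored once per trait and only
the score column varies across permutations, so a thousand refits reduce
to a few matrix products (OLS) or a batched Newton solve (logistic).
Per-trait missingness masks are fixed under this scheme, which is exactly
the case-wise-deletion behaviour of the unpermuted analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .io_formats import PhenotypeTable

_EPS = 1e-12


@dataclass
class ZVector:
    """Per-trait transformed statistics for one gene; NaN marks degenerate cells."""

    gene_id: str
    z: np.ndarray  # (m,)
    per_trait_p: np.ndarray  # (m,) = 2 * (1 - Phi(|z|))
    dfs: np.ndarray  # residual df per trait; NaN for binary (asymptotic)
    trait_names: list


def inverse_normal_transform(stat, df=None):
    """Map a t statistic to the standard-normal scale.

    ``Z = Phi^-1(F_t(t; df))`` for finite ``df``; identity when ``df`` is
    None/NaN (Wald z from logistic regression, already asymptotically
    normal).  Antisymmetric in ``stat`` and monotone at fixed ``df``;
    evaluated through log survival functions so extreme statistics do not
    overflow to infinity.
    """
    stat = np.asarray(stat, dtype=float)
    if df is None:
        return stat.copy() if stat.ndim else float(stat)
    df_arr = np.asarray(df, dtype=float)
    if np.any(df_arr[np.isfinite(df_arr)] <= 0):
        raise ValueError("degrees of freedom must be positive")
    scalar = stat.ndim == 0 and df_arr.ndim == 0
    stat, df_arr = np.atleast_1d(stat), np.atleast_1d(df_arr)
    out = np.full(np.broadcast(stat, df_arr).shape, np.nan)
    asym = ~np.isfinite(df_arr)
    b_stat, b_df = np.broadcast_arrays(stat, df_arr)
    out[asym & np.isfinite(b_stat)] = b_stat[asym & np.isfinite(b_stat)]
    ok = np.isfinite(b_stat) & ~asym
    if ok.any():
        # upper-tail log p of |t|, then -Phi^-1 of it, restore the sign
        logsf = stats.t.logsf(np.abs(b_stat[ok]), b_df[ok])
        out[ok] = np.sign(b_stat[ok]) * -special.ndtri_exp(logsf)
    return float(out[0]) if scalar else out


def two_sided_normal_p(z):
    """2 * (1 - Phi(|z|)) with NaN pass-through."""
    z = np.asarray(z, dtype=float)
    return 2.0 * stats.norm.sf(np.abs(z))


def _design(covariates: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Intercept + covariates on the complete-case rows."""
    return np.column_stack([np.ones(int(mask.sum())), covariates[mask]])


def _ols_t_batch(y: np.ndarray, F: np.ndarray, S: np.ndarray):
    """t statistics of the score coefficient for many score columns at once.

    ``y`` (n,) response, ``F`` (n,p0) fixed design (intercept+covariates),
    ``S`` (n,N) score columns.  Uses the Frisch-Waugh projection: residualize
    ``y`` and every score column on ``F``, then simple regression.  Returns
    ``(t, df)`` with NaN where the score is collinear with ``F`` or the fit
    is perfect (zero residual variance).
    """
    n, p0 = F.shape
    df = n - p0 - 1
    if df <= 0:
        return np.full(S.shape[1], np.nan), df
    Q, _ = np.linalg.qr(F)
    ey = y - Q @ (Q.T @ y)
    ES = S - Q @ (Q.T @ S)
    ss = np.einsum("ij,ij->j", ES, ES)
    syy = float(ey @ ey)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (ES.T @ ey) / ss
        rss = syy - beta**2 * ss
        sigma2 = rss / df
        t = beta / np.sqrt(sigma2 / ss)
    scale = max(syy, 1.0)
    t[(ss <= _EPS * n) | (sigma2 <= _EPS * scale)] = np.nan
    return t, df


def _logistic_fit_base(y: np.ndarray, F: np.ndarray, max_iter=100, tol=1e-8):
    """Covariates-only ML logistic fit (Newton); used as warm start."""
    p0 = F.shape[1]
    beta = np.zeros(p0)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = F @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        H = (F * w[:, None]).T @ F
        g = F.T @ (y - mu)
        try:
            beta = beta + np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if abs(ll - ll_old) < tol:
            return beta
        ll_old = ll
    return beta  # hit cap; caller's per-column convergence check governs


def _logistic_wald_batch(y: np.ndarray, F: np.ndarray, S: np.ndarray,
                         max_iter: int = 100, tol: float = 1e-8):
    """Wald z of the score coefficient for many score columns at once.

    Batched Newton-Raphson over the (p0+1)-dimensional coefficient vectors,
    warm-started at the covariates-only fit.  Convergence is declared when
    the Newton decrement ``g' H^-1 g / 2`` — which equals the remaining
    log-likelihood improvement at quadratic convergence — falls below
    ``tol``; converged columns leave the active set, so late iterations
    touch only the stragglers.  Columns that fail to converge within
    ``max_iter`` or show signs of separation (unbounded coefficients,
    singular information) come back NaN rather than aborting the batch.
    """
    n, p0 = F.shape
    N = S.shape[1]
    p = p0 + 1
    base = _logistic_fit_base(y, F, max_iter, tol)
    if base is None or not (0 < y.sum() < n):
        return np.full(N, np.nan)
    beta = np.tile(np.append(base, 0.0), (N, 1))  # (N, p)
    z = np.full(N, np.nan)
    active = np.arange(N)
    for _ in range(max_iter):
        S_a = S[:, active]
        b_a = beta[active]
        eta = F @ b_a[:, :p0].T + S_a * b_a[:, p0]  # (n, N_active)
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        g = np.empty((len(active), p))
        g[:, :p0] = resid.T @ F
        g[:, p0] = np.einsum("ij,ij->j", resid, S_a)
        H = np.empty((len(active), p, p))
        H[:, :p0, :p0] = np.einsum("ab,an,ac->nbc", F, w, F, optimize=True)
        cross = np.einsum("ab,an,an->nb", F, w, S_a, optimize=True)
        H[:, :p0, p0] = cross
        H[:, p0, :p0] = cross
        H[:, p0, p0] = np.einsum("ij,ij->j", w, S_a * S_a)
        try:
            step = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.full_like(g, np.nan)
            for k in range(len(active)):
                try:
                    step[k] = np.linalg.solve(H[k], g[k])
                except np.linalg.LinAlgError:
                    pass
        decrement = 0.5 * np.einsum("np,np->n", g, step)
        upd = b_a + step
        # saturated linear predictors signal (quasi-)separation: the Wald z
        # is meaningless there even if the decrement converges
        bad = (~np.isfinite(upd).all(axis=1)
               | (np.abs(upd).max(axis=1) > 1e6)
               | (np.abs(eta).max(axis=0) > 30.0))
        done = (np.abs(decrement) < tol) & ~bad
        beta[active] = np.where(bad[:, None], np.nan, upd)
        if done.any():
            idx = active[done]
            var = np.linalg.inv(H[done])[:, p0, p0]
            with np.errstate(invalid="ignore"):
                ok = var > 0
                z[idx[ok]] = beta[idx[ok], p0] / np.sqrt(var[ok])
        active = active[~done & ~bad]
        if active.size == 0:
            break
    return z


def fit_trait_association(score: np.ndarray, trait: np.ndarray, trait_type: str,
                          covariates: np.ndarray):
    """Single-trait fit; returns ``(statistic, df)``.

    Quantitative: OLS t of the score coefficient with residual
    ``df = n - c - 2``.  Binary: ML-logistic Wald z with ``df = inf``
    (asymptotic).  Degenerate fits (zero score variance, collinearity,
    perfect fit, separation, non-convergence) return ``(nan, df)``.
    """
    score = np.asarray(score, dtype=float)
    trait = np.asarray(trait, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    mask = np.isfinite(trait)
    if covariates.size:
        mask &= np.isfinite(covariates).all(axis=1)
    y = trait[mask]
    F = _design(covariates, mask)
    s = score[mask][:, None]
    if np.ptp(score[mask]) == 0:
        return np.nan, np.nan
    if trait_type == "quantitative":
        t, df = _ols_t_batch(y, F, s)
        return float(t[0]), float(df)
    if trait_type == "binary":
        z = _logistic_wald_batch(y, F, s)
        return float(z[0]), np.inf
    raise ValueError(f"unknown trait type {trait_type!r}")


def z_matrix(score_columns: np.ndarray, pheno: PhenotypeTable) -> np.ndarray:
    """Z statistics for every (score column, trait) pair — the batch core.

    ``score_columns`` is (n, N); column k is the gene score under the k-th
    permutation (or the observed score for N=1).  Returns an (N, m) array.
    """
    n, N = score_columns.shape
    m = pheno.n_traits
    Z = np.full((N, m), np.nan)
    for l in range(m):
        trait = pheno.traits[:, l]
        mask = np.isfinite(trait)
        if pheno.covariates.size:
            mask &= np.isfinite(pheno.covariates).all(axis=1)
        y = trait[mask]
        F = _design(pheno.covariates, mask)
        S = score_columns[mask]
        if y.size < F.shape[1] + 2 or np.ptp(y) == 0:
            continue
        if pheno.trait_types[l] == "quantitative":
            t, df = _ols_t_batch(y, F, S)
            Z[:, l] = inverse_normal_transform(t, df)
        else:
            Z[:, l] = _logistic_wald_batch(y, F, S)
    return Z


def z_vector(score: np.ndarray, pheno: PhenotypeTable, gene_id: str = "") -> ZVector:
    """Observed per-trait Z vector and two-sided p-values for one gene."""
    score = np.asarray(score, dtype=float)
    Z = z_matrix(score[:, None], pheno)[0]
    dfs = np.array(
        [
            (np.isfinite(pheno.traits[:, l]).sum() - pheno.covariates.shape[1] - 2)
            if pheno.trait_types[l] == "quantitative"
            else np.inf
            for l in range(pheno.n_traits)
        ],
        dtype=float,
    )
    return ZVector(
        gene_id=gene_id,
        z=Z,
        per_trait_p=two_sided_normal_p(Z),
        dfs=dfs,
        trait_names=list(pheno.trait_names),
    )


def permutation_score_columns(score: np.ndarray, n_perm: int,
                              rng: np.random.Generator) -> np.ndarray:
    """(n, N) matrix of independently permuted copies of the score.

    Permuting the score against fixed phenotype rows is statistically
    identical to permuting the joint phenotype+covariate block against
    fixed genotypes (the regressions are row-order invariant).
    """
    n = score.shape[0]
    idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    return score[idx].T
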