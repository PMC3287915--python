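"""Combined-multiple-traits tests: quadratic (CMT-Q) and linear (CMT-L).

The per-trait statistics Z = (Z_1, ..., Z_m) are asymptotically jointly
normal N_m(0, Sigma) under the null, with Sigma the correlation matrix of
Z induced by trait-trait (and trait-covariate) correlation.  Sigma is
unknown and is estimated by permutation: the phenotype rows are permuted
as one unit N times, Z is recomputed under each permutation exactly as in
the unpermuted analysis, and Sigma-hat is the sample correlation matrix of
the N permuted Z vectors (unit diagonal enforced).

CMT-Q:  T_Q = Z' Sigma^-1 Z   ~  chi-square_m        (two-sided in every trait)
CMT-L:  T_L = 1'Z / sqrt(1' Sigma 1)  ~  N(0, 1)     (direction-sensitive)

T_L gains power when all traits are associated in the same direction and
loses it under sign cancellation; T_Q is the robust default.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np
from scipy import linalg, stats

from .io_formats import PhenotypeTable
from .univariate import permutation_score_columns, z_matrix

logger = logging.getLogger(__name__)

#: smallest acceptable eigenvalue of Sigma-hat before shrinkage kicks in
_PD_TOL = 1e-8
#: shrinkage weight toward the identity used by the conditioning step
_SHRINK_EPS = 1e-6


class DegenerateStatistic(Exception):
    """The combined statistic is undefined for this gene (non-PD Sigma, ...)."""


@dataclass
class SigmaEstimate:
    """Permutation estimate of the m x m correlation matrix of Z."""

    sigma_hat: np.ndarray
    n_perm: int
    condition_flag: str = "ok"  # ok | regularized
    permuted_z: np.ndarray | None = None  # (N, m), kept for OCMT reuse

    @property
    def m(self) -> int:
        return self.sigma_hat.shape[0]


def _conditioned(sigma: np.ndarray) -> tuple[np.ndarray, str]:
    """Return a positive-definite version of ``sigma`` plus a flag.

    If the smallest eigenvalue is below tolerance, shrink once toward the
    identity, ``(1-eps) S + eps I``; if still not PD, raise.
    """
    sigma = np.asarray(sigma, dtype=float)
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    if eigmin >= _PD_TOL:
        return sigma, "ok"
    shrunk = (1.0 - _SHRINK_EPS) * sigma + _SHRINK_EPS * np.eye(len(sigma))
    if float(np.linalg.eigvalsh(shrunk)[0]) >= _PD_TOL * _SHRINK_EPS:
        return shrunk, "regularized"
    raise DegenerateStatistic("Sigma-hat is not positive definite after regularization")


def estimate_sigma(score: np.ndarray, pheno: PhenotypeTable, n_perm: int = 1000,
                   rng: np.random.Generator | int | None = None) -> SigmaEstimate:
    """Estimate Sigma from ``n_perm`` joint permutations of the phenotype rows.

    The permuted Z matrix is retained on the result so the OCMT layer and
    diagnostics can reuse it without refitting.  With a single trait the
    estimate is the trivial ``[[1.0]]``.

    Raises
    ------
    ValueError
        If any trait yields no finite permuted statistic (e.g. a constant
        trait), naming the trait.
    """
    rng = np.random.default_rng(rng)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for Sigma estimation; >=100 recommended")
    score = np.asarray(score, dtype=float)
    m = pheno.n_traits
    if m == 1:
        return SigmaEstimate(np.ones((1, 1)), n_perm, "ok", None)
    S = permutation_score_columns(score, n_perm, rng)
    Zp = z_matrix(S, pheno)
    ok_rows = np.isfinite(Zp).all(axis=1)
    for l, name in enumerate(pheno.trait_names):
        if not np.isfinite(Zp[:, l]).any():
            raise ValueError(f"trait {name!r} is degenerate under permutation")
    n_ok = int(ok_rows.sum())
    if n_ok < 10:
        raise ValueError("fewer than 10 usable permutations for Sigma estimation")
    if n_ok < n_perm:
        logger.info("Sigma estimation: dropped %d/%d permutations with "
                    "non-finite statistics", n_perm - n_ok, n_perm)
    with np.errstate(invalid="ignore"):
        sigma = np.corrcoef(Zp[ok_rows], rowvar=False)
    sigma = np.where(np.isfinite(sigma), sigma, 0.0)
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    # record conditioning status but store the raw estimate; the quadratic
    # solvers re-apply the shrinkage policy at use time
    try:
        _, flag = _conditioned(sigma)
    except DegenerateStatistic:
        flag = "degenerate"
    return SigmaEstimate(sigma, n_perm, flag, Zp[ok_rows])


def _quadratic_form(z: np.ndarray, sigma: np.ndarray) -> float:
    """z' Sigma^-1 z via Cholesky solve (no explicit inverse)."""
    c, low = linalg.cho_factor(sigma, lower=True)
    return float(z @ linalg.cho_solve((c, low), z))


def cmt_quadratic(z: np.ndarray, sigma: SigmaEstimate | np.ndarray):
    """CMT-Q statistic ``T_Q = Z' Sigma^-1 Z`` and its chi-square_m p-value."""
    z = np.asarray(z, dtype=float)
    sig = sigma.sigma_hat if isinstance(sigma, SigmaEstimate) else np.asarray(sigma, float)
    if not np.isfinite(z).all():
        raise DegenerateStatistic("non-finite Z entries")
    sig, _ = _conditioned(sig)
    try:
        t_q = _quadratic_form(z, sig)
    except np.linalg.LinAlgError as exc:
        raise DegenerateStatistic(str(exc)) from exc
    return t_q, float(stats.chi2.sf(t_q, len(z)))


def cmt_linear(z: np.ndarray, sigma: SigmaEstimate | np.ndarray):
    """CMT-L statistic ``T_L = 1'Z / sqrt(1' Sigma 1)`` and its normal p-value."""
    z = np.asarray(z, dtype=float)
    sig = sigma.sigma_hat if isinstance(sigma, SigmaEstimate) else np.asarray(sigma, float)
    if not np.isfinite(z).all():
        raise DegenerateStatistic("non-finite Z entries")
    denom = float(np.sum(sig))
    if denom <= 0:
        raise DegenerateStatistic("1' Sigma 1 is not positive")
    t_l = float(z.sum() / np.sqrt(denom))
    return t_l, float(2.0 * stats.norm.sf(abs(t_l)))
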