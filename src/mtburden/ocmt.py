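"""Optimal-subset test (OCMT): min CMT-Q p-value over trait subsets.

When a gene affects only some of the m traits, pooling all of them into
CMT-Q wastes degrees of freedom.  OCMT evaluates the quadratic statistic
T_Q(A) = Z_A' Sigma_A^-1 Z_A for every trait subset A with |A| >= 2
(2^m - m - 1 candidates), selects the subset A* with the smallest
chi-square p-value, and calibrates that minimum — which is optimistically
biased by the selection — with a second, independent layer of phenotype
permutations: p_OCMT = (1 + #{pi : p_{A*(pi)} <= p_{A*}}) / (N2 + 1).

Sigma-hat is the one estimated from the first permutation layer and is
reused unchanged for every OCMT permutation (re-estimating it inside each
permutation would need N x N2 nested refits for no change in the null
distribution of the min-p statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .cmt import DegenerateStatistic, SigmaEstimate, _conditioned
from .io_formats import PhenotypeTable
from .univariate import permutation_score_columns, z_matrix

#: exhaustive enumeration guard; 2^12 - 12 - 1 = 4083 subsets
MAX_TRAITS = 12


@dataclass
class SubsetResult:
    """CMT-Q evaluated on one trait subset."""

    subset: tuple  # trait indices, sorted
    stat: float
    p_value: float
    is_optimal: bool = False


def candidate_subsets(m: int) -> list[tuple]:
    """All trait-index subsets with >= 2 members, ordered by (size, lexicographic).

    The ordering is the tie-break order of :func:`min_subset`: ties on the
    p-value go to the smaller subset, then to the lexicographically first.
    """
    if m > MAX_TRAITS:
        raise ValueError(f"m={m} exceeds the exhaustive-enumeration cap {MAX_TRAITS}")
    subsets = []
    for size in range(2, m + 1):
        subsets.extend(combinations(range(m), size))
    return subsets


def _subset_solves(sigma: np.ndarray, subsets) -> list[np.ndarray]:
    """Per-subset inverse of the conditioned Sigma submatrix.

    The inverses are precomputed once because the same submatrices are hit
    for every one of the N2 permutations.
    """
    inverses = []
    for A in subsets:
        idx = np.asarray(A)
        sub, _ = _conditioned(sigma[np.ix_(idx, idx)])
        inverses.append(np.linalg.inv(sub))
    return inverses


def subset_pvalue(z: np.ndarray, sigma: SigmaEstimate | np.ndarray, subset) -> SubsetResult:
    """T_Q on the subvector/submatrix of Z and Sigma, p from chi-square_{|A|}."""
    z = np.asarray(z, dtype=float)
    sig = sigma.sigma_hat if isinstance(sigma, SigmaEstimate) else np.asarray(sigma, float)
    A = tuple(sorted(subset))
    if len(A) < 2:
        raise ValueError("subsets must contain at least two traits")
    idx = np.asarray(A)
    sub, _ = _conditioned(sig[np.ix_(idx, idx)])
    zA = z[idx]
    if not np.isfinite(zA).all():
        raise DegenerateStatistic("non-finite Z entries in subset")
    t = float(zA @ np.linalg.solve(sub, zA))
    return SubsetResult(A, t, float(stats.chi2.sf(t, len(A))))


def _min_subset_batch(Z: np.ndarray, sigma: np.ndarray, subsets, inverses):
    """Vectorized min-p selection for many Z rows; returns (argmin, p_min, t)."""
    N = Z.shape[0]
    pmat = np.full((N, len(subsets)), np.inf)
    tmat = np.full((N, len(subsets)), np.nan)
    for k, (A, inv) in enumerate(zip(subsets, inverses)):
        idx = np.asarray(A)
        ZA = Z[:, idx]
        t = np.einsum("ni,ij,nj->n", ZA, inv, ZA)
        ok = np.isfinite(t)
        tmat[ok, k] = t[ok]
        pmat[ok, k] = stats.chi2.sf(t[ok], len(A))
    best = np.argmin(pmat, axis=1)  # first occurrence = (size, lex) tie-break
    rows = np.arange(N)
    return best, pmat[rows, best], tmat[rows, best]


def min_subset(z: np.ndarray, sigma: SigmaEstimate | np.ndarray) -> SubsetResult:
    """Exhaustive arg-min of the subset p-value; the observed A*.

    Ties are broken toward the smaller subset, then lexicographic trait
    order.  Raises :class:`DegenerateStatistic` when no subset yields a
    finite statistic.
    """
    z = np.asarray(z, dtype=float)
    sig = sigma.sigma_hat if isinstance(sigma, SigmaEstimate) else np.asarray(sigma, float)
    m = len(z)
    if m < 2:
        raise ValueError("need at least two traits")
    subsets = candidate_subsets(m)
    inverses = _subset_solves(sig, subsets)
    best, pmin, tmin = _min_subset_batch(z[None, :], sig, subsets, inverses)
    if not np.isfinite(pmin[0]):
        raise DegenerateStatistic("all subsets degenerate")
    return SubsetResult(subsets[best[0]], float(tmin[0]), float(pmin[0]), is_optimal=True)


def ocmt_pvalue(score: np.ndarray, pheno: PhenotypeTable, sigma: SigmaEstimate,
                observed: SubsetResult, n_perm: int = 1000,
                rng: np.random.Generator | int | None = None) -> float:
    """Permutation-calibrated p-value of the observed minimum subset p.

    A fresh set of ``n_perm`` joint phenotype-row permutations is drawn
    (independent of the ones that built Sigma-hat); for each, Z(pi) is
    recomputed and the min-subset selection repeated against the same
    Sigma-hat.  The add-one estimator (1 + count)/(N2 + 1) keeps the
    p-value strictly positive; permutations tying the observed minimum
    count as successes.
    """
    import warnings

    rng = np.random.default_rng(rng)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for OCMT calibration; >=100 recommended")
    score = np.asarray(score, dtype=float)
    m = pheno.n_traits
    sig = sigma.sigma_hat
    subsets = candidate_subsets(m)
    inverses = _subset_solves(sig, subsets)
    S = permutation_score_columns(score, n_perm, rng)
    Zp = z_matrix(S, pheno)
    ok = np.isfinite(Zp).all(axis=1)
    _, pmin, _ = _min_subset_batch(Zp[ok], sig, subsets, inverses)
    n_used = int(ok.sum())
    if n_used == 0:
        raise DegenerateStatistic("no usable OCMT permutations")
    count = int((pmin <= observed.p_value).sum())
    return (1.0 + count) / (n_used + 1.0)
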