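"""Population-stratification correction via genotype principal components.

Top principal components of the frequency-normalized genome-wide genotype
matrix (each variant column centered at twice its sample allele frequency
and scaled by sqrt(2 p (1-p))) capture ancestry axes.  Gene scores and
quantitative traits are residualized on the first K components before
testing; binary traits keep their 0/1 coding and instead receive the K
components as extra covariates in the logistic regression.  LD pruning and
iterative outlier removal are not performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class PCScores:
    """Per-individual principal-component scores (columns are orthogonal)."""

    scores: np.ndarray  # (n, K) = U_K * s_K
    explained_variance_ratio: np.ndarray  # (K,)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def compute_pcs(genotypes: GenotypeMatrix, n_components: int = 10) -> PCScores:
    """Principal components of the frequency-normalized dosage matrix.

    Missing dosages are imputed to 0 before normalization; zero-variance
    (monomorphic) variants are dropped.  The returned scores are the left
    singular vectors scaled by the singular values.

    Raises
    ------
    ValueError
        If ``n_components`` exceeds the rank available after filtering.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    D = np.where(genotypes.dosages == MISSING, 0, genotypes.dosages).astype(float)
    p = D.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    D = D[:, keep]
    p = p[keep]
    if D.shape[1] < n_components:
        raise ValueError(
            f"only {D.shape[1]} polymorphic variants; cannot extract {n_components} PCs"
        )
    X = (D - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"requested {n_components} PCs but matrix rank is {rank}")
    total = float((s**2).sum())
    return PCScores(
        scores=U[:, :n_components] * s[:n_components],
        explained_variance_ratio=s[:n_components] ** 2 / total,
    )


def residualize(values: np.ndarray, pcs: PCScores) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus the PC columns.

    A projection: applying it twice equals applying it once.  NaNs in
    ``values`` are preserved (the fit uses complete cases only).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != pcs.scores.shape[0]:
        raise ValueError("length mismatch between values and PC scores")
    X = np.column_stack([np.ones(len(values)), pcs.scores])
    mask = np.isfinite(values)
    coef, _, rank, _ = np.linalg.lstsq(X[mask], values[mask], rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient PC design in residualization")
    out = np.full_like(values, np.nan)
    out[mask] = values[mask] - X[mask] @ coef
    return out


def read_pc_file(path, n_components: int | None = None) -> tuple[np.ndarray, PCScores]:
    """Load precomputed PC scores (TSV: sample ID + K columns).

    Returns ``(sample_ids, PCScores)``; explained-variance fractions are
    unknown for external files and reported as NaN.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    scores = df.iloc[:, 1:].to_numpy(dtype=float)
    if n_components is not None:
        scores = scores[:, :n_components]
    return (
        df.iloc[:, 0].to_numpy(dtype=object),
        PCScores(scores, np.full(scores.shape[1], np.nan)),
    )
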