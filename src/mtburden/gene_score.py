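"""Weighted-sum burden score pooling all variants of a gene.

Each individual's score is a frequency-weighted sum of minor-allele
dosages over the gene's variants, S_j = sum_i I_ij / w_i, with the
Madsen-Browning weight w_i = sqrt(n q_i (1 - q_i)) built from the
add-one allele-frequency estimate q_i = (m_i + 1) / (2n + 2) computed
over ALL individuals (not controls only, so that quantitative traits
and disease status can share one score).  Rare variants therefore
contribute more per minor-allele copy than common ones; no MAF
threshold is applied — rare and common variants are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


class DegenerateGene(Exception):
    """Raised when a gene cannot support any downstream test."""


@dataclass
class GeneScoreVector:
    """Per-individual weighted-sum score for one gene."""

    gene_id: str
    scores: np.ndarray  # (n,) non-negative
    weights: np.ndarray  # (L,) positive
    est_freqs: np.ndarray  # (L,) in (0, 1)
    n_imputed: int = 0  # missing genotype calls imputed to 0

    @property
    def is_degenerate(self) -> bool:
        """True when the score carries no information (zero variance)."""
        return bool(np.ptp(self.scores) == 0)


def weighted_sum_scores(genotypes: GenotypeMatrix, gene_id: str = "") -> GeneScoreVector:
    """Compute the weighted-sum score from a gene-restricted genotype matrix.

    Missing dosages are imputed to 0 (no minor allele) before summing; the
    number of imputed calls is recorded on the result.  Monomorphic variants
    get a well-defined positive weight via the add-one frequency estimate
    and contribute 0 to every individual.

    Raises
    ------
    DegenerateGene
        If the gene has no variants.
    ValueError
        If fewer than two individuals are present.
    """
    n = genotypes.n_samples
    if genotypes.n_variants == 0:
        raise DegenerateGene(f"gene {gene_id!r} has no variants")
    if n < 2:
        raise ValueError("need at least two individuals")
    dosages = genotypes.dosages
    missing = dosages == MISSING
    imputed = np.where(missing, 0, dosages).astype(float)
    m_i = imputed.sum(axis=0)  # minor-allele count over all individuals
    q_hat = (m_i + 1.0) / (2.0 * n + 2.0)
    weights = np.sqrt(n * q_hat * (1.0 - q_hat))
    scores = imputed @ (1.0 / weights)
    return GeneScoreVector(
        gene_id=gene_id,
        scores=scores,
        weights=weights,
        est_freqs=q_hat,
        n_imputed=int(missing.sum()),
    )
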