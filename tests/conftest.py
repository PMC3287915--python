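import numpy as np
import pytest

from mtburden.io_formats import GenotypeMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, sample_ids=None, variant_ids=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    return GenotypeMatrix(
        sample_ids=sample_ids or [f"S{i+1}" for i in range(n)],
        variant_ids=variant_ids or [f"v{i+1}" for i in range(L)],
        dosages=dosages,
    )


def make_phenotypes(traits, trait_types, covariates=None, sample_ids=None,
                    trait_names=None) -> PhenotypeTable:
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    if traits.shape[0] == 1 and len(trait_types) == 1:
        traits = traits.T
    n, m = traits.shape
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return PhenotypeTable(
        sample_ids=sample_ids or [f"S{i+1}" for i in range(n)],
        traits=traits,
        trait_types=list(trait_types),
        trait_names=trait_names or [f"Y{j+1}" for j in range(m)],
        covariates=covariates,
        covariate_names=[f"C{j+1}" for j in range(covariates.shape[1])],
    )
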