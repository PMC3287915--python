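"""Synthetic genotype/phenotype generator and the power-evaluation harness.

The generator emulates the study design the tests target: unrelated
individuals with gene-clustered rare (and some common) variants under
Hardy-Weinberg equilibrium, several correlated quantitative traits with
covariate effects, a binary disease produced by thresholding a latent
liability built from the quantitative traits' *genetic* components, and
optional discrete population structure (Balding-Nichols allele-frequency
divergence plus subpopulation trait-mean shifts) to create confounding.

Variants are drawn independently (no LD): the weighted-sum burden score
aggregates dosages linearly, so LD within a gene changes none of the
null-calibration or power-ordering properties exercised here.

Effect sizes are expressed per standard deviation of the gene score, so a
quantitative-trait effect ``beta`` yields a univariate noncentrality of
about ``beta * sqrt(n)``; :func:`effect_for_power` inverts that relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gene_score import weighted_sum_scores
from .io_formats import GeneMap, GenotypeMatrix, PhenotypeTable

__all__ = [
    "GeneSpec",
    "StratConfig",
    "DiseaseConfig",
    "SimConfig",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_dataset",
    "estimate_power",
    "effect_for_power",
    "liability_attenuation",
    "null_scenario",
    "pleiotropic_scenario",
    "single_trait_scenario",
    "cancellation_scenario",
    "stratified_null_scenario",
    "write_dataset",
    "load_scenario",
]


@dataclass
class GeneSpec:
    """One simulated gene: a block of independent variants."""

    gene_id: str
    n_variants: int = 20
    maf_range: tuple = (5e-4, 0.05)  # log-uniform
    common_fraction: float = 0.1
    common_maf_range: tuple = (0.05, 0.5)  # uniform

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5]: {self.maf_range}")
        if not (0 <= self.common_fraction <= 1):
            raise ValueError("common_fraction must be in [0, 1]")


@dataclass
class StratConfig:
    """Discrete population structure; individuals are split into equal blocks."""

    n_subpops: int = 2
    fst: float = 0.05
    trait_shift: float = 0.0  # per-subpop mean shift on quantitative traits & liability


@dataclass
class DiseaseConfig:
    """Liability-threshold disease derived from the traits' genetic components."""

    prevalence: float = 0.3
    liability_weights: tuple | None = None  # per quantitative trait; None = equal, scaled
    liability_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")


@dataclass
class SimConfig:
    """Full scenario description; the truth table is derivable from `effects`."""

    n: int
    genes: list = field(default_factory=lambda: [GeneSpec("G1")])
    n_quant_traits: int = 3
    binary_trait: bool = True
    effects: dict = field(default_factory=dict)  # gene_id -> per-quant-trait beta
    trait_corr: np.ndarray | None = None  # environmental correlation, default identity
    n_covariates: int = 3  # Age (std normal), Sex, Smoking status
    covariate_effect: float = 0.2  # each covariate on each quantitative trait
    disease: DiseaseConfig = field(default_factory=DiseaseConfig)
    stratification: StratConfig | None = None
    n_background_variants: int = 0  # extra unlinked common variants (for PCA)
    background_maf_range: tuple = (0.05, 0.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trait_corr is not None:
            R = np.asarray(self.trait_corr, dtype=float)
            if R.shape != (self.n_quant_traits, self.n_quant_traits):
                raise ValueError("trait_corr shape mismatch")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError("trait_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(R)[0] <= 0:
                raise ValueError("trait_corr must be positive definite")
            self.trait_corr = R
        for g, b in self.effects.items():
            if len(np.atleast_1d(b)) != self.n_quant_traits:
                raise ValueError(f"effects[{g!r}] needs {self.n_quant_traits} entries")

    @property
    def trait_names(self) -> list:
        names = [f"Q{i + 1}" for i in range(self.n_quant_traits)]
        return names + (["D"] if self.binary_trait else [])


def effect_for_power(power: float, n: int, alpha: float = 0.05) -> float:
    """Per-SD score effect giving approximately the target two-sided power."""
    ncp = stats.norm.isf(alpha / 2.0) + stats.norm.ppf(power)
    return float(ncp / np.sqrt(n))


def liability_attenuation(prevalence: float) -> float:
    """Observed-scale attenuation of a latent liability effect after thresholding.

    phi(Phi^-1(1-K)) / sqrt(K (1-K)) for prevalence K; the liability-weight
    presets divide by this so the binary trait's univariate power roughly
    matches the quantitative traits'.
    """
    thr = stats.norm.ppf(1.0 - prevalence)
    return float(stats.norm.pdf(thr) / np.sqrt(prevalence * (1.0 - prevalence)))


def _subpop_labels(n: int, k: int) -> np.ndarray:
    """Deterministic equal-block assignment of individuals to subpopulations."""
    return np.repeat(np.arange(k), -(-n // k))[:n]


def _draw_mafs(spec: GeneSpec, rng: np.random.Generator) -> np.ndarray:
    n_common = int(round(spec.common_fraction * spec.n_variants))
    n_rare = spec.n_variants - n_common
    lo, hi = spec.maf_range
    rare = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_rare))
    common = rng.uniform(*spec.common_maf_range, size=n_common)
    return np.concatenate([rare, common])


def _genotype_block(mafs: np.ndarray, n: int, strat: StratConfig | None,
                    rng: np.random.Generator) -> np.ndarray:
    if strat is None or strat.fst == 0:
        return rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int8)
    labels = _subpop_labels(n, strat.n_subpops)
    F = strat.fst
    a, b = mafs * (1 - F) / F, (1 - mafs) * (1 - F) / F
    out = np.empty((n, len(mafs)), dtype=np.int8)
    for k in range(strat.n_subpops):
        pk = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)  # Balding-Nichols subpop freqs
        rows = labels == k
        out[rows] = rng.binomial(2, pk, size=(int(rows.sum()), len(mafs)))
    return out


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | int | None = None
                       ) -> tuple[GenotypeMatrix, GeneMap]:
    """Draw genotypes for every gene (plus background variants) and the gene map."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    sample_ids = np.array([f"S{i + 1}" for i in range(config.n)], dtype=object)
    blocks, variant_ids = [], []
    gene_map = GeneMap()
    for spec in config.genes:
        mafs = _draw_mafs(spec, rng)
        blocks.append(_genotype_block(mafs, config.n, config.stratification, rng))
        vids = [f"{spec.gene_id}_v{i + 1}" for i in range(spec.n_variants)]
        variant_ids.extend(vids)
        gene_map[spec.gene_id] = vids
    if config.n_background_variants:
        mafs = rng.uniform(*config.background_maf_range,
                           size=config.n_background_variants)
        blocks.append(_genotype_block(mafs, config.n, config.stratification, rng))
        variant_ids.extend(f"bg_v{i + 1}" for i in range(config.n_background_variants))
    dosages = np.concatenate(blocks, axis=1)
    # simulated dosages already count the allele drawn as "minor" by MAF;
    # sampling noise can push a common variant past 50%, so re-orient
    from .io_formats import _orient_minor

    gm = GenotypeMatrix(sample_ids, np.asarray(variant_ids, dtype=object),
                        _orient_minor(dosages))
    return gm, gene_map


def _standardized_scores(genotypes: GenotypeMatrix, gene_map: GeneMap) -> dict:
    out = {}
    for gene, vids in gene_map.items():
        s = weighted_sum_scores(genotypes.subset_variants(vids), gene).scores
        sd = s.std()
        out[gene] = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    return out


def simulate_traits(genotypes: GenotypeMatrix, gene_map: GeneMap, config: SimConfig,
                    rng: np.random.Generator | int | None = None
                    ) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Generate the phenotype table and the truth table of causal effects.

    Quantitative traits: Y = sum_g beta_g S_g(std) + Gamma C + shift + E with
    E multivariate normal (correlation ``trait_corr``).  Binary trait: the
    latent liability is the weighted sum of the traits' genetic components
    plus Gaussian noise (plus the stratification shift), thresholded at the
    empirical quantile matching the target prevalence.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n, mq = config.n, config.n_quant_traits
    scores = _standardized_scores(genotypes, gene_map)
    G = np.zeros((n, mq))  # genetic components
    for gene, betas in config.effects.items():
        if gene in scores:
            G += np.outer(scores[gene], np.atleast_1d(betas))
    covs = np.column_stack([
        rng.normal(size=n),             # Age (standardized)
        rng.binomial(1, 0.5, size=n),   # Sex
        rng.binomial(1, 0.3, size=n),   # Smoking status
    ])[:, : config.n_covariates]
    cov_names = ["Age", "Sex", "Smoke"][: config.n_covariates]
    R = config.trait_corr if config.trait_corr is not None else np.eye(mq)
    E = rng.multivariate_normal(np.zeros(mq), R, size=n, method="cholesky")
    shift = np.zeros(n)
    if config.stratification is not None and config.stratification.trait_shift:
        labels = _subpop_labels(n, config.stratification.n_subpops)
        centered = labels - labels.mean()
        shift = centered / max(np.abs(centered).max(), 1e-12) \
            * config.stratification.trait_shift
    Y = G + config.covariate_effect * covs.sum(axis=1, keepdims=True) \
        + shift[:, None] + E
    traits, names, types = [Y], [f"Q{i+1}" for i in range(mq)], ["quantitative"] * mq
    latent_effect = np.zeros(len(gene_map))
    if config.binary_trait:
        d = config.disease
        lam = (np.asarray(d.liability_weights, dtype=float)
               if d.liability_weights is not None
               else np.full(mq, 1.0 / (mq * liability_attenuation(d.prevalence))))
        liability = G @ lam + shift + rng.normal(scale=d.liability_noise_sd, size=n)
        thr = np.quantile(liability, 1.0 - d.prevalence)
        traits.append((liability > thr).astype(float)[:, None])
        names.append("D")
        types.append("binary")
        latent_effect = np.array([
            float(np.atleast_1d(config.effects.get(g, np.zeros(mq))) @ lam)
            for g in gene_map
        ])
    pheno = PhenotypeTable(
        sample_ids=genotypes.sample_ids,
        traits=np.column_stack(traits),
        trait_types=types,
        trait_names=names,
        covariates=covs,
        covariate_names=cov_names,
    )
    truth = pd.DataFrame(
        {f"beta_Q{i+1}": [float(np.atleast_1d(config.effects.get(g, np.zeros(mq)))[i])
                          for g in gene_map]
         for i in range(mq)},
        index=pd.Index(list(gene_map), name="gene_id"),
    )
    if config.binary_trait:
        truth["latent_effect_D"] = latent_effect
    truth["causal"] = (truth.abs().sum(axis=1) > 0)
    return pheno, truth


def simulate_dataset(config: SimConfig, rng=None):
    """Genotypes, gene map, phenotypes and truth table in one call."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    genotypes, gene_map = simulate_genotypes(config, rng)
    pheno, truth = simulate_traits(genotypes, gene_map, config, rng)
    return genotypes, gene_map, pheno, truth


# ---------------------------------------------------------------------------
# named scenario presets


def null_scenario(n: int = 500, m_quant: int = 3, binary: bool = True,
                  trait_corr: np.ndarray | None = None) -> SimConfig:
    """Global null: one 20-variant gene, no genetic effects, 3 covariates."""
    return SimConfig(n=n, genes=[GeneSpec("G1")], n_quant_traits=m_quant,
                     binary_trait=binary, trait_corr=trait_corr)


def pleiotropic_scenario(n: int = 500, per_trait_power: float = 0.30,
                         sign: int = 1) -> SimConfig:
    """Equal same-sign effects on all traits; each tuned to ``per_trait_power``."""
    beta = sign * effect_for_power(per_trait_power, n)
    return SimConfig(n=n, genes=[GeneSpec("G1")], n_quant_traits=3,
                     binary_trait=True, effects={"G1": [beta, beta, beta]})


def single_trait_scenario(n: int = 500, power: float = 0.95) -> SimConfig:
    """Effect on the first quantitative trait only."""
    beta = effect_for_power(power, n)
    return SimConfig(n=n, genes=[GeneSpec("G1")], n_quant_traits=3,
                     binary_trait=True, effects={"G1": [beta, 0.0, 0.0]})


def cancellation_scenario(n: int = 500, per_trait_power: float = 0.5) -> SimConfig:
    """Two quantitative traits with equal-magnitude, opposite-sign effects."""
    beta = effect_for_power(per_trait_power, n)
    return SimConfig(n=n, genes=[GeneSpec("G1")], n_quant_traits=2,
                     binary_trait=False, effects={"G1": [beta, -beta]})


def stratified_null_scenario(n: int = 400, fst: float = 0.1,
                             trait_shift: float = 0.8,
                             n_background: int = 150) -> SimConfig:
    """Confounded null: two subpopulations shift both allele freqs and trait means."""
    return SimConfig(
        n=n,
        genes=[GeneSpec("G1", n_variants=20, common_fraction=0.3)],
        n_quant_traits=2,
        binary_trait=False,
        stratification=StratConfig(n_subpops=2, fst=fst, trait_shift=trait_shift),
        n_background_variants=n_background,
    )


# ---------------------------------------------------------------------------
# file round-trip (dog-foods the io_formats readers) and YAML scenarios


def write_dataset(prefix, genotypes: GenotypeMatrix, gene_map: GeneMap,
                  pheno: PhenotypeTable) -> dict:
    """Write genotype/phenotype/gene-map TSVs in the dialects io_formats reads."""
    paths = {
        "geno": f"{prefix}.geno.tsv",
        "pheno": f"{prefix}.pheno.tsv",
        "genemap": f"{prefix}.genemap.tsv",
    }
    gdf = pd.DataFrame(genotypes.dosages, columns=genotypes.variant_ids)
    gdf = gdf.mask(gdf < 0)  # missing marker -> NA
    gdf.insert(0, "sample_id", genotypes.sample_ids)
    gdf.to_csv(paths["geno"], sep="\t", index=False, na_rep="NA",
               float_format="%g")
    pdf = pd.DataFrame(pheno.traits, columns=pheno.trait_names)
    for j, c in enumerate(pheno.covariate_names):
        pdf[c] = pheno.covariates[:, j]
    pdf.insert(0, "sample_id", pheno.sample_ids)
    pdf.to_csv(paths["pheno"], sep="\t", index=False, na_rep="NA")
    with open(paths["genemap"], "w") as fh:
        for gene, vids in gene_map.items():
            for v in vids:
                fh.write(f"{gene}\t{v}\n")
    return paths


def load_scenario(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML key-value scenario file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    genes = [GeneSpec(**g) if isinstance(g, dict) else GeneSpec(g)
             for g in raw.pop("genes", [{"gene_id": "G1"}])]
    strat = raw.pop("stratification", None)
    disease = raw.pop("disease", None)
    cfg = SimConfig(
        genes=genes,
        stratification=StratConfig(**strat) if strat else None,
        disease=DiseaseConfig(**disease) if disease else DiseaseConfig(),
        **raw,
    )
    return cfg


# ---------------------------------------------------------------------------
# power harness


def estimate_power(config: SimConfig, methods=("cmt-q", "cmt-l", "ocmt", "single-trait"),
                   n_reps: int = 200, alpha: float = 0.05, seed: int = 0,
                   n_perm_sigma: int = 1000, n_perm_ocmt: int = 1000,
                   correct_stratification: bool = False, n_pcs: int = 10,
                   return_pvalues: bool = False):
    """Rejection proportion per gene and method over independent replicates.

    Each replicate simulates a fresh dataset from ``config`` and runs the
    full per-gene pipeline (score -> univariate -> CMT -> OCMT, with
    optional PC correction).  Returns a tidy DataFrame with columns
    ``gene_id, method, power, se, n_reps`` (binomial standard errors);
    with ``return_pvalues`` the raw per-replicate p-value table is
    appended.
    """
    from .pipeline import analyze_dataset  # deferred: pipeline imports this module

    if n_reps < 50:
        import warnings

        warnings.warn(f"n_reps={n_reps} is low for power estimation; >=50 recommended")
    run_methods = {m for m in methods if m != "single-trait"}
    rows = []
    root = np.random.SeedSequence([int(seed), 0x9E3779B9])
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        genotypes, gene_map, pheno, _ = simulate_dataset(config, rng)
        results = analyze_dataset(
            genotypes, gene_map, pheno,
            methods=run_methods or {"cmt-q"},
            n_perm_sigma=n_perm_sigma, n_perm_ocmt=n_perm_ocmt,
            seed=int(rng.integers(2**31 - 1)),
            correct_stratification=correct_stratification, n_pcs=n_pcs,
        )
        for res in results:
            rec = {"rep": rep, "gene_id": res.gene_id}
            if "cmt-q" in methods:
                rec["cmt-q"] = res.cmt_q_p
            if "cmt-l" in methods:
                rec["cmt-l"] = res.cmt_l_p
            if "ocmt" in methods:
                rec["ocmt"] = res.ocmt_p
            if "single-trait" in methods:
                for name, p in zip(res.trait_names, res.per_trait_p):
                    rec[f"trait:{name}"] = p
            rows.append(rec)
    pvals = pd.DataFrame(rows)
    method_cols = [c for c in pvals.columns if c not in ("rep", "gene_id")]
    out = []
    for gene, block in pvals.groupby("gene_id", sort=True):
        for mcol in method_cols:
            p = block[mcol].to_numpy()
            ok = np.isfinite(p)
            frac = float((p[ok] <= alpha).mean()) if ok.any() else np.nan
            n_ok = int(ok.sum())
            se = float(np.sqrt(frac * (1 - frac) / n_ok)) if n_ok else np.nan
            out.append({"gene_id": gene, "method": mcol, "power": frac,
                        "se": se, "n_reps": n_ok})
    power = pd.DataFrame(out)
    return (power, pvals) if return_pvalues else power
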