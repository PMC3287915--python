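"""Per-gene orchestration: score -> univariate -> CMT -> OCMT.

Gene iteration follows sorted gene ID, and each gene draws its permutation
stream from a seed derived from (global seed, gene index in that sorted
order).  Results are therefore byte-identical across reruns and across
serial vs. parallel execution, and adding or removing other genes does not
perturb a given gene's permutations as long as its sorted position is
unchanged.  Statistical degeneracies (monomorphic genes, separation,
non-PD Sigma) degrade the affected fields to NA; only structural errors
(missing columns, unknown genes) abort a run.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import io_formats
from .cmt import DegenerateStatistic, estimate_sigma, cmt_linear, cmt_quadratic
from .gene_score import DegenerateGene, GeneScoreVector, weighted_sum_scores
from .io_formats import GeneMap, GeneResult, GenotypeMatrix, PhenotypeTable
from .ocmt import min_subset, ocmt_pvalue
from .stratification import PCScores, compute_pcs, residualize
from .univariate import two_sided_normal_p, z_vector

logger = logging.getLogger(__name__)

ALL_METHODS = ("cmt-q", "cmt-l", "ocmt")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the method's standard
    settings (1000 + 1000 permutations, alpha 0.05, 10 PCs)."""

    geno_path: str = ""
    pheno_path: str = ""
    genemap_path: str = ""
    geno_format: str = "tsv"
    trait_spec: list = field(default_factory=list)  # (name, type) pairs
    covariates: list = field(default_factory=list)
    methods: tuple = ALL_METHODS
    n_perm_sigma: int = 1000
    n_perm_ocmt: int = 1000
    alpha: float = 0.05
    n_pcs: int = 10
    correct_stratification: bool = False
    pc_path: str | None = None
    seed: int = 0
    out_path: str = "results.tsv"
    strict: bool = False
    n_jobs: int = 1
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.n_perm_sigma < 1 or self.n_perm_ocmt < 1:
            raise ValueError("permutation counts must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _degenerate_result(gene_id, n_variants, trait_names) -> GeneResult:
    m = len(trait_names)
    return GeneResult(
        gene_id=gene_id, n_variants=n_variants, trait_names=list(trait_names),
        z=np.full(m, np.nan), per_trait_p=np.full(m, np.nan), status="degenerate",
    )


def _apply_correction(score: np.ndarray, pheno: PhenotypeTable,
                      pcs: PCScores) -> tuple[np.ndarray, PhenotypeTable]:
    """Residualize the score and quantitative traits on the PCs; binary
    traits keep their 0/1 coding and get the PCs as extra covariates."""
    score = residualize(score, pcs)
    traits = pheno.traits.copy()
    for l, ttype in enumerate(pheno.trait_types):
        if ttype == "quantitative":
            traits[:, l] = residualize(traits[:, l], pcs)
    corrected = PhenotypeTable(
        sample_ids=pheno.sample_ids, traits=traits,
        trait_types=list(pheno.trait_types), trait_names=list(pheno.trait_names),
        covariates=pheno.covariates, covariate_names=list(pheno.covariate_names),
    )
    if any(t == "binary" for t in pheno.trait_types):
        corrected = corrected.with_extra_covariates(
            pcs.scores, [f"PC{k + 1}" for k in range(pcs.n_components)]
        )
    return score, corrected


def analyze_gene(score_vec: GeneScoreVector, pheno: PhenotypeTable,
                 methods=ALL_METHODS, n_perm_sigma: int = 1000,
                 n_perm_ocmt: int = 1000,
                 seed_seq: np.random.SeedSequence | int | None = None,
                 pcs: PCScores | None = None) -> GeneResult:
    """Run the requested tests for one gene against a prepared phenotype table."""
    trait_names = list(pheno.trait_names)
    if score_vec.is_degenerate:
        return _degenerate_result(score_vec.gene_id, len(score_vec.weights), trait_names)
    score = score_vec.scores.astype(float)
    if pcs is not None:
        score, pheno = _apply_correction(score, pheno, pcs)
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(0 if seed_seq is None else seed_seq)
    sigma_rng, ocmt_rng = (np.random.default_rng(s) for s in seed_seq.spawn(2))

    zv = z_vector(score, pheno, score_vec.gene_id)
    result = GeneResult(
        gene_id=score_vec.gene_id, n_variants=len(score_vec.weights),
        trait_names=trait_names, z=zv.z, per_trait_p=two_sided_normal_p(zv.z),
    )
    methods = set(methods)
    if not methods & {"cmt-q", "cmt-l", "ocmt"}:
        return result
    ok = np.flatnonzero(np.isfinite(zv.z))
    if ok.size == 0:
        result.status = "degenerate"
        return result
    pheno_ok = pheno.subset_traits(ok) if ok.size < pheno.n_traits else pheno
    z_ok = zv.z[ok]
    try:
        sigma = estimate_sigma(score, pheno_ok, n_perm_sigma, sigma_rng)
    except ValueError as exc:
        logger.warning("gene %s: Sigma estimation failed (%s)", score_vec.gene_id, exc)
        result.status = "degenerate"
        return result
    result.n_perm_sigma = sigma.n_perm
    if sigma.condition_flag == "degenerate":
        result.status = "degenerate"
        return result
    if "cmt-q" in methods:
        try:
            result.cmt_q_stat, result.cmt_q_p = cmt_quadratic(z_ok, sigma)
        except DegenerateStatistic:
            pass
    if "cmt-l" in methods:
        try:
            result.cmt_l_stat, result.cmt_l_p = cmt_linear(z_ok, sigma)
        except DegenerateStatistic:
            pass
    if "ocmt" in methods and ok.size >= 2:
        try:
            best = min_subset(z_ok, sigma)
            result.ocmt_subset = tuple(pheno_ok.trait_names[i] for i in best.subset)
            result.ocmt_p = ocmt_pvalue(score, pheno_ok, sigma, best,
                                        n_perm_ocmt, ocmt_rng)
            result.n_perm_ocmt = n_perm_ocmt
        except DegenerateStatistic:
            pass
    return result


def analyze_dataset(genotypes: GenotypeMatrix, gene_map: GeneMap,
                    pheno: PhenotypeTable, methods=ALL_METHODS,
                    n_perm_sigma: int = 1000, n_perm_ocmt: int = 1000,
                    seed: int = 0, correct_stratification: bool = False,
                    n_pcs: int = 10, pcs: PCScores | None = None,
                    n_jobs: int = 1) -> list[GeneResult]:
    """Run every gene of an in-memory dataset; genes in sorted-ID order."""
    if correct_stratification and pcs is None:
        pcs = compute_pcs(genotypes, n_pcs)
    gene_ids = sorted(gene_map)
    jobs = []
    for gene_index, gene_id in enumerate(gene_ids):
        try:
            sv = weighted_sum_scores(genotypes.subset_variants(gene_map[gene_id]),
                                     gene_id)
        except DegenerateGene:
            jobs.append(("deg", gene_id, len(gene_map[gene_id])))
            continue
        jobs.append(("run", sv, np.random.SeedSequence([int(seed), gene_index])))

    def _one(job):
        if job[0] == "deg":
            return _degenerate_result(job[1], job[2], pheno.trait_names)
        _, sv, ss = job
        return analyze_gene(sv, pheno, methods, n_perm_sigma, n_perm_ocmt, ss, pcs)

    if n_jobs != 1 and len(jobs) > 1:
        from joblib import Parallel, delayed

        return list(Parallel(n_jobs=n_jobs)(delayed(_one)(j) for j in jobs))
    return [_one(j) for j in jobs]


def run_all(config: RunConfig) -> list[GeneResult]:
    """Read input files, run every gene, write the results TSV."""
    t0 = time.monotonic()
    genotypes = io_formats.read_genotypes(config.geno_path, config.geno_format,
                                          strict=config.strict)
    pheno = io_formats.read_phenotypes(config.pheno_path, config.trait_spec,
                                       config.covariates)
    genotypes, pheno = io_formats.join_samples(genotypes, pheno)
    gene_map = io_formats.read_gene_map(config.genemap_path, genotypes,
                                        strict=config.strict)
    pcs = None
    if config.correct_stratification:
        if config.pc_path:
            from .stratification import read_pc_file

            pc_ids, pcs = read_pc_file(config.pc_path, config.n_pcs)
            order = {s: i for i, s in enumerate(pc_ids)}
            rows = [order[s] for s in genotypes.sample_ids]
            pcs = PCScores(pcs.scores[rows], pcs.explained_variance_ratio)
        else:
            pcs = compute_pcs(genotypes, config.n_pcs)
    logger.info("loaded %d samples, %d variants, %d genes (%.2fs)",
                genotypes.n_samples, genotypes.n_variants, len(gene_map),
                time.monotonic() - t0)
    results = analyze_dataset(
        genotypes, gene_map, pheno, methods=config.methods,
        n_perm_sigma=config.n_perm_sigma, n_perm_ocmt=config.n_perm_ocmt,
        seed=config.seed, pcs=pcs, n_jobs=config.n_jobs,
    )
    n_deg = sum(r.status == "degenerate" for r in results)
    if n_deg:
        logger.info("%d/%d genes degenerate", n_deg, len(results))
    df = io_formats.results_frame(results, pheno.trait_names)
    if config.bonferroni:
        n_tested = max(int(df["cmt_q_p"].notna().sum()), 1)
        for col in ("cmt_q_p", "cmt_l_p", "ocmt_p"):
            df[f"{col}_bonf"] = (df[col] * n_tested).clip(upper=1.0)
    df.to_csv(config.out_path, sep="\t", index=False, na_rep="NA",
              float_format="%.6g")
    logger.info("wrote %d gene rows to %s (%.2fs total)",
                len(results), config.out_path, time.monotonic() - t0)
    return results
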