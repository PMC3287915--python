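"""Readers and writers for the genotype, phenotype, gene-map and result tables.

All downstream modules consume only the in-memory containers defined here:
:class:`GenotypeMatrix`, :class:`PhenotypeTable`, :class:`GeneMap` and
:class:`GeneResult`.  Genotypes are stored as minor-allele dosages in
{0, 1, 2} with ``-1`` marking a missing call; orientation to the minor
allele (computed over all individuals) happens at read time and is
idempotent.  Variants are identified by ID only — the burden score never
uses genomic position or strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: fixed column order of the results table; stable regardless of which
#: methods were run (absent methods are NA-filled)
_RESULT_FIXED_COLS = [
    "gene_id",
    "n_variants",
    "status",
    "cmt_q_stat",
    "cmt_q_p",
    "cmt_l_stat",
    "cmt_l_p",
    "ocmt_subset",
    "ocmt_p",
    "n_perm_sigma",
    "n_perm_ocmt",
]


class ParseError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Invalid column specification or option."""


class ValidationError(ValueError):
    """Input violates a structural invariant (e.g. non-binary disease coding)."""


@dataclass
class GenotypeMatrix:
    """n individuals x L variants of minor-allele dosages.

    ``dosages`` is an ``int8`` array with entries in {0, 1, 2} or ``-1``
    (missing).  ``minor_allele_counts[i]`` is the column sum of observed
    dosages after minor-allele orientation, so ``m_i <= 2 n_obs - m_i``
    for every variant (ties at 50% frequency keep the file's coding).
    """

    sample_ids: np.ndarray
    variant_ids: np.ndarray
    dosages: np.ndarray
    minor_allele_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("dosages must be 0/1/2 or -1 (missing)")
        if self.minor_allele_counts is None:
            obs = self.dosages != MISSING
            self.minor_allele_counts = np.where(obs, self.dosages, 0).sum(axis=0)
        self.minor_allele_counts = np.asarray(self.minor_allele_counts, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        """Restrict to the given variants (order preserved as given)."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            cols = [index[v] for v in variant_ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variant_ids=np.asarray(list(variant_ids), dtype=object),
            dosages=self.dosages[:, cols],
            minor_allele_counts=self.minor_allele_counts[cols],
        )

    def subset_samples(self, row_indices) -> "GenotypeMatrix":
        """Restrict to the given sample rows; minor-allele counts are recomputed."""
        return GenotypeMatrix(
            sample_ids=self.sample_ids[row_indices],
            variant_ids=self.variant_ids,
            dosages=self.dosages[row_indices],
        )


@dataclass
class PhenotypeTable:
    """n individuals x m traits plus c covariates.

    Binary traits are coded 0/1; missing trait or covariate values are NaN
    and are handled by case-wise deletion per trait downstream.
    """

    sample_ids: np.ndarray
    traits: np.ndarray
    trait_types: list
    trait_names: list
    covariates: np.ndarray
    covariate_names: list

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.traits = np.asarray(self.traits, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n = len(self.sample_ids)
        if self.traits.shape != (n, len(self.trait_names)):
            raise ValidationError("trait matrix shape mismatch")
        if self.covariates.shape[0] != n:
            raise ValidationError("covariate matrix row mismatch")
        if len(self.trait_types) != len(self.trait_names):
            raise ValidationError("trait_types/trait_names length mismatch")
        for ttype, name, col in zip(self.trait_types, self.trait_names, self.traits.T):
            if ttype not in ("binary", "quantitative"):
                raise ConfigError(f"unknown trait type {ttype!r} for {name}")
            if ttype == "binary":
                levels = np.unique(col[~np.isnan(col)])
                if not np.all(np.isin(levels, (0.0, 1.0))):
                    raise ValidationError(
                        f"binary trait {name!r} has levels {levels.tolist()}; expected 0/1"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def subset_samples(self, row_indices) -> "PhenotypeTable":
        return PhenotypeTable(
            sample_ids=self.sample_ids[row_indices],
            traits=self.traits[row_indices],
            trait_types=list(self.trait_types),
            trait_names=list(self.trait_names),
            covariates=self.covariates[row_indices],
            covariate_names=list(self.covariate_names),
        )

    def subset_traits(self, indices) -> "PhenotypeTable":
        """Restrict to the given trait columns (covariates unchanged)."""
        indices = list(indices)
        return PhenotypeTable(
            sample_ids=self.sample_ids,
            traits=self.traits[:, indices],
            trait_types=[self.trait_types[i] for i in indices],
            trait_names=[self.trait_names[i] for i in indices],
            covariates=self.covariates,
            covariate_names=list(self.covariate_names),
        )

    def with_extra_covariates(self, extra: np.ndarray, names) -> "PhenotypeTable":
        """Return a copy with extra covariate columns appended (e.g. PCs)."""
        return PhenotypeTable(
            sample_ids=self.sample_ids,
            traits=self.traits.copy(),
            trait_types=list(self.trait_types),
            trait_names=list(self.trait_names),
            covariates=np.column_stack([self.covariates, extra])
            if self.covariates.size
            else np.asarray(extra, dtype=float),
            covariate_names=list(self.covariate_names) + list(names),
        )


class GeneMap(dict):
    """Mapping gene_id -> ordered list of variant IDs.

    Variant order is first appearance in the map file; duplicates within a
    gene are rejected.
    """


@dataclass
class GeneResult:
    """Per-gene record of univariate, CMT and OCMT results."""

    gene_id: str
    n_variants: int
    trait_names: list
    z: np.ndarray  # per-trait Z (NaN where degenerate)
    per_trait_p: np.ndarray
    cmt_q_stat: float = math.nan
    cmt_q_p: float = math.nan
    cmt_l_stat: float = math.nan
    cmt_l_p: float = math.nan
    ocmt_subset: tuple = ()
    ocmt_p: float = math.nan
    n_perm_sigma: int = 0
    n_perm_ocmt: int = 0
    status: str = "ok"


def _orient_minor(dosages: np.ndarray) -> np.ndarray:
    """Flip columns whose counted allele is the major one (> 50% frequency).

    Exact 50% ties keep the original coding, which makes the operation
    idempotent and deterministic.
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    obs = dosages != MISSING
    counted = np.where(obs, dosages, 0).sum(axis=0)
    total = 2 * obs.sum(axis=0)
    flip = counted * 2 > total  # strict: ties keep original coding
    out = dosages.copy()
    flipped = np.where(out[:, flip] == MISSING, MISSING, 2 - out[:, flip])
    out[:, flip] = flipped.astype(np.int8)
    return out


def read_genotypes(path, format: str = "tsv", strict: bool = True) -> GenotypeMatrix:
    """Read a genotype file into a minor-allele-oriented :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        TSV (first column sample ID, remaining columns variant dosages,
        header row of variant IDs; ``NA``/empty = missing) or VCF with GT
        fields.
    format
        ``"tsv"`` or ``"vcf"``.
    strict
        For VCF: reject non-biallelic records instead of skipping them.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path, strict=strict)
    raise ConfigError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a sample-ID column plus >=1 variant column")
    sample_ids = df.iloc[:, 0].to_numpy(dtype=object)
    variant_ids = np.asarray(df.columns[1:], dtype=object)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    dosages = np.full(values.shape, MISSING, dtype=np.int8)
    obs = ~np.isnan(values)
    rounded = np.rint(values[obs])
    if not np.all(np.isin(rounded, (0, 1, 2))):
        bad_rows = np.argwhere(obs)[~np.isin(rounded, (0, 1, 2))]
        line = int(bad_rows[0, 0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: non-0/1/2 dosage near line {line}")
    dosages[obs] = rounded.astype(np.int8)
    return GenotypeMatrix(sample_ids, variant_ids, _orient_minor(dosages))


def _read_genotypes_vcf(path, strict: bool = True) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples, dtype=object)
    variant_ids, columns = [], []
    for record in vcf:
        if len(record.ALT) != 1:
            if strict:
                raise ParseError(
                    f"{path}: non-biallelic record at {record.CHROM}:{record.POS}"
                )
            logger.warning("skipping non-biallelic record %s:%s", record.CHROM, record.POS)
            continue
        vid = record.ID
        if vid in (None, "."):
            vid = f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}"
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(record.gt_types)
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        variant_ids.append(vid)
        columns.append(col.astype(np.int8))
    if not columns:
        raise ParseError(f"{path}: no usable variant records")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(sample_ids, np.asarray(variant_ids, dtype=object),
                          _orient_minor(dosages))


def read_phenotypes(path, trait_spec, covariate_spec=()) -> PhenotypeTable:
    """Read a phenotype TSV.

    Parameters
    ----------
    trait_spec
        Sequence of ``(name, type)`` pairs with type ``"binary"`` or
        ``"quantitative"``, or strings ``"name:binary"`` etc.
    covariate_spec
        Covariate column names (may be empty).
    """
    spec = []
    for item in trait_spec:
        if isinstance(item, str):
            name, _, ttype = item.partition(":")
            spec.append((name, ttype or "quantitative"))
        else:
            spec.append(tuple(item))
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
    id_col = df.columns[0]
    needed = [name for name, _ in spec] + list(covariate_spec)
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ConfigError(f"{path}: missing column(s) {missing_cols}")
    traits = df[[name for name, _ in spec]].to_numpy(dtype=float)
    covs = (
        df[list(covariate_spec)].to_numpy(dtype=float)
        if covariate_spec
        else np.empty((len(df), 0))
    )
    n_dropped = int(np.isnan(traits).any(axis=1).sum() + np.isnan(covs).any(axis=1).sum())
    if n_dropped:
        logger.info("%s: %d rows carry missing trait/covariate values "
                    "(case-wise deletion per trait downstream)", path, n_dropped)
    return PhenotypeTable(
        sample_ids=df[id_col].to_numpy(dtype=object),
        traits=traits,
        trait_types=[t for _, t in spec],
        trait_names=[n for n, _ in spec],
        covariates=covs,
        covariate_names=list(covariate_spec),
    )


def read_gene_map(path, genotypes: GenotypeMatrix | None = None,
                  strict: bool = False) -> GeneMap:
    """Read a two-column (gene_id, variant_id) whitespace-delimited map.

    Unknown variants (when ``genotypes`` is given) are dropped with a
    warning, or raise under ``strict``; genes left empty are removed.
    """
    known = set(genotypes.variant_ids) if genotypes is not None else None
    gene_map = GeneMap()
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            gene, var = parts
            if (gene, var) in seen:
                raise ParseError(f"{path}:{lineno}: duplicate entry {gene} {var}")
            seen.add((gene, var))
            if known is not None and var not in known:
                if strict:
                    raise ParseError(f"{path}:{lineno}: unknown variant {var!r}")
                logger.warning("%s:%d: variant %r not in genotypes; dropped",
                               path, lineno, var)
                gene_map.setdefault(gene, [])
                continue
            gene_map.setdefault(gene, []).append(var)
    for gene in [g for g, v in gene_map.items() if not v]:
        logger.warning("gene %r has no usable variants; dropped", gene)
        del gene_map[gene]
    return gene_map


def join_samples(genotypes: GenotypeMatrix,
                 phenotypes: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Align the two tables on the intersection of sample IDs.

    Row order follows the genotype file; the number of samples dropped from
    each side is logged.
    """
    pheno_index = {s: i for i, s in enumerate(phenotypes.sample_ids)}
    geno_rows, pheno_rows = [], []
    for i, s in enumerate(genotypes.sample_ids):
        j = pheno_index.get(s)
        if j is not None:
            geno_rows.append(i)
            pheno_rows.append(j)
    n_common = len(geno_rows)
    if n_common == 0:
        raise ValidationError("no sample IDs shared between genotypes and phenotypes")
    logger.info("sample join: %d common, %d genotype-only, %d phenotype-only",
                n_common, genotypes.n_samples - n_common,
                phenotypes.n_samples - n_common)
    return genotypes.subset_samples(geno_rows), phenotypes.subset_samples(pheno_rows)


def _result_row(res: GeneResult, trait_names) -> dict:
    row = {
        "gene_id": res.gene_id,
        "n_variants": res.n_variants,
        "status": res.status,
        "cmt_q_stat": res.cmt_q_stat,
        "cmt_q_p": res.cmt_q_p,
        "cmt_l_stat": res.cmt_l_stat,
        "cmt_l_p": res.cmt_l_p,
        "ocmt_subset": "+".join(res.ocmt_subset) if res.ocmt_subset else np.nan,
        "ocmt_p": res.ocmt_p,
        "n_perm_sigma": res.n_perm_sigma,
        "n_perm_ocmt": res.n_perm_ocmt,
    }
    for i, name in enumerate(trait_names):
        if res.trait_names and name in res.trait_names:
            k = res.trait_names.index(name)
            row[f"z_{name}"] = res.z[k] if res.z is not None else np.nan
            row[f"p_{name}"] = res.per_trait_p[k] if res.per_trait_p is not None else np.nan
        else:
            row[f"z_{name}"] = np.nan
            row[f"p_{name}"] = np.nan
    return row


def results_frame(results, trait_names=None) -> pd.DataFrame:
    """Assemble :class:`GeneResult` records into a fixed-schema DataFrame."""
    if trait_names is None:
        trait_names = results[0].trait_names if results else []
    cols = (_RESULT_FIXED_COLS[:3]
            + [f"{p}_{t}" for t in trait_names for p in ("z", "p")]
            + _RESULT_FIXED_COLS[3:])
    df = pd.DataFrame([_result_row(r, trait_names) for r in results], columns=cols)
    return df


def write_results(results, path, trait_names=None) -> None:
    """Write one row per gene as TSV; p-values keep >= 6 significant digits."""
    df = results_frame(results, trait_names)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Re-read a results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
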