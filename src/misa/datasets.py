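"""Core containers and IO for case-control SNP association studies.

A study is a matrix of minor-allele counts (subjects x SNPs, entries in
{0, 1, 2} with NaN for no-calls), a binary case indicator, the design
covariates included in every association model (age, genotyping batch and
the per-sample genotyping quality score GC50PCT), and per-SNP annotation
(gene label, optional position).

Genotypes are oriented so that the counted allele is the minor allele
*among controls*: after :func:`orient_to_control_minor` the control
frequency of the counted allele is at most 0.5 for every SNP, which fixes
the direction of reported odds ratios.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneticModel",
    "StudyDataset",
    "DesignMatrix",
    "SNPSummary",
    "read_study",
    "write_study",
    "read_vcf_genotypes",
    "encode_genotype",
    "encode_column",
    "minor_allele_frequency",
    "orient_to_control_minor",
    "build_design_matrix",
    "snp_summaries",
]

#: Reserved leading columns of the tabular study format, in order.
COVARIATE_COLUMNS = ("subject_id", "status", "age", "batch", "gc50pct")


class GeneticModel(enum.Enum):
    """Genetic parameterization of a SNP's effect on the log-odds scale.

    LOG_ADDITIVE codes the genotype as the minor-allele count (0/1/2),
    DOMINANT as carrier status (0/1/1) and RECESSIVE as rare-homozygote
    status (0/0/1).
    """

    LOG_ADDITIVE = "log_additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    @property
    def code(self) -> str:
        return {"log_additive": "A", "dominant": "D", "recessive": "R"}[self.value]


@dataclass
class StudyDataset:
    """Genotypes, case status, design covariates and SNP annotation.

    Parameters
    ----------
    genotypes : (n_subjects, n_snps) float array
        Minor-allele counts in {0, 1, 2}; NaN marks a missing call.
    case_status : (n_subjects,) int array
        1 for cases, 0 for controls.
    covariates : DataFrame
        One row per subject with columns ``age`` (years), ``batch``
        (categorical label) and ``gc50pct`` (quality score in [0, 1]).
    snp_info : DataFrame
        One row per SNP with columns ``snp_id`` and ``gene`` (optional
        ``chrom``/``pos``, 1-based positions).
    """

    genotypes: np.ndarray
    case_status: np.ndarray
    covariates: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.case_status = np.asarray(self.case_status, dtype=int)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D subjects x SNPs array")
        n, s = self.genotypes.shape
        if self.case_status.shape != (n,):
            raise ValueError(
                f"case_status length {self.case_status.shape[0]} does not match "
                f"{n} genotype rows"
            )
        if len(self.covariates) != n:
            raise ValueError("covariates must have one row per subject")
        if len(self.snp_info) != s:
            raise ValueError("snp_info must have one row per SNP")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0, 2.0))]))
            raise ValueError(f"genotype values outside {{0,1,2,missing}}: {bad}")
        if not np.isin(self.case_status, (0, 1)).all():
            raise ValueError("case_status must be 0/1")
        ids = self.snp_info["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids: {dup}")
        for col in ("age", "batch", "gc50pct"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates missing required column {col!r}")
        self.covariates = self.covariates.reset_index(drop=True)
        self.snp_info = self.snp_info.reset_index(drop=True)

    # -- basic views -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_info["snp_id"].to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.genotypes)

    @property
    def control_mask(self) -> np.ndarray:
        return self.case_status == 0

    @property
    def case_mask(self) -> np.ndarray:
        return self.case_status == 1

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return int(idx[0])

    def select_snps(self, indices) -> "StudyDataset":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return replace(
            self,
            genotypes=self.genotypes[:, indices].copy(),
            snp_info=self.snp_info.iloc[indices].reset_index(drop=True),
        )

    def select_subjects(self, indices) -> "StudyDataset":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return replace(
            self,
            genotypes=self.genotypes[indices].copy(),
            case_status=self.case_status[indices].copy(),
            covariates=self.covariates.iloc[indices].reset_index(drop=True),
        )

    def copy(self) -> "StudyDataset":
        return replace(
            self,
            genotypes=self.genotypes.copy(),
            case_status=self.case_status.copy(),
            covariates=self.covariates.copy(),
            snp_info=self.snp_info.copy(),
        )


@dataclass
class SNPSummary:
    """Per-SNP allele-frequency and completeness summary."""

    snp_id: str
    maf: float
    missing_count: int
    call_rate_by_batch: dict[str, float] = field(default_factory=dict)


@dataclass
class DesignMatrix:
    """Null-model design: intercept, age, batch dummies, GC50PCT and
    batch x GC50PCT interactions.

    Continuous covariates are standardized internally so the diffuse prior
    on design coefficients is scale-free; ``columns`` names each column of
    ``matrix``.
    """

    matrix: np.ndarray
    columns: list[str]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# genotype encodings and allele frequencies


def encode_genotype(g: int, model: GeneticModel) -> int:
    """Encode one minor-allele count under a genetic parameterization."""
    if g is None or (isinstance(g, float) and np.isnan(g)):
        raise ValueError("missing genotype: impute before encoding")
    if g not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1 or 2, got {g!r}")
    if model is GeneticModel.LOG_ADDITIVE:
        return int(g)
    if model is GeneticModel.DOMINANT:
        return 1 if g >= 1 else 0
    return 1 if g == 2 else 0


def encode_column(column: np.ndarray, model: GeneticModel) -> np.ndarray:
    """Vectorized :func:`encode_genotype` over a complete genotype column."""
    column = np.asarray(column, dtype=float)
    if np.isnan(column).any():
        raise ValueError("missing genotypes present: impute before encoding")
    if model is GeneticModel.LOG_ADDITIVE:
        return column.copy()
    if model is GeneticModel.DOMINANT:
        return (column >= 1).astype(float)
    return (column == 2).astype(float)


def minor_allele_frequency(column: np.ndarray, control_mask: np.ndarray) -> float:
    """MAF as the minimum of the two observed allele frequencies in controls."""
    column = np.asarray(column, dtype=float)
    ctrl = column[np.asarray(control_mask, dtype=bool)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if ctrl.size == 0:
        raise ValueError("no non-missing control genotypes")
    p = ctrl.sum() / (2.0 * ctrl.size)
    return float(min(p, 1.0 - p))


def orient_to_control_minor(dataset: StudyDataset) -> tuple[StudyDataset, np.ndarray]:
    """Flip genotype columns so the counted allele is minor among controls.

    Returns the re-oriented dataset and a boolean array of flipped columns.
    Ties at frequency exactly 0.5 are left as coded (the tabular format has
    no allele labels to break them with).
    """
    geno = dataset.genotypes.copy()
    ctrl = dataset.control_mask
    flipped = np.zeros(dataset.n_snps, dtype=bool)
    for j in range(dataset.n_snps):
        col = geno[ctrl, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        p = col.sum() / (2.0 * col.size)
        if p > 0.5:
            geno[:, j] = 2.0 - geno[:, j]
            flipped[j] = True
    return replace(dataset, genotypes=geno), flipped


def snp_summaries(dataset: StudyDataset) -> list[SNPSummary]:
    """Per-SNP MAF, missing count and per-batch call rate."""
    out = []
    batches = dataset.covariates["batch"].to_numpy()
    ctrl = dataset.control_mask
    for j, snp_id in enumerate(dataset.snp_ids):
        col = dataset.genotypes[:, j]
        maf = minor_allele_frequency(col, ctrl)
        rates = {}
        for b in pd.unique(batches):
            in_b = batches == b
            rates[str(b)] = float(1.0 - np.isnan(col[in_b]).mean())
        out.append(
            SNPSummary(
                snp_id=str(snp_id),
                maf=maf,
                missing_count=int(np.isnan(col).sum()),
                call_rate_by_batch=rates,
            )
        )
    return out


# ---------------------------------------------------------------------------
# design matrix


def build_design_matrix(dataset: StudyDataset) -> DesignMatrix:
    """Design matrix for the null (no-association) model.

    Columns: intercept, standardized age, batch indicator for every
    non-reference batch level, standardized GC50PCT, and batch x GC50PCT
    interactions. The reference batch is the first level in sorted order.

    Raises
    ------
    ValueError
        If any covariate is missing, a continuous covariate is constant,
        or the assembled matrix is rank deficient (collinear columns are
        named in the message).
    """
    cov = dataset.covariates
    if cov[["age", "batch", "gc50pct"]].isna().any().any():
        raise ValueError("design covariates must be complete")
    n = dataset.n_subjects
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    for name in ("age", "gc50pct"):
        x = cov[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0.0:
            raise ValueError(f"collinear design columns: {name!r} is constant")
        z = (x - x.mean()) / sd
        if name == "age":
            cols.append(z)
            names.append("age")
        else:
            gc_std = z
    cols.append(gc_std)
    names.append("gc50pct")

    levels = sorted(pd.unique(cov["batch"]).tolist(), key=str)
    if len(levels) == 1:
        warnings.warn(
            "single batch level: batch and batch x GC50PCT columns omitted",
            UserWarning,
            stacklevel=2,
        )
    else:
        for lev in levels[1:]:
            ind = (cov["batch"] == lev).to_numpy(dtype=float)
            cols.append(ind)
            names.append(f"batch[{lev}]")
        for lev in levels[1:]:
            ind = (cov["batch"] == lev).to_numpy(dtype=float)
            cols.append(ind * gc_std)
            names.append(f"batch[{lev}]:gc50pct")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns past the numerical rank in a pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        guilty = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"collinear design columns: {guilty}")
    return DesignMatrix(matrix=X, columns=names)


# ---------------------------------------------------------------------------
# IO

_MISSING_CODE = "NA"


def read_study(
    genotype_path,
    covariate_path=None,
    format: str = "table",
    orient: bool = True,
) -> StudyDataset:
    """Read a study from the tabular format or from VCF + covariate table.

    The tabular dialect is a single delimited file: header row, leading
    columns ``subject_id, status, age, batch, gc50pct`` followed by one
    column per SNP (values 0/1/2 or ``NA``). Delimiter is inferred from the
    extension (``.csv`` comma, otherwise tab). With ``format='vcf'``,
    ``genotype_path`` is a VCF of hard calls and ``covariate_path`` holds
    the five covariate columns in subject order.

    When ``orient`` is true, columns are recoded so the counted allele is
    the control-minor allele.
    """
    if format == "table":
        sep = "," if str(genotype_path).endswith(".csv") else "\t"
        df = pd.read_csv(genotype_path, sep=sep, dtype={"batch": str})
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        snp_cols = [c for c in df.columns if c not in COVARIATE_COLUMNS]
        geno = df[snp_cols].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
        snp_info = pd.DataFrame({"snp_id": snp_cols})
        snp_info["gene"] = [c.split("_")[0] if "_" in c else "" for c in snp_cols]
        dataset = StudyDataset(
            genotypes=geno,
            case_status=df["status"].to_numpy(dtype=int),
            covariates=df[["age", "batch", "gc50pct"]].copy(),
            snp_info=snp_info,
        )
    elif format == "vcf":
        if covariate_path is None:
            raise ValueError("VCF input requires a covariate table")
        sep = "," if str(covariate_path).endswith(".csv") else "\t"
        cov = pd.read_csv(covariate_path, sep=sep, dtype={"batch": str})
        geno, snp_info = read_vcf_genotypes(genotype_path)
        dataset = StudyDataset(
            genotypes=geno,
            case_status=cov["status"].to_numpy(dtype=int),
            covariates=cov[["age", "batch", "gc50pct"]].copy(),
            snp_info=snp_info,
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    if orient:
        dataset, _ = orient_to_control_minor(dataset)
    return dataset


def read_vcf_genotypes(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Hard-call GT fields from a VCF as an alternate-allele count matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, ids, genes, chroms, poss = [], [], [], [], []
    for var in vcf:
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        rows.append(col)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        genes.append("")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows:
        raise ValueError("no variants in VCF")
    geno = np.column_stack(rows)
    info = pd.DataFrame({"snp_id": ids, "gene": genes, "chrom": chroms, "pos": poss})
    return geno, info


def write_study(dataset: StudyDataset, path) -> None:
    """Write the tabular dialect (round-trips with :func:`read_study`)."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(dataset.n_subjects)],
            "status": dataset.case_status,
            "age": dataset.covariates["age"].to_numpy(),
            "batch": dataset.covariates["batch"].to_numpy(),
            "gc50pct": dataset.covariates["gc50pct"].to_numpy(),
        }
    )
    geno = pd.DataFrame(dataset.genotypes, columns=dataset.snp_ids)
    # integer-format genotype entries, NA for missing
    geno = geno.apply(lambda c: c.map(lambda v: _MISSING_CODE if np.isnan(v) else str(int(v))))
    pd.concat([df, geno], axis=1).to_csv(path, sep=sep, index=False)
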