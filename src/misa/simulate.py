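"""Synthetic case-control genotype studies.

Generates data with the statistical structure the analysis pipeline
assumes: SNPs in linkage-disequilibrium blocks drawn as haplotype pairs
under random mating (so Hardy-Weinberg equilibrium holds marginally in
the error-free population), a frequency-matched retrospective
case-control sample from a logistic disease model with a handful of
truly associated SNPs under log-additive/dominant/recessive effects,
design covariates (age, genotyping batch with an uneven-allocation
batch, the GC50PCT quality score and a batch x quality interaction),
MCAR/MAR/MNAR missingness, and genotyping error concentrated in
low-quality samples, which distorts HWE and is what the quality
threshold scan is meant to detect.

Every generated dataset carries a truth manifest; pipeline estimates are
validated only against that manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import GeneticModel, StudyDataset, encode_column

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_case_control",
    "inject_missingness",
    "inject_genotype_error",
    "simulate_study",
    "default_scenario",
]


@dataclass
class SimulationConfig:
    """Recipe for one synthetic study.

    Defaults mirror a candidate-gene panel of 484 QC-passed SNPs typed on
    364 cases and 761 controls in four batches, with per-allele causal
    odds ratios in the 0.53-1.65 range.
    """

    n_snps: int = 484
    n_cases: int = 364
    n_controls: int = 761
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_size: int = 4
    ld_rho: float = 0.6  # adjacent-SNP haplotype correlation within a block
    haplotype_freqs: list | None = None  # optional explicit per-block (haps, freqs)
    #: (snp index, parameterization, odds ratio)
    causal: list[tuple[int, GeneticModel, float]] = field(
        default_factory=lambda: [
            (12, GeneticModel.LOG_ADDITIVE, 1.65),
            (120, GeneticModel.LOG_ADDITIVE, 0.66),
            (240, GeneticModel.DOMINANT, 0.69),
            (360, GeneticModel.RECESSIVE, 0.53),
        ]
    )
    baseline_logit: float = math.log(0.3 / 0.7)
    age_log_or_per_sd: float = 0.05
    n_batches: int = 4
    #: per-batch log-odds offsets; the last batch is deliberately uneven
    batch_log_or: tuple = (0.0, 0.0, 0.0, 1.0)
    gc_log_or_per_sd: float = 0.2
    #: batch x GC50PCT interaction log-odds (per sd of quality)
    batch_gc_log_or: tuple = (0.0, 0.0, 0.0, 0.5)
    missing_mechanism: str = "mcar"  # mcar | mar | mnar
    missing_rate: float = 0.005
    mnar_rare_multiplier: float = 5.0
    genotype_error_rate: float = 0.0
    error_quality_boundary: float = 0.789
    low_quality_fraction: float = 0.05
    population_size: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for _, _, orr in self.causal:
            if orr <= 0:
                raise ValueError("odds ratios must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0.0 <= self.genotype_error_rate <= 1.0:
            raise ValueError("genotype_error_rate must lie in [0, 1]")
        if len(self.batch_log_or) != self.n_batches or len(self.batch_gc_log_or) != self.n_batches:
            raise ValueError("batch effect tuples must have n_batches entries")


def _block_haplotypes(rng, n_hap: int, width: int, config: SimulationConfig) -> np.ndarray:
    """Binary haplotypes for one block: first-order Markov chain with
    target adjacent correlation ``ld_rho`` and allele frequencies drawn
    from ``maf_range``."""
    p = rng.uniform(*config.maf_range, size=width)
    H = np.empty((n_hap, width))
    H[:, 0] = rng.random(n_hap) < p[0]
    for s in range(1, width):
        p0, p1 = p[s - 1], p[s]
        cov = config.ld_rho * math.sqrt(p0 * (1 - p0) * p1 * (1 - p1))
        cond1 = np.clip(p1 + cov / p0, 0.0, 1.0)
        cond0 = np.clip(p1 - cov / (1 - p0), 0.0, 1.0)
        prev = H[:, s - 1] == 1
        u = rng.random(n_hap)
        H[:, s] = np.where(prev, u < cond1, u < cond0)
    return H


def simulate_genotypes(config: SimulationConfig, n: int, rng=None) -> np.ndarray:
    """Population genotype matrix: haplotypes per LD block paired under
    random mating, so HWE holds marginally."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cols = []
    s = 0
    bi = 0
    while s < config.n_snps:
        if config.haplotype_freqs is not None:
            haps, freqs = config.haplotype_freqs[bi % len(config.haplotype_freqs)]
            haps = np.asarray(haps, dtype=float)
            freqs = np.asarray(freqs, dtype=float)
            if not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("haplotype frequencies must sum to 1")
            width = min(haps.shape[1], config.n_snps - s)
            idx1 = rng.choice(len(freqs), size=n, p=freqs)
            idx2 = rng.choice(len(freqs), size=n, p=freqs)
            block = haps[idx1][:, :width] + haps[idx2][:, :width]
        else:
            width = min(config.block_size, config.n_snps - s)
            h = _block_haplotypes(rng, 2 * n, width, config)
            block = h[:n] + h[n:]
        cols.append(block)
        s += width
        bi += 1
    return np.hstack(cols)


def _covariates(rng, n: int, config: SimulationConfig) -> pd.DataFrame:
    age = np.clip(rng.normal(55.0, 10.0, size=n), 20.0, 74.0)
    batch = rng.integers(config.n_batches, size=n)
    # quality: most samples near 1, a configurable low-quality tail below
    # the error boundary
    gc = 1.0 - 0.25 * rng.beta(1.5, 8.0, size=n)
    low = rng.random(n) < config.low_quality_fraction
    gc[low] = rng.uniform(0.70, config.error_quality_boundary, size=int(low.sum()))
    return pd.DataFrame(
        {"age": age, "batch": np.array([f"b{b + 1}" for b in batch]), "gc50pct": np.round(gc, 4)}
    )


def simulate_case_control(
    config: SimulationConfig, genotypes: np.ndarray, rng=None
) -> tuple[StudyDataset, dict]:
    """Retrospective case-control sample from the logistic disease model.

    Disease status is drawn for the whole synthetic population from a
    logistic model with the configured genetic and design effects; then
    exactly ``n_cases`` cases and ``n_controls`` controls are sampled.
    Returns the dataset and a truth manifest with every true parameter.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genotypes = np.asarray(genotypes, dtype=float)
    n = genotypes.shape[0]
    cov = _covariates(rng, n, config)
    age_z = (cov["age"] - cov["age"].mean()) / cov["age"].std()
    gc_z = (cov["gc50pct"] - cov["gc50pct"].mean()) / cov["gc50pct"].std()
    batch_idx = cov["batch"].str.slice(1).astype(int) - 1

    eta = np.full(n, config.baseline_logit)
    eta += config.age_log_or_per_sd * age_z.to_numpy()
    eta += config.gc_log_or_per_sd * gc_z.to_numpy()
    eta += np.asarray(config.batch_log_or)[batch_idx]
    eta += np.asarray(config.batch_gc_log_or)[batch_idx] * gc_z.to_numpy()
    for snp, gm, orr in config.causal:
        eta += math.log(orr) * encode_column(genotypes[:, snp], gm)
    status = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    if case_idx.size < config.n_cases or ctrl_idx.size < config.n_controls:
        raise ValueError(
            f"population of {n} yielded {case_idx.size} cases / {ctrl_idx.size} "
            "controls; increase population_size"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=config.n_cases, replace=False),
            rng.choice(ctrl_idx, size=config.n_controls, replace=False),
        ]
    )
    snp_info = pd.DataFrame(
        {
            "snp_id": [f"snp{j:04d}" for j in range(config.n_snps)],
            "gene": [f"gene{j // (2 * config.block_size):03d}" for j in range(config.n_snps)],
        }
    )
    dataset = StudyDataset(
        genotypes=genotypes[take],
        case_status=status[take],
        covariates=cov.iloc[take].reset_index(drop=True),
        snp_info=snp_info,
    )
    truth = {
        "causal": [(int(s), gm.value, float(orr)) for s, gm, orr in config.causal],
        "log_or": {int(s): math.log(orr) for s, _, orr in config.causal},
        "baseline_logit": config.baseline_logit,
        "batch_log_or": list(config.batch_log_or),
        "batch_gc_log_or": list(config.batch_gc_log_or),
        "age_log_or_per_sd": config.age_log_or_per_sd,
        "gc_log_or_per_sd": config.gc_log_or_per_sd,
        "population_size": n,
        "population_maf": (np.nanmean(genotypes, axis=0) / 2.0).tolist(),
    }
    return dataset, truth


def inject_missingness(dataset: StudyDataset, config: SimulationConfig, rng=None) -> StudyDataset:
    """Apply the configured missingness mechanism.

    mcar: every entry independently at ``missing_rate``. mar: the rate is
    doubled in the last batch and tripled for samples below the quality
    boundary (a function of observables only). mnar: rare homozygotes go
    missing at ``mnar_rare_multiplier`` times the base rate — the
    low-frequency-polymorphism-interferes-with-the-assay scenario, not
    recoverable from observed data.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    out = dataset.copy()
    n, s = out.genotypes.shape
    base = config.missing_rate
    if base == 0.0:
        return out
    if config.missing_mechanism == "mcar":
        rate = np.full((n, 1), base)
    elif config.missing_mechanism == "mar":
        batch = out.covariates["batch"].to_numpy()
        gc = out.covariates["gc50pct"].to_numpy(dtype=float)
        mult = np.ones(n)
        mult[batch == f"b{config.n_batches}"] *= 2.0
        mult[gc < config.error_quality_boundary] *= 3.0
        rate = np.clip(base * mult, 0.0, 1.0)[:, None]
    elif config.missing_mechanism == "mnar":
        rate = np.where(out.genotypes == 2.0, min(base * config.mnar_rare_multiplier, 1.0), base)
    else:
        raise ValueError(f"unknown missingness mechanism {config.missing_mechanism!r}")
    mask = rng.random((n, s)) < rate
    out.genotypes[mask] = np.nan
    return out


def inject_genotype_error(dataset: StudyDataset, config: SimulationConfig, rng=None) -> StudyDataset:
    """Flip genotypes of low-quality samples.

    Samples with GC50PCT below ``error_quality_boundary`` have each
    genotype replaced, with probability ``genotype_error_rate``, by a
    uniformly chosen *different* genotype — which breaks HWE among the
    affected samples and is what the quality threshold scan detects.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    out = dataset.copy()
    if config.genotype_error_rate == 0.0:
        return out
    low = out.covariates["gc50pct"].to_numpy(dtype=float) < config.error_quality_boundary
    rows = np.flatnonzero(low)
    if rows.size == 0:
        return out
    g = out.genotypes
    flip = rng.random((rows.size, g.shape[1])) < config.genotype_error_rate
    shift = rng.integers(1, 3, size=flip.shape)  # +1 or +2 mod 3 => a different value
    sub = g[rows]
    ok = flip & ~np.isnan(sub)
    sub[ok] = np.mod(sub[ok] + shift[ok], 3.0)
    g[rows] = sub
    return out


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, dict]:
    """Full generator: population genotypes -> retrospective sample ->
    missingness -> genotyping error. One seed drives everything; fixed
    seed gives byte-identical datasets."""
    rng = np.random.default_rng(config.seed)
    if config.population_size is not None:
        npop = config.population_size
    else:
        npop = int(max(config.n_cases / 0.18, config.n_controls / 0.40))
    geno = simulate_genotypes(config, npop, rng)
    dataset, truth = simulate_case_control(config, geno, rng)
    dataset = inject_missingness(dataset, config, rng)
    dataset = inject_genotype_error(dataset, config, rng)
    truth["config"] = {
        k: (v if not isinstance(v, list) or not v or not isinstance(v[0], tuple) else str(v))
        for k, v in asdict(config).items()
    }
    return dataset, truth


def default_scenario(seed: int | None = None, **overrides) -> SimulationConfig:
    """The shipped study-scale scenario (484 SNPs, 364 cases, 761
    controls, four batches, modest genotyping error below quality
    0.789)."""
    kw = dict(genotype_error_rate=0.10, seed=seed)
    kw.update(overrides)
    return SimulationConfig(**kw)
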