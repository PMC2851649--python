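"""SNP- and sample-level quality control.

Implements the filter cascade used for Golden-Gate-style candidate-gene
panels: per-batch call-rate masking, reference-trio concordance checks,
a continuity-corrected chi-square test for Hardy-Weinberg equilibrium
among controls, a tail diagnostic on the resulting p-value distribution,
a scan over sample-quality (GC50PCT) thresholds that repairs HWE by
dropping low-quality samples, and removal of perfectly redundant SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import StudyDataset

__all__ = [
    "HWEResult",
    "TailDiagnostic",
    "QCReport",
    "hwe_test",
    "hwe_pvalues",
    "hwe_tail_diagnostic",
    "call_rate_filter",
    "reference_concordance",
    "quality_threshold_scan",
    "redundancy_filter",
    "apply_qc",
]


@dataclass
class HWEResult:
    """Continuity-corrected chi-square goodness-of-fit test for HWE."""

    n0: int
    n1: int
    n2: int
    expected: tuple[float, float, float]
    statistic: float
    p_value: float
    monomorphic: bool = False


@dataclass
class TailDiagnostic:
    """Left-tail calibration of a collection of p-values.

    Under independence and uniformity the count below ``alpha`` is
    Binomial(n, alpha); ``percentile_low``/``percentile_high`` are its
    2.5th and 97.5th percentiles.
    """

    n: int
    alpha: float
    observed: int
    expected: float
    percentile_low: int
    percentile_high: int
    qq_uniform: np.ndarray = field(repr=False, default=None)
    qq_observed: np.ndarray = field(repr=False, default=None)

    @property
    def within_band(self) -> bool:
        return self.percentile_low <= self.observed <= self.percentile_high


@dataclass
class QCReport:
    """Outcome of the full QC cascade on one study."""

    call_rate_removed: list[str]
    concordance_removed: list[str]
    redundant_removed: list[str]
    hwe_p: pd.Series
    quality_threshold: float | None
    samples_removed: int
    counts: dict[str, int]


def hwe_test(n0: int, n1: int, n2: int, c: float = 0.25) -> HWEResult:
    """Chi-square test for Hardy-Weinberg equilibrium with continuity
    correction ``c`` (default 0.25), one degree of freedom.

    ``n0/n1/n2`` are counts of common homozygotes, heterozygotes and rare
    homozygotes. Expected counts come from the observed allele frequency;
    each cell contributes ``max(|O - E| - c, 0)^2 / E``. A monomorphic
    sample (one allele unobserved) leaves the test undefined: p is
    reported as 1 with the ``monomorphic`` flag set.
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * n0 + n1) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        e = (n * p * p, 2 * n * p * q, n * q * q)
        return HWEResult(n0, n1, n2, e, 0.0, 1.0, monomorphic=True)
    e = (n * p * p, 2 * n * p * q, n * q * q)
    stat = sum(
        max(abs(o - ei) - c, 0.0) ** 2 / ei for o, ei in zip((n0, n1, n2), e)
    )
    pval = float(stats.chi2.sf(stat, df=1))
    return HWEResult(n0, n1, n2, e, float(stat), pval)


def hwe_pvalues(
    genotypes: np.ndarray, subject_mask: np.ndarray | None = None, c: float = 0.25
) -> np.ndarray:
    """HWE p-value per SNP column over the masked subjects (NaN-aware)."""
    g = np.asarray(genotypes, dtype=float)
    if subject_mask is not None:
        g = g[np.asarray(subject_mask, dtype=bool)]
    out = np.empty(g.shape[1])
    for j in range(g.shape[1]):
        col = g[:, j]
        col = col[~np.isnan(col)]
        out[j] = hwe_test((col == 0).sum(), (col == 1).sum(), (col == 2).sum(), c=c).p_value
    return out


def hwe_tail_diagnostic(p_values, alpha: float = 0.01) -> TailDiagnostic:
    """Compare the left tail of HWE p-values with the uniform expectation."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    if n < 1:
        raise ValueError("at least one p-value required")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    lo = int(stats.binom.ppf(0.025, n, alpha))
    hi = int(stats.binom.ppf(0.975, n, alpha))
    return TailDiagnostic(
        n=n,
        alpha=alpha,
        observed=int((p < alpha).sum()),
        expected=n * alpha,
        percentile_low=lo,
        percentile_high=hi,
        qq_uniform=(np.arange(1, n + 1) - 0.5) / n,
        qq_observed=p,
    )


def call_rate_filter(
    genotypes: np.ndarray,
    batches,
    threshold: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, set[int]]:
    """Per-batch call-rate masking.

    A SNP whose call rate in a batch falls below ``threshold`` (default
    99%) is treated as missing for every sample in that batch; a SNP
    failing in *all* batches is flagged for removal. Returns the masked
    genotype matrix, a (n_batches, n_snps) boolean fail-flag array (batch
    rows ordered by sorted label) and the removed-SNP index set.
    """
    g = np.asarray(genotypes, dtype=float).copy()
    batches = np.asarray(batches)
    levels = sorted(pd.unique(batches).tolist(), key=str)
    flags = np.zeros((len(levels), g.shape[1]), dtype=bool)
    for bi, lev in enumerate(levels):
        rows = batches == lev
        if rows.sum() == 0:
            raise ValueError(f"empty batch {lev!r}")
        rate = 1.0 - np.isnan(g[rows]).mean(axis=0)
        fail = rate < threshold
        flags[bi] = fail
        g[np.ix_(rows, np.flatnonzero(fail))] = np.nan
    removed = set(np.flatnonzero(flags.all(axis=0)).tolist())
    return g, flags, removed


def reference_concordance(
    called: np.ndarray, reference: np.ndarray, rate_threshold: float = 0.95
) -> dict:
    """Concordance of called genotypes with published reference genotypes.

    Two failure modes are flagged: overall concordance below
    ``rate_threshold``, and *any* discordance (for small reference panels
    such as six trios = 18 genotypes, one mismatch already implies an
    estimated error rate >= 1/18).
    """
    a = np.asarray(called, dtype=float).ravel()
    b = np.asarray(reference, dtype=float).ravel()
    ok = ~np.isnan(a) & ~np.isnan(b)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no overlapping non-missing genotype calls")
    matches = int((a[ok] == b[ok]).sum())
    rate = matches / n
    return {
        "n_comparisons": n,
        "n_mismatches": n - matches,
        "concordance": rate,
        "rate_fail": rate < rate_threshold,
        "any_discordance_fail": matches < n,
    }


def quality_threshold_scan(
    dataset: StudyDataset,
    grid=None,
    alpha: float = 0.01,
    c: float = 0.25,
) -> tuple[float, pd.DataFrame]:
    """Scan GC50PCT thresholds and pick the smallest that repairs HWE.

    For each threshold, samples with quality below it are dropped, control
    HWE p-values recomputed, and two summaries recorded: the count of
    p-values below ``alpha`` and the Kolmogorov-Smirnov distance to the
    uniform distribution. Chosen threshold = smallest whose tail count
    lies inside the binomial 95% band; ties in admissibility are broken in
    favor of the smaller threshold, and if no threshold is admissible the
    one with the smallest KS distance wins.
    """
    if grid is None:
        grid = np.round(np.arange(0.70, 0.8005, 0.001), 3)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    quality = dataset.covariates["gc50pct"].to_numpy(dtype=float)
    ctrl = dataset.control_mask
    rows = []
    for thr in grid:
        keep = quality >= thr
        if not (keep & ctrl).any():
            warnings.warn(f"threshold {thr} removes all controls; skipped", UserWarning)
            continue
        p = hwe_pvalues(dataset.genotypes, keep & ctrl, c=c)
        diag = hwe_tail_diagnostic(p, alpha=alpha)
        ks = stats.kstest(p, "uniform").statistic
        rows.append(
            {
                "threshold": float(thr),
                "n_samples": int(keep.sum()),
                "n_below_alpha": diag.observed,
                "expected": diag.expected,
                "band_low": diag.percentile_low,
                "band_high": diag.percentile_high,
                "within_band": diag.within_band,
                "ks_distance": float(ks),
            }
        )
    if not rows:
        raise ValueError("no feasible threshold in grid")
    table = pd.DataFrame(rows)
    ok = table[table["within_band"]]
    if len(ok):
        chosen = float(ok["threshold"].iloc[0])
    else:
        chosen = float(table.loc[table["ks_distance"].idxmin(), "threshold"])
    return chosen, table


def redundancy_filter(genotypes: np.ndarray, snp_ids=None) -> np.ndarray:
    """Indices of a non-redundant SNP set.

    Among pairs with squared genotype correlation exactly 1 on pairwise
    complete cases, the SNP with fewer missing values is kept (ties by
    id, then column order). Correlation is computed on dosages
    (composite LD); phase is not required.
    """
    g = np.asarray(genotypes, dtype=float)
    s = g.shape[1]
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(s)])
    missing = np.isnan(g).sum(axis=0)
    drop = np.zeros(s, dtype=bool)
    for j in range(s):
        if drop[j]:
            continue
        for k in range(j + 1, s):
            if drop[k]:
                continue
            ok = ~np.isnan(g[:, j]) & ~np.isnan(g[:, k])
            if ok.sum() < 2:
                continue
            a, b = g[ok, j], g[ok, k]
            if a.std() == 0.0 or b.std() == 0.0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if np.isclose(r * r, 1.0, atol=1e-12):
                # drop the copy with more missingness
                if missing[j] < missing[k]:
                    drop[k] = True
                elif missing[k] < missing[j]:
                    drop[j] = True
                else:
                    drop[k if str(snp_ids[j]) <= str(snp_ids[k]) else j] = True
            if drop[j]:
                break
    return np.flatnonzero(~drop)


def apply_qc(
    dataset: StudyDataset,
    reference_calls: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    call_rate_threshold: float = 0.99,
    concordance_threshold: float = 0.95,
    hwe_alpha: float = 0.01,
    scan_quality: bool = True,
    drop_hwe_failures: bool = False,
    quality_grid=None,
) -> tuple[StudyDataset, QCReport]:
    """Run the full cascade: call rate -> concordance -> redundancy ->
    quality-threshold scan (-> optional HWE SNP filter).

    ``reference_calls`` maps SNP id to (called, published) genotype arrays
    for reference samples; SNPs with any discordance are removed. The HWE
    tail is primarily a *sample* diagnostic driving the quality scan;
    setting ``drop_hwe_failures`` additionally removes SNPs with control
    HWE p below ``hwe_alpha`` after the scan.
    """
    counts = {"input_snps": dataset.n_snps, "input_samples": dataset.n_subjects}
    ids = dataset.snp_ids

    masked, _, removed_idx = call_rate_filter(
        dataset.genotypes, dataset.covariates["batch"].to_numpy(), call_rate_threshold
    )
    dataset = dataset.copy()
    dataset.genotypes = masked
    call_rate_removed = [str(ids[j]) for j in sorted(removed_idx)]

    concordance_removed = []
    if reference_calls:
        for snp_id, (called, ref) in reference_calls.items():
            res = reference_concordance(called, ref, concordance_threshold)
            if res["rate_fail"] or res["any_discordance_fail"]:
                concordance_removed.append(str(snp_id))

    keep = ~np.isin(ids, call_rate_removed + concordance_removed)
    dataset = dataset.select_snps(keep)
    counts["after_call_rate_concordance"] = dataset.n_snps

    nonred = redundancy_filter(dataset.genotypes, dataset.snp_ids)
    redundant_removed = [
        str(i) for i in dataset.snp_ids[np.setdiff1d(np.arange(dataset.n_snps), nonred)]
    ]
    dataset = dataset.select_snps(nonred)
    counts["after_redundancy"] = dataset.n_snps

    threshold = None
    samples_removed = 0
    if scan_quality:
        threshold, _ = quality_threshold_scan(dataset, grid=quality_grid, alpha=hwe_alpha)
        keep_s = dataset.covariates["gc50pct"].to_numpy(dtype=float) >= threshold
        samples_removed = int((~keep_s).sum())
        dataset = dataset.select_subjects(keep_s)
    counts["after_quality_scan_samples"] = dataset.n_subjects

    hwe_p = pd.Series(
        hwe_pvalues(dataset.genotypes, dataset.control_mask), index=dataset.snp_ids
    )
    if drop_hwe_failures:
        dataset = dataset.select_snps((hwe_p >= hwe_alpha).to_numpy())
    counts["final_snps"] = dataset.n_snps

    report = QCReport(
        call_rate_removed=call_rate_removed,
        concordance_removed=concordance_removed,
        redundant_removed=redundant_removed,
        hwe_p=hwe_p,
        quality_threshold=threshold,
        samples_removed=samples_removed,
        counts=counts,
    )
    return dataset, report
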