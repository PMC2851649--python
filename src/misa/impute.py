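"""Multiple imputation of missing genotypes and missingness diagnostics.

Missing hard calls are imputed from local linkage disequilibrium: for
each SNP with missing entries, a haplotype-frequency model over a small
window of neighboring SNPs is fitted by EM to the unphased genotypes,
and per-entry posterior distributions over {0, 1, 2} are derived by
conditioning on the subject's observed genotypes in the window. The
procedure assumes missingness is ignorable (MCAR/MAR);
:func:`missingness_bf` checks that assumption per SNP by scoring the
association of the 0-1 missingness indicator with case status, given the
design covariates, for SNPs with at least five missing values.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import DesignMatrix, StudyDataset, build_design_matrix
from .evidence import Priors, log_marginal_likelihood

__all__ = [
    "HaplotypeImputer",
    "ImputationSet",
    "fit_imputer",
    "draw_imputations",
    "modal_fill",
    "missingness_bf",
    "MissingnessResult",
]


@dataclass
class ImputationSet:
    """m completed genotype matrices plus the posteriors they came from.

    Observed entries are identical across all matrices; each imputed
    entry is in {0, 1, 2}.
    """

    matrices: list[np.ndarray]
    posteriors: dict[tuple[int, int], np.ndarray]
    seed: int | None
    m: int

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, mat in enumerate(self.matrices):
            np.savetxt(directory / f"imputation_{i:03d}.tsv", mat, fmt="%.0f", delimiter="\t")
        (directory / "manifest.json").write_text(
            json.dumps({"m": self.m, "seed": self.seed, "n_matrices": len(self.matrices)})
        )


@dataclass
class MissingnessResult:
    """BF for dependence of a SNP's missingness on case-control status."""

    snp_id: str
    missing_count: int
    bf: float
    evaluated: bool


class HaplotypeImputer(BaseEstimator, TransformerMixin):
    """Windowed haplotype-frequency EM imputer for hard-call genotypes.

    For each SNP carrying missing values, up to ``window`` SNPs centered
    on it (by column order) define a local haplotype model: frequencies
    of the 2^w binary haplotypes are estimated by EM over unphased,
    possibly incomplete window genotypes, and each missing entry gets a
    posterior over {0, 1, 2} by summing compatible haplotype pairs. A
    window whose EM degenerates falls back to marginal genotype
    frequencies.

    ``transform`` completes a matrix with posterior-mode values;
    ``sample``/:func:`draw_imputations` draw proper multiple imputations.
    """

    def __init__(self, window: int = 5, max_iter: int = 100, tol: float = 1e-6):
        self.window = window
        self.max_iter = max_iter
        self.tol = tol

    # -- EM machinery ----------------------------------------------------
    @staticmethod
    def _em_window(G: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
        """Haplotype frequencies for a window genotype matrix (NaN ok)."""
        n, w = G.shape
        haps = np.array(list(itertools.product((0, 1), repeat=w)), dtype=float)
        H = haps.shape[0]
        pairs = [(i, j) for i in range(H) for j in range(i, H)]
        pair_geno = np.array([haps[i] + haps[j] for i, j in pairs])  # (P, w)
        mult = np.array([1.0 if i == j else 2.0 for i, j in pairs])

        # group subjects by observed pattern
        patterns: dict[tuple, int] = {}
        counts: list[int] = []
        compat: list[np.ndarray] = []
        for r in range(n):
            key = tuple(-1 if math.isnan(v) else int(v) for v in G[r])
            if key in patterns:
                counts[patterns[key]] += 1
            else:
                obs = np.array([k >= 0 for k in key])
                tgt = np.array([max(k, 0) for k in key], dtype=float)
                ok = np.all(pair_geno[:, obs] == tgt[obs], axis=1) if obs.any() else np.ones(len(pairs), bool)
                patterns[key] = len(counts)
                counts.append(1)
                compat.append(ok)
        counts = np.asarray(counts, dtype=float)

        # init from marginal allele frequencies
        with np.errstate(invalid="ignore"):
            p = np.nanmean(G, axis=0) / 2.0
        p = np.clip(np.nan_to_num(p, nan=0.5), 0.01, 0.99)
        f = np.prod(np.where(haps == 1, p, 1 - p), axis=1)
        f /= f.sum()

        ii = np.array([i for i, _ in pairs])
        jj = np.array([j for _, j in pairs])
        prev = -np.inf
        for _ in range(max_iter):
            pw = mult * f[ii] * f[jj]  # (P,)
            expected = np.zeros(H)
            ll = 0.0
            for k, ok in enumerate(compat):
                wk = pw * ok
                tot = wk.sum()
                if tot <= 0:
                    continue
                ll += counts[k] * math.log(tot)
                wk = wk / tot * counts[k]
                np.add.at(expected, ii, wk)
                np.add.at(expected, jj, wk)
            f = np.clip(expected, 1e-12, None)
            f /= f.sum()
            if abs(ll - prev) < tol * (1 + abs(ll)):
                break
            prev = ll
        return f

    @staticmethod
    def _entry_posterior(f: np.ndarray, window_geno: np.ndarray, pos: int) -> np.ndarray:
        """Posterior over {0,1,2} at window position ``pos`` given the
        subject's observed window genotypes."""
        w = window_geno.size
        haps = np.array(list(itertools.product((0, 1), repeat=w)), dtype=float)
        H = haps.shape[0]
        obs = ~np.isnan(window_geno)
        obs[pos] = False
        post = np.zeros(3)
        for i in range(H):
            for j in range(i, H):
                g = haps[i] + haps[j]
                if obs.any() and not np.all(g[obs] == window_geno[obs]):
                    continue
                wgt = (1.0 if i == j else 2.0) * f[i] * f[j]
                post[int(g[pos])] += wgt
        tot = post.sum()
        if tot <= 0:  # degenerate: marginal fallback handled by caller
            return None
        return post / tot

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, s = X.shape
        if s < 1:
            raise ValueError("need at least one SNP")
        if np.isnan(X).all(axis=0).any():
            bad = np.flatnonzero(np.isnan(X).all(axis=0))
            raise ValueError(f"all-missing SNP column(s): {bad.tolist()}")
        self.n_features_in_ = s
        self.posteriors_ = {}
        missing_cols = np.flatnonzero(np.isnan(X).any(axis=0))
        half = max(int(self.window) - 1, 0) // 2
        for j in missing_cols:
            lo = max(0, j - half)
            hi = min(s, lo + max(int(self.window), 1))
            lo = max(0, hi - max(int(self.window), 1))
            cols = np.arange(lo, hi)
            pos = int(np.flatnonzero(cols == j)[0])
            Gw = X[:, cols]
            f = self._em_window(Gw, self.max_iter, self.tol)
            # marginal fallback distribution for this SNP
            colv = X[:, j]
            obs = colv[~np.isnan(colv)]
            marg = np.array([(obs == v).sum() for v in (0, 1, 2)], dtype=float)
            marg = marg / marg.sum() if marg.sum() else np.array([1 / 3] * 3)
            for r in np.flatnonzero(np.isnan(colv)):
                post = self._entry_posterior(f, Gw[r], pos)
                self.posteriors_[(int(r), int(j))] = marg if post is None else post
        return self

    def transform(self, X) -> np.ndarray:
        """Complete a matrix with posterior-mode genotypes (ties to the
        smaller count)."""
        X = np.asarray(X, dtype=float).copy()
        for (r, j), post in self.posteriors_.items():
            if np.isnan(X[r, j]):
                X[r, j] = float(np.argmax(np.round(post, 12)))
        return X

    def sample(self, X, m: int = 100, seed: int | None = None) -> ImputationSet:
        """Draw ``m`` independent completions of ``X`` from the per-entry
        posteriors (reproducible under a fixed seed)."""
        if m < 1:
            raise ValueError("m must be >= 1")
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(seed)
        mats = []
        entries = sorted(self.posteriors_)
        for _ in range(m):
            mat = X.copy()
            for (r, j) in entries:
                if np.isnan(mat[r, j]):
                    mat[r, j] = float(rng.choice(3, p=self.posteriors_[(r, j)]))
            mats.append(mat)
        return ImputationSet(matrices=mats, posteriors=dict(self.posteriors_), seed=seed, m=m)


def fit_imputer(genotypes: np.ndarray, window_size: int = 5, **kw) -> HaplotypeImputer:
    """Fit the windowed haplotype EM imputer to a genotype matrix."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    return HaplotypeImputer(window=window_size, **kw).fit(np.asarray(genotypes, dtype=float))


def draw_imputations(
    model: HaplotypeImputer, genotypes: np.ndarray, m: int = 100, seed: int | None = None
) -> ImputationSet:
    """m posterior draws of the completed genotype matrix."""
    return model.sample(genotypes, m=m, seed=seed)


def modal_fill(imputations: ImputationSet) -> np.ndarray:
    """Single completed matrix with each missing entry replaced by its
    most frequent imputed value (ties to the smaller genotype count)."""
    if imputations.m < 1:
        raise ValueError("need at least one imputation")
    out = imputations.matrices[0].copy()
    for (r, j) in imputations.posteriors:
        vals = np.array([mat[r, j] for mat in imputations.matrices])
        counts = [(vals == v).sum() for v in (0, 1, 2)]
        out[r, j] = float(int(np.argmax(counts)))  # argmax ties -> smaller count
    return out


def missingness_bf(
    dataset: StudyDataset,
    snp,
    design: DesignMatrix | None = None,
    priors: Priors | None = None,
    min_missing: int = 5,
    method: str = "laplace",
) -> MissingnessResult:
    """BF for conditional dependence of a SNP's missingness on
    case-control status given the design variables.

    The SNP's 0-1 missingness indicator stands in for its genotype in a
    single-covariate logistic model against the design-only null; SNPs
    with fewer than ``min_missing`` (default 5) missing values are
    flagged not-evaluated.
    """
    if priors is None:
        priors = Priors()
    if design is None:
        design = build_design_matrix(dataset)
    j = dataset.snp_index(snp) if isinstance(snp, str) else int(snp)
    indicator = np.isnan(dataset.genotypes[:, j]).astype(float)
    n_missing = int(indicator.sum())
    snp_id = str(dataset.snp_ids[j])
    if n_missing < min_missing:
        return MissingnessResult(snp_id, n_missing, math.nan, evaluated=False)
    y = dataset.case_status
    log_null, _ = log_marginal_likelihood(design.matrix, None, y, priors, method)
    log_alt, _ = log_marginal_likelihood(design.matrix, indicator[:, None], y, priors, method)
    return MissingnessResult(snp_id, n_missing, math.exp(log_alt - log_null), evaluated=True)
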