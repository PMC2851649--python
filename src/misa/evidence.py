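"""Marginal likelihoods, Bayes factors and the evidence calculus.

Association models are logistic regressions of case status on the design
covariates plus encoded SNP effects. Marginal likelihoods integrate the
logistic likelihood against independent zero-mean normal priors — a
diffuse prior (sd 10, on standardized covariates) shared by the design
coefficients of every model, and a prior calibrated for small-to-modest
effects (sd 0.5 on the log-odds-ratio scale) on each genetic coefficient
— via a Laplace approximation at the posterior mode. An AIC-based
evidence (-AIC/2) is available as a documented fast alternative.

The Bayes factor for hypothesis H1 over H0 is the ratio of their
marginal likelihoods; it updates prior odds pi/(1-pi) to posterior odds
PO = BF * pi/(1-pi) and PPA = PO/(1+PO).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import DesignMatrix, GeneticModel, StudyDataset, build_design_matrix, encode_column, minor_allele_frequency

__all__ = [
    "Priors",
    "EvidenceSummary",
    "LogisticFit",
    "fit_logistic_map",
    "log_marginal_likelihood",
    "marginal_snp_bf",
    "MarginalBayesScreen",
    "screen",
    "bf_to_evidence",
    "jeffreys_category",
]

_SEPARATION_BOUND = 15.0

GENETIC_MODELS = (GeneticModel.LOG_ADDITIVE, GeneticModel.DOMINANT, GeneticModel.RECESSIVE)


@dataclass
class Priors:
    """Prior specification shared by the screen and the model search.

    ``effect_sd`` is the sd of the zero-mean normal prior on each genetic
    log-odds-ratio (default 0.5: 95% of prior OR mass in about
    [0.38, 2.66]); ``design_sd`` the diffuse sd on intercept and design
    coefficients, which appear in every model and approximately cancel in
    Bayes factors. ``a`` and ``b`` parameterize the beta-binomial prior on
    model size (``b`` defaults to the number of SNPs searched, set where
    the search is run); the three genetic parameterizations are a priori
    equally likely given inclusion.
    """

    effect_sd: float = 0.5
    design_sd: float = 10.0
    a: float = 1.0 / 8.0
    b: float | None = None
    genetic_model_prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.effect_sd <= 0 or self.design_sd <= 0:
            raise ValueError("prior standard deviations must be positive")
        if self.a <= 0 or (self.b is not None and self.b <= 0):
            raise ValueError("beta-binomial parameters must be positive")


@dataclass
class EvidenceSummary:
    """BF with the prior/posterior odds and probability it implies."""

    bf: float
    prior_probability: float
    prior_odds: float
    posterior_odds: float
    ppa: float
    category: str


@dataclass
class LogisticFit:
    beta: np.ndarray
    log_likelihood: float
    hessian: np.ndarray = field(repr=False)
    converged: bool
    n_iter: int


def _log_likelihood(X, y, beta):
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic_map(
    X: np.ndarray,
    y: np.ndarray,
    prior_precision: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Newton-Raphson for the logistic posterior mode.

    ``prior_precision`` is the diagonal of the normal prior precision
    (zeros give the unpenalized MLE). Step halving guards against
    overshoot; convergence is on the change in the penalized objective.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    lam = np.zeros(p) if prior_precision is None else np.asarray(prior_precision, float)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()

    def objective(b):
        return _log_likelihood(X, y, b) - 0.5 * float(lam @ (b * b))

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - lam * beta
        H = (X.T * w) @ X + np.diag(lam)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            new = beta + t * step
            new_obj = objective(new)
            if new_obj >= obj - 1e-12:
                break
            t *= 0.5
        beta, delta, obj = new, new_obj - obj, new_obj
        if abs(delta) < tol * (1.0 + abs(obj)):
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X.T * w) @ X + np.diag(lam)
    return LogisticFit(
        beta=beta,
        log_likelihood=_log_likelihood(X, y, beta),
        hessian=H,
        converged=converged,
        n_iter=it,
    )


def _mle_separated(X, y, beta0=None) -> bool:
    """Attempt the unpenalized MLE; flag separation by non-convergence or
    a coefficient beyond +/-15 on the log-odds scale."""
    fit = fit_logistic_map(X, y, prior_precision=None, beta0=beta0, max_iter=25)
    return (not fit.converged) or bool(np.abs(fit.beta).max() > _SEPARATION_BOUND)


def log_marginal_likelihood(
    X_design: np.ndarray,
    genetic_columns: np.ndarray | None,
    y: np.ndarray,
    priors: Priors,
    method: str = "laplace",
    check_estimability: bool = False,
    beta0: np.ndarray | None = None,
):
    """Log evidence of one association model.

    ``X_design`` is the (already standardized) null-model design including
    the intercept; ``genetic_columns`` the encoded SNP covariates (or None
    for the null model).

    Laplace: log p(D) = l(b^) - b^'Lb^/2 + log|L|/2 - log|H|/2 with L the
    prior precision and H the negative log-posterior Hessian at the mode
    b^; the mode always exists under the proper prior, so separated
    models keep finite evidence. AIC: -AIC/2 at the (possibly penalized)
    mode, a fast large-sample surrogate.

    Returns ``(log_evidence, info)`` where info carries the mode, its
    covariance diagonal and an ``estimable`` flag (only evaluated when
    ``check_estimability``; separation means the MLE does not exist).
    """
    X_design = np.asarray(X_design, dtype=float)
    if np.linalg.matrix_rank(X_design) < X_design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if genetic_columns is None or (hasattr(genetic_columns, "size") and genetic_columns.size == 0):
        X = X_design
        k = 0
    else:
        G = np.atleast_2d(np.asarray(genetic_columns, dtype=float))
        if G.shape[0] != X_design.shape[0]:
            G = G.T
        X = np.hstack([X_design, G])
        k = G.shape[1]
    p = X.shape[1]
    lam = np.empty(p)
    lam[: p - k] = 1.0 / priors.design_sd**2
    if k:
        lam[p - k :] = 1.0 / priors.effect_sd**2

    fit = fit_logistic_map(X, y, prior_precision=lam, beta0=beta0)
    sign, logdet = np.linalg.slogdet(fit.hessian)
    if sign <= 0:
        raise FloatingPointError("non-positive-definite Hessian in Laplace step")
    if method == "laplace":
        log_ev = (
            fit.log_likelihood
            - 0.5 * float(lam @ (fit.beta**2))
            + 0.5 * float(np.log(lam).sum())
            - 0.5 * logdet
        )
    elif method == "aic":
        # -AIC/2 wants the unpenalized MLE log-likelihood; warm-start from
        # the mode and fall back to it if the MLE diverges (separation)
        mle = fit_logistic_map(X, y, prior_precision=None, beta0=fit.beta, max_iter=25)
        ll = mle.log_likelihood if mle.converged else fit.log_likelihood
        log_ev = ll - p
    else:
        raise ValueError(f"unknown evidence method {method!r}")

    estimable = True
    if check_estimability and k:
        estimable = not _mle_separated(X, y, beta0=fit.beta)
    cov = np.linalg.inv(fit.hessian)
    info = {
        "beta": fit.beta,
        "se": np.sqrt(np.diag(cov)),
        "estimable": estimable,
        "converged": fit.converged,
        "n_genetic": k,
    }
    return float(log_ev), info


def marginal_snp_bf(
    snp_column: np.ndarray,
    X_design: np.ndarray,
    y: np.ndarray,
    priors: Priors,
    method: str = "laplace",
    log_ev_null: float | None = None,
) -> dict:
    """Single-SNP Bayes factors under each genetic parameterization.

    For each parameterization g, BF_g compares design+SNP(g) against the
    design-only null. Encodings that are constant in the data (e.g.
    recessive with no rare homozygotes) are skipped with a flag. Also
    reports the posterior-mode OR with a normal-approximation 95%
    credible interval per parameterization, NA when the MLE for that
    model does not exist.
    """
    snp_column = np.asarray(snp_column, dtype=float)
    if log_ev_null is None:
        log_ev_null, _ = log_marginal_likelihood(X_design, None, y, priors, method)
    out: dict = {"bf": {}, "or": {}, "ci": {}, "estimable": {}, "skipped": []}
    for g in GENETIC_MODELS:
        enc = encode_column(snp_column, g)
        if enc.std() == 0.0:
            out["skipped"].append(g)
            out["bf"][g] = math.nan
            out["or"][g] = math.nan
            out["ci"][g] = (math.nan, math.nan)
            out["estimable"][g] = False
            continue
        log_ev, info = log_marginal_likelihood(
            X_design, enc[:, None], y, priors, method, check_estimability=True
        )
        out["bf"][g] = math.exp(log_ev - log_ev_null)
        b, se = info["beta"][-1], info["se"][-1]
        if info["estimable"]:
            out["or"][g] = math.exp(b)
            out["ci"][g] = (math.exp(b - 1.959963984540054 * se), math.exp(b + 1.959963984540054 * se))
        else:
            out["or"][g] = math.nan
            out["ci"][g] = (math.nan, math.nan)
        out["estimable"][g] = info["estimable"]
    bfs = [v for v in out["bf"].values() if not math.isnan(v)]
    if not bfs:
        out["max_bf"] = math.nan
        out["excluded"] = True
    else:
        out["max_bf"] = max(bfs)
        out["excluded"] = False
    return out


class MarginalBayesScreen(BaseEstimator):
    """Permissive SNP-at-a-time Bayes-factor screen.

    Fits, for every SNP, the three single-SNP logistic models against the
    design-only null and records the Bayes factor of each; a SNP passes
    when its maximum BF exceeds ``threshold`` (strictly; default 1.0).
    With multiple imputations of missing genotypes, per-SNP BFs are the
    arithmetic mean of the per-imputation BFs (averaged on the BF scale,
    not the log scale).

    After ``fit``, behaves as a feature selector: ``transform`` keeps the
    passing SNP columns.

    Attributes
    ----------
    results_ : DataFrame with per-SNP BFs, ORs/CIs per parameterization,
        the maximum BF and the pass flag.
    support_ : boolean mask of passing SNPs.
    n_pass_ : number of passing SNPs (the ``S`` entering the
        model-search stage).
    """

    def __init__(self, priors: Priors | None = None, threshold: float = 1.0, method: str = "laplace"):
        self.priors = priors
        self.threshold = threshold
        self.method = method

    def fit(self, X, y, design: np.ndarray | DesignMatrix | None = None, snp_ids=None):
        priors = self.priors if self.priors is not None else Priors()
        y = np.asarray(y, dtype=float)
        matrices = X if isinstance(X, (list, tuple)) else [X]
        matrices = [np.asarray(m, dtype=float) for m in matrices]
        n, s = matrices[0].shape
        if design is None:
            Xd = np.ones((n, 1))
        elif isinstance(design, DesignMatrix):
            Xd = design.matrix
        else:
            Xd = np.asarray(design, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{j}" for j in range(s)]

        log_ev_null, _ = log_marginal_likelihood(Xd, None, y, priors, self.method)
        bf_sum = np.zeros((s, len(GENETIC_MODELS)))
        bf_count = np.zeros_like(bf_sum)
        last = [None] * s
        for m in matrices:
            if np.isnan(m).any():
                raise ValueError("screen requires completed genotypes (impute first)")
            for j in range(s):
                res = marginal_snp_bf(m[:, j], Xd, y, priors, self.method, log_ev_null)
                last[j] = res
                for gi, g in enumerate(GENETIC_MODELS):
                    if not math.isnan(res["bf"][g]):
                        bf_sum[j, gi] += res["bf"][g]
                        bf_count[j, gi] += 1
        with np.errstate(invalid="ignore"):
            bf_mean = np.where(bf_count > 0, bf_sum / np.maximum(bf_count, 1), np.nan)

        rows = []
        for j, sid in enumerate(snp_ids):
            row = {"snp_id": sid}
            for gi, g in enumerate(GENETIC_MODELS):
                row[f"bf_{g.value}"] = bf_mean[j, gi]
                row[f"or_{g.value}"] = last[j]["or"][g]
                lo, hi = last[j]["ci"][g]
                row[f"ci_low_{g.value}"], row[f"ci_high_{g.value}"] = lo, hi
            finite = bf_mean[j][~np.isnan(bf_mean[j])]
            row["max_bf"] = finite.max() if finite.size else math.nan
            row["pass"] = bool(finite.size and row["max_bf"] > self.threshold)
            rows.append(row)
        self.results_ = pd.DataFrame(rows)
        self.bf_ = bf_mean
        self.max_bf_ = self.results_["max_bf"].to_numpy()
        self.support_ = self.results_["pass"].to_numpy(dtype=bool)
        self.n_pass_ = int(self.support_.sum())
        self.log_evidence_null_ = log_ev_null
        return self

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]


def screen(
    dataset: StudyDataset,
    priors: Priors | None = None,
    imputations=None,
    threshold: float = 1.0,
    method: str = "laplace",
) -> pd.DataFrame:
    """Run the marginal screen on a study (thin wrapper over
    :class:`MarginalBayesScreen`).

    ``imputations`` may be an :class:`~misa.impute.ImputationSet` or a
    list of completed genotype matrices; without it the genotypes must
    already be complete. Adds gene labels and control MAF to the result
    table.
    """
    design = build_design_matrix(dataset)
    if imputations is None:
        mats = [dataset.genotypes]
    elif hasattr(imputations, "matrices"):
        mats = list(imputations.matrices)
    else:
        mats = list(imputations)
    est = MarginalBayesScreen(priors=priors, threshold=threshold, method=method)
    est.fit(mats, dataset.case_status, design=design, snp_ids=list(dataset.snp_ids))
    res = est.results_
    res.insert(1, "gene", dataset.snp_info["gene"].to_numpy())
    ctrl = dataset.control_mask
    res["maf"] = [
        minor_allele_frequency(dataset.genotypes[:, j], ctrl) for j in range(dataset.n_snps)
    ]
    return res


# ---------------------------------------------------------------------------
# evidence calculus

_JEFFREYS_BANDS = (
    (100.0, "decisive"),
    (30.0, "very strong"),
    (10.0, "strongly supportive"),
    (3.2, "supportive"),
    (1.0, "weakly supportive"),
)


def jeffreys_category(bf: float) -> str:
    """Jeffreys-style evidence label for a Bayes factor.

    Band lower bounds are inclusive: [1, 3.2) weakly supportive,
    [3.2, 10) supportive, [10, 30) strongly supportive, [30, 100) very
    strong, >= 100 decisive. A BF below 1 is evidence *for* the null: its
    reciprocal is categorized and the label suffixed accordingly.
    """
    if not bf > 0:
        raise ValueError("BF must be positive")
    if bf < 1.0:
        return jeffreys_category(1.0 / bf) + " of no association"
    for bound, label in _JEFFREYS_BANDS:
        if bf >= bound:
            return label
    return label  # pragma: no cover


def bf_to_evidence(bf: float, prior_probability: float) -> EvidenceSummary:
    """Convert a BF and prior probability pi into odds and PPA.

    PO = BF * pi/(1-pi); PPA = PO/(1+PO).
    """
    if not bf > 0:
        raise ValueError("BF must be positive")
    if not 0.0 < prior_probability < 1.0:
        raise ValueError("prior probability must lie in (0, 1)")
    prior_odds = prior_probability / (1.0 - prior_probability)
    po = bf * prior_odds
    return EvidenceSummary(
        bf=bf,
        prior_probability=prior_probability,
        prior_odds=prior_odds,
        posterior_odds=po,
        ppa=po / (1.0 + po),
        category=jeffreys_category(bf),
    )
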