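"""Posterior sampling over multivariate association models.

The model space contains every logistic regression that adds main
effects for a subset of SNPs — each under a log-additive, dominant or
recessive parameterization — to the fixed design covariates. A
beta-binomial prior on the number of included SNPs (parameters ``a``,
``b``; ``b`` set to the number of SNPs searched) induces an automatic
multiplicity correction with marginal prior inclusion odds ``a/b``;
given inclusion the three parameterizations are equally likely.

The posterior is explored either exactly, by enumerating all 4^S models
of a small panel, or by an evolutionary Monte Carlo (EMC) sampler: a
population of tempered Metropolis-Hastings chains mixed by mutation
(add/drop/re-parameterize a SNP), crossover between chains, and
temperature-exchange moves. SNP, gene and global Bayes factors are
posterior-to-prior inclusion odds ratios, Rao-Blackwellized over the
evaluated model set by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp
from sklearn.base import BaseEstimator

from .datasets import DesignMatrix, GeneticModel, StudyDataset, build_design_matrix, encode_column
from .evidence import Priors, jeffreys_category, log_marginal_likelihood

__all__ = [
    "Model",
    "ModelSpacePrior",
    "ModelEvidence",
    "PosteriorSample",
    "model_log_prior",
    "enumerate_posterior",
    "emc_sample",
    "snp_bf",
    "gene_bf",
    "global_bf",
    "snp_report",
    "model_image",
    "EmcModelSearch",
]

_GM = (GeneticModel.LOG_ADDITIVE, GeneticModel.DOMINANT, GeneticModel.RECESSIVE)

#: A model is a canonical tuple of (snp index, parameterization index 0/1/2),
#: sorted by SNP index; the empty tuple is the null model.
Model = tuple[tuple[int, int], ...]


def _canonical(pairs) -> Model:
    pairs = tuple(sorted((int(s), int(g)) for s, g in pairs))
    snps = [s for s, _ in pairs]
    if len(set(snps)) != len(snps):
        raise ValueError("a SNP may appear at most once in a model")
    return pairs


@dataclass
class ModelSpacePrior:
    """Beta-binomial prior on model size with uniform parameterizations.

    P(model M with k SNPs) = B(a+k, b+S-k)/B(a, b) * (1/3)^k over the S
    SNPs entering the search. The marginal prior inclusion probability is
    a/(a+b) and the prior inclusion odds a/b — independent of S when
    b = S, which is the multiplicity correction.
    """

    S: int
    a: float = 1.0 / 8.0
    b: float | None = None

    def __post_init__(self) -> None:
        if self.b is None:
            self.b = float(self.S)
        if self.S < 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("require S >= 0 and positive a, b")

    @property
    def inclusion_probability(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def inclusion_odds(self) -> float:
        return self.a / self.b

    def log_prior_size(self, k: int) -> float:
        """Log prior of one *specific* SNP subset of size k (no choose term)."""
        if not 0 <= k <= self.S:
            raise ValueError("model size out of range")
        return float(betaln(self.a + k, self.b + self.S - k) - betaln(self.a, self.b))

    def log_prior(self, model: Model) -> float:
        k = len(model)
        return self.log_prior_size(k) + k * math.log(1.0 / 3.0)

    def log_prob_size(self, k: int) -> float:
        """Log prior that the model contains exactly k SNPs (any subset)."""
        logchoose = gammaln(self.S + 1) - gammaln(k + 1) - gammaln(self.S - k + 1)
        return float(logchoose + self.log_prior_size(k))

    def prob_null(self) -> float:
        return math.exp(self.log_prior_size(0))

    def prob_none_of(self, g: int) -> float:
        """Prior probability that none of a fixed set of g SNPs is included."""
        if not 0 <= g <= self.S:
            raise ValueError("set size out of range")
        total = 0.0
        for k in range(0, self.S - g + 1):
            logterm = (
                gammaln(self.S - g + 1)
                - gammaln(k + 1)
                - gammaln(self.S - g - k + 1)
                + self.log_prior_size(k)
            )
            total += math.exp(logterm)
        return min(total, 1.0)


def model_log_prior(model, prior: ModelSpacePrior) -> float:
    """Log prior probability of a model (SNP set + parameterizations)."""
    return prior.log_prior(_canonical(model))


class ModelEvidence:
    """Cached log-evidence evaluator for association models.

    Builds the encoded genetic columns for a model from a completed
    genotype matrix and scores it with the Laplace (or AIC) marginal
    likelihood; results are cached by canonical model key since samplers
    revisit models constantly.
    """

    def __init__(
        self,
        genotypes: np.ndarray,
        y: np.ndarray,
        design: np.ndarray,
        priors: Priors,
        method: str = "laplace",
    ):
        self.genotypes = np.asarray(genotypes, dtype=float)
        if np.isnan(self.genotypes).any():
            raise ValueError("model evidence requires completed genotypes")
        self.y = np.asarray(y, dtype=float)
        self.design = np.asarray(design, dtype=float)
        self.priors = priors
        self.method = method
        self._cache: dict[Model, float] = {}
        self._info: dict[Model, dict] = {}
        self.n_evaluations = 0

    def columns(self, model: Model) -> np.ndarray | None:
        if not model:
            return None
        cols = [encode_column(self.genotypes[:, s], _GM[g]) for s, g in model]
        return np.column_stack(cols)

    def __call__(self, model) -> float:
        key = _canonical(model)
        if key not in self._cache:
            log_ev, info = log_marginal_likelihood(
                self.design, self.columns(key), self.y, self.priors, self.method
            )
            self._cache[key] = log_ev
            self._info[key] = info
            self.n_evaluations += 1
        return self._cache[key]

    def info(self, model) -> dict:
        self(model)
        return self._info[_canonical(model)]


@dataclass
class PosteriorSample:
    """Posterior over association models, exact or sampled.

    ``probs`` are normalized over the evaluated model set: exact
    probabilities when enumerated, Rao-Blackwellized estimates (renormalized
    evidence x prior) when sampled. ``visit_counts`` holds raw cold-chain
    visit frequencies for samplers.
    """

    models: list[Model]
    log_post: np.ndarray
    probs: np.ndarray
    prior: ModelSpacePrior
    snp_ids: list[str]
    exact: bool
    visit_counts: dict[Model, int] | None = None
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None
    ladder: tuple[float, ...] | None = None

    def inclusion_mass(self, snp: int, method: str = "rao-blackwell") -> float:
        w = self._weights(method)
        return float(
            sum(wi for m, wi in zip(self.models, w) if any(s == snp for s, _ in m))
        )

    def _weights(self, method: str) -> np.ndarray:
        if method == "rao-blackwell" or self.exact:
            return self.probs
        if method == "frequency":
            if not self.visit_counts:
                raise ValueError("no visit counts available")
            total = sum(self.visit_counts.values())
            return np.array([self.visit_counts.get(m, 0) / total for m in self.models])
        raise ValueError(f"unknown weighting {method!r}")


def _posterior_from_scores(models, log_posts, prior, snp_ids, exact, **kw) -> PosteriorSample:
    log_posts = np.asarray(log_posts, dtype=float)
    probs = np.exp(log_posts - logsumexp(log_posts))
    probs /= probs.sum()
    return PosteriorSample(
        models=list(models), log_post=log_posts, probs=probs, prior=prior,
        snp_ids=list(snp_ids), exact=exact, **kw,
    )


def enumerate_posterior(
    evidence: ModelEvidence,
    prior: ModelSpacePrior,
    snp_ids=None,
    max_snps: int = 8,
) -> PosteriorSample:
    """Exact posterior by scoring every one of the 4^S models of a panel.

    Feasible for small panels only (S <= ``max_snps``); larger spaces need
    :func:`emc_sample`.
    """
    S = evidence.genotypes.shape[1]
    if S > max_snps:
        raise ValueError(
            f"enumeration over 4^{S} models is infeasible; use the EMC sampler"
        )
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(S)]
    models: list[Model] = []
    scores = []
    # states per SNP: 0 = absent, 1..3 = parameterization index + 1
    for code in np.ndindex(*(4,) * S):
        model = _canonical((s, st - 1) for s, st in enumerate(code) if st > 0)
        models.append(model)
        scores.append(evidence(model) + prior.log_prior(model))
    return _posterior_from_scores(models, scores, prior, snp_ids, exact=True)


def emc_sample(
    evidence,
    prior: ModelSpacePrior,
    n_iterations: int = 50_000,
    n_chains: int = 5,
    temp_low: float = 0.3,
    burn_in: float = 0.2,
    move_probs: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int | None = None,
    snp_ids=None,
) -> PosteriorSample:
    """Evolutionary Monte Carlo over the model space.

    A population of ``n_chains`` chains targets the posterior raised to
    temperatures geometrically spaced from 1.0 down to ``temp_low``. Each
    iteration proposes one move — mutation (toggle a SNP in/out with a
    random parameterization, or re-parameterize a present SNP), uniform
    crossover of two chains' SNP assignments, or a state exchange between
    adjacent temperatures — accepted by Metropolis-Hastings at the
    chains' temperatures. Cold-chain states after burn-in form the visit
    counts; Bayes factors are by default Rao-Blackwellized over every
    model evaluated anywhere in the population.

    ``evidence`` is any callable ``model -> log evidence`` (normally a
    :class:`ModelEvidence`); non-finite evidence rejects the move.
    """
    S = prior.S
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(S)]
    if n_chains < 1:
        raise ValueError("need at least one chain")
    rng = np.random.default_rng(seed)
    if n_chains == 1:
        ladder = (1.0,)
    else:
        ladder = tuple(np.geomspace(1.0, temp_low, n_chains))
    mp = np.asarray(move_probs, dtype=float)
    mp = mp / mp.sum()
    if n_chains == 1:
        mp = np.array([1.0, 0.0, 0.0])  # no partner chains: mutation only

    scored: dict[Model, float] = {}

    def log_post(model: Model) -> float:
        if model not in scored:
            ev = evidence(model)
            scored[model] = (ev + prior.log_prior(model)) if np.isfinite(ev) else -np.inf
        return scored[model]

    state: list[Model] = [() for _ in range(n_chains)]
    lp = [log_post(m) for m in state]
    burn = int(burn_in * n_iterations)
    visits: dict[Model, int] = {}
    acc = {"mutation": [0, 0], "crossover": [0, 0], "exchange": [0, 0]}
    n_nonfinite = 0

    for it in range(n_iterations):
        u = rng.random()
        if u < mp[0]:  # mutation on one chain
            c = rng.integers(n_chains)
            m = state[c]
            if rng.random() < 0.5:  # toggle
                s = int(rng.integers(S))
                present = dict(m)
                if s in present:
                    newm = _canonical((a, b) for a, b in m if a != s)
                    log_q = math.log(1.0 / 3.0)  # reverse re-adds with a random param
                else:
                    g = int(rng.integers(3))
                    newm = _canonical(list(m) + [(s, g)])
                    log_q = math.log(3.0)
            else:  # re-parameterize a present SNP
                if not m:
                    acc["mutation"][1] += 1
                    continue
                i = int(rng.integers(len(m)))
                s, g = m[i]
                g_new = int((g + 1 + rng.integers(2)) % 3)
                newm = _canonical([(a, b) if a != s else (s, g_new) for a, b in m])
                log_q = 0.0
            new_lp = log_post(newm)
            if not np.isfinite(new_lp):
                n_nonfinite += 1
            acc["mutation"][1] += 1
            if math.log(rng.random() + 1e-300) < ladder[c] * (new_lp - lp[c]) + log_q:
                state[c], lp[c] = newm, new_lp
                acc["mutation"][0] += 1
        elif u < mp[0] + mp[1]:  # crossover between two random chains
            i, j = rng.choice(n_chains, size=2, replace=False)
            mi, mj = dict(state[i]), dict(state[j])
            union = sorted(set(mi) | set(mj))
            if not union:
                acc["crossover"][1] += 1
                continue
            ci, cj = dict(mi), dict(mj)
            for s in union:
                if rng.random() < 0.5:  # swap this SNP's assignment
                    gi, gj = ci.pop(s, None), cj.pop(s, None)
                    if gj is not None:
                        ci[s] = gj
                    if gi is not None:
                        cj[s] = gi
            child_i = _canonical(ci.items())
            child_j = _canonical(cj.items())
            lpi, lpj = log_post(child_i), log_post(child_j)
            if not (np.isfinite(lpi) and np.isfinite(lpj)):
                n_nonfinite += 1
            acc["crossover"][1] += 1
            log_alpha = ladder[i] * (lpi - lp[i]) + ladder[j] * (lpj - lp[j])
            if math.log(rng.random() + 1e-300) < log_alpha:
                state[i], lp[i] = child_i, lpi
                state[j], lp[j] = child_j, lpj
                acc["crossover"][0] += 1
        else:  # exchange between adjacent temperatures
            c = int(rng.integers(n_chains - 1))
            log_alpha = (ladder[c] - ladder[c + 1]) * (lp[c + 1] - lp[c])
            acc["exchange"][1] += 1
            if math.log(rng.random() + 1e-300) < log_alpha:
                state[c], state[c + 1] = state[c + 1], state[c]
                lp[c], lp[c + 1] = lp[c + 1], lp[c]
                acc["exchange"][0] += 1
        if it >= burn:
            visits[state[0]] = visits.get(state[0], 0) + 1

    finite = [(m, s) for m, s in scored.items() if np.isfinite(s)]
    models = [m for m, _ in finite]
    scores = [s for _, s in finite]
    diag = {
        "acceptance": {
            k: (v[0] / v[1] if v[1] else math.nan) for k, v in acc.items()
        },
        "n_evaluated": len(scored),
        "n_nonfinite": n_nonfinite,
        "n_cold_samples": sum(visits.values()),
    }
    return _posterior_from_scores(
        models, scores, prior, snp_ids, exact=False,
        visit_counts=visits, diagnostics=diag, seed=seed, ladder=ladder,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def snp_bf(sample: PosteriorSample, snp: int, method: str = "rao-blackwell"):
    """Bayes factor for inclusion of one SNP.

    BF = [posterior odds of inclusion] / [prior odds a/b]. A SNP present
    in no evaluated model gets BF 0 with a lower-bound flag (the sampler
    never scored it, so 0 is only a bound).
    """
    p = sample.inclusion_mass(snp, method)
    prior_odds = sample.prior.inclusion_odds
    if p <= 0.0:
        return 0.0, True
    if p >= 1.0:
        return math.inf, False
    return (p / (1.0 - p)) / prior_odds, False


def gene_bf(sample: PosteriorSample, gene_map: dict[str, list[int]], method: str = "rao-blackwell") -> dict[str, float]:
    """Per-gene BF: posterior-to-prior odds that >= 1 SNP of the gene is
    included; the prior term comes from beta-binomial enumeration."""
    w = sample._weights(method)
    out = {}
    for gene, snps in gene_map.items():
        if not snps:
            continue
        snpset = set(int(s) for s in snps)
        post = float(
            sum(wi for m, wi in zip(sample.models, w) if any(s in snpset for s, _ in m))
        )
        p0 = sample.prior.prob_none_of(len(snpset))
        prior_odds = (1.0 - p0) / p0
        if post >= 1.0:
            out[gene] = math.inf
        else:
            out[gene] = (post / (1.0 - post)) / prior_odds
    return out


def global_bf(sample: PosteriorSample, method: str = "rao-blackwell") -> float:
    """Overall BF of any association: posterior-to-prior odds against the
    null model."""
    w = sample._weights(method)
    p_null = float(sum(wi for m, wi in zip(sample.models, w) if not m))
    prior_null = sample.prior.prob_null()
    prior_odds = (1.0 - prior_null) / prior_null
    if p_null <= 0.0:
        return math.inf
    return ((1.0 - p_null) / p_null) / prior_odds


def snp_report(
    sample: PosteriorSample,
    evidence: ModelEvidence | None = None,
    genes=None,
    method: str = "rao-blackwell",
) -> pd.DataFrame:
    """Per-SNP summary table: model-averaged BF, most likely genetic
    parameterization with its probability (conditional on inclusion),
    and the posterior-mode OR with 95% equal-tailed normal-approximation
    credible interval under that parameterization (NA when the single-SNP
    MLE does not exist)."""
    w = sample._weights(method)
    S = sample.prior.S
    rows = []
    for s in range(S):
        mass = np.zeros(3)
        for m, wi in zip(sample.models, w):
            for si, gi in m:
                if si == s:
                    mass[gi] += wi
        bf, lower_bound = snp_bf(sample, s, method)
        row = {
            "snp_id": sample.snp_ids[s],
            "bf": bf,
            "bf_lower_bound": lower_bound,
            "jeffreys": jeffreys_category(bf) if bf > 0 else "never included",
        }
        if genes is not None:
            row["gene"] = genes[s]
        incl = mass.sum()
        if incl > 0:
            cond = mass / incl
            gi = int(np.argmax(cond))
            row["most_likely_model"] = _GM[gi].value
            row["model_probability"] = float(cond[gi])
            if evidence is not None:
                one = log_marginal_likelihood(
                    evidence.design,
                    evidence.columns(((s, gi),)),
                    evidence.y,
                    evidence.priors,
                    evidence.method,
                    check_estimability=True,
                )[1]
                b, se = one["beta"][-1], one["se"][-1]
                if one["estimable"]:
                    row["median_or"] = math.exp(b)
                    row["ci_low"] = math.exp(b - 1.959963984540054 * se)
                    row["ci_high"] = math.exp(b + 1.959963984540054 * se)
                else:
                    row["median_or"] = math.nan
                    row["ci_low"] = math.nan
                    row["ci_high"] = math.nan
        else:
            row["most_likely_model"] = None
            row["model_probability"] = math.nan
            row["median_or"] = math.nan
            row["ci_low"] = math.nan
            row["ci_high"] = math.nan
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("bf", ascending=False).reset_index(drop=True)
    return df


def model_image(sample: PosteriorSample, top_k: int = 100) -> pd.DataFrame:
    """Long-format description of the top-model inclusion image.

    Columns: model rank (by posterior probability, descending), the
    model's probability (column width is proportional to it), SNP id and
    parameterization code (A/D/R) for every SNP in the model; rows of the
    rendered image are SNPs ordered by BF. The null model, having no
    SNPs, contributes a rank with an empty SNP field.
    """
    order = np.argsort(-sample.probs)[: min(top_k, len(sample.models))]
    bf_order = {
        sid: rank
        for rank, sid in enumerate(
            snp_report(sample, evidence=None)["snp_id"].tolist()
        )
    }
    rows = []
    for rank, mi in enumerate(order, start=1):
        m = sample.models[mi]
        prob = float(sample.probs[mi])
        if not m:
            rows.append(
                {"model_rank": rank, "probability": prob, "snp_id": "", "parameterization": "", "snp_row": -1}
            )
        for s, g in m:
            sid = sample.snp_ids[s]
            rows.append(
                {
                    "model_rank": rank,
                    "probability": prob,
                    "snp_id": sid,
                    "parameterization": _GM[g].code,
                    "snp_row": bf_order.get(sid, -1),
                }
            )
    return pd.DataFrame(rows)


class EmcModelSearch(BaseEstimator):
    """Model-averaged SNP association search (sklearn-style estimator).

    Fits the EMC sampler (or exact enumeration for panels of up to
    ``enumerate_below`` SNPs) to a completed genotype matrix and exposes
    the posterior summaries as fitted attributes.

    Attributes
    ----------
    sample_ : PosteriorSample
    snp_bf_ : ndarray of per-SNP Bayes factors
    report_ : per-SNP summary DataFrame (Table-1-style)
    gene_bf_ : dict of per-gene BFs (when gene labels are given)
    global_bf_ : overall BF against the null model
    """

    def __init__(
        self,
        priors: Priors | None = None,
        a: float = 1.0 / 8.0,
        b: float | None = None,
        n_iterations: int = 50_000,
        n_chains: int = 5,
        temp_low: float = 0.3,
        burn_in: float = 0.2,
        move_probs: tuple[float, float, float] = (0.70, 0.15, 0.15),
        seed: int | None = None,
        method: str = "laplace",
        enumerate_below: int = 0,
    ):
        self.priors = priors
        self.a = a
        self.b = b
        self.n_iterations = n_iterations
        self.n_chains = n_chains
        self.temp_low = temp_low
        self.burn_in = burn_in
        self.move_probs = move_probs
        self.seed = seed
        self.method = method
        self.enumerate_below = enumerate_below

    def fit(self, X, y, design=None, snp_ids=None, genes=None):
        X = np.asarray(X, dtype=float)
        n, S = X.shape
        if design is None:
            design = np.ones((n, 1))
        elif isinstance(design, DesignMatrix):
            design = design.matrix
        priors = self.priors if self.priors is not None else Priors()
        if snp_ids is None:
            snp_ids = [f"snp{j}" for j in range(S)]
        prior = ModelSpacePrior(S=S, a=self.a, b=self.b)
        ev = ModelEvidence(X, y, design, priors, self.method)
        if S <= self.enumerate_below:
            sample = enumerate_posterior(ev, prior, snp_ids=snp_ids)
        else:
            sample = emc_sample(
                ev,
                prior,
                n_iterations=self.n_iterations,
                n_chains=self.n_chains,
                temp_low=self.temp_low,
                burn_in=self.burn_in,
                move_probs=self.move_probs,
                seed=self.seed,
                snp_ids=snp_ids,
            )
        self.evidence_ = ev
        self.sample_ = sample
        self.snp_bf_ = np.array([snp_bf(sample, s)[0] for s in range(S)])
        self.report_ = snp_report(sample, evidence=ev, genes=genes)
        if genes is not None:
            gmap: dict[str, list[int]] = {}
            for j, g in enumerate(genes):
                gmap.setdefault(str(g), []).append(j)
            self.gene_bf_ = gene_bf(sample, gmap)
        else:
            self.gene_bf_ = None
        self.global_bf_ = global_bf(sample)
        return self


def run_search(
    dataset: StudyDataset,
    priors: Priors | None = None,
    a: float = 1.0 / 8.0,
    b: float | None = None,
    seed: int | None = None,
    **sampler_kw,
) -> EmcModelSearch:
    """Run the model-search stage on a completed study dataset."""
    design = build_design_matrix(dataset)
    est = EmcModelSearch(priors=priors, a=a, b=b, seed=seed, **sampler_kw)
    est.fit(
        dataset.genotypes,
        dataset.case_status,
        design=design,
        snp_ids=list(dataset.snp_ids),
        genes=dataset.snp_info["gene"].tolist(),
    )
    return est
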