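import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import logsumexp

from misa.datasets import GeneticModel, build_design_matrix, encode_column
from misa.evidence import (
    MarginalBayesScreen,
    Priors,
    bf_to_evidence,
    fit_logistic_map,
    jeffreys_category,
    log_marginal_likelihood,
    marginal_snp_bf,
)
from misa.simulate import SimulationConfig, simulate_study
from .conftest import make_dataset


class TestEvidenceCalculus:
    def test_bf_ten_multiplies_prior_odds_by_ten(self):
        ev = bf_to_evidence(10.0, 0.3)
        assert ev.posterior_odds / ev.prior_odds == pytest.approx(10.0, rel=1e-12)

    def test_bf_one_leaves_probability_unchanged(self):
        ev = bf_to_evidence(1.0, 0.2)
        assert ev.posterior_odds == pytest.approx(ev.prior_odds)
        assert ev.ppa == pytest.approx(0.2)

    def test_printed_prior_odds_example(self):
        # prior odds 0.0016 with BF 10 -> PO 0.016, PPA ~ 0.0157
        pi = 0.0016 / 1.0016
        ev = bf_to_evidence(10.0, pi)
        assert ev.posterior_odds == pytest.approx(0.016, rel=1e-10)
        assert ev.ppa == pytest.approx(0.016 / 1.016, rel=1e-10)

    @given(
        st.floats(0.01, 100.0), st.floats(1e-6, 0.9)
    )
    @settings(derandomize=True, max_examples=200)
    def test_odds_identity_to_twelve_digits(self, bf, pi):
        ev = bf_to_evidence(bf, pi)
        lhs = ev.ppa / (1.0 - ev.ppa)
        rhs = bf * pi / (1.0 - pi)
        assert lhs == pytest.approx(rhs, rel=1e-12)
        assert ev.posterior_odds == pytest.approx(rhs, rel=1e-14)


class TestJeffreysScale:
    @pytest.mark.parametrize(
        "bf, label",
        [
            (28.940, "strongly supportive"),
            (9.086, "supportive"),
            (1.5, "weakly supportive"),
            (10.0, "strongly supportive"),  # lower bound inclusive
            (3.2, "supportive"),
            (30.0, "very strong"),
            (100.0, "decisive"),
            (250.0, "decisive"),
        ],
    )
    def test_bands(self, bf, label):
        assert jeffreys_category(bf) == label

    def test_reciprocal_rule_for_null_support(self):
        assert jeffreys_category(0.1) == "strongly supportive of no association"

    def test_invalid_bf(self):
        with pytest.raises(ValueError):
            jeffreys_category(0.0)


class TestLogisticFit:
    def test_mle_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(2, 0.3, n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.5 * X[:, 1])))).astype(float)
        fit = fit_logistic_map(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)


class TestLaplaceEvidence:
    def test_matches_importance_sampling_oracle(self):
        """Laplace log evidence within 0.1 of a large importance-sampling
        estimate on a 2-coefficient toy model."""
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + 0.8 * x)))).astype(float)
        X = np.column_stack([np.ones(n), x])
        pr = Priors()
        lap, _ = log_marginal_likelihood(X[:, :1], X[:, 1:], y, pr)
        lam = np.array([1 / pr.design_sd**2, 1 / pr.effect_sd**2])
        fit = fit_logistic_map(X, y, lam)
        cov = np.linalg.inv(fit.hessian)
        M = 200_000
        prop = stats.multivariate_t(loc=fit.beta, shape=cov * 1.5, df=7)
        samp = prop.rvs(M, random_state=2)
        eta = samp @ X.T
        ll = (y * eta - np.logaddexp(0, eta)).sum(axis=1)
        lp = stats.norm.logpdf(samp[:, 0], 0, pr.design_sd) + stats.norm.logpdf(
            samp[:, 1], 0, pr.effect_sd
        )
        oracle = logsumexp(ll + lp - prop.logpdf(samp)) - math.log(M)
        assert abs(lap - oracle) < 0.1

    def test_null_beats_alternatives_under_null(self):
        """On data simulated without genetic effects at study scale, the
        null model's evidence is finite and exceeds a given single-SNP
        model's in >= 90% of pairwise comparisons."""
        wins = 0.0
        R = 100
        n = 1125
        pr = Priors()
        for r in range(R):
            rng = np.random.default_rng(3000 + r)
            g = rng.binomial(2, 0.3, size=n).astype(float)
            y = rng.integers(0, 2, size=n).astype(float)
            X = np.ones((n, 1))
            null, _ = log_marginal_likelihood(X, None, y, pr)
            assert math.isfinite(null)
            alts = [
                log_marginal_likelihood(X, encode_column(g, m)[:, None], y, pr)[0]
                for m in GeneticModel
            ]
            wins += np.mean([null > a for a in alts])
        assert wins / R >= 0.90

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            log_marginal_likelihood(X, None, np.zeros(20), Priors())

    def test_separated_model_finite_evidence_with_flag(self):
        """Recessive encoding with rare homozygotes only among controls:
        the MLE does not exist but the prior-regularized evidence is
        finite and the estimability flag is set."""
        n = 200
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(70), np.zeros(130)]
        rec = np.zeros(n)
        rec[150:160] = 1.0  # rare homozygotes, all controls
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        log_ev, info = log_marginal_likelihood(
            X, rec[:, None], y, Priors(), check_estimability=True
        )
        assert math.isfinite(log_ev)
        assert not info["estimable"]

    def test_bf_invariant_to_age_rescaling(self):
        ds = make_dataset(n=200, s=1, seed=11, maf=0.25)
        pr = Priors()
        dm1 = build_design_matrix(ds)
        res1 = marginal_snp_bf(ds.genotypes[:, 0], dm1.matrix, ds.case_status, pr)
        ds2 = ds.copy()
        ds2.covariates["age"] = ds2.covariates["age"] * 365.25  # days
        dm2 = build_design_matrix(ds2)
        res2 = marginal_snp_bf(ds2.genotypes[:, 0], dm2.matrix, ds2.case_status, pr)
        for m in GeneticModel:
            assert res2["bf"][m] == pytest.approx(res1["bf"][m], rel=1e-6)

    def test_aic_evidence_is_minus_half_aic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 250
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.4 * x))).astype(float)
        X = np.column_stack([np.ones(n), x])
        log_ev, _ = log_marginal_likelihood(X[:, :1], X[:, 1:], y, Priors(), method="aic")
        ref = sm.Logit(y, X).fit(disp=0)
        assert log_ev == pytest.approx(-ref.aic / 2, abs=1e-5)


class TestMarginalScreen:
    def test_determinism(self, small_study, small_design, priors):
        ds, _ = small_study
        a = marginal_snp_bf(ds.genotypes[:, 1], small_design.matrix, ds.case_status, priors)
        b = marginal_snp_bf(ds.genotypes[:, 1], small_design.matrix, ds.case_status, priors)
        assert a["bf"] == b["bf"]

    def test_monomorphic_recessive_encoding_skipped(self, priors):
        n = 150
        rng = np.random.default_rng(8)
        col = rng.binomial(1, 0.2, size=n).astype(float)  # no rare homozygotes
        y = rng.integers(0, 2, size=n)
        res = marginal_snp_bf(col, np.ones((n, 1)), y, priors)
        assert GeneticModel.RECESSIVE in res["skipped"]
        assert math.isnan(res["bf"][GeneticModel.RECESSIVE])
        assert not res["excluded"]

    def test_fully_monomorphic_snp_excluded(self, priors):
        n = 100
        res = marginal_snp_bf(np.zeros(n), np.ones((n, 1)), np.r_[np.ones(40), np.zeros(60)], priors)
        assert res["excluded"]

    def test_pass_requires_strictly_greater_than_threshold(self):
        est = MarginalBayesScreen.__new__(MarginalBayesScreen)
        # rule check at the boundary via a fitted frame
        import pandas as pd

        est.threshold = 1.0
        frame = pd.DataFrame({"max_bf": [1.0, 1.0001, 0.5]})
        passes = frame["max_bf"] > est.threshold
        assert passes.tolist() == [False, True, False]

    def test_no_missing_data_m1_equals_m100(self, small_study, small_design, priors):
        ds, _ = small_study
        y = ds.case_status
        est1 = MarginalBayesScreen(priors=priors).fit(
            [ds.genotypes], y, design=small_design
        )
        est100 = MarginalBayesScreen(priors=priors).fit(
            [ds.genotypes] * 5, y, design=small_design
        )
        np.testing.assert_allclose(est1.bf_, est100.bf_, rtol=1e-12)

    def test_causal_snp_screen_power(self):
        """A per-allele OR of 1.65 at study scale is detected (max BF > 10)
        in at least half of replicates."""
        hits = 0
        R = 20
        for r in range(R):
            cfg = SimulationConfig(
                n_snps=2, n_cases=364, n_controls=761, block_size=2,
                causal=[(0, GeneticModel.LOG_ADDITIVE, 1.65)],
                missing_rate=0.0, seed=40_000 + r,
            )
            ds, _ = simulate_study(cfg)
            dm = build_design_matrix(ds)
            res = marginal_snp_bf(ds.genotypes[:, 0], dm.matrix, ds.case_status, Priors())
            hits += res["max_bf"] > 10
        assert hits >= R // 2

    def test_null_snp_bf_near_one(self):
        """Median max-BF of a null SNP over replicates lies in [0.3, 3]."""
        bfs = []
        for r in range(60):
            rng = np.random.default_rng(50_000 + r)
            n = 400
            g = rng.binomial(2, 0.3, size=n).astype(float)
            y = np.r_[np.ones(130), np.zeros(270)]
            res = marginal_snp_bf(g, np.ones((n, 1)), y, Priors())
            bfs.append(res["max_bf"])
        assert 0.3 <= np.median(bfs) <= 3.0
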