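import itertools
import math

import numpy as np
import pytest

from misa.datasets import GeneticModel, build_design_matrix
from misa.evidence import Priors
from misa.search import (
    EmcModelSearch,
    ModelEvidence,
    ModelSpacePrior,
    emc_sample,
    enumerate_posterior,
    gene_bf,
    global_bf,
    model_image,
    model_log_prior,
    snp_bf,
    snp_report,
)
from misa.simulate import SimulationConfig, simulate_study


class TestModelSpacePrior:
    def test_marginal_prior_odds_at_study_scale(self):
        prior = ModelSpacePrior(S=77, a=1 / 8, b=77)
        assert prior.inclusion_odds == pytest.approx(0.0016, abs=5e-5)
        assert prior.inclusion_odds == pytest.approx(1 / (8 * 77), rel=1e-14)

    def test_prior_sums_to_one_over_all_models(self):
        """Enumeration over all 4^3 = 64 models of a 3-SNP panel."""
        prior = ModelSpacePrior(S=3, a=1 / 8, b=3)
        total = 0.0
        for code in itertools.product(range(4), repeat=3):
            model = tuple((s, st - 1) for s, st in enumerate(code) if st > 0)
            total += math.exp(model_log_prior(model, prior))
        assert total == pytest.approx(1.0, rel=1e-12)

    def test_size_ratio_depends_only_on_size(self):
        """Exchangeability: the prior odds of any size-(k+1) over size-k
        model is a function of k alone."""
        prior = ModelSpacePrior(S=6, a=1 / 8, b=6)
        for k in range(3):
            base = tuple((j, 0) for j in range(k))
            ratios = set()
            for extra in range(k, 6):
                for g in range(3):
                    bigger = base + ((extra, g),)
                    ratios.add(
                        round(model_log_prior(bigger, prior) - model_log_prior(base, prior), 12)
                    )
            assert len(ratios) == 1

    def test_inclusion_probability_matches_enumeration(self):
        prior = ModelSpacePrior(S=4, a=1 / 8, b=4)
        mass = 0.0
        for code in itertools.product(range(4), repeat=4):
            model = tuple((s, st - 1) for s, st in enumerate(code) if st > 0)
            if any(s == 0 for s, _ in model):
                mass += math.exp(model_log_prior(model, prior))
        assert mass == pytest.approx(prior.inclusion_probability, rel=1e-10)


@pytest.fixture(scope="module")
def small_panel():
    cfg = SimulationConfig(
        n_snps=4, n_cases=120, n_controls=200, block_size=2,
        causal=[(0, GeneticModel.LOG_ADDITIVE, 2.0)],
        missing_rate=0.0, seed=21,
    )
    ds, _ = simulate_study(cfg)
    dm = build_design_matrix(ds)
    ev = ModelEvidence(ds.genotypes, ds.case_status, dm.matrix, Priors())
    prior = ModelSpacePrior(S=4, a=1 / 8, b=4)
    return ds, ev, prior


class TestEnumeration:
    def test_probabilities_normalized(self, small_panel):
        _, ev, prior = small_panel
        sample = enumerate_posterior(ev, prior)
        assert len(sample.models) == 4**4
        assert sample.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_snp_panel_is_null_certain(self):
        ev = ModelEvidence(
            np.empty((30, 0)), np.r_[np.ones(10), np.zeros(20)], np.ones((30, 1)), Priors()
        )
        sample = enumerate_posterior(ev, ModelSpacePrior(S=0, a=1 / 8, b=1))
        assert sample.models == [()]
        assert sample.probs[0] == pytest.approx(1.0)

    def test_too_many_snps_refused(self):
        ev = ModelEvidence(
            np.zeros((10, 9)), np.r_[np.ones(5), np.zeros(5)], np.ones((10, 1)), Priors()
        )
        with pytest.raises(ValueError, match="EMC"):
            enumerate_posterior(ev, ModelSpacePrior(S=9, a=1 / 8, b=9))

    def test_true_parameterization_gains_mass_with_n(self):
        """Posterior mass on the simulated dominant parameterization of a
        single SNP grows with sample size."""
        masses = {}
        for n_cases, n_controls in ((60, 100), (400, 700)):
            cfg = SimulationConfig(
                n_snps=1, n_cases=n_cases, n_controls=n_controls, block_size=1,
                causal=[(0, GeneticModel.DOMINANT, 2.4)], missing_rate=0.0, seed=33,
            )
            ds, _ = simulate_study(cfg)
            dm = build_design_matrix(ds)
            ev = ModelEvidence(ds.genotypes, ds.case_status, dm.matrix, Priors())
            sample = enumerate_posterior(ev, ModelSpacePrior(S=1, a=1 / 8, b=1))
            dom = tuple([(0, 1)])
            masses[n_cases] = {m: p for m, p in zip(sample.models, sample.probs)}[dom]
        assert masses[400] > masses[60]


class TestEmcSampler:
    def test_matches_enumeration(self, small_panel):
        _, ev, prior = small_panel
        exact = enumerate_posterior(ev, prior)
        samp = emc_sample(ev, prior, n_iterations=20_000, seed=5)
        exact_map = dict(zip(exact.models, exact.probs))
        tv = 0.5 * sum(
            abs(exact_map.get(m, 0.0) - p) for m, p in zip(samp.models, samp.probs)
        )
        tv += 0.5 * sum(p for m, p in exact_map.items() if m not in set(samp.models))
        assert tv < 0.05
        for s in range(prior.S):
            be, _ = snp_bf(exact, s)
            bs, _ = snp_bf(samp, s)
            assert bs == pytest.approx(be, rel=0.10)

    def test_single_chain_is_plain_metropolis(self, small_panel):
        _, ev, prior = small_panel
        samp = emc_sample(ev, prior, n_iterations=3000, n_chains=1, seed=3)
        assert samp.ladder == (1.0,)
        assert samp.diagnostics["acceptance"]["exchange"] != samp.diagnostics["acceptance"]["exchange"]  # NaN: never fired
        assert samp.diagnostics["n_cold_samples"] > 0

    def test_seed_reproducibility(self, small_panel):
        _, ev, prior = small_panel
        a = emc_sample(ev, prior, n_iterations=4000, seed=11)
        b = emc_sample(ev, prior, n_iterations=4000, seed=11)
        assert a.models == b.models
        assert a.visit_counts == b.visit_counts
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_two_seeds_agree_on_bfs(self, small_panel):
        _, ev, prior = small_panel
        a = emc_sample(ev, prior, n_iterations=20_000, seed=1)
        b = emc_sample(ev, prior, n_iterations=20_000, seed=2)
        for s in range(prior.S):
            ba, _ = snp_bf(a, s)
            bb, _ = snp_bf(b, s)
            assert bb == pytest.approx(ba, rel=0.10)

    def test_constant_evidence_reproduces_prior(self):
        """Detailed-balance sanity: with flat evidence the cold chain's
        visit frequencies match the model-space prior."""
        prior = ModelSpacePrior(S=3, a=1.0, b=2.0)  # heavier prior: visitable space
        samp = emc_sample(lambda m: 0.0, prior, n_iterations=120_000, seed=9)
        freq = {m: c for m, c in samp.visit_counts.items()}
        total = sum(freq.values())
        tv = 0.0
        for code in itertools.product(range(4), repeat=3):
            model = tuple((s, st - 1) for s, st in enumerate(code) if st > 0)
            tv += 0.5 * abs(freq.get(model, 0) / total - math.exp(prior.log_prior(model)))
        assert tv < 0.05

    def test_prior_equals_posterior_gives_unit_bf(self):
        """No data update (constant evidence) leaves every SNP BF at 1."""
        prior = ModelSpacePrior(S=3, a=1 / 8, b=3)
        ev = lambda m: -1.234
        sample = emc_sample(ev, prior, n_iterations=1, seed=0)
        # exact check via enumeration of the same flat evidence
        models, scores = [], []
        for code in itertools.product(range(4), repeat=3):
            m = tuple((s, st - 1) for s, st in enumerate(code) if st > 0)
            models.append(m)
            scores.append(ev(m) + prior.log_prior(m))
        from misa.search import _posterior_from_scores

        exact = _posterior_from_scores(models, scores, prior, ["a", "b", "c"], exact=True)
        for s in range(3):
            bf, flag = snp_bf(exact, s)
            assert bf == pytest.approx(1.0, rel=1e-9)
            assert not flag


class TestSummaries:
    def test_causal_snp_ranks_first(self):
        """One causal SNP (OR 1.65) among nulls attains the panel's top BF
        in most replicates."""
        top = 0
        R = 12
        for r in range(R):
            cfg = SimulationConfig(
                n_snps=6, n_cases=364, n_controls=761, block_size=2,
                causal=[(0, GeneticModel.LOG_ADDITIVE, 1.65)],
                missing_rate=0.0, seed=60_000 + r,
            )
            ds, _ = simulate_study(cfg)
            dm = build_design_matrix(ds)
            ev = ModelEvidence(ds.genotypes, ds.case_status, dm.matrix, Priors())
            sample = enumerate_posterior(ev, ModelSpacePrior(S=6, a=1 / 8, b=6))
            bfs = [snp_bf(sample, s)[0] for s in range(6)]
            top += int(np.argmax(bfs)) == 0
        assert top >= 0.8 * R

    def test_single_snp_gene_bf_equals_snp_bf(self, small_panel):
        _, ev, prior = small_panel
        sample = enumerate_posterior(ev, prior)
        gbf = gene_bf(sample, {"g0": [0]})["g0"]
        sbf, _ = snp_bf(sample, 0)
        assert gbf == pytest.approx(sbf, rel=1e-10)

    def test_gene_bf_with_perfect_ld_pair_dominates_snp_bfs(self):
        """Two SNPs in perfect LD split inclusion mass; their gene's BF is
        at least each individual SNP BF."""
        rng = np.random.default_rng(2)
        n = 500
        h = (rng.random((2 * n, 1)) < 0.3).astype(float)
        g = (h[:n] + h[n:]).ravel()
        eta = -0.8 + 0.6 * g
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        X = np.column_stack([g, g.copy()])
        ev = ModelEvidence(X, y, np.ones((n, 1)), Priors())
        sample = enumerate_posterior(ev, ModelSpacePrior(S=2, a=1 / 8, b=2))
        gbf = gene_bf(sample, {"g": [0, 1]})["g"]
        for s in (0, 1):
            sbf, _ = snp_bf(sample, s)
            assert gbf >= sbf - 1e-9

    def test_global_bf_below_one_under_null(self):
        """All-null simulations favor the null model globally."""
        under = 0
        R = 10
        for r in range(R):
            cfg = SimulationConfig(
                n_snps=4, n_cases=200, n_controls=400, block_size=2,
                causal=[], missing_rate=0.0, seed=70_000 + r,
            )
            ds, _ = simulate_study(cfg)
            dm = build_design_matrix(ds)
            ev = ModelEvidence(ds.genotypes, ds.case_status, dm.matrix, Priors())
            sample = enumerate_posterior(ev, ModelSpacePrior(S=4, a=1 / 8, b=4))
            under += global_bf(sample) < 1.0
        assert under > R / 2

    def test_dominant_snp_recovered(self):
        """A strong dominant effect is identified as dominant with
        conditional probability > 0.5 in most replicates."""
        hits = 0
        R = 10
        for r in range(R):
            cfg = SimulationConfig(
                n_snps=3, n_cases=364, n_controls=761, block_size=3,
                causal=[(1, GeneticModel.DOMINANT, 2.2)],
                missing_rate=0.0, seed=80_000 + r,
            )
            ds, _ = simulate_study(cfg)
            dm = build_design_matrix(ds)
            ev = ModelEvidence(ds.genotypes, ds.case_status, dm.matrix, Priors())
            sample = enumerate_posterior(ev, ModelSpacePrior(S=3, a=1 / 8, b=3))
            rep = snp_report(sample, evidence=ev)
            row = rep[rep["snp_id"] == "snp1"].iloc[0]
            hits += row["most_likely_model"] == "dominant" and row["model_probability"] > 0.5
        assert hits >= 0.8 * R

    def test_separated_recessive_reports_na_with_finite_bf(self):
        """No case rare-homozygotes under a recessive encoding: the OR/CI
        are NA but the BF stays finite."""
        rng = np.random.default_rng(14)
        n = 300
        y = np.r_[np.ones(100), np.zeros(200)].astype(int)
        g = rng.binomial(1, 0.25, size=n).astype(float)
        g[260:275] = 2.0  # rare homozygotes only among controls
        ev = ModelEvidence(g[:, None], y, np.ones((n, 1)), Priors())
        sample = enumerate_posterior(ev, ModelSpacePrior(S=1, a=1.0, b=1.0))
        rep = snp_report(sample, evidence=ev)
        row = rep.iloc[0]
        assert math.isfinite(row["bf"]) and row["bf"] > 0
        if row["most_likely_model"] == "recessive":
            assert math.isnan(row["median_or"])

    def test_null_coefficient_interval_covers_one(self):
        cfg = SimulationConfig(
            n_snps=1, n_cases=800, n_controls=1600, block_size=1,
            causal=[], missing_rate=0.0, seed=91,
        )
        ds, _ = simulate_study(cfg)
        dm = build_design_matrix(ds)
        ev = ModelEvidence(ds.genotypes, ds.case_status, dm.matrix, Priors())
        sample = enumerate_posterior(ev, ModelSpacePrior(S=1, a=1 / 8, b=1))
        rep = snp_report(sample, evidence=ev)
        row = rep.iloc[0]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]


class TestModelImage:
    def test_concentrated_posterior_single_column(self):
        prior = ModelSpacePrior(S=2, a=1 / 8, b=2)
        from misa.search import _posterior_from_scores

        models = [(), ((0, 0),)]
        scores = [-50.0, 0.0]  # all mass on the single-SNP model
        sample = _posterior_from_scores(models, scores, prior, ["rsA", "rsB"], exact=True)
        img = model_image(sample, top_k=1)
        assert len(img) == 1
        assert img.iloc[0]["snp_id"] == "rsA"
        assert img.iloc[0]["probability"] == pytest.approx(1.0)

    def test_top_k_clamped_to_visited(self, small_panel):
        _, ev, prior = small_panel
        sample = enumerate_posterior(ev, prior)
        img = model_image(sample, top_k=10**6)
        assert img["model_rank"].max() == len(sample.models)

    def test_enumerated_ordering_matches_hand_computation(self, small_panel):
        _, ev, prior = small_panel
        sample = enumerate_posterior(ev, prior)
        img = model_image(sample, top_k=3)
        order = np.argsort(-sample.probs)[:3]
        expected_probs = [float(sample.probs[i]) for i in order]
        got = img.drop_duplicates("model_rank")["probability"].tolist()
        assert got == pytest.approx(expected_probs)


class TestEstimator:
    def test_fit_exposes_summaries(self, small_panel):
        ds, _, _ = small_panel
        dm = build_design_matrix(ds)
        est = EmcModelSearch(n_iterations=4000, seed=2, enumerate_below=4)
        est.fit(
            ds.genotypes, ds.case_status, design=dm,
            snp_ids=list(ds.snp_ids), genes=ds.snp_info["gene"].tolist(),
        )
        assert est.sample_.exact
        assert est.snp_bf_.shape == (4,)
        assert set(est.report_.columns) >= {"snp_id", "bf", "most_likely_model"}
        assert est.gene_bf_ is not None
        assert math.isfinite(est.global_bf_)

    def test_get_params_round_trip(self):
        est = EmcModelSearch(n_iterations=123, seed=7)
        params = est.get_params()
        est2 = EmcModelSearch(**params)
        assert est2.n_iterations == 123 and est2.seed == 7
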