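# misa

Two-stage Bayesian model-averaged SNP association analysis for
case-control studies, with the genotype QC, missing-data imputation and
synthetic-data machinery needed to run and validate it end to end.

The package is aimed at candidate-gene association studies of a few
hundred SNPs typed on roughly a thousand subjects — the setting where
single-SNP p-value scans are noisy, multiplicity corrections are blunt,
and the genetic parameterization (log-additive, dominant, recessive) of
each variant is itself uncertain.

## The model

Let `D_i ∈ {0,1}` indicate whether subject `i` is a case and `Z_i` the
design covariates included in every model (age, genotyping batch, the
DNA quality score GC50PCT, and batch × GC50PCT interactions). The null
model of no genetic association is

```
logit P(D_i = 1) = α0 + Z_i' β0 .
```

A model of association `M` adds main effects for any subset of SNPs,
each coded under one of three genetic parameterizations of its
minor-allele count `g ∈ {0,1,2}`: log-additive (`g`), dominant
(`1[g ≥ 1]`) or recessive (`1[g = 2]`). Evidence for `M` against the
null is measured by the Bayes factor

```
BF(M : M0) = p(D | M) / p(D | M0) ,
```

with marginal likelihoods integrating a N(0, 0.5²) prior on each
genetic log-odds-ratio (small-to-modest effects) and a diffuse shared
prior on the design coefficients, via a Laplace approximation at the
posterior mode. Bayes factors convert to posterior odds and posterior
probabilities of association by `PO = BF × π/(1−π)` and
`PPA = PO/(1+PO)`.

The analysis is two-staged:

1. **Marginal screen** — every SNP is scored one at a time under all
   three parameterizations; SNPs with maximum marginal BF > 1 pass.
   With multiply-imputed genotypes the per-SNP BF is the arithmetic
   mean of per-imputation BFs.
2. **Model search** — over the `S` screen survivors, the number of
   included SNPs gets a beta-binomial prior with `a = 1/8`, `b = S`,
   which fixes the marginal prior odds of inclusion at `a/b`
   independent of `S` — an automatic multiplicity correction — and the
   three parameterizations are equally likely given inclusion. An
   evolutionary Monte Carlo sampler (tempered chains with mutation,
   crossover and exchange moves) explores the 4^S model space; exact
   enumeration is available for small panels and is used as the
   sampler's test oracle. Per-SNP, per-gene and global BFs are
   posterior-to-prior inclusion odds ratios, Rao-Blackwellized over the
   evaluated models.

Upstream QC mirrors standard array-panel practice: per-batch call-rate
masking (99%), reference-trio concordance (95% / any-discordance),
Hardy-Weinberg goodness-of-fit among controls using the chi-square
statistic with continuity correction 0.25, a binomial tail diagnostic
on the HWE p-value distribution, a scan over GC50PCT sample-quality
thresholds that repairs HWE by excluding low-quality samples, and
removal of perfectly redundant (r² = 1) SNPs. Missing genotypes are
multiply imputed (default m = 100) from local-LD haplotype models
fitted by EM, and a per-SNP missingness-indicator BF checks the
ignorable-missingness assumption for SNPs with ≥ 5 missing values.

## Worked example

```python
from misa import SimulationConfig, simulate_study, screen, GeneticModel
from misa.search import run_search

cfg = SimulationConfig(
    n_snps=30, n_cases=364, n_controls=761, block_size=3,
    causal=[(3, GeneticModel.LOG_ADDITIVE, 1.65),
            (20, GeneticModel.RECESSIVE, 0.53)],
    missing_rate=0.0, seed=2026,
)
dataset, truth = simulate_study(cfg)

table = screen(dataset)                       # stage 1
survivors = dataset.select_snps(table["pass"].to_numpy(bool))
est = run_search(survivors, seed=2026, n_iterations=20_000)  # stage 2
print(est.report_.head(4))
```

Output (13 of 30 SNPs pass the screen):

```
 snp_id    gene            bf most_likely_model  model_probability  median_or  jeffreys
snp0003 gene000 969525.779221      log_additive              0.739      1.802  decisive
snp0020 gene003     38.707639         recessive              0.960      0.557  very strong
snp0026 gene004     18.821029      log_additive              0.506      0.738  strongly supportive
snp0023 gene003     12.769987          dominant              0.734      1.346  strongly supportive
```

Both simulated causal SNPs rank first, each recovered under its true
parameterization: snp0003 (true per-allele OR 1.65) is decisive with a
log-additive posterior-mode OR of 1.80 (95% CI 1.47–2.21), and snp0020
(true rare-homozygote OR 0.53) is very strong with a recessive OR of
0.56 (0.35–0.87). The `bf` column is the model-averaged Bayes factor —
posterior over prior odds of inclusion — and `model_probability` is the
probability of the named parameterization conditional on inclusion. The
remaining rows are null SNPs whose chance associations survive at this
panel size; at the shipped study scale the beta-binomial prior holds
the fraction of null SNPs with BF > 10 below 1%.

A command-line pipeline wraps the same stages
(`misa all --seed 1 --out run/`, or `simulate`/`qc`/`impute`/`screen`/
`search`/`report` individually) and writes TSV tables, a model-inclusion
image in long format, and a JSON-lines run log.

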