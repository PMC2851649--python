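# Methods

This note records the statistical model, the numerical choices behind
it, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable option
existed. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and evidence

Case status is modeled by logistic regression. Every model — including
the null — contains the design covariates: intercept, age, batch
indicators (reference = first sorted level), GC50PCT, and
batch × GC50PCT interactions. Age and GC50PCT are standardized
internally; this makes Bayes factors invariant to covariate rescaling
(e.g. age in days vs years) and lets one diffuse prior serve all design
coefficients. A model of association adds, for each included SNP, a
single column encoding its minor-allele count under a log-additive
(0/1/2), dominant (0/1/1) or recessive (0/0/1) parameterization.
Genotypes are oriented so the counted allele is the minor allele among
controls, which fixes the direction of odds ratios; ties at control
frequency exactly 0.5 are left as coded, since tabular input carries no
allele labels to break them with.

Priors: each genetic coefficient gets N(0, 0.5²) on the log-OR scale —
95% of prior OR mass in roughly [0.38, 2.66], our operationalization of
"small to modest effects" — and each design coefficient (on the
standardized scale) gets N(0, 10²). Because the design block and its
prior are shared by every model, the diffuse prior's contribution
approximately cancels in Bayes factors.

The marginal likelihood is a Laplace approximation at the posterior
mode: `log p(D) = ℓ(β̂) − ½β̂'Λβ̂ + ½log|Λ| − ½log|H|`, with `Λ` the
prior precision and `H = X'WX + Λ`. The mode is found by Newton-Raphson
with step halving; it always exists under the proper prior, so models
with separated likelihoods (e.g. a recessive encoding with no case
rare-homozygotes) keep finite evidence. Separation itself is detected
by attempting the unpenalized MLE (25 Newton iterations; flagged on
non-convergence or any |coefficient| > 15) and reported downstream as
NA effect estimates, while the BF remains finite. The test suite checks
the Laplace value against a 2×10⁵-draw importance-sampling estimate on
a two-coefficient model (observed agreement well inside 0.1 log units)
and the mode/likelihood against an independent MLE implementation.
`−AIC/2` at the MLE is available (`method="aic"`) as a documented fast
surrogate, not used by default.

Effect summaries use the normal approximation at the mode: the reported
"median OR" is `exp(β̂)` (mean = median = mode on the log scale) with a
95% equal-tailed interval `exp(β̂ ± 1.96·se)`, the se taken from the
inverse Hessian.

## Two stages

**Screen.** Each SNP is scored under all three parameterizations
against the design-only null; encodings that are constant in the data
(e.g. recessive with zero rare homozygotes) are skipped with a flag,
and a SNP monomorphic under every encoding is excluded. A SNP passes
when its maximum BF exceeds 1.0 strictly. With multiple imputations,
per-SNP BFs are averaged on the BF scale (arithmetic mean), not the log
scale.

**Search.** Over the S survivors, model size k has prior
`P(specific subset of size k) = B(a+k, b+S−k)/B(a,b)` with `a = 1/8`
and `b = S` by default, times `(1/3)^k` for the parameterization
assignment. The marginal prior inclusion odds are `a/b` — 0.0016 at
S = 77 — independent of S, which is the multiplicity correction. The
evolutionary Monte Carlo sampler uses 5 chains at temperatures
geometrically spaced 1.0 → 0.3, with moves proposed 70/15/15:

- *mutation*: with probability ½ toggle a uniformly chosen SNP (adding
  with a uniform random parameterization; Hastings factor 3 on add, ⅓
  on drop), otherwise re-parameterize a uniformly chosen present SNP
  (symmetric; a no-op rejection on the empty model keeps the branch
  probabilities state-independent);
- *crossover*: two random chains swap each SNP's assignment
  independently with probability ½ (symmetric), both children accepted
  jointly at their chains' temperatures;
- *exchange*: adjacent-temperature chains swap states.

Burn-in defaults to 20% of iterations; all randomness flows from one
`numpy` Generator seeded explicitly. Evidence values are cached by
canonicalized model, since models are revisited constantly. SNP, gene
and global BFs are posterior-to-prior odds of the relevant inclusion
event; posteriors are Rao-Blackwellized by default — renormalized
`evidence × prior` over every model evaluated anywhere in the
population — which is exact on enumerated spaces and lower-variance
than cold-chain visit frequencies (also available, and used for the
detailed-balance check against the prior under flat evidence). A SNP
appearing in no evaluated model is reported as BF 0 with a lower-bound
flag. Gene and global prior-odds terms come from exact beta-binomial
enumeration, not sampling. Exact enumeration of all 4^S models is the
oracle for S ≤ 8 and the default execution path when
`enumerate_below` allows it.

The per-SNP report gives the most likely parameterization and its
probability *conditional on inclusion* (documented choice; the
unconditional probability is recoverable as the product with the
inclusion probability), and effect summaries from the single-SNP model
under that parameterization.

## QC

The HWE statistic is the chi-square goodness-of-fit with Emigh-style
continuity correction: each cell contributes
`max(|O − E| − 0.25, 0)²/E`, guaranteeing a non-negative statistic;
df = 1; monomorphic samples are flagged with p = 1 rather than tested.
The correction makes the test slightly conservative; its size at
α = 0.05 is checked to land in [0.035, 0.065] at n = 500.

The tail diagnostic compares the count of p-values below α with the
Binomial(n, α) expectation and its 2.5th/97.5th percentiles (4.84 and
(1, 10) at n = 484, α = 0.01). The quality-threshold scan drops
samples below each grid point (default grid 0.70–0.80, step 0.001),
recomputes control HWE p-values, and chooses the smallest threshold
whose tail count falls inside the binomial band; if none qualifies the
smallest Kolmogorov-Smirnov distance to uniform decides. This binomial
band + KS rule is our operationalization of a "dramatically improved"
p-value distribution; no explicit published rule exists. Whether SNPs
failing HWE after the scan are removed is a switch
(`drop_hwe_failures`, default off): the tail is primarily a *sample*
diagnostic, and the filter choice is left to the analyst.

Redundancy removal computes r² on genotype dosages (composite LD —
phase is unavailable) over pairwise-complete cases and keeps, within
each r² = 1 pair, the copy with fewer missing values.

## Imputation

The imputer replaces an external phasing tool with a windowed
haplotype-frequency model: for each SNP with missing entries, up to 5
SNPs centered on it (column order) define a window; frequencies of the
2^w binary haplotypes are fitted by EM over unphased, possibly
incomplete window genotypes (subjects grouped by observed pattern;
frequencies floored at 1e−12); each missing entry's posterior over
{0,1,2} sums compatible haplotype pairs conditional on the subject's
observed window genotypes. A degenerate window falls back to marginal
genotype frequencies. This is MAR-correct local-LD imputation; it makes
no claim of equivalence to a full cluster-based phasing model, and
long-range LD beyond the window is ignored. m = 100 draws by default;
the screen consumes BF averages over draws, the model search consumes
the single modal-fill completion (mode over draws, ties to the smaller
genotype count). Observed entries are never altered.

Missingness diagnostics score, for each SNP with ≥ 5 missing values,
the BF of (design + missingness indicator) against (design only) with
the same Laplace machinery — a check that missingness is conditionally
independent of case status given the design.

## Synthetic data

The generator emulates: LD blocks (first-order Markov binary haplotypes
with configurable adjacent correlation, default ρ = 0.6, or explicit
haplotype frequencies), MAF drawn from [0.05, 0.5], random mating (so
HWE holds marginally in the error-free population), a logistic disease
model with a handful of causal SNPs (default ORs 0.53–1.65 across the
three parameterizations), age, four batches with a deliberately uneven
last batch (log-odds offset 1.0) and a batch × quality interaction,
retrospective sampling to exactly n_cases/n_controls (default 364/761
across 484 SNPs, the shipped study-scale scenario), MCAR/MAR/MNAR
missingness, and genotyping error confined to samples with GC50PCT
below 0.789 (uniform flips to a different genotype, which breaks HWE in
the contaminated subset and gives the threshold scan something real to
find). Because contamination is uniform below the boundary, the scan's
chosen threshold can sit a grid step or two *below* the boundary once
the residual contaminated sliver is too small to disturb HWE; tests
therefore require the choice to land within 0.015 of the boundary.

Not emulated: coalescent-realistic LD decay, population stratification,
relatedness, X-linked inheritance, multi-allelic sites. Passing tests
on this generator therefore demonstrate correctness of the machinery
and its calibration under the stated assumptions, not robustness to
confounding by ancestry or cryptic structure.

## Problem sizes and test design

The test suite runs the expensive checks at deliberately chosen scales:
sampler-vs-enumeration agreement on 6-SNP panels (4096-model
enumeration oracle; EMC at 50k iterations, TV < 0.05 and SNP BFs within
10%); credible-interval coverage for ln(1.65) over 200 replicates at
n = 400 (accepted band [0.90, 0.98] — small-n prior shrinkage pulls
coverage slightly below 95%, which the band anticipates); global-null
multiplicity control with S = 77 and n = 1125 over 20 replicates
(< 1% of SNPs at BF > 10); HWE test size over 2000 replicates at
n = 500. Simulation seeds are fixed throughout, so every quoted rate is
a deterministic function of the code.

## Known limitations

- The Laplace approximation degrades for very small cell counts; the
  separated-model path keeps evidence finite but its absolute accuracy
  is untested beyond the reporting convention.
- SNP × SNP and SNP × covariate interactions, haplotype-level models
  and phasing-aware imputation are out of scope.
- The sampler guarantees reproducibility per seed and chain count, not
  across different chain counts.
- The conditional most-likely-parameterization probability can be high
  even when inclusion probability is low; read it jointly with the BF.
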