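# Methods

## The model

The unit of analysis is a gene, and the data for a gene are counts of rare,
putatively damaging variants from up to three sources: `N` sequenced trios
(unaffected parents, affected child), contributing de novo events `x_dn` and
transmitted/nontransmitted inherited variants `x_t` / `x_nt`; and `N1` cases
and `N0` controls, contributing carrier counts. Variants are grouped into
categories — loss-of-function (LoF: nonsense, splice site, frameshift) and
probably-damaging missense (Mis3) — and all qualifying variants of a category
in one gene are collapsed to a single damaging "allele" per gene, justified
because each is individually very rare.

Three gene-level parameters govern the counts: the per-chromosome,
per-generation mutation rate `mu` (supplied externally, estimated from gene
length and base content), the allele frequency `q` of the damaging allele,
and the multiplicative relative risk `gamma` of carrying it. Under a
dominant model and first-order in `q`, the counts are approximately Poisson:

    x_dn ~ Poisson(2 N mu gamma)
    x_t  ~ Poisson(2 N q gamma)        x_case ~ Poisson(2 N1 q gamma)
    x_nt ~ Poisson(2 N q)              x_ctrl ~ Poisson(2 N0 q)

Transmission counts are therefore a pseudo case-control contrast with `N`
cases and `N` controls, and both sources pool into `x1 = x_case + x_t` with
chromosome exposure `e1 = 2(N1 + N)` and `x0 = x_ctrl + x_nt` with
`e0 = 2(N0 + N)`. The testable content of the rate constants is the null
symmetry of the two arms at `gamma = 1` and linearity in sample sizes, `mu`
and `q`; the constants themselves are confined to `gene_model.compute_rates`.

## Hierarchical priors and the Bayes factor

A fraction `pi` of genes are risk genes (H1); the rest are null (H0, `gamma
= 1`). Under H1, `gamma ~ Gamma(gamma_mean * beta, beta)` — mean
`gamma_mean`, with `beta` acting as a precision/pseudo-count — and `q ~
Gamma(rho1, nu1)`; under H0, `q ~ Gamma(rho0, nu0)`. The gene's evidence is
the Bayes factor `P(x_dn, x1, x0 | H1) / P(x_dn, x1, x0 | H0)` with both
gene-level parameters integrated out.

The `q` integrals are conjugate and evaluated in closed form (a
negative-binomial-type expression over the two Poisson arms). The `gamma`
integral couples the de novo term and the case arm; it is evaluated by
Gauss-Legendre quadrature on `log gamma` over the central `1 - 1e-10` prior
mass, doubling the order from 32 until the log-result is stable to `1e-6`
(capped at 256 nodes; the integrand is smooth and unimodal on the log axis).
All likelihoods live in log space; Bayes factors are reported as log10. A
factorized mode (independent `gamma` integrals for the two streams) is
retained as a fast approximation and as the exact form of the de-novo-only
analysis, where the `gamma` integral is itself conjugate
(negative-binomial closed form).

For multi-category data, categories are modeled independently and the gene's
total BF is the product of per-category BFs. Because predicted-damaging
missense calls include some functionally neutral variants, a category can be
assigned a mixture weight `w` (probability its variants are truly damaging);
its BF enters the product as `w * BF + (1 - w)`. Default `w = 0.5` for
missense-type categories — the neutral-fraction mixture is symmetric absent
better calibration data — and `w = 1` for LoF; both are configurable.

## Empirical-Bayes fitting

The six prior parameters per category are estimated by maximizing the
mixture marginal likelihood `sum_i log[pi P(d_i|H1) + (1-pi) P(d_i|H0)]`
with `pi` fixed (default `1000/18000`, the externally estimated risk-gene
fraction). The optimizer is multi-start L-BFGS-B on log coordinates — `(log
gamma_mean, log beta, log q-prior means, log q-prior shapes)` — with box
bounds `gamma_mean in [1.1, 500]`, `beta in [1e-3, 1e3]`, prior means of `q`
in `[1e-7, 0.049]`, shapes in `[1e-2, 1e3]`. The first start is moment-based
(pooled variant frequency for the null `q` mean; the de novo enrichment
inverted through the architecture identity for `gamma_mean`); further starts
jitter it multiplicatively. Inside the optimizer the quadrature order is
fixed at 32 nodes; the reported optimum is re-evaluated with the adaptive
rule. `beta` is weakly identified — likelihood surfaces are flat in it —
which is why the log-reparameterization and multi-start matter;
`gamma_mean` and the `q` prior means are the well-identified quantities, and
the recovery tests target those.

## Significance

A Bayes factor is converted to a p-value against a simulated genome-wide
null: each replicate draws a gene uniformly from the analyzed list (keeping
the empirical mutation-rate spectrum), draws `q` from the fitted H0 prior,
generates counts at the null rates, and evaluates the same BF. The p-value
is `(1 + #{pool >= observed}) / (1 + pool size)`, floored at the pool
resolution; the production pool default is 1e6 replicates (resolution 1e-6).
A per-gene pool (gene fixed) is available for single-gene analyses such as
the sensitivity scans. Multiple testing uses Benjamini-Hochberg q-values
(statsmodels), and a median-based genomic-control factor `lambda =
median(chi2_1 quantiles of p) / 0.4549` diagnoses inflation.

Because counts are discrete, p-values from a *per-gene* null are granular
and the tests are conservative at a fixed nominal level; against the
*pooled* null the mutation-rate spectrum smooths the BF distribution and
p-values are uniform under H0 (verified by KS at 5,000 simulated null
genes, with type-I error at `alpha = 0.001` inside the binomial band).

## Baselines

The comparison tests are implemented as in the field: the multiplicity rule
(call at >= C de novo events); the De Novo Test (Poisson upper tail at rate
`2 N mu`); a one-sided Fisher exact test on `[[x1, e1-x1], [x0, e0-x0]]`
(vectorized as the hypergeometric tail; "greater" in the case arm, because
the integrated test is effectively one-sided for adverse minor alleles);
and the Meta test combining the de novo and inherited p-values by Fisher's
method (de novo p floored at the smallest positive float before taking
logs; exactly two p-values per gene).

## Architecture estimation

With `k` of `m` genes at risk and mean relative risk `gamma_mean`, the
expected proband/sibling de novo fold-enrichment is `lambda = 1 + k
(gamma_mean - 1) / m` (equal-rate approximation), giving the inverse curve
`k = m (lambda - 1) / (gamma_mean - 1)`. The expected number of multi-hit
genes (>= 2 de novo events) breaks the `(k, gamma_mean)` degeneracy: it is
computed per gene as the `k/m`-weighted mixture of the Poisson tail at the
null rate and its expectation over the relative-risk distribution (Gamma
with mean `gamma_mean` and coefficient of variation 1 by default; the CV is
a configuration knob). Heterogeneity in `mu` and `gamma` raises this
expectation at fixed totals (Jensen's inequality), which is why equal-rate
treatments underestimate `k`; the package demonstrates the effect
numerically rather than analytically. The curve along the
enrichment-constrained path is unimodal in `k`; the plausible `k` range
inverts its decreasing branch at a band around the observed multi-hit count
(bisection to one gene), and the final `k` maximizes the fitted marginal
likelihood over a grid with `pi = k/m`.

## The synthetic-data generator

`simulate.SimConfig` defaults are the estimated ASD architecture: `m =
18,000` genes, `k = 1,000` risk genes, `gamma ~ Gamma(mean 20, beta 1)` for
risk genes, null allele-frequency prior mean `1e-3` and risk-gene mean
`5e-5` (both Gamma with shape 0.5 — rare alleles with a heavy mass near
zero), and a log-normal LoF mutation-rate spectrum with median `1e-6` and
log-SD 1 (mean ~1.6e-6 per chromosome per generation, consistent with ~34
LoF de novo events observed among ~590 sibling exomes spread over 18,000
genes). A `mutation_selection` mode ties a risk gene's frequency to its
sampled risk, `q = c mu / gamma`, with `c` solved from the configured means
— a one-parameter mutation-selection balance. Counts are Poisson at the
model rates from per-gene counter-based substreams keyed by `(seed, gene
index)`, so any subset of genes reproduces its counts exactly.

What the generator does *not* emulate: linkage and haplotype structure,
population stratification, variable sequencing depth or call quality,
per-individual variation in mutation rate, and ascertainment beyond the
affected-child conditioning already in the rates. Passing tests therefore
validate the statistical machinery under the model's own assumptions, not
robustness to those real-data complications (the genomic-control diagnostic
exists precisely because stratification is outside the model).

## Problem sizes and numerical choices in the test suite

Validation experiments run at the study scale where that scale is the point
— recovery and power experiments use `m = 18,000`-gene genomes with 1,000
trios (plus 1,000/1,000 cases/controls for recovery) — and at reduced scale
elsewhere. Null pools in tests use 1e5-2e5 replicates (p-value resolution
5e-6 to 1e-5, sufficient for the `alpha >= 1e-3` levels tested) versus the
1e6 production default; empirical-Bayes fits in tests use 2 optimizer
starts from the moment-based initialization, which lands on the same
optimum as the 5-start default on these well-behaved synthetic likelihoods.
Closed-form marginals are validated against scrambled-Sobol quasi-Monte-
Carlo integration (2^20 points through the inverse Gamma CDF), whose error
is far below the 1e-3 assertion tolerance — plain Monte Carlo at the same
size would itself be noisier than the tolerance for diffuse (shape < 1)
frequency priors.

## Known limitations

* Dominant-acting, rare variation only: no recessive model, covariates or
  quantitative traits.
* `mu` is an input; the package does not estimate mutation rates from
  sequence.
* The plug-in (posterior-mean) Bayes factor approximation is provided for
  insight into the integrated test's relationship to a likelihood-ratio
  test, not as a substitute: its sign agrees with the exact BF >= 90% of
  the time in simulation but its magnitudes are not calibrated.
* `beta` (the relative-risk prior precision) is reported but weakly
  identified; do not over-interpret its fitted value.
* The genomic-control factor is the standard median-based `lambda`; no
  rare-variant-specific modification is applied.
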