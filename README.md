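# tada

Gene-level association testing for rare, large-effect, dominantly acting
variation — integrating **de novo mutations**, **transmitted/nontransmitted
inherited variants** and **case-control carrier counts** in one
hierarchical-Bayes framework (TADA: Transmission And De novo Association).

## Who this is for

Statistical geneticists analyzing whole-exome family and case-control data
for early-onset disorders (autism being the motivating case) in which recurrent
de novo loss-of-function events flag risk genes, but most of the collected
signal — inherited rare variants, case-control carriers, non-LoF damaging
mutations — is wasted by simple recurrence tests.

## The model in brief

For each gene, with `N` trios, `N1` cases and `N0` controls, counts are
approximately Poisson in three gene-level parameters — mutation rate `mu`
(known), damaging-allele frequency `q`, relative risk `gamma`:

    x_dn ~ Pois(2 N mu gamma),   x1 ~ Pois(2(N1+N) q gamma),   x0 ~ Pois(2(N0+N) q)

where `x1` pools case carriers with transmitted variants and `x0` pools
control carriers with nontransmitted ones. A fraction `pi` of genes are risk
genes with `gamma ~ Gamma(gamma_mean * beta, beta)` and `q ~ Gamma(rho1, nu1)`;
null genes have `gamma = 1`, `q ~ Gamma(rho0, nu0)`. Prior parameters are
estimated genome-wide by maximizing the marginal likelihood (empirical
Bayes); each gene's evidence is the Bayes factor

    BF_i = P(x_dn, x1, x0 | H1) / P(x_dn, x1, x0 | H0)

with `gamma` and `q` integrated out (conjugate in `q`, quadrature in
`gamma`), multiplied across mutation categories (LoF, damaging missense with
a neutral-fraction downweight `w`), and converted to a p-value against a
simulated genome-wide null, then to Benjamini-Hochberg q-values. See
`docs/methods.md` for the full account.

Also included: the baseline tests it is compared against (multiplicity,
Poisson de novo test, Fisher-exact + Fisher's-method meta test), a
genetic-architecture estimator (number of risk genes `k` and mean relative
risk from de novo enrichment and multi-hit counts), a genome-wide synthetic
data generator, and power/FDR experiment drivers.

## Worked example

```python
from tada import TADA
from tada.gene_model import StudyDesign
from tada.simulate import SimConfig, simulate_genome

design = StudyDesign(n_trios=1000, n_cases=1000, n_controls=1000, categories=("LoF",))
genome = simulate_genome(SimConfig(m=3000, k=200, design=design), seed=7)

model = TADA.from_dataframe(genome.counts, n_trios=1000, n_cases=1000,
                            n_controls=1000, pi=200 / 3000)
res = model.fit(n_starts=2, seed=7)
print(res.summary())
```

```
Hierarchical-Bayes rare-variant association (TADA)
==========================================================
Genes:   3000    Trios: 1000   Cases: 1000   Controls: 1000
pi (risk-gene fraction, fixed): 0.0667
Marginal log-likelihood: -12904.343   converged: True
----------------------------------------------------------
category   gamma_mean     beta    E[q|H1]    E[q|H0]     w
LoF            17.385    0.452  6.170e-05  1.011e-03  1.00
==========================================================
```

The genome was generated with mean relative risk 20, risk-gene allele
frequency mean 5e-5 and null mean 1e-3; the fit recovers 17.4, 6.2e-5 and
1.01e-3. Per-gene inference:

```python
table = res.gene_results(null_pool_size=100_000, seed=7)
print(table.head(5)[["gene", "log10_bf_total", "p", "q"]].to_string(index=False))
```

```
  gene  log10_bf_total       p      q
G00129        4.227542 0.00001 0.0025
G00150        6.354315 0.00001 0.0025
G00334        3.954574 0.00001 0.0025
G00573        3.566086 0.00001 0.0025
G00751        3.970324 0.00001 0.0025
```

All ten top-ranked genes are planted risk genes; 48 genes pass q < 0.1.
`log10_bf_total` is the log10 Bayes factor for "risk gene" vs "null", `p`
its null-simulation p-value (floored at the pool resolution), `q` the BH
false-discovery estimate.

A command-line surface wraps the same pipeline:

```
tada simulate --m 3000 --k 200 --n-trios 1000 --seed 7 --out genome.tsv
tada test --genes genome.tsv --config config.yaml --seed 7 --out results.tsv
tada baselines --genes genome.tsv --config config.yaml --out baselines.tsv
tada architecture --m 18000 --n-trios 932 --lambda 2 --multihit 5 --out arch.json
```

## Bundled data

`tada.datasets.load_asd_top_genes()` returns the published per-gene LoF
counts (de novo, transmitted, nontransmitted, case, control) and p-values
for the top candidate genes from combined ASD whole-exome data (932 trios,
935 cases / 870 controls) — the package's reference worked example for
count conventions; five of these genes carry two independent de novo LoF
events.

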