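# ibvs — integrative Bayesian variable selection for case–control GWAS

`ibvs` selects disease-associated **genes and SNPs simultaneously** in
case–control genome-wide association studies, borrowing strength from a
gene–gene interaction network. It is aimed at statistical geneticists who
want interpretable posterior inclusion probabilities per marker instead of
penalized-regression coefficients, together with simulation, screening,
prediction and benchmarking tools.

## The model

Each binary outcome Y_i is driven by a latent Gaussian liability
(probit link):

    Y_i = 1  iff  Z_i > 0,      Z = T_(ξ,γ) β + ε,   ε_i ~ N(0, 1)

* **γ ∈ {0,1}^P** flags selected SNPs, **ξ ∈ {0,1}^J** flags selected genes
  (a gene is selected iff at least one of its SNPs is).
* **T_(ξ,γ)** has one column per selected gene: the first partial-least-squares
  component of the gene's selected SNP dosages against the outcome — a
  one-dimensional summary of the gene's joint SNP effect.
* **β | T ~ N(0, c (T'T)⁺)** — a generalized Zellner g-prior using the
  Moore–Penrose inverse, so collinear (high-LD) designs remain proper.
* **γ_p ~ Bernoulli(π)** independently; π encodes the believed fraction of
  causal SNPs.
* **ξ** follows a Markov-random-field prior over the gene network R:
  P(ξ) ∝ exp(μ 1'ξ + η ξ'Rξ), so a gene's inclusion odds rise with the
  number of selected network neighbours (μ controls sparsity, η smoothing).

β is integrated out analytically; a Metropolis–Hastings sampler explores
(ξ, γ) with gene-level and SNP-level add/remove moves while Z is refreshed
by exact truncated-normal Gibbs sweeps. Posterior inclusion probabilities
(PIPs) are post-burn-in averages of the indicators.

## Worked example

```python
import numpy as np
from ibvs import (ScenarioConfig, simulate_replicate, train_test_split,
                  ChainConfig, run_chain, auc_from_probabilities)
from ibvs.benchmark import simulation_priors

cfg = ScenarioConfig.scenario("H70", seed=13)   # 70% liability variance genetic
geno, pheno, truth = simulate_replicate(cfg, np.random.default_rng(13))
(train_g, train_y), _ = train_test_split(geno, pheno)

out = run_chain(train_g, train_y, truth.network, simulation_priors(cfg),
                ChainConfig(n_burnin=2000, n_samples=10000, seed=13))
print("top SNPs:", np.argsort(-out.pip_snp)[:10])
print("causal  :", truth.causal_snps)
print("selection AUC:", round(auc_from_probabilities(out.pip_snp,
                                                     truth.causal_snps), 3))
```

Output:

```
top SNPs: [235 234 249 245 229  25 260 299 266 264]
causal  : [ 15  25 229 234 235 245 249 260 264 267]
selection AUC: 0.998
```

The chain concentrates posterior mass on the causal SNPs (neighbours such
as 299 and 266 are close LD partners of causal markers 260/264/267); the
AUC is the fraction of (causal, non-causal) pairs ranked correctly by PIP.

The same workflow is available from the shell:

```bash
ibvs simulate --scenario H70 --replicates 1 --seed 13 --out sim/
ibvs fit -g sim/rep000/genotypes.tsv -y sim/rep000/phenotype.txt \
         -m sim/rep000/gene_map.tsv -n sim/rep000/network.tsv -o fit/
ibvs evaluate --truth sim/rep000/truth.json --pips fit/pip_snp.tsv
```

plus `ibvs screen` (univariate p-value screening with gene-level
extraction), `ibvs predict` (two-stage top-i PLS logistic prediction) and
`ibvs benchmark` (scenario-level method comparison).

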