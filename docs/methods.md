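# Methods

## Model

The package implements hierarchical Bayesian variable selection for
case–control GWAS with three levels:

1. **Probit data augmentation.** Binary outcomes are represented through a
   latent liability Z_i ~ N(0,1) with Y_i = 1 iff Z_i > 0. Conditional on
   the selected design this yields truncated-normal Gibbs updates for Z.
2. **Gene scores by partial least squares.** A selected gene contributes a
   single design column: the first PLS component of its selected SNP
   dosage columns against the response — the unit direction w ∝ X'y
   maximizing covariance between the score Xw and the response. Columns
   are centered, not variance-scaled (coded genotypes share a scale; a
   flag enables scaling). The weight sign is fixed so the score's
   covariance with the response is non-negative, making the design a
   deterministic function of the indicators.
3. **Selection priors.** SNP indicators are i.i.d. Bernoulli(π). Gene
   indicators follow a Markov random field over the gene network R,
   P(ξ) ∝ exp(μ 1'ξ + η ξ'Rξ), with η ≥ 0 enforced (negative smoothing
   induces phase-transition pathologies). Note the quadratic form counts
   each edge twice, so the conditional log-odds of one gene are
   μ + 2η·(number of selected neighbours); the univariate and multivariate
   ways of writing this prior in the literature differ by exactly this
   factor of two, and the implementation is consistent with the
   multivariate form throughout (verified by enumeration).

Coefficients carry a generalized g-prior β | T ~ N(0, c(T'T)⁺) and are
integrated out. With P_T the orthogonal projector onto col(T) and
m = rank(T), the standard marginalization gives

    Σ = c·P_T + I,   log|Σ| = m·log(1+c),
    Z'Σ⁻¹Z = Z'Z − c/(1+c) · Z'P_T Z.

Some presentations state the collapsed covariance as Σ⁻¹ = c·P_T + I
instead; the two differ only in the sign/role of c. The package defaults
to the derived form (`convention="derived"`), which is the mathematically
consistent collapse of the stated prior and the only one that rewards
alignment between Z and the design; the literal alternative is available
behind `convention="literal"` and both are tested against dense-matrix
oracles.

### PLS response

The response the PLS components are computed against is the observed
binary Y, fixed across the chain (config `pls_response`). This keeps the
design a deterministic function of (ξ, γ), so per-gene score columns can
be cached and marginal-likelihood evaluations are coherent; conditioning
the design on the evolving latent Z would make the "marginal likelihood"
state-dependent.

## Sampler

Each iteration performs one Metropolis–Hastings update of (ξ, γ) followed
by a full Gibbs sweep of Z.

**Move classes.** (1) gene-and-SNP: add an unselected gene uniformly with
one of its SNPs uniformly, or remove a selected gene with all its selected
SNPs; (2) SNP-only: add an unselected SNP uniformly within the selected
genes, or remove a selected SNP uniformly. Removing a gene's last SNP is
reclassified as removing the gene (the matching reverse is a class-1 add).
Proposal ratios sum the probabilities of every mechanism that can produce
a transition; a class-1 removal of a gene holding ≥ 2 selected SNPs has no
reverse mechanism and is therefore always rejected — wasteful but exactly
reversible (multi-SNP genes dissolve through SNP-level removals instead).
Chain correctness is verified against an enumerated posterior (orthant
probabilities of the truncated multivariate normal) on a 16-model toy
problem with a χ² test.

**Truncated-normal sweeps.** Σ⁻¹ = I + b·UU' for an orthonormal basis U of
col(T) (b = −c/(1+c) derived, +c literal), so each univariate conditional
costs O(rank). Sampling uses plain rejection from the normal when the
truncation boundary is favourable and Robert's exponential-envelope
rejection in the far tail — exact at any truncation point. The sweep is
JIT-compiled when numba is available; the pure-Python path is identical.

**Initialization** is the null model with half-normal liabilities matched
to the outcome signs. Defaults: 10000 burn-in, 50000 samples, thin 1,
single chain; every random draw flows from one seeded PCG64 generator, so
runs are bit-reproducible.

## Hyperparameters

| parameter | meaning | default |
|---|---|---|
| π | prior SNP inclusion probability | 0.01 (library); causal fraction of the scenario (benchmark) |
| μ | MRF gene sparsity (prior log-odds scale) | −2.0 (library); logit of the scenario's causal-gene fraction (benchmark) |
| η | MRF smoothing, ≥ 0 | 0.8 |
| c | g-prior scale | n (unit-information) |

The library defaults mirror a real-data analysis with ~3400 screened SNPs
in ~100 genes; the benchmark derives π and μ from the simulated scenario's
design (10 causal of 300 SNPs, 5 of 22 genes) following the elicitation
rule that π reflects the believed number of causal SNPs. c is never
stated in the source analyses; c = n is the standard unit-information
default, and the sensitivity set {10, n, P} is exposed in the config.

## Synthetic-data generator

The generator emulates a case–control cohort of 400 individuals with 300
SNPs in 22 genes, 10 causal SNPs in 5 networked causal genes, at a
controlled fraction of liability variance explained by genetics
(H70/H50/H30 = 0.70/0.50/0.30).

* **Genotypes** come from a Gaussian copula: per gene, a latent AR(1)
  vector (ρ = `ld_decay`, default 0.5) thresholded at Hardy–Weinberg
  quantiles for a per-SNP MAF drawn uniform on [0.05, 0.5]. This gives
  realistic within-gene LD decay and exact HWE marginals, but not the
  block structure, allele-frequency spectrum or long-range LD of real
  haplotype data — results on it demonstrate correctness of the machinery
  and relative method behaviour, not performance on real genomes.
* **Gene-level effects** t_i ~ N(0, Ω⁻¹) with Ω built from the simulated
  network (unit diagonal, ±`edge_strength` = 0.4 on edges, diagonal
  inflation to minimum eigenvalue 0.05). The causal genes are joined in a
  ring so the network genuinely carries information about them, plus
  Erdős–Rényi background edges (density 0.1); causal genes therefore have
  somewhat higher degree than background genes, which is precisely the
  setting where an informative MRF prior should help.
* **Causal gene scores** T_ik = Σ_j b_j x_ij + 0.3·t_ik. Effect weights
  b_j are unit magnitude on the standardized-dosage scale with random
  signs, so each causal SNP contributes comparable liability variance
  regardless of MAF and sign patterns vary across genes; the gene-level
  term is scaled to 0.3 SD so the SNP effects dominate the gene scores.
  With unit-variance gene noise the SNP-attributable share of the
  liability collapses to a few percent and no method can rank causal
  SNPs — incompatible with the operating point the benchmark targets
  (causal SNPs detectable near the univariate screening threshold).
* **Liability** z = Σ_k φ_k T_ik + ε, ε ~ N(0,1), with equal gene weights
  φ rescaled on each cohort so the realized explained variance equals the
  scenario label exactly (±0.02 tested); z is centered before
  thresholding at zero, giving ~50% cases.

Replicates use `SeedSequence([master_seed, replicate])`, making scenario
sets reproducible and replicates independent.

## Evaluation and comparators

Selection performance is pairwise ranking AUC over (causal, non-causal)
SNP pairs: PIPs for the Bayesian model (strictly-greater indicator; ties
count zero by default, half under `ties="half"`), path entry order for
LASSO and stepwise (strictly-earlier indicator, never-entered = +∞). Both
equal Mann–Whitney statistics and are tested against exhaustive pairwise
oracles.

LASSO entry order comes from the LARS implementation of the lasso path.
Stepwise is the classic sequential-F forward/backward selection on the
numeric 0/1 outcome (entry at the AIC-equivalent p < 0.157, removal at
p > 0.20), which ranks markers along a path extending over most of the
design; a logistic variant (score-test entry, Wald removal) is available
but its path saturates at separation — on 200 training samples after
roughly 30 entries — leaving most markers unranked, which makes
entry-order AUC uninformative at that sample size.

Prediction uses the two-stage protocol: rank SNPs by PIP (or by entry
order for the baselines), fit one PLS component + univariate logistic on
the top-i SNPs, choose i by stratified 10-fold CV of classification error
at threshold 0.5 (first minimum under ties), and score the held-out half;
ROC curves average sensitivity/specificity pointwise over replicates on
the fixed threshold grid 0.01…0.99.

## Scale choices

The benchmark and acceptance runs use 10 replicates per scenario (8 in the
test suite) with 5000 burn-in + 25000 sampling iterations, rather than the
50 replicates of a full study; Monte-Carlo standard errors of mean AUC at
this scale are ~0.02–0.03. Shorter chains (e.g. 2000+10000) measurably
depress the Bayesian model's AUC through PIP sampling noise, so chain
length is kept near the full protocol while replicates are reduced.

## Known limitations

* The copula genotype model understates real-genome LD complexity (see
  above); absolute AUC levels on real data will differ.
* Entry-order AUC depends on comparator settings (stepwise entry
  threshold, never-entered convention); both conventions are exposed and
  the defaults documented.
* Single-chain inference; split-R̂ style multi-chain diagnostics are not
  bundled into the benchmark loop.
* The screening stage tests SNPs marginally without covariate or
  stratification adjustment.
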