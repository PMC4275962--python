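"""Synthetic case-control GWAS generator with LD blocks and a gene network.

Genotypes are drawn from a Gaussian-copula model: within each gene a latent
Gaussian vector with AR(1) correlation ``rho^|k-k'|`` is thresholded at the
quantiles implied by Hardy-Weinberg proportions for a per-SNP minor-allele
frequency, giving 0/1/2 dosages with tunable linkage disequilibrium;
genes are independent of each other.  Phenotypes follow a liability
threshold model: causal gene scores

    T_ik = sum_{causal SNP j in gene k} b_j x_ij + t_ik,

where the gene effects t_i are multivariate normal with precision matrix
Omega encoding the gene network; the liability is z_i = sum_k phi_k T_ik +
eps_i with eps_i ~ N(0,1), and Y_i = 1 iff z_i >= 0.  The gene-level
weights phi are rescaled so the realized fraction of liability variance
explained by the genetic component matches the scenario label (H70/H50/H30)
on each simulated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data_model import GeneNetwork, GenotypeData, Phenotype, encode_genotypes

SCENARIOS = {"H70": 0.70, "H50": 0.50, "H30": 0.30}


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings of one simulation scenario (defaults match the study design)."""

    n_individuals: int = 400          # first half train, second half test
    n_snps: int = 300
    n_genes: int = 22
    n_causal_snps: int = 10
    n_causal_genes: int = 5
    explained_variance: float = 0.70
    genetic_model: str = "additive"
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 0.5             # AR(1) rho of the latent copula
    network_density: float = 0.1
    edge_strength: float = 0.4        # off-diagonal magnitude in Omega
    gene_noise_scale: float = 0.3     # SD multiplier of the t_ik term
    b_range: tuple = (1.0, 1.0)       # |b_j| range, standardized-dosage scale
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.explained_variance < 1.0:
            raise ValueError("explained_variance must lie in (0,1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.genetic_model not in ("additive", "dominant"):
            raise ValueError("genetic_model must be additive or dominant")

    @classmethod
    def scenario(cls, label: str, **kw) -> "ScenarioConfig":
        return cls(explained_variance=SCENARIOS[label.upper()], **kw)


@dataclass
class SimTruth:
    """Ground truth of one simulated replicate."""

    causal_snps: np.ndarray
    causal_genes: np.ndarray
    b: np.ndarray                 # per-causal-SNP effect weights
    phi: np.ndarray               # per-causal-gene weights after rescaling
    omega: np.ndarray             # gene-network precision matrix
    network: GeneNetwork
    realized_explained_variance: float = np.nan
    latent_z: np.ndarray | None = None


def _gene_sizes(n_snps: int, n_genes: int) -> np.ndarray:
    sizes = np.full(n_genes, n_snps // n_genes, dtype=int)
    sizes[: n_snps % n_genes] += 1
    return sizes


def simulate_genotypes(cfg: ScenarioConfig, rng: np.random.Generator
                       ) -> GenotypeData:
    """Draw coded genotypes with AR(1) within-gene LD, HWE marginals."""
    sizes = _gene_sizes(cfg.n_snps, cfg.n_genes)
    rho = cfg.ld_decay
    cols, gene_of_snp = [], []
    for j, pj in enumerate(sizes):
        # latent AR(1) Gaussian: e_1 ~ N(0,1); e_k = rho e_{k-1} + sqrt(1-rho^2) w
        eps = rng.standard_normal((cfg.n_individuals, pj))
        lat = np.empty_like(eps)
        lat[:, 0] = eps[:, 0]
        for k in range(1, pj):
            lat[:, k] = rho * lat[:, k - 1] + np.sqrt(1 - rho ** 2) * eps[:, k]
        maf = rng.uniform(*cfg.maf_range, size=pj)
        # HWE genotype probabilities for minor-allele dosage: (1-q)^2, 2q(1-q), q^2
        p_hom_major = (1 - maf) ** 2
        p_het = 2 * maf * (1 - maf)
        t1 = stats.norm.ppf(p_hom_major)           # below -> dosage 0
        t2 = stats.norm.ppf(p_hom_major + p_het)   # between -> 1, above -> 2
        dos = (lat > t1).astype(np.int8) + (lat > t2).astype(np.int8)
        cols.append(dos)
        gene_of_snp.extend([j] * pj)
    X = np.hstack(cols)
    X = encode_genotypes(X, cfg.genetic_model)
    snp_ids = [f"snp{k}" for k in range(cfg.n_snps)]
    sample_ids = [f"s{i}" for i in range(cfg.n_individuals)]
    gene_ids = [f"gene{j}" for j in range(cfg.n_genes)]
    return GenotypeData(X, sample_ids, snp_ids, np.array(gene_of_snp),
                        gene_ids, cfg.genetic_model)


def simulate_network(cfg: ScenarioConfig, causal_genes: np.ndarray,
                     rng: np.random.Generator) -> GeneNetwork:
    """Random gene network; causal genes are linked in a ring so the MRF
    prior carries information about them, plus Erdos-Renyi background."""
    J = cfg.n_genes
    R = (rng.random((J, J)) < cfg.network_density).astype(np.int8)
    R = np.triu(R, 1)
    cg = np.asarray(causal_genes)
    for a, b in zip(cg, np.roll(cg, -1)):
        i, j = min(a, b), max(a, b)
        if i != j:
            R[i, j] = 1
    R = R + R.T
    np.fill_diagonal(R, 0)
    return GeneNetwork(R, [f"gene{j}" for j in range(J)])


def build_network_precision(network: GeneNetwork, edge_strength: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Precision matrix Omega: unit diagonal, +/- edge_strength on edges,
    then diagonal inflation until the smallest eigenvalue is >= 0.05."""
    J = network.J
    signs = np.where(rng.random((J, J)) < 0.5, -1.0, 1.0)
    signs = np.triu(signs, 1)
    signs = signs + signs.T
    omega = np.eye(J) + edge_strength * signs * network.R
    lam = np.linalg.eigvalsh(omega).min()
    if lam < 0.05:
        omega += (0.05 - lam) * np.eye(J)
    return omega


def simulate_phenotypes(geno: GenotypeData, truth: SimTruth,
                        cfg: ScenarioConfig, rng: np.random.Generator
                        ) -> tuple[Phenotype, np.ndarray]:
    """Liability-threshold phenotypes at the scenario's explained variance.

    phi is rescaled (in place on ``truth``) so that Var(g)/(Var(g)+1)
    equals ``cfg.explained_variance`` on this cohort, where g is the
    genetic component of the liability.
    """
    n = geno.n
    sigma = np.linalg.inv(truth.omega)
    t = cfg.gene_noise_scale * rng.multivariate_normal(
        np.zeros(geno.J), sigma, size=n, method="cholesky")
    scores = np.empty((n, truth.causal_genes.size))
    for idx, g in enumerate(truth.causal_genes):
        snps = [s for s in truth.causal_snps if geno.gene_of_snp[s] == g]
        bvals = truth.b[np.isin(truth.causal_snps, snps)]
        scores[:, idx] = geno.X[:, snps] @ bvals + t[:, g]
    g_raw = scores @ truth.phi
    var_g = g_raw.var()
    if var_g == 0.0:
        raise ValueError("degenerate genetic component: Var(g) = 0")
    h2 = cfg.explained_variance
    scale = np.sqrt(h2 / (1 - h2) / var_g)  # Var(scale*g)/(Var+1) = h2
    truth.phi = truth.phi * scale
    g = g_raw * scale
    z = g - g.mean() + rng.standard_normal(n)
    truth.realized_explained_variance = float(
        g.var() / (g.var() + 1.0))
    truth.latent_z = z
    return Phenotype((z >= 0).astype(np.int8)), z


def simulate_replicate(cfg: ScenarioConfig, rng: np.random.Generator):
    """One (GenotypeData, Phenotype, SimTruth) triple."""
    sizes = _gene_sizes(cfg.n_snps, cfg.n_genes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    causal_genes = np.sort(rng.choice(cfg.n_genes, cfg.n_causal_genes,
                                      replace=False))
    per_gene = np.full(cfg.n_causal_genes,
                       cfg.n_causal_snps // cfg.n_causal_genes)
    per_gene[: cfg.n_causal_snps % cfg.n_causal_genes] += 1
    causal_snps = []
    for g, k in zip(causal_genes, per_gene):
        causal_snps.extend(np.sort(
            rng.choice(np.arange(offsets[g], offsets[g + 1]), k,
                       replace=False)))
    causal_snps = np.array(causal_snps)
    network = simulate_network(cfg, causal_genes, rng)
    omega = build_network_precision(network, cfg.edge_strength, rng)
    geno = simulate_genotypes(cfg, rng)
    # effect weights on the standardized-genotype scale, so each causal
    # SNP contributes comparable liability variance regardless of its MAF
    lo, hi = cfg.b_range
    u = rng.uniform(lo, hi, cfg.n_causal_snps) * \
        rng.choice([-1.0, 1.0], cfg.n_causal_snps)
    sd = geno.X[:, causal_snps].std(axis=0)
    sd[sd == 0] = 1.0
    b = u / sd
    truth = SimTruth(causal_snps, causal_genes, b,
                     np.ones(cfg.n_causal_genes), omega, network)
    pheno, _ = simulate_phenotypes(geno, truth, cfg, rng)
    return geno, pheno, truth


def train_test_split(geno: GenotypeData, pheno: Phenotype):
    """First half of the cohort trains, second half tests."""
    n2 = geno.n // 2
    def sub(lo, hi):
        return GenotypeData(geno.X[lo:hi], geno.sample_ids[lo:hi],
                            geno.snp_ids, geno.gene_of_snp, geno.gene_ids,
                            geno.coding)
    return ((sub(0, n2), Phenotype(pheno.Y[:n2])),
            (sub(n2, geno.n), Phenotype(pheno.Y[n2:])))


def generate_scenario(cfg: ScenarioConfig):
    """All replicates of a scenario with deterministic per-replicate seeds."""
    out = []
    for r in range(cfg.n_replicates):
        seed = np.random.SeedSequence([cfg.seed, r])
        rng = np.random.Generator(np.random.PCG64(seed))
        out.append(simulate_replicate(cfg, rng))
    return out
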