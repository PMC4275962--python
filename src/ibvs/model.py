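"""Priors and the collapsed posterior kernel.

The hierarchical probit model puts a latent liability ``Z_i ~ N(0,1)`` behind
each binary outcome (``Y_i = 1`` iff ``Z_i > 0``), regresses Z on the
gene-score design T with coefficients under a generalized Zellner g-prior
``beta | T ~ N(0, c (T'T)^+)`` (Moore-Penrose inverse, tolerating rank
deficiency from LD), an independent Bernoulli(pi) prior on the SNP
indicators gamma, and a Markov-random-field prior on the gene indicators xi,

    P(xi | mu, eta) ∝ exp(mu 1' xi + eta xi' R xi),

where R is the gene-network adjacency.  The coefficients are integrated out
analytically, leaving a kernel over (Z, xi, gamma) only.

Two conventions for the collapsed covariance are provided.  Marginalising
beta under the stated prior yields Sigma = c P_T + I (``derived``, the
default), where P_T is the orthogonal projector onto col(T); the alternative
``literal`` convention instead takes Sigma^{-1} = c P_T + I.  The two differ
only in the sign/role of c and both reduce to Sigma = I for the null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .data_model import GeneNetwork, GenotypeData
from .gene_summary import GeneScoreMatrix, build_design, check_consistency

CONVENTIONS = ("derived", "literal")

#: relative cutoff for treating a singular value of T as zero
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class Hyperparams:
    """Prior hyperparameters.

    pi : SNP prior inclusion probability, in (0,1).
    mu : MRF sparsity parameter (more negative -> sparser gene selection).
    eta : MRF smoothing parameter, >= 0 (rewards selecting network
        neighbours together; negative values are rejected to avoid
        phase-transition pathologies).
    c : g-prior scale, > 0, or the string ``"n"`` to use the sample size
        (unit-information prior).
    convention : collapsed-covariance convention, ``derived`` or ``literal``.
    pls_response : response the PLS components are computed against
        (``Y``: the observed outcome, fixed across the chain; ``Z``: the
        evolving latent liability).
    """

    pi: float = 0.01
    mu: float = -2.0
    eta: float = 0.8
    c: float | str = "n"
    convention: str = "derived"
    pls_response: str = "Y"

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0,1)")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.c != "n" and not (np.isreal(self.c) and self.c > 0):
            raise ValueError("c must be > 0 or 'n'")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.pls_response not in ("Y", "Z"):
            raise ValueError("pls_response must be 'Y' or 'Z'")

    def resolve_c(self, n: int) -> float:
        return float(n) if self.c == "n" else float(self.c)

    @classmethod
    def from_yaml(cls, path) -> "Hyperparams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


@dataclass
class ModelState:
    """Current MCMC state: indicators, latent liabilities, cached design."""

    xi: np.ndarray
    gamma: np.ndarray
    Z: np.ndarray
    design: GeneScoreMatrix | None = None
    #: cache of per-gene PLS scores keyed by (gene, selected-SNP tuple)
    score_cache: dict = field(default_factory=dict)

    def copy_indicators(self) -> tuple[np.ndarray, np.ndarray]:
        return self.xi.copy(), self.gamma.copy()


def log_prior_gamma(gamma: np.ndarray, pi: float) -> float:
    """Independent Bernoulli(pi) log prior of the SNP indicator vector."""
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must lie in (0,1)")
    gamma = np.asarray(gamma)
    k = int(gamma.sum())
    return k * np.log(pi) + (gamma.size - k) * np.log1p(-pi)


def log_prior_xi_unnorm(xi: np.ndarray, mu: float, eta: float,
                        R: np.ndarray) -> float:
    """Unnormalised MRF log prior mu 1'xi + eta xi'R xi.

    The quadratic form counts each edge with both endpoints selected twice,
    exactly as the multivariate form is written.
    """
    xi = np.asarray(xi, dtype=float)
    R = np.asarray(R)
    if R.shape != (xi.size, xi.size):
        raise ValueError("dimension mismatch between xi and R")
    return float(mu * xi.sum() + eta * (xi @ R @ xi))


def mrf_conditional_prob(j: int, xi: np.ndarray, mu: float, eta: float,
                         R: np.ndarray) -> float:
    """P(xi_j = 1 | xi_{-j}) implied by the multivariate MRF form.

    Because xi'R xi counts each edge twice, the conditional log-odds are
    ``mu + 2 eta * sum_{i in Nb_j} xi_i``.
    """
    s = float(np.asarray(R)[j] @ np.asarray(xi, dtype=float)) - \
        float(R[j, j] * xi[j])
    logodds = mu + 2.0 * eta * s
    return 1.0 / (1.0 + np.exp(-logodds))


def orthonormal_basis(T: np.ndarray) -> np.ndarray:
    """Orthonormal basis U of col(T); U is n x rank(T)."""
    if T.shape[1] == 0:
        return np.empty((T.shape[0], 0))
    U, s, _ = np.linalg.svd(T, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.empty((T.shape[0], 0))
    r = int(np.sum(s > _RANK_RTOL * s[0]))
    return U[:, :r]


def collapsed_log_marginal(T, Z: np.ndarray, c: float,
                           convention: str = "derived") -> float:
    """Log of the beta-integrated Gaussian factor, -(log|Sigma| + Z'Sigma^-1 Z)/2.

    ``T`` may be a :class:`GeneScoreMatrix` or a plain n x m array.  With
    m = rank(T) and P_T the projector onto col(T):

    - ``derived``  : Sigma = c P_T + I, so log|Sigma| = m log(1+c) and
      Z'Sigma^-1 Z = Z'Z - c/(1+c) * Z'P_T Z.
    - ``literal``  : Sigma^-1 = c P_T + I, so log|Sigma| = -m log(1+c) and
      Z'Sigma^-1 Z = Z'Z + c * Z'P_T Z.

    For m = 0 both give -Z'Z/2.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if isinstance(T, GeneScoreMatrix):
        T = T.T
    T = np.asarray(T, dtype=float)
    Z = np.asarray(Z, dtype=float)
    U = orthonormal_basis(T)
    m = U.shape[1]
    zz = float(Z @ Z)
    proj = float(np.sum((U.T @ Z) ** 2))  # Z' P_T Z
    if convention == "derived":
        logdet = m * np.log1p(c)
        quad = zz - c / (1.0 + c) * proj
    else:
        logdet = -m * np.log1p(c)
        quad = zz + c * proj
    return -0.5 * (logdet + quad)


def truncation_satisfied(Z: np.ndarray, Y: np.ndarray) -> bool:
    """Whether every liability agrees in sign with its outcome."""
    Z = np.asarray(Z)
    Y = np.asarray(Y)
    return bool(np.all((Z > 0) == (Y == 1)))


def log_posterior_kernel(state: ModelState, Y: np.ndarray,
                         geno: GenotypeData, net: GeneNetwork,
                         hp: Hyperparams) -> float:
    """Collapsed log posterior kernel of (Z, xi, gamma); -inf off-support."""
    check_consistency(geno, state.xi, state.gamma)
    if not truncation_satisfied(state.Z, Y):
        return -np.inf
    if state.design is None:
        response = Y if hp.pls_response == "Y" else state.Z
        state.design = build_design(geno, state.xi, state.gamma, response,
                                    score_cache=state.score_cache)
    c = hp.resolve_c(geno.n)
    return (collapsed_log_marginal(state.design, state.Z, c, hp.convention)
            + log_prior_gamma(state.gamma, hp.pi)
            + log_prior_xi_unnorm(state.xi, hp.mu, hp.eta, net.R))


def with_convention(hp: Hyperparams, convention: str) -> Hyperparams:
    return replace(hp, convention=convention)
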