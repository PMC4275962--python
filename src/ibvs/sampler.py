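"""MCMC posterior inference over (xi, gamma, Z).

Each iteration alternates

1. a Metropolis-Hastings update of the selection indicators using two move
   classes — (1) add/remove a gene together with one of its SNPs, and
   (2) add/remove a single SNP within the selected genes — and
2. a full Gibbs sweep of the latent liabilities Z, each coordinate drawn
   from its univariate normal conditional under N(0, Sigma) truncated to
   (0, inf) when Y_i = 1 and (-inf, 0] otherwise.

Truncated-normal draws use plain rejection from the normal when the
truncation boundary is favourable and an exponential-envelope rejection
sampler (Devroye/Robert) in the far tail, so the sweep is exact at any
truncation point.  The sweep exploits Sigma^{-1} = I + b U U' (U an
orthonormal basis of the design column space), so a full sweep costs
O(n * rank) after an O(n rank^2) factorisation per accepted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import GeneNetwork, GenotypeData, Phenotype
from .gene_summary import build_design
from .model import (Hyperparams, ModelState, collapsed_log_marginal,
                    log_prior_gamma, log_prior_xi_unnorm, orthonormal_basis)

try:  # optional JIT for the Z sweep (pure-python fallback is identical)
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


@dataclass
class ChainConfig:
    """MCMC run settings."""

    n_burnin: int = 10_000
    n_samples: int = 50_000
    seed: int = 0
    thin: int = 1
    move_probs: tuple = (0.5, 0.5)
    store_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_burnin < 0 or self.n_samples <= 0 or self.thin < 1:
            raise ValueError("iteration counts must be positive")
        if abs(sum(self.move_probs) - 1.0) > 1e-12:
            raise ValueError("move_probs must sum to 1")


@dataclass
class ChainOutput:
    """Posterior summaries and diagnostics of one chain."""

    pip_snp: np.ndarray
    pip_gene: np.ndarray
    acceptance: dict
    logker_trace: np.ndarray
    n_models_visited: int
    draws_gamma: np.ndarray | None = None
    draws_xi: np.ndarray | None = None
    config: ChainConfig | None = None


# ---------------------------------------------------------------- truncated N

@_njit(cache=False)
def _std_truncnorm_lower(a: float, rng) -> float:
    """Standard normal truncated to (a, inf), exact for any a."""
    if a <= 0.0:
        while True:  # acceptance probability >= 1/2
            x = rng.standard_normal()
            if x > a:
                return x
    # Robert's exponential-envelope rejection for a > 0
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        x = a + rng.standard_exponential() / alpha
        d = x - alpha
        if rng.random() <= math.exp(-0.5 * d * d):
            return x


@_njit(cache=False)
def _truncnorm_sign(mean: float, sd: float, positive: bool, rng) -> float:
    """N(mean, sd^2) truncated to (0, inf) if positive else (-inf, 0]."""
    if positive:
        a = (0.0 - mean) / sd
        return mean + sd * _std_truncnorm_lower(a, rng)
    a = mean / sd  # reflect: -X ~ N(-mean, sd^2) truncated to (0, inf)
    return -(-mean + sd * _std_truncnorm_lower(a, rng))


@_njit(cache=False)
def _gibbs_sweep(U, b, d, Z, ypos, rng):
    """In-place sweep of Z under precision Q = I + b U U' with diag d."""
    m = U.shape[1]
    w = U.T.copy() @ Z if m else np.zeros(0)
    n = Z.shape[0]
    for i in range(n):
        ui = U[i]
        qz_i = Z[i]
        if m:
            qz_i += b * np.dot(ui, w)
        mean = Z[i] - qz_i / d[i]
        sd = 1.0 / math.sqrt(d[i])
        z_new = _truncnorm_sign(mean, sd, ypos[i], rng)
        if m:
            w += ui * (z_new - Z[i])
        Z[i] = z_new
    return Z


def _precision_terms(U: np.ndarray, c: float, convention: str):
    """(b, d) with Sigma^{-1} = I + b U U' and d its diagonal."""
    b = c if convention == "literal" else -c / (1.0 + c)
    d = 1.0 + b * np.einsum("ij,ij->i", U, U)
    return b, d


def sample_Z(state: ModelState, Y, hp: Hyperparams, rng: np.random.Generator
             ) -> np.ndarray:
    """One full Gibbs sweep of the latent liabilities; updates state.Z."""
    Y = Y.Y if isinstance(Y, Phenotype) else np.asarray(Y)
    n = state.Z.shape[0]
    c = hp.resolve_c(n)
    T = state.design.T if state.design is not None else np.empty((n, 0))
    U = orthonormal_basis(T)
    b, d = _precision_terms(U, c, hp.convention)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise FloatingPointError("non-positive conditional variance; "
                                 "broken covariance convention")
    ypos = np.asarray(Y) == 1
    _gibbs_sweep(np.ascontiguousarray(U), b, d, state.Z, ypos, rng)
    return state.Z


# ------------------------------------------------------------------ proposals

def _counts(geno: GenotypeData, xi: np.ndarray, gamma: np.ndarray) -> dict:
    sel_g = np.flatnonzero(xi == 1)
    unsel_g = np.flatnonzero(xi == 0)
    sel_s = np.flatnonzero(gamma == 1)
    addable = np.flatnonzero((gamma == 0) & (xi[geno.gene_of_snp] == 1))
    return {"sel_g": sel_g, "unsel_g": unsel_g, "sel_s": sel_s,
            "addable": addable}


def _class_dir_logp(cnt: dict, move_probs, cls: int, add: bool) -> float:
    """log P(choose this class and direction) at a state with counts cnt."""
    c1 = cnt["unsel_g"].size > 0 or cnt["sel_g"].size > 0
    c2 = cnt["addable"].size > 0 or cnt["sel_s"].size > 0
    if cls == 1:
        p_cls = move_probs[0] if (c1 and c2) else 1.0
        both = cnt["unsel_g"].size > 0 and cnt["sel_g"].size > 0
    else:
        p_cls = move_probs[1] if (c1 and c2) else 1.0
        both = cnt["addable"].size > 0 and cnt["sel_s"].size > 0
    return math.log(p_cls) + (math.log(0.5) if both else 0.0)


def propose_move(state: ModelState, geno: GenotypeData,
                 rng: np.random.Generator, move_probs=(0.5, 0.5)):
    """Draw one MH proposal; returns (xi', gamma', log_ratio, move_class).

    ``log_ratio`` is log q(x|x') - log q(x'|x), summed over every move
    mechanism that can produce the transition.  A class-1 removal of a gene
    carrying >= 2 selected SNPs has no reverse move (nothing re-adds a gene
    with two SNPs at once) and returns -inf, so it is always rejected;
    the chain remains reversible.
    """
    xi, gamma = state.xi, state.gamma
    cnt = _counts(geno, xi, gamma)
    c1 = cnt["unsel_g"].size > 0 or cnt["sel_g"].size > 0
    c2 = cnt["addable"].size > 0 or cnt["sel_s"].size > 0
    if not (c1 or c2):
        raise RuntimeError("no legal move: empty problem")
    cls = 1 if rng.random() < move_probs[0] else 2
    if cls == 1 and not c1:
        cls = 2
    elif cls == 2 and not c2:
        cls = 1

    if cls == 1:
        can_add, can_rem = cnt["unsel_g"].size > 0, cnt["sel_g"].size > 0
    else:
        can_add, can_rem = cnt["addable"].size > 0, cnt["sel_s"].size > 0
    if can_add and can_rem:
        add = rng.random() < 0.5
    else:
        add = can_add

    xi2, gamma2 = xi.copy(), gamma.copy()
    sel_count = np.bincount(geno.gene_of_snp, weights=gamma,
                            minlength=geno.J).astype(int)

    if cls == 1 and add:
        j = int(cnt["unsel_g"][rng.integers(cnt["unsel_g"].size)])
        snps = geno.snps_of_gene(j)
        k = int(snps[rng.integers(snps.size)])
        xi2[j] = 1
        gamma2[k] = 1
        log_fwd = (_class_dir_logp(cnt, move_probs, 1, True)
                   - math.log(cnt["unsel_g"].size) - math.log(snps.size))
        cnt2 = _counts(geno, xi2, gamma2)
        # reverse: class-1 remove of gene j, plus class-2 remove of SNP k
        # (reclassified, since k is the gene's only selected SNP)
        log_rev = np.logaddexp(
            _class_dir_logp(cnt2, move_probs, 1, False)
            - math.log(cnt2["sel_g"].size),
            _class_dir_logp(cnt2, move_probs, 2, False)
            - math.log(cnt2["sel_s"].size))
        return xi2, gamma2, float(log_rev - log_fwd), 1

    if cls == 1 and not add:
        j = int(cnt["sel_g"][rng.integers(cnt["sel_g"].size)])
        members = geno.snps_of_gene(j)
        single = sel_count[j] == 1
        xi2[j] = 0
        gamma2[members] = 0
        log_fwd = (_class_dir_logp(cnt, move_probs, 1, False)
                   - math.log(cnt["sel_g"].size))
        if single:
            # same transition also reachable as a reclassified class-2 removal
            k = int(members[gamma[members] == 1][0])
            log_fwd = np.logaddexp(
                log_fwd,
                _class_dir_logp(cnt, move_probs, 2, False)
                - math.log(cnt["sel_s"].size))
            cnt2 = _counts(geno, xi2, gamma2)
            log_rev = (_class_dir_logp(cnt2, move_probs, 1, True)
                       - math.log(cnt2["unsel_g"].size)
                       - math.log(members.size))
            return xi2, gamma2, float(log_rev - log_fwd), 1
        return xi2, gamma2, -np.inf, 1  # no reverse move exists

    if cls == 2 and add:
        k = int(cnt["addable"][rng.integers(cnt["addable"].size)])
        gamma2[k] = 1
        log_fwd = (_class_dir_logp(cnt, move_probs, 2, True)
                   - math.log(cnt["addable"].size))
        cnt2 = _counts(geno, xi2, gamma2)
        log_rev = (_class_dir_logp(cnt2, move_probs, 2, False)
                   - math.log(cnt2["sel_s"].size))
        return xi2, gamma2, float(log_rev - log_fwd), 2

    # class 2 remove
    k = int(cnt["sel_s"][rng.integers(cnt["sel_s"].size)])
    j = int(geno.gene_of_snp[k])
    gamma2[k] = 0
    log_fwd = (_class_dir_logp(cnt, move_probs, 2, False)
               - math.log(cnt["sel_s"].size))
    if sel_count[j] == 1:
        # reclassified: removing the gene's last SNP removes the gene too;
        # identical transition to a class-1 removal of that gene
        xi2[j] = 0
        log_fwd = np.logaddexp(
            log_fwd,
            _class_dir_logp(cnt, move_probs, 1, False)
            - math.log(cnt["sel_g"].size))
        cnt2 = _counts(geno, xi2, gamma2)
        log_rev = (_class_dir_logp(cnt2, move_probs, 1, True)
                   - math.log(cnt2["unsel_g"].size)
                   - math.log(geno.snps_of_gene(j).size))
    else:
        cnt2 = _counts(geno, xi2, gamma2)
        log_rev = (_class_dir_logp(cnt2, move_probs, 2, True)
                   - math.log(cnt2["addable"].size))
    return xi2, gamma2, float(log_rev - log_fwd), 2


def mh_accept(current_logker: float, proposal_logker: float,
              log_ratio: float, rng: np.random.Generator) -> bool:
    """Metropolis-Hastings accept with probability min(1, exp(delta))."""
    if not np.isfinite(current_logker):
        raise ValueError("current kernel must be finite")
    delta = proposal_logker - current_logker + log_ratio
    if delta >= 0:
        return True
    if delta == -np.inf:
        return False
    return math.log(rng.random()) < delta


# ----------------------------------------------------------------- the chain

def initial_state(geno: GenotypeData, Y: np.ndarray,
                  rng: np.random.Generator) -> ModelState:
    """Null model with half-normal liabilities matching the outcome signs."""
    Z = np.abs(rng.standard_normal(geno.n))
    Z[np.asarray(Y) == 0] *= -1.0
    # Y=0 requires Z <= 0; flip exact zeros into the open negative half-line
    Z[Z == 0.0] = -1e-12
    return ModelState(np.zeros(geno.J, dtype=np.int8),
                      np.zeros(geno.P, dtype=np.int8), Z)


def run_chain(geno: GenotypeData, Y, net: GeneNetwork, hp: Hyperparams,
              cfg: ChainConfig) -> ChainOutput:
    """Run one MCMC chain and return posterior inclusion probabilities."""
    Y = Y.Y if isinstance(Y, Phenotype) else np.asarray(Y)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    c = hp.resolve_c(geno.n)
    # with the evolving latent Z as PLS response the per-gene score cache
    # would go stale, so it is disabled in that mode
    use_cache = hp.pls_response == "Y"
    state = initial_state(geno, Y, rng)
    cache = state.score_cache if use_cache else None
    state.design = build_design(geno, state.xi, state.gamma, Y,
                                score_cache=cache)
    U = orthonormal_basis(state.design.T)
    b, d = _precision_terms(U, c, hp.convention)
    lp_gamma = log_prior_gamma(state.gamma, hp.pi)
    lp_xi = log_prior_xi_unnorm(state.xi, hp.mu, hp.eta, net.R)

    n_iter = cfg.n_burnin + cfg.n_samples
    pip_snp = np.zeros(geno.P)
    pip_gene = np.zeros(geno.J)
    trace = np.empty(n_iter)
    acc = {1: [0, 0], 2: [0, 0]}  # class -> [accepted, proposed]
    seen = set()
    draws_g = (np.empty((cfg.n_samples // cfg.thin, geno.P), dtype=np.uint8)
               if cfg.store_draws else None)
    draws_x = (np.empty((cfg.n_samples // cfg.thin, geno.J), dtype=np.uint8)
               if cfg.store_draws else None)
    n_stored = 0
    ypos = Y == 1

    for it in range(n_iter):
        # --- MH update of (xi, gamma) -------------------------------------
        if not use_cache:  # Z moved last sweep: refresh the design
            state.design = build_design(geno, state.xi, state.gamma,
                                        state.Z)
            U = orthonormal_basis(state.design.T)
            b, d = _precision_terms(U, c, hp.convention)
        cur_marg = collapsed_log_marginal(state.design.T, state.Z, c,
                                          hp.convention)
        cur_ker = cur_marg + lp_gamma + lp_xi
        xi2, gamma2, log_ratio, cls = propose_move(state, geno, rng,
                                                   cfg.move_probs)
        acc[cls][1] += 1
        if np.isfinite(log_ratio):
            resp = Y if use_cache else state.Z
            design2 = build_design(geno, xi2, gamma2, resp,
                                   score_cache=cache)
            lp_gamma2 = log_prior_gamma(gamma2, hp.pi)
            lp_xi2 = log_prior_xi_unnorm(xi2, hp.mu, hp.eta, net.R)
            prop_ker = (collapsed_log_marginal(design2.T, state.Z, c,
                                               hp.convention)
                        + lp_gamma2 + lp_xi2)
            if mh_accept(cur_ker, prop_ker, log_ratio, rng):
                acc[cls][0] += 1
                state.xi, state.gamma, state.design = xi2, gamma2, design2
                lp_gamma, lp_xi = lp_gamma2, lp_xi2
                cur_ker = prop_ker
                U = orthonormal_basis(state.design.T)
                b, d = _precision_terms(U, c, hp.convention)

        # --- Gibbs sweep of Z ---------------------------------------------
        _gibbs_sweep(np.ascontiguousarray(U), b, d, state.Z, ypos, rng)

        trace[it] = (collapsed_log_marginal(state.design.T, state.Z, c,
                                            hp.convention)
                     + lp_gamma + lp_xi)
        if it >= cfg.n_burnin:
            pip_snp += state.gamma
            pip_gene += state.xi
            seen.add(state.gamma.tobytes())
            s = it - cfg.n_burnin
            if cfg.store_draws and s % cfg.thin == 0 and n_stored < len(draws_g):
                draws_g[n_stored] = state.gamma
                draws_x[n_stored] = state.xi
                n_stored += 1

    pip_snp /= cfg.n_samples
    pip_gene /= cfg.n_samples
    acceptance = {cls: (a / p if p else np.nan) for cls, (a, p) in acc.items()}
    return ChainOutput(pip_snp, pip_gene, acceptance, trace, len(seen),
                       draws_g, draws_x, cfg)


def split_rhat(traces: np.ndarray) -> float:
    """Split-R-hat of scalar chain traces (chains x draws)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    half = traces.shape[1] // 2
    halves = np.vstack([traces[:, :half], traces[:, half:2 * half]])
    m, n = halves.shape
    means = halves.mean(axis=1)
    B = n * means.var(ddof=1)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return np.inf if B > 0 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def run_chains(geno: GenotypeData, Y, net: GeneNetwork, hp: Hyperparams,
               cfg: ChainConfig, n_chains: int = 4):
    """Independent chains from per-chain seeds; returns (outputs, diagnostics).

    Diagnostics carry the split-R-hat of the post-burn-in log-kernel trace
    and the across-chain pooled PIPs.
    """
    outs = []
    for k in range(n_chains):
        seed = int(np.random.SeedSequence([cfg.seed, k]).generate_state(1)[0]
                   % (2 ** 31))
        cfg_k = ChainConfig(cfg.n_burnin, cfg.n_samples, seed, cfg.thin,
                            cfg.move_probs, cfg.store_draws)
        outs.append(run_chain(geno, Y, net, hp, cfg_k))
    traces = np.vstack([o.logker_trace[cfg.n_burnin:] for o in outs])
    diag = {"split_rhat_logkernel": split_rhat(traces),
            "pip_snp_pooled": np.mean([o.pip_snp for o in outs], axis=0),
            "pip_gene_pooled": np.mean([o.pip_gene for o in outs], axis=0)}
    return outs, diag
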