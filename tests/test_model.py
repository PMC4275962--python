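import itertools

import numpy as np
import pytest

from ibvs import (GeneNetwork, Hyperparams, ModelState,
                  collapsed_log_marginal, log_posterior_kernel,
                  log_prior_gamma, log_prior_xi_unnorm)
from ibvs.gene_summary import build_design
from ibvs.model import mrf_conditional_prob

from conftest import consistent_models_2x2


def dense_marginal_oracle(T, Z, c, convention):
    """Brute-force: form Sigma explicitly, invert, slogdet."""
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    P_T = T @ np.linalg.pinv(T.T @ T) @ T.T if T.shape[1] else np.zeros((n, n))
    if convention == "derived":
        Sigma = c * P_T + np.eye(n)
    else:
        Sigma = np.linalg.inv(c * P_T + np.eye(n))
    sign, logdet = np.linalg.slogdet(Sigma)
    assert sign > 0
    return -0.5 * (logdet + Z @ np.linalg.solve(Sigma, Z))


class TestPriors:
    def test_gamma_prior_closed_forms(self):
        assert log_prior_gamma(np.zeros(4, dtype=int), 0.5) == \
            pytest.approx(4 * np.log(0.5))
        g = np.zeros(3388, dtype=int)
        g[7] = 1
        assert log_prior_gamma(g, 0.01) == \
            pytest.approx(np.log(0.01) + 3387 * np.log(0.99))

    def test_gamma_prior_normalizes_by_enumeration(self):
        P, pi = 10, 0.23
        tot = sum(np.exp(log_prior_gamma(np.array(g), pi))
                  for g in itertools.product([0, 1], repeat=P))
        assert tot == pytest.approx(1.0, abs=1e-12)

    def test_mrf_prior_values(self):
        R = np.array([[0, 1], [1, 0]])
        assert log_prior_xi_unnorm(np.zeros(2), -2.0, 0.8, R) == 0.0
        # both genes selected: mu*2 + eta * (edge counted twice)
        assert log_prior_xi_unnorm(np.ones(2), -2.0, 0.8, R) == \
            pytest.approx(-4 + 0.8 * 2)

    @pytest.mark.parametrize("J", [2, 3, 4])
    def test_mrf_joint_conditional_consistency_all_networks(self, J):
        """Conditionals derived from the joint match the closed form
        with the doubled interaction coefficient, for every network."""
        mu, eta = -1.2, 0.7
        n_edges = J * (J - 1) // 2
        pairs = list(itertools.combinations(range(J), 2))
        for mask in range(2 ** n_edges):
            R = np.zeros((J, J), dtype=int)
            for b, (i, j) in enumerate(pairs):
                if mask >> b & 1:
                    R[i, j] = R[j, i] = 1
            states = [np.array(s) for s in
                      itertools.product([0, 1], repeat=J)]
            w = np.array([np.exp(log_prior_xi_unnorm(s, mu, eta, R))
                          for s in states])
            w /= w.sum()
            for j in range(J):
                for s in states:
                    s1, s0 = s.copy(), s.copy()
                    s1[j], s0[j] = 1, 0
                    p1 = w[[np.array_equal(t, s1) for t in states].index(True)]
                    p0 = w[[np.array_equal(t, s0) for t in states].index(True)]
                    cond = p1 / (p1 + p0)
                    assert cond == pytest.approx(
                        mrf_conditional_prob(j, s, mu, eta, R), abs=1e-12)

    def test_hyperparam_validation(self):
        with pytest.raises(ValueError):
            Hyperparams(pi=1.5)
        with pytest.raises(ValueError):
            Hyperparams(eta=-0.1)
        with pytest.raises(ValueError):
            Hyperparams(c=-3)
        assert Hyperparams(c="n").resolve_c(200) == 200.0


class TestCollapsedMarginal:
    def test_null_model_is_half_squared_norm(self, rng):
        Z = rng.standard_normal(7)
        for conv in ("derived", "literal"):
            assert collapsed_log_marginal(np.empty((7, 0)), Z, 5.0, conv) \
                == pytest.approx(-0.5 * Z @ Z)

    @pytest.mark.parametrize("convention", ["derived", "literal"])
    def test_matches_dense_oracle_on_random_instances(self, convention):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(2, 13)
            m = rng.integers(0, 5)
            T = rng.standard_normal((n, m))
            if m >= 2 and rng.random() < 0.3:
                T[:, -1] = T[:, 0]  # force rank deficiency
            Z = rng.standard_normal(n)
            c = float(rng.uniform(0.5, 50))
            got = collapsed_log_marginal(T, Z, c, convention)
            want = dense_marginal_oracle(T, Z, c, convention)
            assert got == pytest.approx(want, abs=1e-8)

    def test_duplicated_column_leaves_value_unchanged(self, rng):
        T = rng.standard_normal((8, 2))
        Z = rng.standard_normal(8)
        T2 = np.column_stack([T, T[:, 0]])
        for conv in ("derived", "literal"):
            assert collapsed_log_marginal(T, Z, 3.0, conv) == \
                pytest.approx(collapsed_log_marginal(T2, Z, 3.0, conv),
                              abs=1e-10)


class TestPosteriorKernel:
    def test_truncation_violation_gives_minus_inf(self, toy_geno, toy_y,
                                                  toy_net):
        hp = Hyperparams(pi=0.2, c=5.0)
        Z = np.array([-1.0, 1.0, 1.0, -1.0, -1.0, -1.0])  # Z_1<0 but Y_1=1
        st = ModelState(np.zeros(2, dtype=np.int8), np.zeros(4, dtype=np.int8), Z)
        assert log_posterior_kernel(st, toy_y.Y, toy_geno, toy_net, hp) \
            == -np.inf

    def test_null_model_closed_form(self, toy_geno, toy_y, toy_net):
        hp = Hyperparams(pi=0.2, c=5.0)
        Z = np.where(toy_y.Y == 1, 0.5, -0.5)
        st = ModelState(np.zeros(2, dtype=np.int8), np.zeros(4, dtype=np.int8), Z)
        got = log_posterior_kernel(st, toy_y.Y, toy_geno, toy_net, hp)
        assert got == pytest.approx(-0.5 * Z @ Z + 4 * np.log(0.8))

    def test_inconsistent_state_raises_not_minus_inf(self, toy_geno, toy_y,
                                                     toy_net):
        hp = Hyperparams()
        Z = np.where(toy_y.Y == 1, 0.5, -0.5)
        st = ModelState(np.array([1, 0], dtype=np.int8),
                        np.zeros(4, dtype=np.int8), Z)
        with pytest.raises(ValueError):
            log_posterior_kernel(st, toy_y.Y, toy_geno, toy_net, hp)

    def test_enumeration_ranks_states_like_manual_kernel(self, toy_geno,
                                                         toy_y, toy_net):
        """Exhaustive toy enumeration: module kernel equals the sum of its
        three factors computed independently, for every consistent state."""
        hp = Hyperparams(pi=0.3, mu=-0.5, eta=0.4, c=4.0)
        Z = np.where(toy_y.Y == 1, 0.8, -0.8)
        vals, manual = [], []
        for xi, gam in consistent_models_2x2():
            st = ModelState(xi.astype(np.int8), gam.astype(np.int8), Z.copy())
            vals.append(log_posterior_kernel(st, toy_y.Y, toy_geno, toy_net,
                                             hp))
            T = build_design(toy_geno, xi, gam, toy_y.Y).T
            manual.append(collapsed_log_marginal(T, Z, 4.0)
                          + log_prior_gamma(gam, 0.3)
                          + log_prior_xi_unnorm(xi, -0.5, 0.4, toy_net.R))
        np.testing.assert_allclose(vals, manual, atol=1e-10)
        assert np.argsort(vals).tolist() == np.argsort(manual).tolist()

    def test_gene_relabeling_invariance(self, rng):
        """Permuting gene labels consistently leaves the kernel unchanged."""
        from ibvs import GenotypeData
        X = rng.integers(0, 3, (8, 6))
        gene_of = np.array([0, 0, 1, 1, 2, 2])
        geno = GenotypeData(X, list("abcdefgh"),
                            [f"p{i}" for i in range(6)], gene_of,
                            ["g0", "g1", "g2"])
        R = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        net = GeneNetwork(R, ["g0", "g1", "g2"])
        Y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        Z = np.where(Y == 1, 0.7, -0.7)
        hp = Hyperparams(pi=0.2, mu=-1.0, eta=0.5, c=3.0)
        xi = np.array([1, 0, 1], dtype=np.int8)
        gam = np.array([1, 0, 0, 0, 1, 1], dtype=np.int8)
        base = log_posterior_kernel(ModelState(xi, gam, Z.copy()), Y, geno,
                                    net, hp)
        perm = np.array([2, 0, 1])  # new label of each old gene
        order = np.argsort(perm)
        geno_p = GenotypeData(X, list("abcdefgh"),
                              [f"p{i}" for i in range(6)],
                              perm[gene_of], [f"h{j}" for j in range(3)])
        net_p = GeneNetwork(R[np.ix_(order, order)],
                            [f"h{j}" for j in range(3)])
        got = log_posterior_kernel(
            ModelState(xi[order], gam, Z.copy()), Y, geno_p, net_p, hp)
        assert got == pytest.approx(base, abs=1e-10)
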