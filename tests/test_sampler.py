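import numpy as np
import pytest

from ibvs import ChainConfig, Hyperparams, ModelState, Phenotype, run_chain
from ibvs.gene_summary import build_design
from ibvs.sampler import initial_state, mh_accept, propose_move, sample_Z


class TestProposeMove:
    def test_null_model_only_gene_add_is_legal(self, toy_geno, rng):
        st = ModelState(np.zeros(2, dtype=np.int8), np.zeros(4, dtype=np.int8),
                        np.zeros(6))
        for _ in range(50):
            xi2, g2, _, cls = propose_move(st, toy_geno, rng)
            assert cls == 1
            assert xi2.sum() == 1 and g2.sum() == 1
            # the added SNP belongs to the added gene
            j = int(np.flatnonzero(xi2)[0])
            assert toy_geno.gene_of_snp[int(np.flatnonzero(g2)[0])] == j

    def test_removing_last_snp_unselects_gene(self, toy_geno, rng):
        # gene 0 selected with exactly one SNP; force class-2 removals
        st = ModelState(np.array([1, 0], dtype=np.int8),
                        np.array([1, 0, 0, 0], dtype=np.int8), np.zeros(6))
        seen_gene_removal = False
        for _ in range(200):
            xi2, g2, r, cls = propose_move(st, toy_geno, rng)
            if cls == 2 and g2.sum() == 0:
                assert xi2.sum() == 0  # reclassified to gene removal
                seen_gene_removal = True
        assert seen_gene_removal

    def test_multi_snp_gene_removal_has_no_reverse(self, toy_geno, rng):
        st = ModelState(np.array([1, 0], dtype=np.int8),
                        np.array([1, 1, 0, 0], dtype=np.int8), np.zeros(6))
        saw = False
        for _ in range(300):
            xi2, g2, r, cls = propose_move(st, toy_geno, rng)
            if cls == 1 and xi2.sum() == 0:
                assert r == -np.inf
                saw = True
        assert saw

    def test_proposal_log_ratio_antisymmetric(self, toy_geno, rng):
        """q-ratio of a move equals minus the ratio of its reverse."""
        st = ModelState(np.zeros(2, dtype=np.int8), np.zeros(4, dtype=np.int8),
                        np.zeros(6))
        checked = 0
        for _ in range(300):
            xi2, g2, r, _ = propose_move(st, toy_geno, rng)
            if not np.isfinite(r):
                continue
            st2 = ModelState(xi2, g2, np.zeros(6))
            for _ in range(500):
                xi3, g3, r2, _ = propose_move(st2, toy_geno, rng)
                if np.array_equal(xi3, st.xi) and np.array_equal(g3, st.gamma):
                    assert r2 == pytest.approx(-r, abs=1e-12)
                    checked += 1
                    break
            st = st2 if rng.random() < 0.5 else st
            if checked > 20:
                break
        assert checked > 5


class TestMHAccept:
    def test_certain_accept_and_reject(self, rng):
        assert mh_accept(-5.0, np.inf, 0.0, rng)
        assert not mh_accept(-5.0, -np.inf, 0.0, rng)
        assert mh_accept(0.0, np.log(2.0), 0.0, rng)  # min(1,2) = 1

    def test_acceptance_frequency_matches_ratio(self, rng):
        # delta = log(0.3): acceptance frequency should approach 0.3
        acc = sum(mh_accept(0.0, np.log(0.3), 0.0, rng) for _ in range(20000))
        assert acc / 20000 == pytest.approx(0.3, abs=0.02)


class TestSampleZ:
    def test_half_normal_mean_under_null_model(self):
        """Null model: Z_i | Y_i=1 is half-normal with mean sqrt(2/pi)."""
        rng = np.random.default_rng(5)
        n = 100_000
        Y = np.ones(n, dtype=np.int8)
        st = ModelState(np.zeros(1, dtype=np.int8), np.zeros(1, dtype=np.int8),
                        np.full(n, 0.5))
        hp = Hyperparams(c=5.0)
        sample_Z(st, Y, hp, rng)
        want = np.sqrt(2 / np.pi)
        se = np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(st.Z.mean() - want) < 3 * se

    def test_truncation_support_respected(self, rng):
        n = 500
        Y = (np.arange(n) % 2).astype(np.int8)
        st = ModelState(np.zeros(1, dtype=np.int8), np.zeros(1, dtype=np.int8),
                        np.where(Y == 1, 0.1, -0.1).astype(float))
        sample_Z(st, Y, Hyperparams(c=2.0), rng)
        assert np.all((st.Z > 0) == (Y == 1))

    def test_correlated_bivariate_moments_match_quadrature(self):
        """n=2 with one shared design column: Gibbs moments vs numerical
        integration of the truncated bivariate normal."""
        from scipy import integrate, stats
        T = np.array([[1.0], [1.0]])
        c = 3.0
        U = T / np.linalg.norm(T)
        Sigma = np.eye(2) + c * (U @ U.T)
        Y = np.array([1, 1], dtype=np.int8)
        pdf = stats.multivariate_normal(np.zeros(2), Sigma).pdf

        norm_c, _ = integrate.dblquad(lambda y, x: pdf([x, y]), 0, 12,
                                      0, 12)
        m1, _ = integrate.dblquad(lambda y, x: x * pdf([x, y]), 0, 12,
                                  0, 12)
        want = m1 / norm_c

        rng = np.random.default_rng(17)
        st = ModelState(np.ones(1, dtype=np.int8), np.ones(1, dtype=np.int8),
                        np.array([0.5, 0.5]))
        from ibvs.gene_summary import GeneScoreMatrix
        st.design = GeneScoreMatrix(T, [np.array([1.0])], [0],
                                    [np.array([0])])
        hp = Hyperparams(c=c)
        draws = []
        for _ in range(40_000):
            sample_Z(st, Y, hp, rng)
            draws.append(st.Z[0])
        draws = np.asarray(draws)
        se = draws.std() / np.sqrt(len(draws) / 5)  # autocorrelation slack
        assert draws.mean() == pytest.approx(want, abs=max(3 * se, 0.02))


class TestRunChain:
    def test_same_seed_reproduces_everything(self, toy_geno, toy_y, toy_net):
        hp = Hyperparams(pi=0.2, c=5.0)
        cfg = ChainConfig(n_burnin=200, n_samples=800, seed=99,
                          store_draws=True)
        a = run_chain(toy_geno, toy_y, toy_net, hp, cfg)
        b = run_chain(toy_geno, toy_y, toy_net, hp, cfg)
        np.testing.assert_array_equal(a.pip_snp, b.pip_snp)
        np.testing.assert_array_equal(a.logker_trace, b.logker_trace)
        np.testing.assert_array_equal(a.draws_gamma, b.draws_gamma)

    def test_gene_pip_dominates_its_snps(self, toy_geno, toy_y, toy_net):
        hp = Hyperparams(pi=0.2, c=5.0)
        out = run_chain(toy_geno, toy_y, toy_net, hp,
                        ChainConfig(n_burnin=500, n_samples=3000, seed=3))
        for j in range(toy_geno.J):
            snps = toy_geno.snps_of_gene(j)
            assert out.pip_gene[j] >= out.pip_snp[snps].max() - 1e-12
        assert np.all(out.pip_snp >= 0) and np.all(out.pip_snp <= 1)

    def test_chain_accepts_gene_moves_on_signal(self, rng):
        """A dataset with real signal must see accepted class-1 moves."""
        from ibvs import GenotypeData
        n = 80
        X = rng.integers(0, 3, (n, 6))
        liab = (X[:, 0] - X[:, 0].mean()) * 1.5 + rng.standard_normal(n)
        Y = Phenotype((liab > 0).astype(np.int8))
        geno = GenotypeData(X, [f"s{i}" for i in range(n)],
                            [f"p{k}" for k in range(6)],
                            np.repeat([0, 1], 3), ["gA", "gB"])
        from ibvs import GeneNetwork
        out = run_chain(geno, Y, GeneNetwork.empty(["gA", "gB"]),
                        Hyperparams(pi=0.1, c="n"),
                        ChainConfig(n_burnin=500, n_samples=3000, seed=8))
        assert out.acceptance[1] > 0
        assert out.pip_snp[0] > 0.5


def test_multi_chain_rhat_near_one_on_toy(toy_geno, toy_y, toy_net):
    from ibvs.sampler import run_chains, split_rhat
    hp = Hyperparams(pi=0.2, c=5.0)
    outs, diag = run_chains(toy_geno, toy_y, toy_net, hp,
                            ChainConfig(n_burnin=500, n_samples=4000,
                                        seed=2), n_chains=3)
    assert len(outs) == 3
    assert diag["split_rhat_logkernel"] < 1.1  # fast-mixing toy
    assert split_rhat(np.vstack([np.ones(100), np.zeros(100)])) > 2.0


def test_initial_state_is_null_and_sign_consistent(toy_geno, rng):
    Y = np.array([1, 0, 1, 0, 1, 0])
    st = initial_state(toy_geno, Y, rng)
    assert st.xi.sum() == 0 and st.gamma.sum() == 0
    assert np.all((st.Z > 0) == (Y == 1))
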