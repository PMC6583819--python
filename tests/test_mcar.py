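"""CAR precision algebra, the joint log posterior, and the MCAR sampler."""

import numpy as np
import pytest
from scipy import sparse, stats
from scipy.special import gammaln

import smallcounts as sc
from smallcounts.mcar import MCARHyper, MCARState


def _graph(pairs, areas):
    nbrs = {a: set() for a in areas}
    for a, b in pairs:
        nbrs[a].add(b)
        nbrs[b].add(a)
    return sc.AdjacencyGraph(tuple(areas), {a: frozenset(v) for a, v in nbrs.items()})


class TestCarPrecision:
    def test_path_graph_definition(self):
        g = _graph([("A", "B")], ("A", "B"))
        M = sc.car_precision(g, 0.9).toarray()
        np.testing.assert_allclose(M, [[1.0, -0.9], [-0.9, 1.0]])

    def test_alpha_zero_is_diagonal_of_degrees(self):
        g = sc.make_lattice(3, 3)
        M = sc.car_precision(g, 0.0).toarray()
        deg = [g.degree[a] for a in g.areas]
        np.testing.assert_allclose(M, np.diag(deg))

    def test_positive_definite_near_alpha_one_on_lattice(self):
        g = sc.make_lattice(5, 5)
        M = sc.car_precision(g, 0.99).toarray()
        assert np.linalg.eigvalsh(M).min() > 0

    def test_alpha_out_of_range(self):
        g = sc.make_lattice(2, 2)
        with pytest.raises(ValueError):
            sc.car_precision(g, 1.0)
        with pytest.raises(ValueError):
            sc.car_precision(g, -0.1)


def _brute_log_posterior(state, censored, graph, hyper):
    """Straight-line reimplementation: scalar log-pmfs plus quadratic forms."""
    total = 0.0
    y = censored.observed.astype(float).copy()
    for (i, k), v in zip(np.argwhere(censored.suppressed), state.imputed):
        y[i, k] = v
    lam = np.exp(state.beta0[None, :] + state.z + state.phi)
    for i in range(censored.I):
        for k in range(censored.K):
            mu = censored.n[i, k] * lam[i, k]
            total += y[i, k] * np.log(mu) - mu - gammaln(y[i, k] + 1)
    order = censored.area_ids
    M = sc.car_precision(graph, state.alpha, order=order).toarray()
    deg = np.array([graph.degree[a] for a in order])
    nz = deg > 0
    K = censored.K
    Mnn = M[np.ix_(nz, nz)]
    Z = state.z[nz]
    quad = 0.0
    for a in range(Z.shape[0]):
        for b in range(Z.shape[0]):
            quad += Mnn[a, b] * Z[a] @ state.Lambda @ Z[b]
    total += 0.5 * K * np.linalg.slogdet(Mnn)[1]
    total += 0.5 * Z.shape[0] * np.linalg.slogdet(state.Lambda)[1]
    total -= 0.5 * quad + 0.5 * Z.shape[0] * K * np.log(2 * np.pi)
    for i in np.where(~nz)[0]:
        total += stats.norm.logpdf(state.z[i], 0, np.sqrt(hyper.iso_var)).sum()
    for k in range(K):
        total += stats.norm.logpdf(state.phi[:, k], 0, np.sqrt(state.sigma2[k])).sum()
    total += stats.norm.logpdf(state.beta0, 0, hyper.beta0_sd).sum()
    total += stats.wishart.logpdf(state.Lambda, K + 1, np.eye(K))
    total += stats.invgamma.logpdf(state.sigma2, 0.5, scale=0.0005).sum()
    return float(total)


class TestLogPosterior:
    def _random_state(self, I, K, n_sup, rng):
        L = rng.standard_normal((K, K))
        Lam = L @ L.T + K * np.eye(K)
        return MCARState(
            beta0=rng.standard_normal(K) - 5,
            z=rng.standard_normal((I, K)) * 0.3,
            phi=rng.standard_normal((I, K)) * 0.1,
            Lambda=Lam,
            alpha=0.7,
            sigma2=np.abs(rng.standard_normal(K)) + 0.05,
            imputed=rng.integers(0, 10, n_sup),
        )

    def test_matches_brute_force_on_lattice(self):
        rng = np.random.default_rng(4)
        g = sc.make_lattice(3, 3)
        t = sc.SimConfig(nrow=3, ncol=3, seed=4)
        table, _ = sc.simulate_table(t)
        censored = sc.apply_suppression(table, threshold=10)
        state = self._random_state(9, 3, censored.n_suppressed(), rng)
        hyper = MCARHyper()
        mine = sc.log_posterior(state, censored, g, hyper)
        brute = _brute_log_posterior(state, censored, g, hyper)
        assert mine == pytest.approx(brute, abs=1e-8)

    def test_single_cell_likelihood_at_mode(self):
        c = sc.CensoredCountTable(
            ("A",), {"A": "S"}, ("g",),
            np.array([[7]]), np.array([[100]]), np.array([[False]]),
            threshold=1, zero_visible=True,
        )
        g = _graph([], ("A",))
        state = MCARState(
            beta0=np.array([np.log(7 / 100)]),
            z=np.zeros((1, 1)), phi=np.zeros((1, 1)),
            Lambda=np.eye(1), alpha=0.0, sigma2=np.array([1.0]),
            imputed=np.zeros(0, dtype=int),
        )
        lp = sc.log_posterior(state, c, g)
        assert np.isfinite(lp)
        # doubling n with lambda fixed changes only the likelihood term
        c2 = sc.CensoredCountTable(
            ("A",), {"A": "S"}, ("g",),
            np.array([[7]]), np.array([[200]]), np.array([[False]]),
            threshold=1, zero_visible=True,
        )
        lp2 = sc.log_posterior(state, c2, g)
        assert lp2 - lp == pytest.approx(
            stats.poisson.logpmf(7, 14.0) - stats.poisson.logpmf(7, 7.0)
        )

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            MCARState(
                beta0=np.zeros(1), z=np.zeros((1, 1)), phi=np.zeros((1, 1)),
                Lambda=np.eye(1), alpha=1.2, sigma2=np.array([1.0]),
                imputed=np.zeros(0, dtype=int),
            )
        with pytest.raises(np.linalg.LinAlgError):
            MCARState(
                beta0=np.zeros(2), z=np.zeros((1, 2)), phi=np.zeros((1, 2)),
                Lambda=np.array([[1.0, 2.0], [2.0, 1.0]]), alpha=0.5,
                sigma2=np.ones(2), imputed=np.zeros(0, dtype=int),
            )


class TestFitMcar:
    def test_symmetry_identical_neighboring_areas(self):
        c = sc.CensoredCountTable(
            ("A", "B"), {"A": "S", "B": "S"}, ("g",),
            np.array([[20], [20]]), np.array([[500], [500]]),
            np.zeros((2, 1), bool),
        )
        g = _graph([("A", "B")], ("A", "B"))
        post = sc.fit_mcar(
            c, g, mcmc=sc.MCMCConfig(chains=1, burnin=1000, draws=8000, seed=2)
        )
        ks = stats.ks_2samp(post.lam[:, 0, 0], post.lam[:, 1, 0])
        assert ks.pvalue > 0.01

    def test_reduced_single_cell_model_self_consistent(self):
        # one isolated area, K=1: the model collapses to a log-normal-
        # Poisson cell; two independent long runs must agree
        c = sc.CensoredCountTable(
            ("A",), {"A": "S"}, ("g",),
            np.array([[30]]), np.array([[1000]]), np.array([[False]]),
        )
        g = _graph([], ("A",))
        mc1 = sc.MCMCConfig(chains=1, burnin=2000, draws=15000, seed=31)
        mc2 = sc.MCMCConfig(chains=1, burnin=2000, draws=15000, seed=77)
        a = sc.fit_mcar(c, g, mcmc=mc1).lam[:, 0, 0]
        b = sc.fit_mcar(c, g, mcmc=mc2).lam[:, 0, 0]
        def mcse(x):
            # batch-means standard error to account for autocorrelation
            nb = 30
            bm = x[: (x.size // nb) * nb].reshape(nb, -1).mean(axis=1)
            return bm.std(ddof=1) / np.sqrt(nb)
        diff = abs(a.mean() - b.mean())
        assert diff < 3 * np.hypot(mcse(a), mcse(b))

    def test_determinism_given_seed(self, small_study):
        mc = sc.MCMCConfig(chains=2, burnin=100, draws=200, seed=8)
        a = sc.fit_mcar(small_study.censored, small_study.graph, mcmc=mc)
        b = sc.fit_mcar(small_study.censored, small_study.graph, mcmc=mc)
        np.testing.assert_array_equal(a.lam, b.lam)
        np.testing.assert_array_equal(a.imputed, b.imputed)
        assert (a.lam > 0).all()

    def test_spatial_shrinkage_pulls_suppressed_cell_up(self):
        # a suppressed cell surrounded by high-rate neighbors: the MCAR
        # posterior median should exceed that of a flat-prior Poisson-gamma
        # fit, which has no neighbors to borrow from
        rng = np.random.default_rng(0)
        g = sc.make_lattice(3, 3)
        areas = g.areas
        n = np.full((9, 1), 150)
        y = np.full((9, 1), 25)  # high observed rates all around
        y[4, 0] = 5  # center cell, suppressed below 10
        state_of = {a: "S" for a in areas}
        table = sc.CountTable(areas, state_of, ("g",), y, n)
        censored = sc.apply_suppression(table, threshold=10)
        assert censored.suppressed[4, 0] and censored.n_suppressed() == 1
        mc = sc.MCMCConfig(chains=1, burnin=2000, draws=6000, seed=13)
        post_mcar = sc.fit_mcar(censored, g, mcmc=mc)
        flat = sc.PriorTable({("S", "g"): 0.01}, {("S", "g"): 0.1})
        post_pg = sc.fit_poisson_gamma(censored, flat, mc)
        med_mcar = np.median(post_mcar.lam[:, 4, 0])
        med_pg = np.median(post_pg.lam[:, 4, 0])
        assert med_mcar > med_pg
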