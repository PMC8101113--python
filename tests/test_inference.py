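"""MCMC correctness: oracles, conjugacy, recovery and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from bymmap import (
    AdjacencyGraph,
    McmcConfig,
    ModelSpec,
    SimulationConfig,
    compute_expected_counts,
    fit,
    fit_nonspatial_mle,
    gelman_rubin,
    lattice_graph,
    log_posterior,
    simulate_dataset,
    simulate_icar_field,
)
from bymmap.graph import icar_quadratic_form
from bymmap.inference import InferenceError, PosteriorDraws
from tests.conftest import draws_from_theta, toy_table


def path3() -> AdjacencyGraph:
    return AdjacencyGraph.from_edges([("A", "B"), ("B", "C")], ["A", "B", "C"])


def reference_log_posterior(params, y, E, X, graph, spec):
    """Term-by-term reimplementation, kept deliberately naive."""
    beta0 = params["beta0"]
    beta = np.asarray(params.get("beta", []), dtype=float)
    eta = beta0 + (X @ beta if beta.size else 0.0)
    lp = 0.0
    if spec.spatial:
        u, v = np.asarray(params["u"]), np.asarray(params["v"])
        s2u, s2v = params["sigma_u2"], params["sigma_v2"]
        eta = eta + u + v
        quad = 0.0
        for i, j in graph.edge_array():
            quad += (u[i] - u[j]) ** 2
        G = graph.n_components
        lp += -0.5 * (len(y) - G) * np.log(s2u) - quad / (2 * s2u)
        for vi in v:
            lp += -0.5 * np.log(s2v) - vi**2 / (2 * s2v)
        a, r = spec.prior_precision_shape, spec.prior_precision_rate
        for s2 in (s2u, s2v):
            lp += (a - 1) * np.log(1 / s2) - r / s2
    for k in range(beta.size):
        lp += -beta[k] ** 2 / (2 * spec.prior_beta_sd**2)
    for i in range(len(y)):
        lp += y[i] * (np.log(E[i]) + eta[i]) - E[i] * np.exp(eta[i])
    return lp


class TestLogPosterior:
    def test_matches_naive_reimplementation(self):
        g = path3()
        rng = np.random.default_rng(0)
        table = toy_table([3, 1, 0], E=[1.2, 0.8, 2.0])
        for rec, x in zip(table, [0.5, -1.0, 0.2]):
            rec.covariates["x1"] = x
        spec = ModelSpec(
            covariate_names=("x1",), spatial=True, standardize_covariates=False
        )
        y, E = table.cases_array(), table.expected_array()
        X = np.array([[0.5], [-1.0], [0.2]])
        for _ in range(5):
            params = {
                "beta0": rng.normal(),
                "beta": rng.normal(size=1),
                "u": rng.normal(size=3),
                "v": rng.normal(size=3),
                "sigma_u2": float(rng.uniform(0.1, 2)),
                "sigma_v2": float(rng.uniform(0.1, 2)),
            }
            got = log_posterior(params, table, g, spec)
            want = reference_log_posterior(params, y, E, X, g, spec)
            assert got == pytest.approx(want, rel=1e-12)

    def test_single_area_maximized_at_log_count(self):
        table = toy_table([3], E=[1.0])
        spec = ModelSpec()
        grid = np.linspace(-1, 3, 401)
        vals = [
            log_posterior({"beta0": b, "beta": []}, table, None, spec)
            for b in grid
        ]
        assert grid[int(np.argmax(vals))] == pytest.approx(np.log(3), abs=0.02)

    def test_unit_risk_beats_scaled_risk_when_y_equals_e(self):
        table = toy_table([4, 2, 7], E=[4, 2, 7])
        spec = ModelSpec()
        at_one = log_posterior({"beta0": 0.0, "beta": []}, table, None, spec)
        for t in (0.5, 0.9, 1.1, 2.0):
            assert (
                log_posterior({"beta0": np.log(t), "beta": []}, table, None, spec)
                < at_one
            )


class TestConjugateUpdates:
    def test_precision_full_conditional_matches_grid(self):
        """Gibbs Gamma parameters agree with grid evaluation of the joint."""
        g = path3()
        table = toy_table([2, 3, 1], E=[1.0, 2.0, 1.5])
        spec = ModelSpec(spatial=True)
        u = np.array([0.4, -0.1, -0.3])
        v = np.array([0.2, 0.1, -0.15])
        quad = icar_quadratic_form(g, u)
        n, G = 3, 1
        a, r = spec.prior_precision_shape, spec.prior_precision_rate
        # full conditional of tau_u = 1/sigma_u2: Gamma(a + (n-G)/2, r + quad/2)
        shape, rate = a + 0.5 * (n - G), r + 0.5 * quad
        taus = np.linspace(0.3, 8.0, 40)
        base = dict(beta0=0.1, beta=[], u=u, v=v, sigma_v2=0.5)
        lp = np.array(
            [
                log_posterior({**base, "sigma_u2": 1.0 / t}, table, g, spec)
                for t in taus
            ]
        )
        want = stats.gamma(shape, scale=1.0 / rate).logpdf(taus)
        # equality up to a constant: compare differences along the grid
        assert lp - lp[0] == pytest.approx(want - want[0], abs=1e-8)

    def test_unstructured_precision_conditional_matches_grid(self):
        g = path3()
        table = toy_table([2, 3, 1], E=[1.0, 2.0, 1.5])
        spec = ModelSpec(spatial=True)
        v = np.array([0.25, -0.4, 0.05])
        a, r = spec.prior_precision_shape, spec.prior_precision_rate
        shape, rate = a + 1.5, r + 0.5 * float(v @ v)
        taus = np.linspace(0.5, 12.0, 30)
        base = dict(beta0=-0.2, beta=[], u=[0.1, 0.0, -0.1], sigma_u2=0.7, v=v)
        lp = np.array(
            [
                log_posterior({**base, "sigma_v2": 1.0 / t}, table, g, spec)
                for t in taus
            ]
        )
        want = stats.gamma(shape, scale=1.0 / rate).logpdf(taus)
        assert lp - lp[0] == pytest.approx(want - want[0], abs=1e-8)


class TestFit:
    def test_single_area_gamma_poisson_oracle(self):
        """Flat prior on log(theta): posterior is Gamma(y, E), mean y/E."""
        import arviz as az

        table = toy_table([3], E=[1.0])
        draws = fit(
            table,
            None,
            ModelSpec(),
            McmcConfig(n_chains=2, n_iter=6000, n_burnin=1000, thin=1, seed=11),
        )
        theta = draws.stacked("theta").ravel()
        ess = float(az.ess(np.asarray(draws.theta[:, :, 0])))
        mcse = theta.std() / np.sqrt(ess)
        assert abs(theta.mean() - 3.0) < 3 * mcse
        lo, hi = np.quantile(theta, [0.025, 0.975])
        glo, ghi = stats.gamma(3).ppf([0.025, 0.975])
        assert lo == pytest.approx(glo, rel=0.15)
        assert hi == pytest.approx(ghi, rel=0.10)

    def test_matches_poisson_mle_under_vague_priors(self):
        cfg = SimulationConfig(
            lattice=(14, 14), beta={"x1": 0.3}, sigma_u=0.0, sigma_v=0.0, seed=21
        )
        table, _, _ = simulate_dataset(cfg)
        table = compute_expected_counts(table)
        spec = ModelSpec(covariate_names=("x1",), standardize_covariates=False)
        mle = fit_nonspatial_mle(table, spec)
        draws = fit(
            table,
            None,
            spec,
            McmcConfig(n_chains=2, n_iter=4000, n_burnin=1000, thin=1, seed=13),
        )
        b = draws.stacked("beta")[:, 0]
        se = mle["se"]["beta[x1]"]
        assert b.mean() == pytest.approx(mle["beta"]["x1"], abs=0.5 * se)
        assert draws.stacked("beta0").mean() == pytest.approx(
            mle["beta0"], abs=0.5 * mle["se"]["beta0"]
        )

    def test_theta_recomputable_and_recentred(self):
        cfg = SimulationConfig(lattice=(5, 5), beta={"x1": 0.2}, seed=2)
        table, g, _ = simulate_dataset(cfg)
        table = compute_expected_counts(table)
        spec = ModelSpec(covariate_names=("x1",), spatial=True)
        draws = fit(
            table, g, spec,
            McmcConfig(n_chains=2, n_iter=600, n_burnin=300, thin=2, seed=4),
        )
        eta = (
            draws.beta0[..., None]
            + np.einsum("ckp,np->ckn", draws.beta, draws.design_matrix)
            + draws.u
            + draws.v
        )
        assert draws.theta == pytest.approx(np.exp(eta), rel=1e-12)
        assert np.abs(draws.u.sum(axis=-1)).max() < 1e-8

    def test_no_spatial_signal_shrinks_u(self):
        cfg = SimulationConfig(
            lattice=(8, 8), beta={}, sigma_u=0.0, sigma_v=0.0,
            population_range=(50_000, 50_000), seed=31,
        )
        table, g, _ = simulate_dataset(cfg)
        table = compute_expected_counts(table)
        draws = fit(
            table, g, ModelSpec(spatial=True),
            McmcConfig(n_chains=2, n_iter=2000, n_burnin=1000, thin=2, seed=6),
        )
        u_means = draws.stacked("u").mean(axis=0)
        assert np.abs(u_means).max() < 0.1
        assert np.median(draws.stacked("sigma_u2")) < 0.05

    def test_offset_shift_moves_intercept_only(self):
        """Scaling every E by k divides theta by k; theta*E is invariant."""
        cfg = SimulationConfig(lattice=(6, 6), beta={}, sigma_u=0.3, seed=12)
        table, g, _ = simulate_dataset(cfg)
        table = compute_expected_counts(table)
        k = 2.5
        import dataclasses

        table2 = dataclasses.replace(table)
        table2.records = [
            dataclasses.replace(r, expected=r.expected * k) for r in table
        ]
        mc = McmcConfig(n_chains=2, n_iter=3000, n_burnin=1500, thin=2, seed=3)
        d1 = fit(table, g, ModelSpec(spatial=True), mc)
        d2 = fit(table2, g, ModelSpec(spatial=True), mc)
        m1 = d1.stacked("theta").mean(axis=0)
        m2 = d2.stacked("theta").mean(axis=0)
        assert m2 * k == pytest.approx(m1, rel=0.06)
        assert d2.stacked("beta0").mean() == pytest.approx(
            d1.stacked("beta0").mean() - np.log(k), abs=0.05
        )

    def test_spatial_without_graph_rejected(self):
        table = compute_expected_counts(toy_table([1, 2]))
        with pytest.raises(InferenceError, match="graph"):
            fit(table, None, ModelSpec(spatial=True),
                McmcConfig(n_chains=2, n_iter=20, n_burnin=10))

    def test_prior_only_field_matches_exact_sampler(self):
        """With the likelihood switched off and the scale pinned, MCMC u
        draws match exact ICAR draws (two-sample KS on one site)."""
        g = lattice_graph(4, 4)
        # negligible E and y=0 nullify the Poisson term; enormous Gamma
        # shape/rate pin sigma_u2 ~ 0.25
        table = toy_table([0] * 16, E=[1e-10] * 16, area_ids=g.area_ids)
        spec = ModelSpec(
            spatial=True,
            prior_precision_shape=1e8,
            prior_precision_rate=0.25e8,
        )
        draws = fit(
            table, g, spec,
            McmcConfig(n_chains=2, n_iter=16_000, n_burnin=2000, thin=10, seed=19),
        )
        site = 5  # interior site
        mcmc_u = draws.stacked("u")[:, site]
        rng = np.random.default_rng(99)
        exact = np.array(
            [simulate_icar_field(g, 0.5, rng)[site] for _ in range(2800)]
        )
        assert stats.ks_2samp(mcmc_u, exact).pvalue > 0.01


def reference_rank_rhat(chains: np.ndarray) -> float:
    """Split-R-hat on rank-normalized and folded draws (textbook formula)."""

    def split(x):
        half = x.shape[1] // 2
        return np.vstack([x[:, :half], x[:, half : 2 * half]])

    def basic_rhat(x):
        m, n = x.shape
        W = x.var(axis=1, ddof=1).mean()
        B = n * x.mean(axis=1).var(ddof=1)
        return np.sqrt(((n - 1) / n * W + B / n) / W)

    def z_scale(x):
        r = stats.rankdata(x, method="average").reshape(x.shape)
        return stats.norm.ppf((r - 3 / 8) / (x.size + 1 / 4))

    x = split(np.asarray(chains))
    bulk = basic_rhat(z_scale(x))
    folded = basic_rhat(z_scale(np.abs(x - np.median(x))))
    return float(max(bulk, folded))


class TestGelmanRubin:
    def _wrap(self, chains: np.ndarray) -> PosteriorDraws:
        d = draws_from_theta(np.ones((chains.shape[1], 1)))
        d.beta0 = chains
        d.theta = np.ones((chains.shape[0], chains.shape[1], 1))
        return d

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(5)
        r = gelman_rubin(self._wrap(rng.standard_normal((4, 1000))))
        assert r["beta0"] == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((2, 500)) + np.array([[0.0], [50.0]])
        # rank-normalization bounds R-hat; ~1.8 is its saturated ceiling for
        # two disjoint chains, far above the 1.05 convergence gate
        assert gelman_rubin(self._wrap(chains))["beta0"] > 1.5

    def test_matches_textbook_formula_on_ar1(self):
        rng = np.random.default_rng(7)
        chains = np.empty((3, 800))
        for c in range(3):
            x = 0.0
            for t in range(800):
                x = 0.6 * x + rng.standard_normal()
                chains[c, t] = x
        got = gelman_rubin(self._wrap(chains))["beta0"]
        assert got == pytest.approx(reference_rank_rhat(chains), abs=1e-6)

    def test_single_chain_rejected(self):
        d = draws_from_theta(np.ones((10, 1)))
        with pytest.raises(InferenceError):
            gelman_rubin(d)
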