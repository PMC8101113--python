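"""Bayesian Poisson disease-mapping models fitted by MCMC.

Two models share one sampler:

* non-spatial:  log theta_i = beta0 + x_i' beta
* BYM convolution:  log theta_i = beta0 + x_i' beta + u_i + v_i

with ``Y_i ~ Poisson(E_i theta_i)``, ``u`` an intrinsic CAR field on the
supplied adjacency graph (scale ``sigma_u^2``), and ``v ~ N(0, sigma_v^2)``
i.i.d.  Priors: flat on the intercept, ``N(0, prior_beta_sd^2)`` on each
regression coefficient, and ``Gamma(shape, rate)`` on both precisions
``1/sigma_u^2`` and ``1/sigma_v^2`` (defaults 1 and 5e-5 — documented
stand-ins for common vague disease-mapping defaults).

The sampler is Metropolis-within-Gibbs with adaptive random-walk updates for
``beta0``, each ``beta_k``, each ``u_i`` and each ``v_i``, and conjugate
Gibbs draws for the two precisions.  Latent-field updates are *chromatic*:
a greedy colouring of the adjacency graph partitions areas into classes with
no internal edges, so all areas of one colour have mutually independent full
conditionals and are updated as one vectorised block — the transition kernel
is identical to a site-by-site sweep in colour order, at a fraction of the
cost.  The ICAR field is re-centred to mean zero within every connected
component after each sweep (the classic identifiability fix; the flat
intercept absorbs the level).  Step sizes adapt by Robbins-Monro during
burn-in only, targeting an acceptance rate of 0.44, and are frozen afterward
so the post-adaptation chain has the correct stationary distribution.

Note the classic BYM caveat: ``u`` and ``v`` are only identified through
their sum, so per-area summaries of either alone are weakly identified.  The
relative risk ``theta`` and the regression coefficients are the identified
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .county_data import CountyTable
from .graph import AdjacencyGraph, icar_quadratic_form

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PosteriorDraws",
    "log_posterior",
    "fit",
    "fit_nonspatial_mle",
    "gelman_rubin",
]

logger = logging.getLogger(__name__)

_TARGET_DEFAULT = 0.44


class InferenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Model structure and priors.

    ``prior_beta_sd`` defaults to sqrt(1/0.001) ~ 31.62 (precision 0.001 on
    fixed effects); precisions get Gamma(1, 5e-5).  Covariates are
    standardized (zero mean, unit SD over observed areas) before fitting by
    default, so coefficient summaries are per-SD effects.
    """

    covariate_names: tuple[str, ...] = ()
    spatial: bool = False
    prior_beta_sd: float = float(np.sqrt(1.0 / 0.001))
    prior_precision_shape: float = 1.0
    prior_precision_rate: float = 5e-5
    standardize_covariates: bool = True
    missing_policy: str = "impute_mean"

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        if (
            self.prior_beta_sd <= 0
            or self.prior_precision_shape <= 0
            or self.prior_precision_rate <= 0
        ):
            raise ValueError("prior parameters must be positive")


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 5
    seed: int = 0
    target_acceptance: float = _TARGET_DEFAULT
    adapt_until: int | None = None  # defaults to n_burnin

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")
        if self.adapt_until is None:
            self.adapt_until = self.n_burnin

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Retained, thinned draws from all chains.

    Array shapes: ``beta0``, ``sigma_u2``, ``sigma_v2`` are (chains, kept);
    ``beta`` is (chains, kept, p); ``u``, ``v``, ``theta`` are (chains,
    kept, n).  ``u``/``v``/``sigma_*`` are ``None`` for non-spatial fits.
    ``theta`` always satisfies ``theta = exp(beta0 + X beta + u + v)`` with
    the stored (standardized) design matrix.
    """

    beta0: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    u: np.ndarray | None
    v: np.ndarray | None
    sigma_u2: np.ndarray | None
    sigma_v2: np.ndarray | None
    covariate_names: tuple[str, ...]
    area_ids: list[str]
    model_spec: ModelSpec
    mcmc: McmcConfig
    acceptance: dict[str, float] = field(default_factory=dict)
    design_matrix: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_kept(self) -> int:
        return self.beta0.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains flattened into one axis."""
        arr = getattr(self, name)
        if arr is None:
            raise KeyError(f"{name} not sampled for this model")
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Monitored scalar parameters, shape (chains, kept) each."""
        out = {"beta0": self.beta0}
        for k, name in enumerate(self.covariate_names):
            out[f"beta[{name}]"] = self.beta[:, :, k]
        if self.sigma_u2 is not None:
            out["sigma_u2"] = self.sigma_u2
        if self.sigma_v2 is not None:
            out["sigma_v2"] = self.sigma_v2
        return out

    def to_frame(self):
        """Long-format DataFrame with chain and iteration columns."""
        import pandas as pd

        cols: dict[str, np.ndarray] = {}
        C, K = self.beta0.shape
        cols["chain"] = np.repeat(np.arange(C), K)
        cols["iteration"] = np.tile(np.arange(K), C)
        for name, arr in self.scalar_draws().items():
            cols[name] = arr.reshape(-1)
        for i, area in enumerate(self.area_ids):
            cols[f"theta[{area}]"] = self.theta[:, :, i].reshape(-1)
        return pd.DataFrame(cols)


def prepare_design(
    data: CountyTable, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (y, E, X) aligned with the table's record order.

    X is standardized per column when the spec asks for it; missing cells
    follow the spec's missing policy (mean imputation by default).
    """
    y = data.cases_array()
    E = data.expected_array()
    if np.any(E <= 0):
        raise InferenceError("all expected counts must be positive")
    X, _ = data.covariate_matrix(
        spec.covariate_names, missing_policy=spec.missing_policy
    )
    if spec.standardize_covariates and X.shape[1]:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [
                spec.covariate_names[k] for k in np.flatnonzero(sd == 0)
            ]
            raise InferenceError(f"constant covariate(s): {bad}")
        X = (X - X.mean(axis=0)) / sd
    return y, E, X


def log_posterior(
    params: Mapping[str, object],
    data: CountyTable,
    graph: AdjacencyGraph | None,
    spec: ModelSpec,
) -> float:
    """Unnormalized log posterior (additive constant fixed across calls).

    ``params`` carries ``beta0``, ``beta`` and — for spatial specs — ``u``,
    ``v``, ``sigma_u2``, ``sigma_v2``.  The precision priors are evaluated
    as Gamma densities in ``tau = 1/sigma^2``.
    """
    y, E, X = prepare_design(data, spec)
    n = len(y)
    beta0 = float(params["beta0"])
    beta = np.atleast_1d(np.asarray(params.get("beta", []), dtype=float))
    if beta.size != X.shape[1]:
        raise InferenceError(
            f"beta has {beta.size} entries for {X.shape[1]} covariates"
        )
    eta = np.full(n, beta0, dtype=float)
    if beta.size:
        eta += X @ beta
    lp = 0.0
    if spec.spatial:
        if graph is None:
            raise InferenceError("spatial model requires an adjacency graph")
        u = np.asarray(params["u"], dtype=float)
        v = np.asarray(params["v"], dtype=float)
        s2u = float(params["sigma_u2"])
        s2v = float(params["sigma_v2"])
        if s2u <= 0 or s2v <= 0:
            raise InferenceError("variance parameters must be positive")
        eta = eta + u + v
        G = graph.n_components
        quad = icar_quadratic_form(graph, u)
        lp += -0.5 * (n - G) * np.log(s2u) - quad / (2.0 * s2u)
        lp += -0.5 * n * np.log(s2v) - float(v @ v) / (2.0 * s2v)
        a, r = spec.prior_precision_shape, spec.prior_precision_rate
        for s2 in (s2u, s2v):
            tau = 1.0 / s2
            lp += (a - 1.0) * np.log(tau) - r * tau
    if not np.all(np.isfinite(eta)):
        raise InferenceError("non-finite linear predictor")
    # Poisson log-likelihood up to the log(y!) constant
    logE = np.log(E)
    lp += float(y @ (logE + eta) - E @ np.exp(eta))
    if beta.size:
        lp += float(-(beta @ beta) / (2.0 * spec.prior_beta_sd**2))
    if not np.isfinite(lp):
        raise InferenceError("non-finite log posterior")
    return lp


def _color_classes(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Greedy graph colouring; classes have no internal edges."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n))
    g.add_edges_from(map(tuple, graph.edge_array()))
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values(), default=0) + 1
    classes = [[] for _ in range(n_colors)]
    for node, c in coloring.items():
        if graph.neighbors[node]:  # islands are never updated (u fixed at 0)
            classes[c].append(node)
    return [np.array(sorted(c), dtype=int) for c in classes if c]


def _run_chain(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    ginfo: dict | None,
    spec: ModelSpec,
    mcmc: McmcConfig,
    rng: np.random.Generator,
) -> dict:
    n, p = len(y), X.shape[1]
    spatial = ginfo is not None
    target = mcmc.target_acceptance

    # initial state: intercept at the pooled log-SMR, small jitter elsewhere
    b0 = float(np.log(max(y.sum(), 0.5) / E.sum())) + 0.1 * rng.standard_normal()
    b = 0.01 * rng.standard_normal(p)
    u = np.zeros(n)
    v = np.zeros(n)
    s2u = s2v = 0.1
    eta = b0 + (X @ b if p else 0.0)
    if spatial:
        eta = eta + u + v

    step_b0 = 0.1
    step_b = np.full(p, 0.1)
    step_u = np.full(n, 0.3)
    step_v = np.full(n, 0.3)

    kept = {
        "beta0": np.empty(mcmc.n_kept),
        "beta": np.empty((mcmc.n_kept, p)),
        "theta": np.empty((mcmc.n_kept, n)),
    }
    if spatial:
        kept["u"] = np.empty((mcmc.n_kept, n))
        kept["v"] = np.empty((mcmc.n_kept, n))
        kept["sigma_u2"] = np.empty(mcmc.n_kept)
        kept["sigma_v2"] = np.empty(mcmc.n_kept)

    acc_counts: dict[str, float] = {"beta0": 0.0, "beta": 0.0, "u": 0.0, "v": 0.0}
    acc_totals: dict[str, float] = {"beta0": 0.0, "beta": 0.0, "u": 0.0, "v": 0.0}
    a_shape, a_rate = spec.prior_precision_shape, spec.prior_precision_rate
    if spatial:
        A = ginfo["A"]
        n_delta = ginfo["n_delta"]
        classes = ginfo["classes"]
        comps = ginfo["components"]
        G = ginfo["n_components"]
        edges = ginfo["edges"]
    beta_prec = 1.0 / spec.prior_beta_sd**2
    Eexp = E * np.exp(eta)
    ysum = y.sum()
    k_out = 0

    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()
    for t in range(mcmc.n_iter):
        adapting = t < mcmc.adapt_until
        gamma = (t + 1.0) ** -0.6 if adapting else 0.0
        post_burn = t >= mcmc.n_burnin

        # intercept: a shift of eta by delta rescales every Eexp by e^delta
        delta = step_b0 * rng.standard_normal()
        dll = delta * ysum - (np.expm1(delta)) * Eexp.sum()
        if np.log(rng.random()) < dll:
            b0 += delta
            eta += delta
            Eexp *= np.exp(delta)
            acc = 1.0
        else:
            acc = 0.0
        if adapting:
            step_b0 *= np.exp(gamma * (acc - target))
        if post_burn:
            acc_counts["beta0"] += acc
            acc_totals["beta0"] += 1.0

        for k in range(p):
            xk = X[:, k]
            delta = step_b[k] * rng.standard_normal()
            shift = delta * xk
            dll = delta * float(y @ xk) - float(Eexp @ np.expm1(shift))
            bnew = b[k] + delta
            dll += -(bnew * bnew - b[k] * b[k]) * 0.5 * beta_prec
            if np.log(rng.random()) < dll:
                b[k] = bnew
                eta += shift
                Eexp *= np.exp(shift)
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                step_b[k] *= np.exp(gamma * (acc - target))
            if post_burn:
                acc_counts["beta"] += acc
                acc_totals["beta"] += 1.0

        if spatial:
            for idx in classes:
                nbr_sum = A @ u  # neighbours of idx are outside idx
                delta = step_u[idx] * rng.standard_normal(idx.size)
                ucur = u[idx]
                unew = ucur + delta
                dll = (
                    y[idx] * delta
                    - Eexp[idx] * np.expm1(delta)
                    - (
                        n_delta[idx] * (unew * unew - ucur * ucur)
                        - 2.0 * nbr_sum[idx] * delta
                    )
                    / (2.0 * s2u)
                )
                accept = np.log(rng.random(idx.size)) < dll
                if accept.any():
                    hit = idx[accept]
                    u[hit] += delta[accept]
                    eta[hit] += delta[accept]
                    Eexp[hit] *= np.exp(delta[accept])
                if adapting:
                    step_u[idx] *= np.exp(gamma * (accept - target))
                if post_burn:
                    acc_counts["u"] += float(accept.sum())
                    acc_totals["u"] += idx.size

            delta = step_v * rng.standard_normal(n)
            vnew = v + delta
            dll = (
                y * delta
                - Eexp * np.expm1(delta)
                - (vnew * vnew - v * v) / (2.0 * s2v)
            )
            accept = np.log(rng.random(n)) < dll
            if accept.any():
                v[accept] += delta[accept]
                eta[accept] += delta[accept]
                Eexp[accept] *= np.exp(delta[accept])
            if adapting:
                step_v *= np.exp(gamma * (accept - target))
            if post_burn:
                acc_counts["v"] += float(accept.sum())
                acc_totals["v"] += n

            # per-component re-centring (identifiability of the ICAR field)
            for comp in ginfo["component_lists"]:
                m = u[comp].mean()
                if m != 0.0:
                    u[comp] -= m
                    eta[comp] -= m
                    Eexp[comp] *= np.exp(-m)

            # conjugate precision updates
            diffs = u[edges[:, 0]] - u[edges[:, 1]] if len(edges) else np.zeros(0)
            quad = float(diffs @ diffs)
            shape_u = a_shape + 0.5 * (n - G)
            rate_u = a_rate + 0.5 * quad
            shape_v = a_shape + 0.5 * n
            rate_v = a_rate + 0.5 * float(v @ v)
            if min(shape_u, rate_u, shape_v, rate_v) <= 0:
                raise InferenceError(
                    "non-positive Gibbs shape/rate — internal error"
                )
            s2u = 1.0 / rng.gamma(shape_u, 1.0 / rate_u)
            s2v = 1.0 / rng.gamma(shape_v, 1.0 / rate_v)

        if not np.all(np.isfinite(eta)):
            raise InferenceError(f"divergent state at iteration {t}")

        if post_burn and (t - mcmc.n_burnin) % mcmc.thin == 0:
            kept["beta0"][k_out] = b0
            kept["beta"][k_out] = b
            kept["theta"][k_out] = np.exp(eta)
            if spatial:
                kept["u"][k_out] = u
                kept["v"][k_out] = v
                kept["sigma_u2"][k_out] = s2u
                kept["sigma_v2"][k_out] = s2v
            k_out += 1

    errstate.__exit__(None, None, None)
    kept["acceptance"] = {
        key: (acc_counts[key] / acc_totals[key]) if acc_totals[key] else np.nan
        for key in acc_counts
    }
    return kept


def fit(
    data: CountyTable,
    graph: AdjacencyGraph | None,
    spec: ModelSpec,
    mcmc: McmcConfig,
) -> PosteriorDraws:
    """Fit the model by adaptive Metropolis-within-Gibbs.

    Reproducible given ``mcmc.seed`` (each chain gets an independent stream
    spawned from it).  Returns retained, thinned draws from every chain.
    """
    y, E, X = prepare_design(data, spec)
    ginfo = None
    if spec.spatial:
        if graph is None:
            raise InferenceError("spatial model requires an adjacency graph")
        if graph.n != data.n:
            raise InferenceError(
                f"graph has {graph.n} areas, table has {data.n}"
            )
        edges = graph.edge_array()
        if len(edges) == 0:
            raise InferenceError("ICAR undefined: graph has no edges")
        if graph.islands:
            logger.warning(
                "%d island area(s): spatial effect fixed at 0 there",
                len(graph.islands),
            )
        ginfo = {
            "A": graph.adjacency(),
            "n_delta": graph.n_delta.astype(float),
            "classes": _color_classes(graph),
            "components": graph.components,
            "component_lists": graph.component_indices(),
            "n_components": graph.n_components,
            "edges": edges,
        }
    streams = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = [
        _run_chain(y, E, X, ginfo, spec, mcmc, np.random.default_rng(s))
        for s in streams
    ]
    def _stack(key):
        return np.stack([c[key] for c in chains])

    acceptance = {
        key: float(np.nanmean(vals))
        for key in chains[0]["acceptance"]
        if not np.all(np.isnan(vals := [c["acceptance"][key] for c in chains]))
    }
    draws = PosteriorDraws(
        beta0=_stack("beta0"),
        beta=_stack("beta"),
        theta=_stack("theta"),
        u=_stack("u") if spec.spatial else None,
        v=_stack("v") if spec.spatial else None,
        sigma_u2=_stack("sigma_u2") if spec.spatial else None,
        sigma_v2=_stack("sigma_v2") if spec.spatial else None,
        covariate_names=spec.covariate_names,
        area_ids=data.area_ids,
        model_spec=spec,
        mcmc=mcmc,
        acceptance=acceptance,
        design_matrix=X,
    )
    logger.info("acceptance rates: %s", acceptance)
    return draws


def fit_nonspatial_mle(data: CountyTable, spec: ModelSpec) -> dict:
    """Maximum-likelihood Poisson regression with log-E offset.

    Frequentist cross-check for the non-spatial Bayesian fit: Newton-type
    (IRLS) maximization of the same Poisson likelihood.  Returns a dict with
    ``beta0``, ``beta`` (named), standard errors, and the fitted object.
    """
    import statsmodels.api as sm

    y, E, X = prepare_design(data, spec)
    design = np.column_stack([np.ones(len(y)), X])
    model = sm.GLM(
        y, design, family=sm.families.Poisson(), offset=np.log(E)
    )
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise InferenceError("Poisson MLE did not converge in 100 iterations")
    names = ["beta0", *[f"beta[{c}]" for c in spec.covariate_names]]
    return {
        "beta0": float(res.params[0]),
        "beta": {
            name: float(val)
            for name, val in zip(spec.covariate_names, res.params[1:])
        },
        "se": dict(zip(names, map(float, res.bse))),
        "result": res,
    }


def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Rank-normalized split R-hat for every monitored scalar parameter.

    Requires at least two chains.  Values near 1 indicate convergence; the
    pipeline warns above 1.05.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise InferenceError("R-hat requires at least two chains")
    rhat: dict[str, float] = {}
    for name, arr in draws.scalar_draws().items():
        rhat[name] = float(az.rhat(np.asarray(arr), method="rank"))
    return rhat
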