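"""Synthetic areal datasets with the BYM generative structure.

Data are drawn from exactly the model the inference module fits:

    Y_i ~ Poisson(E_i * exp(beta0 + x_i' beta + u_i + v_i))

with ``u`` an intrinsic CAR (ICAR) field on a known graph, ``v`` i.i.d.
Gaussian noise, independently drawn Gaussian covariates, and expected counts
set from an explicit baseline rate (default 150 per 100,000) so the true
parameters are unambiguous.  This is the validation surface for the sampler:
parameter recovery on these datasets is the package's main evidence of
correctness.

The ICAR field is sampled exactly by spectral decomposition of the structure
matrix ``Q = diag(n_delta) - A``: zero-eigenvalue modes (one per connected
component) are dropped, giving a draw with covariance ``sigma_u^2 Q^+`` that
sums to zero within every component by construction.  Degree-zero areas get
``u_i = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .county_data import CountyRecord, CountyTable, crude_rate
from .graph import AdjacencyGraph, GraphError, lattice_graph, write_edge_list

__all__ = ["SimulationConfig", "simulate_icar_field", "simulate_dataset"]

_EIG_TOL = 1e-9


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic dataset.

    Either ``graph`` or ``lattice=(rows, cols)`` must be given.  Covariates
    are drawn independently per area from N(mean, sd^2) as named in
    ``covariate_distributions``; ``beta`` names a coefficient per covariate.
    ``baseline_rate`` is the reference incidence per person over the study
    period (default 150 per 100,000), fixing ``E_i = population_i *
    baseline_rate``.
    """

    graph: AdjacencyGraph | None = None
    lattice: tuple[int, int] | None = None
    beta0: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    sigma_u: float = 0.5
    sigma_v: float = 0.1
    population_range: tuple[int, int] = (5_000, 50_000)
    baseline_rate: float = 150.0 / 100_000.0
    covariate_distributions: dict[str, tuple[float, float]] | None = None
    covariate_correlation: float = 0.0
    seed: int = 0

    def resolve_graph(self) -> AdjacencyGraph:
        if self.graph is not None:
            return self.graph
        if self.lattice is not None:
            return lattice_graph(*self.lattice)
        raise ValueError("SimulationConfig needs a graph or a lattice spec")

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("sigma_u and sigma_v must be non-negative")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad population_range {self.population_range}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.covariate_distributions is None:
            self.covariate_distributions = {
                name: (0.0, 1.0) for name in self.beta
            }


def _icar_basis(graph: AdjacencyGraph) -> tuple[np.ndarray, np.ndarray]:
    """Positive eigenpairs of Q, cached on the graph instance."""
    if "icar_basis" not in graph._cache:
        Q = graph.laplacian().toarray()
        w, V = np.linalg.eigh(Q)
        keep = w > _EIG_TOL * max(w.max(), 1.0)
        graph._cache["icar_basis"] = (w[keep], V[:, keep])
    return graph._cache["icar_basis"]


def simulate_icar_field(
    graph: AdjacencyGraph,
    sigma_u: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One exact draw from the ICAR distribution with scale ``sigma_u``.

    Covariance is ``sigma_u^2 Q^+`` (Moore-Penrose pseudoinverse of the
    structure matrix), i.e. the improper ICAR density constrained to sum to
    zero within each connected component.  Deterministic given the seed.
    """
    if sigma_u < 0:
        raise ValueError("sigma_u must be non-negative")
    if sigma_u == 0:
        return np.zeros(graph.n)
    w, V = _icar_basis(graph)
    if w.size == 0:
        raise GraphError(
            "ICAR undefined: graph has no edges (all areas isolated)"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    z = rng.standard_normal(w.size)
    return V @ (z * sigma_u / np.sqrt(w))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountyTable, AdjacencyGraph, dict]:
    """Draw one dataset; returns (table, graph, truth record).

    The returned table's ``expected`` is left unfilled: fitting applies the
    same internal standardization it would use on real data.  The truth
    record carries the generating parameters plus the true ``E_i``, ``u``,
    ``v`` and ``theta`` for recovery checks.
    """
    graph = config.resolve_graph()
    rng = np.random.default_rng(config.seed)
    n = graph.n
    names = list(config.beta)
    X = np.empty((n, len(names)))
    for k, name in enumerate(names):
        mu, sd = config.covariate_distributions[name]
        X[:, k] = rng.normal(mu, sd, size=n)
    if config.covariate_correlation and len(names) > 1:
        rho = config.covariate_correlation
        C = np.full((len(names), len(names)), rho) + (1 - rho) * np.eye(len(names))
        L = np.linalg.cholesky(C)
        Z = (X - X.mean(0)) / X.std(0)
        X = X.mean(0) + X.std(0) * (Z @ L.T)
    u = simulate_icar_field(graph, config.sigma_u, rng)
    v = rng.normal(0.0, config.sigma_v, size=n)
    beta_vec = np.array([config.beta[name] for name in names])
    eta = config.beta0 + X @ beta_vec + u + v
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor in simulation")
    lo, hi = config.population_range
    pop = rng.integers(lo, hi + 1, size=n)
    expected_true = pop * config.baseline_rate
    y = rng.poisson(expected_true * np.exp(eta))
    records = []
    for i, area_id in enumerate(graph.area_ids):
        covs = {name: float(X[i, k]) for k, name in enumerate(names)}
        records.append(
            CountyRecord(
                area_id=area_id,
                cases=float(y[i]),
                population=int(pop[i]),
                covariates=covs,
                crude_rate=crude_rate(float(y[i]), int(pop[i])),
            )
        )
    table = CountyTable(records=records, period_years=1, source_label="synthetic")
    truth = {
        "beta0": config.beta0,
        "beta": dict(config.beta),
        "sigma_u": config.sigma_u,
        "sigma_v": config.sigma_v,
        "sigma_u2": config.sigma_u**2,
        "sigma_v2": config.sigma_v**2,
        "baseline_rate": config.baseline_rate,
        "u": u.tolist(),
        "v": v.tolist(),
        "theta": np.exp(eta).tolist(),
        "expected_true": expected_true.tolist(),
        "seed": config.seed,
    }
    return table, graph, truth


def write_dataset(
    table: CountyTable,
    graph: AdjacencyGraph,
    truth: dict,
    outdir: str | Path,
) -> None:
    """Persist a simulated dataset as CSV + edge list + truth.json."""
    from .county_data import write_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_csv(table, outdir / "counties.csv")
    write_edge_list(graph, outdir / "edges.txt")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
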