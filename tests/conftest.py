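"""Shared fixtures: the Georgia table, small lattices, toy geometries."""

from __future__ import annotations

import numpy as np
import pytest

from bymmap import (
    CountyRecord,
    CountyTable,
    McmcConfig,
    ModelSpec,
    compute_expected_counts,
    lattice_graph,
    load_county_table,
    with_period_totals,
)
from bymmap.inference import PosteriorDraws


@pytest.fixture(scope="session")
def georgia():
    return load_county_table("georgia_2012_2016")


@pytest.fixture(scope="session")
def georgia_period():
    """Georgia table on a 5-year-total basis with expected counts filled."""
    return compute_expected_counts(
        with_period_totals(load_county_table("georgia_2012_2016"))
    )


@pytest.fixture()
def lattice4():
    return lattice_graph(4, 4)


def make_square_grid_geojson(rows: int, cols: int) -> dict:
    """Grid of unit squares whose ids match lattice_graph naming."""
    features = []
    for i in range(rows):
        for j in range(cols):
            ring = [[j, i], [j + 1, i], [j + 1, i + 1], [j, i + 1], [j, i]]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"id": f"r{i}c{j}"},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    return {"type": "FeatureCollection", "features": features}


@pytest.fixture()
def grid_geojson():
    return make_square_grid_geojson(3, 3)


def toy_table(y, E=None, populations=None, area_ids=None) -> CountyTable:
    """Minimal table; explicit E bypasses internal standardization."""
    y = np.asarray(y, dtype=float)
    pops = populations or [1000] * len(y)
    ids = area_ids or [chr(ord("A") + i) for i in range(len(y))]
    records = [
        CountyRecord(
            area_id=ids[i],
            cases=float(y[i]),
            population=int(pops[i]),
            crude_rate=float(y[i]) / pops[i] * 1e5,
            expected=None if E is None else float(E[i]),
        )
        for i in range(len(y))
    ]
    return CountyTable(records=records)


def draws_from_theta(theta, area_ids=None, covariate_names=()) -> PosteriorDraws:
    """Wrap an explicit (draws, n) theta array for summary-level tests."""
    theta = np.asarray(theta, dtype=float)[None, :, :]  # one chain
    n_kept, n = theta.shape[1:]
    ids = area_ids or [chr(ord("A") + i) for i in range(n)]
    p = len(covariate_names)
    return PosteriorDraws(
        beta0=np.zeros((1, n_kept)),
        beta=np.zeros((1, n_kept, p)),
        theta=theta,
        u=None,
        v=None,
        sigma_u2=None,
        sigma_v2=None,
        covariate_names=tuple(covariate_names),
        area_ids=ids,
        model_spec=ModelSpec(covariate_names=tuple(covariate_names)),
        mcmc=McmcConfig(n_chains=1, n_iter=max(n_kept, 1) + 1, n_burnin=1, thin=1),
        acceptance={},
    )
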