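"""Spatial adjacency structures for areal (CAR/ICAR) models.

An :class:`AdjacencyGraph` is a symmetric, binary neighbour structure over n
areal units, aligned by position with a county table.  It exposes exactly
what the intrinsic CAR prior needs: neighbour lists, neighbour counts
``n_delta``, the graph Laplacian ``Q = diag(n_delta) - A`` (the ICAR
precision up to the scale parameter), and connected-component labels — each
component carries its own sum-to-zero constraint during inference.

Graphs come from GAL neighbour-list files, plain edge lists, queen
contiguity over GeoJSON polygons, or the regular-lattice helper used by the
simulation studies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.geometry import shape
from shapely.strtree import STRtree

__all__ = [
    "AdjacencyGraph",
    "read_neighbor_list",
    "queen_contiguity",
    "lattice_graph",
    "icar_quadratic_form",
]

logger = logging.getLogger(__name__)


class GraphError(ValueError):
    pass


@dataclass
class AdjacencyGraph:
    """Symmetric binary adjacency over ordered areas.

    ``neighbors[i]`` is the sorted list of indices adjacent to area i.
    Symmetry and absence of self-loops are enforced at construction.
    """

    area_ids: list[str]
    neighbors: list[list[int]]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        if len(set(self.area_ids)) != n:
            raise GraphError("duplicate area_ids")
        if len(self.neighbors) != n:
            raise GraphError(
                f"neighbors has {len(self.neighbors)} entries for {n} areas"
            )
        self.neighbors = [sorted(set(nb)) for nb in self.neighbors]
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                if j == i:
                    raise GraphError(f"self-loop at {self.area_ids[i]!r}")
                if not 0 <= j < n:
                    raise GraphError(f"neighbor index {j} out of range")
                if i not in self.neighbors[j]:
                    raise GraphError(
                        f"asymmetric adjacency between {self.area_ids[i]!r} "
                        f"and {self.area_ids[j]!r}"
                    )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        area_ids: Sequence[str],
        symmetrize: bool = True,
    ) -> "AdjacencyGraph":
        index = {a: i for i, a in enumerate(area_ids)}
        edges = list(edges)
        unknown = sorted({a for e in edges for a in e if a not in index})
        if unknown:
            raise GraphError(f"unknown area name(s): {unknown}")
        nbrs: list[set[int]] = [set() for _ in area_ids]
        for a, b in edges:
            i, j = index[a], index[b]
            if i == j:
                continue
            nbrs[i].add(j)
            if symmetrize:
                nbrs[j].add(i)
        return cls(list(area_ids), [sorted(s) for s in nbrs])

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def n_delta(self) -> np.ndarray:
        """Neighbour counts, one per area."""
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    @property
    def islands(self) -> list[int]:
        """Indices of degree-zero areas."""
        return [i for i, nb in enumerate(self.neighbors) if not nb]

    def adjacency(self) -> sp.csr_matrix:
        rows = [i for i, nb in enumerate(self.neighbors) for _ in nb]
        cols = [j for nb in self.neighbors for j in nb]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> sp.csr_matrix:
        """ICAR structure matrix ``Q = diag(n_delta) - A``."""
        return sp.diags(self.n_delta.astype(float)) - self.adjacency()

    @property
    def components(self) -> np.ndarray:
        """Connected-component label per area."""
        if "components" not in self._cache:
            _, labels = connected_components(self.adjacency(), directed=False)
            self._cache["components"] = labels
        return self._cache["components"]

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1 if self.n else 0

    def component_indices(self) -> list[np.ndarray]:
        labels = self.components
        return [np.flatnonzero(labels == c) for c in range(self.n_components)]

    def edge_array(self) -> np.ndarray:
        """Unordered edges as an (m, 2) index array with i < j."""
        edges = [
            (i, j)
            for i, nb in enumerate(self.neighbors)
            for j in nb
            if i < j
        ]
        return np.array(edges, dtype=int).reshape(-1, 2)


def read_neighbor_list(
    path: str | Path, area_ids: Sequence[str]
) -> AdjacencyGraph:
    """Read a GAL neighbour-list file or a two-column edge-list file.

    GAL: a header line whose last token is the node count, then pairs of
    lines ``<name> <k>`` / ``<k neighbour names>``.  Edge list: one edge per
    line, two whitespace-separated area labels.  Asymmetric input is
    symmetrized with a logged warning.
    """
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise GraphError(f"{path}: empty neighbour file")
    head = lines[0].split()
    is_gal = all(tok.lstrip("-").isdigit() for tok in head)
    if is_gal:
        edges: list[tuple[str, str]] = []
        idx = 1
        pairs: list[tuple[str, list[str]]] = []
        while idx < len(lines):
            tokens = lines[idx].split()
            name, k = " ".join(tokens[:-1]), int(tokens[-1])
            idx += 1
            nbrs: list[str] = []
            while len(nbrs) < k:
                if idx >= len(lines):
                    raise GraphError(f"{path}: truncated GAL entry for {name!r}")
                nbrs.extend(lines[idx].split())
                idx += 1
            pairs.append((name, nbrs[:k]))
        asym = False
        listed = {name: set(nbrs) for name, nbrs in pairs}
        for name, nbrs in pairs:
            for other in nbrs:
                if name not in listed.get(other, set()):
                    asym = True
                edges.append((name, other))
        if asym:
            logger.warning("%s: asymmetric GAL input symmetrized", path)
        return AdjacencyGraph.from_edges(edges, area_ids)
    edges = []
    for ln in lines:
        tokens = ln.split()
        if len(tokens) != 2:
            raise GraphError(f"{path}: malformed edge line {ln!r}")
        edges.append((tokens[0], tokens[1]))
    return AdjacencyGraph.from_edges(edges, area_ids)


def write_edge_list(graph: AdjacencyGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in graph.edge_array():
            fh.write(f"{graph.area_ids[i]} {graph.area_ids[j]}\n")


def queen_contiguity(
    geojson: dict | str | Path, id_property: str = "id"
) -> AdjacencyGraph:
    """Queen-contiguity adjacency from a GeoJSON polygon collection.

    Two areas are neighbours when their polygons share at least one boundary
    point (edge *or* corner).  Features are keyed by ``properties[id_property]``
    (falling back to the feature-level ``id``).  Islands — features touching
    nothing — are allowed and reported via a logged warning.  Output is
    invariant to feature ordering up to the area ordering itself.
    """
    if not isinstance(geojson, dict):
        geojson = json.loads(Path(geojson).read_text(encoding="utf-8"))
    features = geojson.get("features")
    if not features:
        raise GraphError("GeoJSON has no features")
    ids: list[str] = []
    geoms = []
    for k, feat in enumerate(features):
        props = feat.get("properties") or {}
        fid = props.get(id_property, feat.get("id"))
        if fid is None:
            raise GraphError(f"feature {k}: no {id_property!r} property or id")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GraphError(f"feature {fid!r}: invalid geometry")
        ids.append(str(fid))
        geoms.append(geom)
    tree = STRtree(geoms)
    nbrs: list[set[int]] = [set() for _ in geoms]
    for i, geom in enumerate(geoms):
        for j in tree.query(geom, predicate="intersects"):
            j = int(j)
            if j != i:
                nbrs[i].add(j)
                nbrs[j].add(i)
    graph = AdjacencyGraph(ids, [sorted(s) for s in nbrs])
    if graph.islands:
        logger.warning(
            "queen contiguity: %d island(s) with no neighbours: %s",
            len(graph.islands),
            [ids[i] for i in graph.islands],
        )
    return graph


def lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency regular lattice (interior degree 4), for simulations."""
    if rows <= 0 or cols <= 0:
        raise GraphError("lattice dimensions must be positive")
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    edges = []
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                edges.append((f"r{i}c{j}", f"r{i}c{j + 1}"))
            if i + 1 < rows:
                edges.append((f"r{i}c{j}", f"r{i + 1}c{j}"))
    return AdjacencyGraph.from_edges(edges, ids)


def icar_quadratic_form(graph: AdjacencyGraph, u: np.ndarray) -> float:
    """Pairwise-difference energy ``sum_{i~j} (u_i - u_j)^2`` over edges.

    Equals ``u' Q u`` with ``Q = diag(n_delta) - A``; zero iff ``u`` is
    constant on every connected component.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n,):
        raise GraphError(f"u has shape {u.shape}, expected ({graph.n},)")
    edges = graph.edge_array()
    if len(edges) == 0:
        return 0.0
    diffs = u[edges[:, 0]] - u[edges[:, 1]]
    return float(diffs @ diffs)
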