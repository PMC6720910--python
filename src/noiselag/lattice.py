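"""Contiguity lattices over areal units.

An irregular lattice of small administrative areas (here called *units*,
grouped into *districts*) is represented as an undirected graph in which two
units are adjacent exactly when they share a border.  From the adjacency we
derive the first- and second-order neighbor sets used as spatial lags, and
the row-standardized weight matrix ``W`` with ``w_ij = 1/n_i`` for the
``n_i`` neighbors of unit ``i``.

Adjacency can be built from an explicit undirected edge list or from
polygons; in polygon mode two units are neighbors only when their boundaries
share a segment of positive length (rook-style contact — touching at a
single corner does not count).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "LatticeGraph",
    "NeighborOrders",
    "WeightMatrix",
    "build_adjacency",
    "neighbor_orders",
    "weight_matrix",
    "read_edge_list_csv",
    "read_units_csv",
    "write_edge_list_csv",
    "write_units_csv",
]

DEFAULT_DISTRICT = "d0"


@dataclass(frozen=True)
class LatticeGraph:
    """Symmetric, irreflexive contiguity graph with a district partition.

    Parameters
    ----------
    unit_ids
        Ordered unit identifiers; the order fixes row/column order of every
        derived matrix.
    adjacency
        Mapping unit -> frozenset of bordering units.
    district_of
        Mapping unit -> district identifier; every unit belongs to exactly
        one district.
    """

    unit_ids: tuple[str, ...]
    adjacency: Mapping[str, frozenset[str]]
    district_of: Mapping[str, str]

    def __post_init__(self) -> None:
        ids = self.unit_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({u for u in ids if list(ids).count(u) > 1})
            raise ValueError(f"duplicate unit ids: {dupes}")
        known = set(ids)
        for i in ids:
            if i not in self.adjacency:
                raise ValueError(f"unit {i!r} missing from adjacency")
            neigh = self.adjacency[i]
            if i in neigh:
                raise ValueError(f"unit {i!r} is its own neighbor")
            for j in neigh:
                if j not in known:
                    raise ValueError(f"adjacency of {i!r} references unknown unit {j!r}")
                if i not in self.adjacency[j]:
                    raise ValueError(f"adjacency not symmetric: {i!r} -> {j!r}")
            if i not in self.district_of:
                raise ValueError(f"unit {i!r} has no district")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def districts(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.district_of.values())))

    def index_of(self, unit: str) -> int:
        return self.unit_ids.index(unit)

    def degree(self, unit: str) -> int:
        return len(self.adjacency[unit])

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean (n_units, n_units) matrix in ``unit_ids`` order."""
        idx = {u: k for k, u in enumerate(self.unit_ids)}
        mat = np.zeros((self.n_units, self.n_units), dtype=bool)
        for i in self.unit_ids:
            for j in self.adjacency[i]:
                mat[idx[i], idx[j]] = True
        return mat

    def edges(self) -> list[tuple[str, str]]:
        """Undirected edges, each reported once with endpoints sorted."""
        out = set()
        for i in self.unit_ids:
            for j in self.adjacency[i]:
                out.add(tuple(sorted((i, j))))
        return sorted(out)


@dataclass(frozen=True)
class NeighborOrders:
    """First- and second-order neighbor sets.

    ``order1`` is the adjacency itself; ``order2(i)`` contains the units at
    shortest-path distance exactly 2 from ``i`` (neighbors-of-neighbors,
    excluding ``i`` and its direct neighbors), so the two sets are disjoint.
    """

    order1: Mapping[str, frozenset[str]]
    order2: Mapping[str, frozenset[str]]


@dataclass(frozen=True)
class WeightMatrix:
    """Row-standardized contiguity weights: ``w_ij = 1/n_i`` for neighbors.

    Rows of units with at least one neighbor sum to one; an isolated unit
    has an all-zero row.
    """

    unit_ids: tuple[str, ...]
    matrix: np.ndarray

    def row(self, unit: str) -> np.ndarray:
        return self.matrix[self.unit_ids.index(unit)]


# ---------------------------------------------------------------------------
# construction


def build_adjacency(
    source,
    *,
    unit_ids: Sequence[str] | None = None,
    district_of: Mapping[str, str] | None = None,
) -> LatticeGraph:
    """Build a :class:`LatticeGraph` from edges or polygons.

    ``source`` may be:

    * an iterable of ``(unit_a, unit_b)`` pairs (undirected edge list);
    * an iterable of ``(unit_id, district_id, geometry)`` triples with
      shapely geometries;
    * a GeoJSON ``FeatureCollection`` mapping whose features carry
      ``unit_id`` and ``district_id`` properties;
    * a path to an edge-list CSV (``unit_a,unit_b``) or a GeoJSON file.

    In edge mode, ``unit_ids`` (and optionally ``district_of``) supply the
    unit universe; units absent from both raise an error when referenced.
    Polygon mode declares two units adjacent iff their boundaries share a
    positive-length intersection (rook contact).
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix.lower() in {".geojson", ".json"}:
            source = json.loads(p.read_text())
        else:
            source = read_edge_list_csv(p)
    if isinstance(source, Mapping):
        if source.get("type") != "FeatureCollection":
            raise ValueError("GeoJSON input must be a FeatureCollection")
        return _from_geojson(source)
    items = list(source)
    if items and len(items[0]) == 3 and isinstance(items[0][2], BaseGeometry):
        return _from_polygons(items)
    return _from_edges(items, unit_ids=unit_ids, district_of=district_of)


def _from_edges(edges, *, unit_ids=None, district_of=None) -> LatticeGraph:
    if unit_ids is None:
        universe: set[str] = set()
        for a, b in edges:
            universe.update((a, b))
        if district_of:
            universe.update(district_of)
        unit_ids = sorted(universe)
    else:
        unit_ids = list(unit_ids)
        if len(set(unit_ids)) != len(unit_ids):
            raise ValueError("duplicate unit ids in unit list")
    known = set(unit_ids)
    adj: dict[str, set[str]] = {u: set() for u in unit_ids}
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop edge ({a!r}, {b!r}) not allowed")
        for u in (a, b):
            if u not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown unit {u!r}")
        adj[a].add(b)
        adj[b].add(a)
    if district_of is None:
        district_of = {u: DEFAULT_DISTRICT for u in unit_ids}
    return LatticeGraph(
        unit_ids=tuple(unit_ids),
        adjacency={u: frozenset(v) for u, v in adj.items()},
        district_of=dict(district_of),
    )


def _from_polygons(items) -> LatticeGraph:
    ids = [u for u, _, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({u for u in ids if ids.count(u) > 1})
        raise ValueError(f"duplicate unit ids: {dupes}")
    for u, _, g in items:
        if not g.is_valid:
            raise ValueError(f"invalid geometry for unit {u!r}")
    adj: dict[str, set[str]] = {u: set() for u in ids}
    boundaries = {u: g.boundary for u, _, g in items}
    geoms = {u: g for u, _, g in items}
    for k, u in enumerate(ids):
        for v in ids[k + 1 :]:
            if not geoms[u].envelope.intersects(geoms[v].envelope):
                continue
            inter = boundaries[u].intersection(boundaries[v])
            # rook contact: a shared border must have positive length
            if inter.length > 0:
                adj[u].add(v)
                adj[v].add(u)
    return LatticeGraph(
        unit_ids=tuple(ids),
        adjacency={u: frozenset(v) for u, v in adj.items()},
        district_of={u: d for u, d, _ in items},
    )


def _from_geojson(fc: Mapping) -> LatticeGraph:
    items = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        if "unit_id" not in props:
            raise ValueError("GeoJSON feature missing 'unit_id' property")
        items.append(
            (
                str(props["unit_id"]),
                str(props.get("district_id", DEFAULT_DISTRICT)),
                _shapely_shape(feat["geometry"]),
            )
        )
    return _from_polygons(items)


# ---------------------------------------------------------------------------
# derived structures


def neighbor_orders(graph: LatticeGraph) -> NeighborOrders:
    """First- and second-order neighbor sets of every unit.

    ``order2(i)`` is the set of units at shortest-path distance exactly 2,
    i.e. reachable through a neighbor but neither ``i`` itself nor one of
    its direct neighbors.  Isolated units get empty sets.
    """
    order1 = {i: frozenset(graph.adjacency[i]) for i in graph.unit_ids}
    order2 = {}
    for i in graph.unit_ids:
        two: set[str] = set()
        for j in graph.adjacency[i]:
            two.update(graph.adjacency[j])
        two.difference_update(graph.adjacency[i])
        two.discard(i)
        order2[i] = frozenset(two)
    return NeighborOrders(order1=order1, order2=order2)


def weight_matrix(graph: LatticeGraph) -> WeightMatrix:
    """Row-standardized contiguity weights ``w_ij = 1/n_i``.

    A unit without neighbors yields an all-zero row and a warning, so that
    downstream neighbor aggregates are zero rather than undefined.
    """
    n = graph.n_units
    mat = np.zeros((n, n), dtype=float)
    idx = {u: k for k, u in enumerate(graph.unit_ids)}
    for i in graph.unit_ids:
        neigh = graph.adjacency[i]
        if not neigh:
            warnings.warn(f"unit {i!r} has no neighbors; weight row is all zero", stacklevel=2)
            continue
        w = 1.0 / len(neigh)
        for j in neigh:
            mat[idx[i], idx[j]] = w
    return WeightMatrix(unit_ids=graph.unit_ids, matrix=mat)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_edge_list_csv(path) -> list[tuple[str, str]]:
    """Read an undirected edge list CSV with header ``unit_a,unit_b``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"unit_a", "unit_b"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns unit_a,unit_b")
        return [(row["unit_a"], row["unit_b"]) for row in reader]


def read_units_csv(path) -> dict[str, str]:
    """Read a unit table CSV with header ``unit_id,district_id``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"unit_id", "district_id"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns unit_id,district_id")
        out: dict[str, str] = {}
        for row in reader:
            u = row["unit_id"]
            if u in out:
                raise ValueError(f"{path}: duplicate unit id {u!r}")
            out[u] = row["district_id"]
        return out


def write_edge_list_csv(graph: LatticeGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_a", "unit_b"])
        writer.writerows(graph.edges())


def write_units_csv(graph: LatticeGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_id", "district_id"])
        for u in graph.unit_ids:
            writer.writerow([u, graph.district_of[u]])
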