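"""Region contiguity graphs for areal (disease-mapping) models.

A :class:`RegionGraph` is the backbone of every spatial prior in this
package: the intrinsic CAR prior on structured region effects, the proper
CAR prior on spatially varying coefficients, and the neighbour bookkeeping
used by the Gibbs sampler all read adjacency and degree information from it.

Two regions are neighbours when they share a common boundary.  Graphs can be
built from an explicit edge list (one edge per line in a text file) or
derived from polygon geometries (queen contiguity: any shared boundary point
counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import shape
from shapely.validation import explain_validity


class GraphError(ValueError):
    """Invalid region graph input (unknown label, self edge, bad geometry)."""


@dataclass(frozen=True)
class RegionGraph:
    """Undirected contiguity graph over labelled regions.

    Parameters
    ----------
    region_ids
        Ordered region labels; this order fixes the index of every region in
        all precision matrices and effect vectors downstream.
    edges
        Unordered pairs of region *indices* (stored as ``(i, j)`` with
        ``i < j``); symmetric by construction, no self edges.
    """

    region_ids: tuple[str, ...]
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise GraphError("duplicate region labels")
        for i, j in self.edges:
            if i == j:
                raise GraphError(f"self-edge at region {self.region_ids[i]!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise GraphError("edge index out of range")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Neighbour count d_j per region, in region_ids order."""
        d = np.zeros(self.n_regions, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix W."""
        W = np.zeros((self.n_regions, self.n_regions))
        for i, j in self.edges:
            W[i, j] = W[j, i] = 1.0
        return W

    def neighbors(self, j: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == j:
                out.append(b)
            elif b == j:
                out.append(a)
        return sorted(out)

    def components(self) -> list[list[int]]:
        """Connected components as sorted index lists (deterministic order)."""
        adj = {k: set() for k in range(self.n_regions)}
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        seen: set[int] = set()
        comps = []
        for start in range(self.n_regions):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            comps.append(sorted(comp))
        return comps

    def index_of(self, label: str) -> int:
        try:
            return self.region_ids.index(label)
        except ValueError:
            raise GraphError(f"unknown region label {label!r}") from None


def build_region_graph(
    edge_list: Iterable[tuple[str, str]], region_ids: Sequence[str]
) -> RegionGraph:
    """Build a :class:`RegionGraph` from labelled edges.

    Every label in ``edge_list`` must appear in ``region_ids``; self edges
    are rejected.  Region order is fixed to ``region_ids`` order.
    """
    ids = tuple(region_ids)
    index = {lab: k for k, lab in enumerate(ids)}
    edges = set()
    for a, b in edge_list:
        if a not in index:
            raise GraphError(f"unknown region label {a!r} in edge list")
        if b not in index:
            raise GraphError(f"unknown region label {b!r} in edge list")
        if a == b:
            raise GraphError(f"self-edge ({a!r}, {b!r}) not allowed")
        i, j = index[a], index[b]
        edges.add((min(i, j), max(i, j)))
    return RegionGraph(region_ids=ids, edges=frozenset(edges))


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a plain-text edge list: two whitespace-separated labels per line,
    ``#`` comment lines ignored."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphError(f"bad edge line: {raw!r}")
        out.append((parts[0], parts[1]))
    return out


def graph_from_polygons(
    geojson: dict | str | Path, label_property: str = "name"
) -> RegionGraph:
    """Derive queen contiguity from a GeoJSON FeatureCollection.

    An edge is present iff two polygons touch (share at least a boundary
    point or segment).  Region labels come from ``label_property`` of each
    feature; region order follows feature order.
    """
    if not isinstance(geojson, dict):
        geojson = json.loads(Path(geojson).read_text())
    feats = geojson.get("features")
    if feats is None:
        raise GraphError("not a GeoJSON FeatureCollection")
    labels, geoms = [], []
    for f in feats:
        props = f.get("properties") or {}
        if label_property not in props:
            raise GraphError(f"feature missing property {label_property!r}")
        g = shape(f["geometry"])
        if not g.is_valid:
            raise GraphError(f"invalid geometry for {props[label_property]!r}: "
                             f"{explain_validity(g)}")
        labels.append(str(props[label_property]))
        geoms.append(g)
    if len(set(labels)) != len(labels):
        raise GraphError("duplicate region labels in feature collection")
    edges = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if geoms[i].touches(geoms[j]) or geoms[i].intersects(geoms[j]):
                # disjoint interiors sharing boundary -> touches; overlapping
                # (sliver) polygons also count as neighbours
                if not geoms[i].disjoint(geoms[j]):
                    edges.append((labels[i], labels[j]))
    return build_region_graph(edges, labels)


def south_africa_graph() -> RegionGraph:
    """The packaged 9-province South Africa contiguity graph.

    Provinces are ordered alphabetically by short label
    (EC, FS, Gau, KN, Lim, Mp, NC, NW, WC); edges are hand-coded from public
    province boundaries.  Demo/test fixture, connected, 17 edges.
    """
    ref = resources.files("svclogit.data").joinpath("za_province_adjacency.txt")
    labels = ("EC", "FS", "Gau", "KN", "Lim", "Mp", "NC", "NW", "WC")
    with resources.as_file(ref) as p:
        return build_region_graph(read_edge_list(p), labels)
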