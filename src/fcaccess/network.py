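"""Directed road networks and thresholded origin-destination travel times.

The network model is deliberately minimal: nodes with planar coordinates
(projected meters) and directed edges carrying a length and a speed limit,
from which the per-edge driving time in minutes is derived. One-way streets
are represented simply by the absence of the reverse edge. Travel-time
catchments are computed with multi-source Dijkstra pruned at the catchment
threshold, yielding a sparse long-format origin-destination matrix that the
FCA stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree, distance_matrix

__all__ = [
    "RoadNetwork",
    "TravelTimeMatrix",
    "edge_travel_time",
    "snap_points",
    "od_cost_matrix",
    "od_matrix_euclidean",
]


def edge_travel_time(length_m, speed_kmh):
    """Driving time in minutes for an edge of ``length_m`` at ``speed_kmh``.

    ``minutes = (length_m / 1000) / speed_kmh * 60 = length_m * 0.06 / speed_kmh``.
    Accepts scalars or arrays; inputs must be strictly positive.
    """
    length_m = np.asarray(length_m, dtype=float)
    speed_kmh = np.asarray(speed_kmh, dtype=float)
    if np.any(length_m <= 0):
        raise ValueError("edge length must be positive")
    if np.any(speed_kmh <= 0):
        raise ValueError("speed must be positive")
    out = length_m * 0.06 / speed_kmh
    return float(out) if out.ndim == 0 else out


@dataclass
class RoadNetwork:
    """Directed road graph over planar (projected-meter) coordinates.

    Attributes
    ----------
    nodes : pandas.DataFrame
        Columns ``node_id, x, y``; ids unique.
    edges : pandas.DataFrame
        Columns ``from_node, to_node, length_m, speed_kmh`` and derived
        ``minutes``. Every endpoint must exist in ``nodes``; a two-way
        street appears as two opposing directed edges.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.nodes = self.nodes.reset_index(drop=True)
        self.edges = self.edges.reset_index(drop=True)
        if self.nodes["node_id"].duplicated().any():
            dup = self.nodes.loc[self.nodes["node_id"].duplicated(), "node_id"]
            raise ValueError(f"duplicate node ids: {sorted(set(dup))[:5]}")
        if "minutes" not in self.edges.columns:
            self.edges = self.edges.assign(
                minutes=edge_travel_time(
                    self.edges["length_m"].to_numpy(),
                    self.edges["speed_kmh"].to_numpy(),
                )
            )
        if np.any(self.edges["minutes"].to_numpy() <= 0):
            raise ValueError("edge travel times must be strictly positive")
        known = set(self.nodes["node_id"])
        for col in ("from_node", "to_node"):
            missing = set(self.edges[col]) - known
            if missing:
                raise ValueError(f"edge {col} references unknown nodes: {sorted(missing)[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> pd.Series:
        """Positional index of each node id (stable order of ``nodes``)."""
        return pd.Series(np.arange(self.n_nodes), index=self.nodes["node_id"])

    def cost_matrix(self) -> csr_matrix:
        """Sparse node-by-node matrix of edge driving times in minutes.

        Parallel edges collapse to their minimum time.
        """
        idx = self.node_index()
        i = idx[self.edges["from_node"]].to_numpy()
        j = idx[self.edges["to_node"]].to_numpy()
        t = self.edges["minutes"].to_numpy(dtype=float)
        # keep the fastest of any parallel edges
        order = np.lexsort((t, j, i))
        i, j, t = i[order], j[order], t[order]
        first = np.ones(len(i), dtype=bool)
        first[1:] = (i[1:] != i[:-1]) | (j[1:] != j[:-1])
        return csr_matrix((t[first], (i[first], j[first])), shape=(self.n_nodes, self.n_nodes))

    @classmethod
    def from_csv(cls, nodes_path, edges_path) -> "RoadNetwork":
        """Load from ``node_id,x,y`` and ``from_node,to_node,length_m,speed_kmh,oneway`` CSVs.

        ``oneway`` is 0 or 1; 0 emits the reverse edge as well.
        """
        nodes = pd.read_csv(nodes_path)
        raw = pd.read_csv(edges_path)
        for col in ("from_node", "to_node", "length_m", "speed_kmh"):
            if col not in raw.columns:
                raise ValueError(f"edge file missing column {col!r}")
        if "oneway" not in raw.columns:
            raw = raw.assign(oneway=1)
        twoway = raw[raw["oneway"] == 0]
        reverse = twoway.rename(columns={"from_node": "to_node", "to_node": "from_node"})
        edges = pd.concat([raw, reverse], ignore_index=True)[
            ["from_node", "to_node", "length_m", "speed_kmh"]
        ]
        return cls(nodes=nodes[["node_id", "x", "y"]], edges=edges)

    def to_csv(self, nodes_path, edges_path) -> None:
        """Write directed node/edge CSVs (every edge emitted as oneway=1)."""
        self.nodes.to_csv(nodes_path, index=False)
        out = self.edges[["from_node", "to_node", "length_m", "speed_kmh"]].assign(oneway=1)
        out.to_csv(edges_path, index=False)


def snap_points(points: pd.DataFrame, network: RoadNetwork) -> pd.Series:
    """Map each point to its nearest network node (Euclidean distance).

    ``points`` needs columns ``id, x, y``. Exact distance ties break to the
    smallest node id, so snapping is fully deterministic. Returns a Series
    ``point id -> node_id``.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot snap to an empty network")
    nodes = network.nodes.sort_values("node_id").reset_index(drop=True)
    xy = nodes[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pts = points[["x", "y"]].to_numpy(dtype=float)
    k = min(2, len(nodes))
    dist, nearest = tree.query(pts, k=k)
    dist, nearest = dist.reshape(len(pts), k), nearest.reshape(len(pts), k)
    node_ids = nodes["node_id"].to_numpy()
    chosen = node_ids[nearest[:, 0]]
    if k == 2:
        # resolve exact distance ties toward the smallest node id
        tied = np.flatnonzero(dist[:, 1] <= dist[:, 0] * (1 + 1e-12))
        for row in tied:
            cands = tree.query_ball_point(pts[row], dist[row, 0] * (1 + 1e-12) + 1e-12)
            exact = [c for c in cands
                     if np.hypot(*(xy[c] - pts[row])) <= dist[row, 0] + 1e-12]
            chosen[row] = node_ids[min(exact)]
    return pd.Series(chosen, index=points["id"].to_numpy(), name="node_id")


@dataclass
class TravelTimeMatrix:
    """Sparse long-format travel times for in-catchment pairs only.

    ``table`` has columns ``demand_id, supply_id, minutes`` with one row per
    reachable pair (``minutes <= d_max``); unreachable pairs are simply
    absent. Zero minutes (co-located points) are allowed.
    """

    table: pd.DataFrame
    d_max: float

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if not self.d_max > 0:
            raise ValueError(f"d_max must be positive, got {self.d_max}")
        t = self.table["minutes"].to_numpy(dtype=float)
        if np.any(t < 0):
            raise ValueError("travel times must be non-negative")
        if np.any(t > self.d_max):
            raise ValueError("travel time exceeds d_max; filter before constructing")
        if self.table.duplicated(["demand_id", "supply_id"]).any():
            raise ValueError("duplicate (demand_id, supply_id) pairs")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path, d_max: float) -> "TravelTimeMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df[["demand_id", "supply_id", "minutes"]], d_max)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def od_cost_matrix(
    network: RoadNetwork,
    origins: pd.Series,
    destinations: pd.Series,
    d_max: float,
) -> TravelTimeMatrix:
    """Thresholded shortest-path travel times, origins to destinations.

    ``origins`` maps demand ids to network node ids (e.g. the output of
    :func:`snap_points`); ``destinations`` maps supply ids likewise. For
    each origin node a single-source Dijkstra search is expanded over the
    directed edge times and pruned once the accumulated cost exceeds
    ``d_max``, so one-way streets make the matrix asymmetric. Only pairs
    with shortest-path time <= ``d_max`` are stored; unreachable pairs are
    absent, not errors.
    """
    if not d_max > 0:
        raise ValueError(f"d_max must be positive, got {d_max}")
    idx = network.node_index()
    for name, mapping in (("origin", origins), ("destination", destinations)):
        unknown = set(mapping) - set(idx.index)
        if unknown:
            raise ValueError(f"unknown {name} nodes: {sorted(unknown)[:5]}")
    o_nodes = idx[origins.to_numpy()].to_numpy()
    dest_nodes = idx[destinations.to_numpy()].to_numpy()
    uniq_o, o_inv = np.unique(o_nodes, return_inverse=True)

    graph = network.cost_matrix()
    dist = dijkstra(graph, directed=True, indices=uniq_o, limit=d_max)
    sub = dist[:, dest_nodes]  # unique-origin x destination travel times

    rows = []
    demand_ids = np.asarray(origins.index)
    supply_ids = np.asarray(destinations.index)
    t = sub[o_inv, :]  # demand x supply
    keep = t <= d_max
    di, sj = np.nonzero(keep)
    return TravelTimeMatrix(
        table=pd.DataFrame(
            {
                "demand_id": demand_ids[di],
                "supply_id": supply_ids[sj],
                "minutes": t[di, sj],
            }
        ),
        d_max=d_max,
    )


def od_matrix_euclidean(
    demand: pd.DataFrame,
    supply: pd.DataFrame,
    speed_kmh: float,
    d_max: float,
) -> TravelTimeMatrix:
    """Straight-line travel-time matrix for data without a road network.

    Times are Euclidean distance at a constant speed; pairs beyond ``d_max``
    are dropped. ``demand`` and ``supply`` need columns ``id, x, y``.
    """
    if not speed_kmh > 0:
        raise ValueError("speed must be positive")
    if not d_max > 0:
        raise ValueError(f"d_max must be positive, got {d_max}")
    dm = distance_matrix(
        demand[["x", "y"]].to_numpy(dtype=float),
        supply[["x", "y"]].to_numpy(dtype=float),
    )
    t = dm * 0.06 / speed_kmh
    di, sj = np.nonzero(t <= d_max)
    return TravelTimeMatrix(
        table=pd.DataFrame(
            {
                "demand_id": demand["id"].to_numpy()[di],
                "supply_id": supply["id"].to_numpy()[sj],
                "minutes": t[di, sj],
            }
        ),
        d_max=d_max,
    )
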