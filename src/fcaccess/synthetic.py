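"""Seeded synthetic regions: population grids, service sites, road lattices.

The generator emulates the structure of the data an accessibility study of
this kind runs on, so the whole pipeline is exercisable without external
data: a hectare-style (100 m) population grid with an urban core and a
sparse rural floor, practice sites clustered toward population, and a car
road lattice with heterogeneous speed limits and one-way streets.

Population density is monocentric by default — a centre peak with
exponential radial decay on top of a uniform rural floor — and cell counts
are Poisson draws around that mean, so empty cells (forest, farmland)
arise naturally and are dropped. Multiple centres give polycentric
("two-town") regions. Everything is driven by one integer seed; a fixed
seed reproduces byte-identical scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import DemandSet, SupplySet
from .network import RoadNetwork, edge_travel_time

__all__ = [
    "ScenarioConfig",
    "make_population_grid",
    "make_supply_sites",
    "make_lattice_network",
    "make_scenario",
    "preset",
    "write_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic study region.

    Attributes
    ----------
    seed : int
        PRNG seed; fixes every random draw in the scenario.
    width_m, height_m : float
        Extent of the region in meters.
    cell_size_m : float
        Population grid cell edge; 100 m mimics a hectare census grid.
    centers : tuple
        Urban centres as ``(x_fraction, y_fraction, peak_scale)`` triples;
        each adds ``peak_scale * center_peak_density`` to the density at
        its core.
    center_peak_density : float
        Mean inhabitants per cell at a centre (scale 1.0).
    decay_range_m : float
        e-folding radius of the exponential density fall-off.
    rural_floor_density : float
        Mean inhabitants per cell far from any centre.
    n_supply : int
        Number of practice sites.
    clustering : float
        Probability that a site is placed population-proportionally
        (1.0 = fully clustered, 0.0 = uniform over the extent).
    capacity_range : tuple[int, int]
        Inclusive range of integer practitioners per site.
    lattice_spacing_m : float
        Road lattice node spacing.
    speed_classes : tuple[float, ...]
        Speed limits (km/h) sampled per street.
    oneway_fraction : float
        Fraction of streets turned one-way (where strong connectivity
        allows).
    """

    seed: int = 0
    width_m: float = 12_000.0
    height_m: float = 12_000.0
    cell_size_m: float = 100.0
    centers: tuple = ((0.5, 0.5, 1.0),)
    center_peak_density: float = 60.0
    decay_range_m: float = 2_000.0
    rural_floor_density: float = 0.4
    n_supply: int = 40
    clustering: float = 0.8
    capacity_range: tuple = (1, 5)
    lattice_spacing_m: float = 600.0
    speed_classes: tuple = (30.0, 50.0, 60.0, 80.0)
    oneway_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.height_m <= 0:
            raise ValueError("extent must be positive")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must lie in [0, 1]")
        if not 0.0 <= self.oneway_fraction <= 1.0:
            raise ValueError("oneway_fraction must lie in [0, 1]")


def _density(cfg: ScenarioConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean inhabitants per cell at coordinates (x, y)."""
    mu = np.full(x.shape, cfg.rural_floor_density, dtype=float)
    for fx, fy, scale in cfg.centers:
        cx, cy = fx * cfg.width_m, fy * cfg.height_m
        r = np.hypot(x - cx, y - cy)
        mu += scale * cfg.center_peak_density * np.exp(-r / cfg.decay_range_m)
    return mu


def make_population_grid(cfg: ScenarioConfig) -> DemandSet:
    """Poisson population counts on cell centroids; empty cells dropped."""
    rng = np.random.default_rng(cfg.seed)
    nx = int(cfg.width_m // cfg.cell_size_m)
    ny = int(cfg.height_m // cfg.cell_size_m)
    if nx < 1 or ny < 1:
        raise ValueError("extent smaller than one grid cell")
    cx = (np.arange(nx) + 0.5) * cfg.cell_size_m
    cy = (np.arange(ny) + 0.5) * cfg.cell_size_m
    X, Y = np.meshgrid(cx, cy)
    x, y = X.ravel(), Y.ravel()
    counts = rng.poisson(_density(cfg, x, y))
    keep = counts > 0
    table = pd.DataFrame(
        {
            "id": [f"d{k}" for k in np.flatnonzero(keep)],
            "x": x[keep],
            "y": y[keep],
            "pop": counts[keep].astype(float),
        }
    )
    return DemandSet(table)


def expected_mean_count(cfg: ScenarioConfig) -> float:
    """Analytic mean inhabitants per cell over the full grid (zeros included)."""
    nx = int(cfg.width_m // cfg.cell_size_m)
    ny = int(cfg.height_m // cfg.cell_size_m)
    cx = (np.arange(nx) + 0.5) * cfg.cell_size_m
    cy = (np.arange(ny) + 0.5) * cfg.cell_size_m
    X, Y = np.meshgrid(cx, cy)
    return float(_density(cfg, X.ravel(), Y.ravel()).mean())


def make_supply_sites(cfg: ScenarioConfig, grid: DemandSet) -> SupplySet:
    """Practice sites mixing population-proportional and uniform placement.

    With probability ``clustering`` a site lands in a populated cell drawn
    proportionally to its inhabitants (jittered within the cell); otherwise
    it is uniform over the extent. Capacities are integers drawn uniformly
    from ``capacity_range``.
    """
    if len(grid) == 0:
        raise ValueError("population grid is empty")
    if cfg.n_supply < 1:
        raise ValueError("n_supply must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1)
    pop = grid.table["pop"].to_numpy(dtype=float)
    p = pop / pop.sum()
    xs = np.empty(cfg.n_supply)
    ys = np.empty(cfg.n_supply)
    clustered = rng.random(cfg.n_supply) < cfg.clustering
    half = cfg.cell_size_m / 2
    for k in range(cfg.n_supply):
        if clustered[k]:
            cell = rng.choice(len(grid), p=p)
            xs[k] = grid.table["x"].iloc[cell] + rng.uniform(-half, half)
            ys[k] = grid.table["y"].iloc[cell] + rng.uniform(-half, half)
        else:
            xs[k] = rng.uniform(0, cfg.width_m)
            ys[k] = rng.uniform(0, cfg.height_m)
    lo, hi = cfg.capacity_range
    caps = rng.integers(lo, hi + 1, size=cfg.n_supply).astype(float)
    table = pd.DataFrame(
        {"id": [f"s{k}" for k in range(cfg.n_supply)], "x": xs, "y": ys, "capacity": caps}
    )
    return SupplySet(table)


def make_lattice_network(cfg: ScenarioConfig) -> RoadNetwork:
    """Road lattice with sampled speed limits and one-way streets.

    Nodes sit on a regular grid; each pair of 4-neighbours starts as a
    two-way street with a speed drawn from ``speed_classes``. A seeded
    fraction of streets is then made one-way by deleting one direction —
    but only where the deletion keeps the whole network strongly
    connected, so every location can still reach (and be reached from)
    everywhere.
    """
    if cfg.lattice_spacing_m <= 0:
        raise ValueError("lattice spacing must be positive")
    nx = int(cfg.width_m // cfg.lattice_spacing_m) + 1
    ny = int(cfg.height_m // cfg.lattice_spacing_m) + 1
    if nx < 2 or ny < 2:
        raise ValueError("lattice degenerate: need at least 2 nodes per axis")
    rng = np.random.default_rng(cfg.seed + 2)

    node_ids = np.arange(nx * ny)
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    nodes = pd.DataFrame(
        {
            "node_id": node_ids,
            "x": gx.ravel() * cfg.lattice_spacing_m,
            "y": gy.ravel() * cfg.lattice_spacing_m,
        }
    )

    # undirected streets between 4-neighbours
    streets = []
    def nid(ix, iy):
        return iy * nx + ix
    for iy in range(ny):
        for ix in range(nx):
            if ix + 1 < nx:
                streets.append((nid(ix, iy), nid(ix + 1, iy)))
            if iy + 1 < ny:
                streets.append((nid(ix, iy), nid(ix, iy + 1)))
    streets = np.array(streets)
    speeds = rng.choice(np.asarray(cfg.speed_classes, dtype=float), size=len(streets))
    length = cfg.lattice_spacing_m

    # directed edge bookkeeping: (u, v) and (v, u) for every street
    present = {}
    for (u, v), s in zip(streets, speeds):
        present[(int(u), int(v))] = s
        present[(int(v), int(u))] = s

    def strongly_connected(edge_dict) -> bool:
        if not edge_dict:
            return False
        ii, jj = zip(*edge_dict.keys())
        g = csr_matrix(
            (np.ones(len(ii)), (ii, jj)), shape=(len(node_ids), len(node_ids))
        )
        n_comp, _ = connected_components(g, directed=True, connection="strong")
        return n_comp == 1

    n_oneway = int(round(cfg.oneway_fraction * len(streets)))
    order = rng.permutation(len(streets))
    flip = rng.random(len(streets)) < 0.5
    made = 0
    for k in order:
        if made >= n_oneway:
            break
        u, v = map(int, streets[k])
        drop = (v, u) if flip[k] else (u, v)
        saved = present.pop(drop)
        if strongly_connected(present):
            made += 1
        else:
            present[drop] = saved

    edges = pd.DataFrame(
        [(u, v, length, s) for (u, v), s in sorted(present.items())],
        columns=["from_node", "to_node", "length_m", "speed_kmh"],
    )
    return RoadNetwork(nodes=nodes, edges=edges)


def make_scenario(cfg: ScenarioConfig) -> tuple[DemandSet, SupplySet, RoadNetwork]:
    """Generate the three layers of a scenario from one config."""
    grid = make_population_grid(cfg)
    supply = make_supply_sites(cfg, grid)
    net = make_lattice_network(cfg)
    return grid, supply, net


_PRESETS = {
    "monocentric": dict(),
    "two-town": dict(
        width_m=15_000.0,
        centers=((0.25, 0.5, 1.0), (0.75, 0.5, 0.85)),
        decay_range_m=1_500.0,
        n_supply=50,
    ),
    "uniform": dict(
        center_peak_density=0.0,
        rural_floor_density=5.0,
        clustering=0.0,
    ),
}


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named study-region presets: ``monocentric``, ``two-town``, ``uniform``."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return ScenarioConfig(seed=seed, **_PRESETS[name])


def write_scenario(
    demand: DemandSet, supply: SupplySet, net: RoadNetwork, outdir
) -> dict:
    """Write the standard CSV layers of a scenario; returns the path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "demand": out / "demand.csv",
        "supply": out / "supply.csv",
        "nodes": out / "nodes.csv",
        "edges": out / "edges.csv",
    }
    demand.table.rename(columns={"pop": "value"}).to_csv(
        paths["demand"], index=False, float_format="%.12g"
    )
    supply.table.rename(columns={"capacity": "value"}).to_csv(
        paths["supply"], index=False, float_format="%.12g"
    )
    net.to_csv(paths["nodes"], paths["edges"])
    return {k: str(v) for k, v in paths.items()}
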