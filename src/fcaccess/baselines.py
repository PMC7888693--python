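"""Classic floating catchment area variants for comparison runs.

These are the methods the Huff-model 3SFCA is usually positioned against.
Each shares the I/O contract of :func:`fcaccess.core.mh3sfca` — same inputs,
same :class:`~fcaccess.core.AccessibilityResult` — so outputs are directly
comparable. Formulas follow the original sources:

* 2SFCA (Luo & Wang 2003): binary catchments.
  ``R_j = S_j / sum_i D_i`` over in-catchment ``i``; ``A_i = sum_j R_j``.
* E2SFCA (Luo & Qi 2009): discrete subzone weights ``W_r``.
  ``R_j = S_j / sum_i D_i W_r(i,j)``; ``A_i = sum_j R_j W_r(i,j)``.
* 3SFCA (Wan, Zou & Sternberg 2012): travel-time-only competition.
  ``G_ij = W_ij / sum_k W_ik``; ``R_j = S_j / sum_i G_ij D_i W_ij``;
  ``A_i = sum_j G_ij R_j W_ij``.
* M2SFCA (Delamater 2013): distance weighting on both sides.
  ``A_i = sum_j S_j W_ij^2 / sum_k D_k W_kj``.

2SFCA conserves capacity exactly (``sum_i A_i D_i = sum_j S_j`` whenever
every site has in-catchment demand); M2SFCA — like MH3SFCA — only bounds it
from above, reflecting that a spatially suboptimal arrangement of sites
delivers less aggregate access than the capacity it deploys.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    AccessibilityResult,
    DemandSet,
    SupplySet,
    _check_ids,
)
from .decay import DecayParams, weight_for
from .network import TravelTimeMatrix

__all__ = ["fca_2sfca", "fca_e2sfca", "fca_3sfca", "fca_m2sfca"]


def _weighted_fca(
    T: TravelTimeMatrix,
    S: SupplySet,
    D: DemandSet,
    weights: np.ndarray,
    method: str,
    params: DecayParams | None,
) -> AccessibilityResult:
    """Shared two-step skeleton: R_j from weighted demand, A_i = sum R_j W."""
    tab = T.table
    pop = D.table.set_index("id")["pop"]
    dw = pop[tab["demand_id"]].to_numpy(dtype=float) * weights
    per_site = pd.Series(dw).groupby(tab["supply_id"].to_numpy()).sum()

    sites = S.table[["id"]].rename(columns={"id": "supply_id"}).copy()
    sites["allocated_demand"] = per_site.reindex(sites["supply_id"]).fillna(0.0).to_numpy()
    cap = S.table["capacity"].to_numpy(dtype=float)
    sites["R"] = np.where(
        sites["allocated_demand"] > 0, cap / sites["allocated_demand"], 0.0
    )

    r = sites.set_index("supply_id")["R"]
    contrib = r[tab["supply_id"]].to_numpy(dtype=float) * weights
    A = pd.Series(contrib).groupby(tab["demand_id"].to_numpy()).sum()
    return _assemble(T, S, D, A, sites, method, params)


def _assemble(T, S, D, A, sites, method, params) -> AccessibilityResult:
    demand = (
        D.table[["id", "x", "y", "pop"]].copy()
        if {"x", "y"} <= set(D.table.columns)
        else D.table[["id", "pop"]].copy()
    )
    demand["A"] = A.reindex(demand["id"]).fillna(0.0).to_numpy()
    metadata = {
        "method": method,
        **(params.as_dict() if params is not None else {"d_max": T.d_max}),
        "n_pairs": int(len(T.table)),
        "n_demand": len(D),
        "n_supply": len(S),
        "n_uncovered_demand": int((~demand["id"].isin(T.table["demand_id"])).sum()),
        "n_undemanded_supply": int((sites["allocated_demand"] <= 0).sum()),
    }
    return AccessibilityResult(
        demand=demand, ratios=sites[["supply_id", "R"]], metadata=metadata
    )


def fca_2sfca(T: TravelTimeMatrix, S: SupplySet, D: DemandSet) -> AccessibilityResult:
    """Two-step FCA with binary (all-or-nothing) catchment weights."""
    _check_ids(T, S, D)
    w = np.ones(len(T.table), dtype=float)
    return _weighted_fca(T, S, D, w, "2sfca", None)


def fca_e2sfca(
    T: TravelTimeMatrix, S: SupplySet, D: DemandSet, params: DecayParams
) -> AccessibilityResult:
    """Enhanced 2SFCA: Gaussian weights discretized over travel-time subzones."""
    _check_ids(T, S, D)
    if params.mode != "subzones":
        raise ValueError("E2SFCA requires DecayParams in subzones mode")
    w = weight_for(T.table["minutes"].to_numpy(), params)
    return _weighted_fca(T, S, D, np.atleast_1d(w), "e2sfca", params)


def fca_3sfca(
    T: TravelTimeMatrix, S: SupplySet, D: DemandSet, params: DecayParams
) -> AccessibilityResult:
    """Three-step FCA with travel-time-based competition among sites.

    The selection weight ``G_ij = W_ij / sum_k W_ik`` splits each
    location's demand over reachable sites by travel time alone (capacity
    does not enter the split, unlike the Huff allocation).
    """
    _check_ids(T, S, D)
    tab = T.table
    w = np.atleast_1d(weight_for(tab["minutes"].to_numpy(), params))
    denom = pd.Series(w).groupby(tab["demand_id"].to_numpy()).transform("sum").to_numpy()
    G = w / denom

    pop = D.table.set_index("id")["pop"]
    dw = G * pop[tab["demand_id"]].to_numpy(dtype=float) * w
    per_site = pd.Series(dw).groupby(tab["supply_id"].to_numpy()).sum()
    sites = S.table[["id"]].rename(columns={"id": "supply_id"}).copy()
    sites["allocated_demand"] = per_site.reindex(sites["supply_id"]).fillna(0.0).to_numpy()
    cap = S.table["capacity"].to_numpy(dtype=float)
    sites["R"] = np.where(
        sites["allocated_demand"] > 0, cap / sites["allocated_demand"], 0.0
    )

    r = sites.set_index("supply_id")["R"]
    contrib = G * r[tab["supply_id"]].to_numpy(dtype=float) * w
    A = pd.Series(contrib).groupby(tab["demand_id"].to_numpy()).sum()
    return _assemble(T, S, D, A, sites, "3sfca", params)


def fca_m2sfca(
    T: TravelTimeMatrix, S: SupplySet, D: DemandSet, params: DecayParams
) -> AccessibilityResult:
    """Modified 2SFCA: decay applied on both the supply and demand side.

    ``A_i = sum_j S_j W_ij^2 / sum_k D_k W_kj`` — equivalently the 2SFCA
    skeleton with weighted demand denominators and the squared weight in
    the accessibility sum, which encodes that service delivered at a
    distance is itself discounted.
    """
    _check_ids(T, S, D)
    tab = T.table
    w = np.atleast_1d(weight_for(tab["minutes"].to_numpy(), params))

    pop = D.table.set_index("id")["pop"]
    dw = pop[tab["demand_id"]].to_numpy(dtype=float) * w
    per_site = pd.Series(dw).groupby(tab["supply_id"].to_numpy()).sum()
    sites = S.table[["id"]].rename(columns={"id": "supply_id"}).copy()
    sites["allocated_demand"] = per_site.reindex(sites["supply_id"]).fillna(0.0).to_numpy()
    cap = S.table["capacity"].to_numpy(dtype=float)
    sites["R"] = np.where(
        sites["allocated_demand"] > 0, cap / sites["allocated_demand"], 0.0
    )

    r = sites.set_index("supply_id")["R"]
    contrib = r[tab["supply_id"]].to_numpy(dtype=float) * w**2
    A = pd.Series(contrib).groupby(tab["demand_id"].to_numpy()).sum()
    return _assemble(T, S, D, A, sites, "m2sfca", params)
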