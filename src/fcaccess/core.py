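"""The modified Huff-model three-step floating catchment area method.

MH3SFCA quantifies potential spatial accessibility — opportunities (e.g.
general practitioners) per person — at every population location. It runs
in three steps over the sparse set of in-catchment demand-supply pairs:

Step 1, Huff interaction probabilities. Each population location ``i``
splits its demand over the supply sites it can reach within the travel
threshold ``d_max``, proportionally to capacity times distance-decay
weight::

    Huff_ij = S_j * W_ij / sum_k S_k * W_ik        (k reachable from i)

The probabilities of each covered location sum to one, so total demand in
the system is conserved — demand at a location only shifts away from a far
site when alternatives exist, it never evaporates.

Step 2, supply-demand ratios. Each site's capacity is divided by the
Huff-allocated, population-weighted demand it attracts::

    R_j = S_j / sum_i Huff_ij * D_i                (i reaching j)

Step 3, accessibility index. Each location sums its distance-weighted
share of the ratios of reachable sites::

    A_i = sum_j Huff_ij * R_j * W_ij

Because ``W_ij <= 1`` appears once more in step 3, the population-weighted
total ``sum_i A_i D_i`` is at most the total capacity, with equality only
when all travel times are zero: a spatially suboptimal configuration of
sites yields less aggregate access than the capacity it deploys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import DecayParams, weight_for
from .network import TravelTimeMatrix

__all__ = [
    "DemandSet",
    "SupplySet",
    "InteractionTable",
    "AccessibilityResult",
    "build_interactions",
    "supply_demand_ratio",
    "accessibility_index",
    "mh3sfca",
]

logger = logging.getLogger(__name__)


@dataclass
class DemandSet:
    """Population locations with inhabitant counts.

    ``table`` has columns ``id, x, y, pop`` (ids unique, counts finite and
    non-negative). In the intended use the rows are centroids of 100 m
    census grid cells, but any point layer works.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"]
            raise ValueError(f"duplicate demand ids: {sorted(set(dup))[:5]}")
        pop = self.table["pop"].to_numpy(dtype=float)
        if not np.all(np.isfinite(pop)) or np.any(pop < 0):
            raise ValueError("population counts must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_population(self) -> float:
        return float(self.table["pop"].sum())


@dataclass
class SupplySet:
    """Service sites with capacities (number of practitioners).

    ``table`` has columns ``id, x, y, capacity``; ids unique, capacities
    strictly positive (zero-capacity sites are rejected on construction).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"]
            raise ValueError(f"duplicate supply ids: {sorted(set(dup))[:5]}")
        cap = self.table["capacity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(cap)) or np.any(cap <= 0):
            bad = self.table.loc[~(cap > 0), "id"].tolist()
            raise ValueError(f"capacities must be finite and positive; offending sites: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_capacity(self) -> float:
        return float(self.table["capacity"].sum())


@dataclass
class InteractionTable:
    """Per-pair travel times, decay weights and Huff probabilities.

    One row per in-catchment ``(demand_id, supply_id)`` pair with columns
    ``minutes, weight, huff``; the Huff column of every demand location
    present sums to one.
    """

    table: pd.DataFrame
    params: DecayParams


@dataclass
class AccessibilityResult:
    """Output of an FCA run.

    ``demand`` carries one row per population location (``id, x, y, pop,
    A``; ``A`` is opportunities per person and equals 0 exactly when no
    site is within the catchment). ``ratios`` carries the per-site
    supply-demand ratios. ``metadata`` records the method, decay
    parameters, and counts of degenerate cases.
    """

    demand: pd.DataFrame
    ratios: pd.DataFrame
    metadata: dict

    def population_weighted_mean(self) -> float:
        d = self.demand
        pop = d["pop"].sum()
        return float((d["A"] * d["pop"]).sum() / pop) if pop > 0 else float("nan")


def _check_ids(T: TravelTimeMatrix, S: SupplySet, D: DemandSet | None) -> None:
    bad_s = set(T.table["supply_id"]) - set(S.table["id"])
    if bad_s:
        raise ValueError(f"travel matrix references unknown supply ids: {sorted(bad_s)[:5]}")
    if D is not None:
        bad_d = set(T.table["demand_id"]) - set(D.table["id"])
        if bad_d:
            raise ValueError(f"travel matrix references unknown demand ids: {sorted(bad_d)[:5]}")


def build_interactions(
    T: TravelTimeMatrix, S: SupplySet, params: DecayParams
) -> InteractionTable:
    """Step 1: decay weights and Huff probabilities for reachable pairs.

    ``Huff_ij = S_j W_ij / sum_k S_k W_ik`` with the sum over the supply
    sites reachable from ``i``. The denominator is positive whenever at
    least one site is reachable (weights and capacities are positive), so
    rows grouped by demand location are exactly normalized. Demand
    locations with no reachable site simply contribute no rows.
    """
    _check_ids(T, S, None)
    tab = T.table.copy()
    cap = S.table.set_index("id")["capacity"]
    tab["weight"] = weight_for(tab["minutes"].to_numpy(), params)
    sw = cap[tab["supply_id"]].to_numpy(dtype=float) * tab["weight"].to_numpy()
    denom = pd.Series(sw).groupby(tab["demand_id"].to_numpy()).transform("sum").to_numpy()
    tab["huff"] = sw / denom
    return InteractionTable(table=tab, params=params)


def supply_demand_ratio(
    I: InteractionTable, S: SupplySet, D: DemandSet
) -> pd.DataFrame:
    """Step 2: capacity per Huff-allocated person for each supply site.

    ``R_j = S_j / sum_i Huff_ij D_i``. Sites whose allocated demand is zero
    (no reachable population, or only zero-count cells) are assigned
    ``R_j = 0`` and counted, with a warning, rather than raising — an
    island site should not abort a regional run.

    Returns a DataFrame ``supply_id, R, allocated_demand``.
    """
    tab = I.table
    pop = D.table.set_index("id")["pop"]
    alloc = tab["huff"].to_numpy() * pop[tab["demand_id"]].to_numpy(dtype=float)
    per_site = (
        pd.Series(alloc).groupby(tab["supply_id"].to_numpy()).sum()
    )
    out = S.table[["id"]].rename(columns={"id": "supply_id"}).copy()
    out["allocated_demand"] = per_site.reindex(out["supply_id"]).fillna(0.0).to_numpy()
    cap = S.table["capacity"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        R = np.where(out["allocated_demand"] > 0, cap / out["allocated_demand"], 0.0)
    n_undemanded = int((out["allocated_demand"] <= 0).sum())
    if n_undemanded:
        logger.warning(
            "%d supply site(s) attract no demand within the catchment; R set to 0",
            n_undemanded,
        )
    out["R"] = R
    return out


def accessibility_index(I: InteractionTable, R: pd.DataFrame) -> pd.Series:
    """Step 3: accessibility index for every covered demand location.

    ``A_i = sum_j Huff_ij R_j W_ij``. Locations absent from the interaction
    table are handled by the caller (they receive 0).
    """
    tab = I.table
    r = R.set_index("supply_id")["R"]
    contrib = tab["huff"].to_numpy() * r[tab["supply_id"]].to_numpy(dtype=float) * tab["weight"].to_numpy()
    return pd.Series(contrib).groupby(tab["demand_id"].to_numpy()).sum()


def mh3sfca(
    T: TravelTimeMatrix,
    S: SupplySet,
    D: DemandSet,
    params: DecayParams,
) -> AccessibilityResult:
    """Run all three MH3SFCA steps and assemble the result.

    Deterministic for fixed inputs; demand locations with no in-catchment
    supply receive ``A = 0`` and are counted in the metadata.
    """
    _check_ids(T, S, D)
    I = build_interactions(T, S, params)
    ratios = supply_demand_ratio(I, S, D)
    A = accessibility_index(I, ratios)

    demand = D.table[["id", "x", "y", "pop"]].copy() if {"x", "y"} <= set(D.table.columns) else D.table[["id", "pop"]].copy()
    demand["A"] = A.reindex(demand["id"]).fillna(0.0).to_numpy()
    n_uncovered = int((~demand["id"].isin(I.table["demand_id"])).sum())
    metadata = {
        "method": "mh3sfca",
        **params.as_dict(),
        "n_pairs": int(len(I.table)),
        "n_demand": len(D),
        "n_supply": len(S),
        "n_uncovered_demand": n_uncovered,
        "n_undemanded_supply": int((ratios["allocated_demand"] <= 0).sum()),
    }
    return AccessibilityResult(
        demand=demand, ratios=ratios[["supply_id", "R"]], metadata=metadata
    )
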