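"""Independent dense reference implementations of every FCA method.

Written as explicit triple loops over dense demand-by-supply travel-time
matrices (``inf`` marks an unreachable pair), straight from the method
formulas and deliberately sharing no code with the sparse pipeline in
``fcaccess``. Used as oracles by the unit and acceptance tests.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from fcaccess.core import DemandSet, SupplySet
from fcaccess.network import TravelTimeMatrix


def dense_weight(d: float, params) -> float:
    """Gaussian weight of one in-catchment distance, per the decay mode."""
    if params.mode == "subzones":
        width = params.d_max / params.n_zones
        zone = min(int(d // width), params.n_zones - 1)
        d = (zone + 0.5) * width
    return math.exp(-(d**2) / params.beta)


def mh3sfca_dense(dmat: np.ndarray, S: np.ndarray, D: np.ndarray, params) -> np.ndarray:
    """Huff 3SFCA by literal evaluation of the three step formulas."""
    n_d, n_s = dmat.shape
    W = np.zeros((n_d, n_s))
    for i in range(n_d):
        for j in range(n_s):
            if dmat[i, j] <= params.d_max:
                W[i, j] = dense_weight(dmat[i, j], params)
    huff = np.zeros((n_d, n_s))
    for i in range(n_d):
        denom = sum(S[k] * W[i, k] for k in range(n_s) if dmat[i, k] <= params.d_max)
        for j in range(n_s):
            if dmat[i, j] <= params.d_max and denom > 0:
                huff[i, j] = S[j] * W[i, j] / denom
    R = np.zeros(n_s)
    for j in range(n_s):
        dem = sum(huff[i, j] * D[i] for i in range(n_d) if dmat[i, j] <= params.d_max)
        R[j] = S[j] / dem if dem > 0 else 0.0
    A = np.zeros(n_d)
    for i in range(n_d):
        A[i] = sum(
            huff[i, j] * R[j] * W[i, j] for j in range(n_s) if dmat[i, j] <= params.d_max
        )
    return A


def sfca2_dense(dmat, S, D, d_max) -> np.ndarray:
    n_d, n_s = dmat.shape
    R = np.zeros(n_s)
    for j in range(n_s):
        dem = sum(D[i] for i in range(n_d) if dmat[i, j] <= d_max)
        R[j] = S[j] / dem if dem > 0 else 0.0
    A = np.zeros(n_d)
    for i in range(n_d):
        A[i] = sum(R[j] for j in range(n_s) if dmat[i, j] <= d_max)
    return A


def e2sfca_dense(dmat, S, D, params) -> np.ndarray:
    n_d, n_s = dmat.shape
    R = np.zeros(n_s)
    for j in range(n_s):
        dem = sum(
            D[i] * dense_weight(dmat[i, j], params)
            for i in range(n_d)
            if dmat[i, j] <= params.d_max
        )
        R[j] = S[j] / dem if dem > 0 else 0.0
    A = np.zeros(n_d)
    for i in range(n_d):
        A[i] = sum(
            R[j] * dense_weight(dmat[i, j], params)
            for j in range(n_s)
            if dmat[i, j] <= params.d_max
        )
    return A


def sfca3_dense(dmat, S, D, params) -> np.ndarray:
    n_d, n_s = dmat.shape
    W = np.zeros((n_d, n_s))
    for i in range(n_d):
        for j in range(n_s):
            if dmat[i, j] <= params.d_max:
                W[i, j] = dense_weight(dmat[i, j], params)
    G = np.zeros((n_d, n_s))
    for i in range(n_d):
        denom = sum(W[i, k] for k in range(n_s) if dmat[i, k] <= params.d_max)
        for j in range(n_s):
            if dmat[i, j] <= params.d_max and denom > 0:
                G[i, j] = W[i, j] / denom
    R = np.zeros(n_s)
    for j in range(n_s):
        dem = sum(
            G[i, j] * D[i] * W[i, j] for i in range(n_d) if dmat[i, j] <= params.d_max
        )
        R[j] = S[j] / dem if dem > 0 else 0.0
    A = np.zeros(n_d)
    for i in range(n_d):
        A[i] = sum(
            G[i, j] * R[j] * W[i, j] for j in range(n_s) if dmat[i, j] <= params.d_max
        )
    return A


def m2sfca_dense(dmat, S, D, params) -> np.ndarray:
    n_d, n_s = dmat.shape
    W = np.zeros((n_d, n_s))
    for i in range(n_d):
        for j in range(n_s):
            if dmat[i, j] <= params.d_max:
                W[i, j] = dense_weight(dmat[i, j], params)
    A = np.zeros(n_d)
    for i in range(n_d):
        for j in range(n_s):
            if dmat[i, j] <= params.d_max:
                dem = sum(D[k] * W[k, j] for k in range(n_d) if dmat[k, j] <= params.d_max)
                if dem > 0:
                    A[i] += S[j] * W[i, j] ** 2 / dem
    return A


def random_instance(rng: np.random.Generator, d_max: float = 30.0, allow_zero_pop=True):
    """Small random problem: dense distance matrix + typed sparse inputs.

    Returns ``(dmat, S, D, supply_set, demand_set, ttm)`` where ``dmat``
    holds ``inf`` for out-of-catchment pairs and ``ttm`` is the equivalent
    sparse :class:`TravelTimeMatrix`.
    """
    n_d = int(rng.integers(2, 31))
    n_s = int(rng.integers(1, 21))
    dmat = rng.uniform(0, d_max * 1.5, size=(n_d, n_s))
    dmat[rng.random((n_d, n_s)) < 0.2] = np.inf  # structurally unreachable
    # a few exact zeros (co-located points)
    zero = rng.random((n_d, n_s)) < 0.05
    dmat[zero] = 0.0
    S = rng.integers(1, 11, size=n_s).astype(float)
    low = 0 if allow_zero_pop else 1
    D = rng.integers(low, 501, size=n_d).astype(float)

    demand_ids = [f"i{i}" for i in range(n_d)]
    supply_ids = [f"j{j}" for j in range(n_s)]
    rows = [
        (demand_ids[i], supply_ids[j], dmat[i, j])
        for i in range(n_d)
        for j in range(n_s)
        if dmat[i, j] <= d_max
    ]
    ttm = TravelTimeMatrix(
        pd.DataFrame(rows, columns=["demand_id", "supply_id", "minutes"]), d_max=d_max
    )
    supply_set = SupplySet(
        pd.DataFrame({"id": supply_ids, "x": 0.0, "y": 0.0, "capacity": S})
    )
    demand_set = DemandSet(
        pd.DataFrame({"id": demand_ids, "x": 0.0, "y": 0.0, "pop": D})
    )
    return dmat, S, D, supply_set, demand_set, ttm
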