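"""Quantile classification and summary statistics for accessibility runs."""

from __future__ import annotations

import warnings
from decimal import ROUND_DOWN, Decimal

import numpy as np
import pandas as pd

from .core import AccessibilityResult

__all__ = [
    "quantile_classify",
    "summarize",
    "truncate8",
    "format_summary",
    "radial_quarter_contrast",
]


def quantile_classify(values, k: int = 5) -> np.ndarray:
    """Assign quantile classes 1..k (1 = lowest) to ``values``.

    Break points are the ``r/k`` empirical quantiles under the
    linear-interpolation definition; a value equal to a break point falls
    in the lower class. The minimum always lands in class 1 and the
    maximum in class k (for non-degenerate data). With tied or degenerate
    breaks a warning is emitted and classes collapse downward.
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if values.size < k:
        raise ValueError(f"need at least k={k} values, got {values.size}")
    breaks = np.quantile(values, np.arange(1, k) / k, method="linear")
    if np.any(np.diff(breaks) <= 0) or breaks[0] == values.min():
        warnings.warn("degenerate quantile breaks; classes will collapse", stacklevel=2)
    return 1 + np.searchsorted(breaks, values, side="left")


def truncate8(v: float) -> str:
    """Truncate (toward zero) to eight decimals, as printed on result maps."""
    return str(Decimal(repr(float(v))).quantize(Decimal("1.00000000"), rounding=ROUND_DOWN))


def summarize(result: AccessibilityResult) -> dict:
    """Headline statistics of an accessibility surface.

    Returns min, max, unweighted mean, population-weighted mean
    (sum A_i D_i / sum D_i) and the count of zero-access locations, at
    full precision.
    """
    d = result.demand
    if len(d) == 0:
        raise ValueError("empty result")
    A = d["A"].to_numpy(dtype=float)
    pop = d["pop"].to_numpy(dtype=float)
    return {
        "n_locations": int(len(d)),
        "min": float(A.min()),
        "max": float(A.max()),
        "mean": float(A.mean()),
        "weighted_mean": float((A * pop).sum() / pop.sum()) if pop.sum() > 0 else float("nan"),
        "n_zero_access": int((A == 0).sum()),
    }


def radial_quarter_contrast(result: AccessibilityResult, center_xy) -> tuple[float, float]:
    """Population-weighted mean index of the central vs peripheral quarter.

    Demand locations are ranked by distance to ``center_xy``; the nearest
    quarter is "central", the farthest quarter "peripheral". Returns the
    pair of population-weighted mean accessibility indices — a central
    excess mirrors the urban/rural contrast these methods are built to
    expose.
    """
    d = result.demand
    r = np.hypot(d["x"] - center_xy[0], d["y"] - center_xy[1]).to_numpy()
    order = np.argsort(r, kind="stable")
    q = max(1, len(d) // 4)

    def wmean(idx):
        A = d["A"].to_numpy()[idx]
        pop = d["pop"].to_numpy()[idx]
        return float((A * pop).sum() / pop.sum())

    return wmean(order[:q]), wmean(order[-q:])


def format_summary(summary: dict) -> str:
    """Human-readable summary with indices truncated to eight decimals."""
    lines = [
        f"locations:            {summary['n_locations']}",
        f"zero-access:          {summary['n_zero_access']}",
        f"min index:            {truncate8(summary['min'])}",
        f"max index:            {truncate8(summary['max'])}",
        f"mean index:           {truncate8(summary['mean'])}",
        f"pop-weighted mean:    {truncate8(summary['weighted_mean'])}",
    ]
    return "\n".join(lines)
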