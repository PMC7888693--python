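"""Readers and writers for point layers, OD matrices and results.

Point layers are plain CSV (``id,x,y,value``) or GeoJSON FeatureCollections
of Point features carrying a ``value`` property (and optionally an ``id``).
Coordinates are planar meters in a projected CRS; no reprojection is
performed. All round trips preserve full double precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AccessibilityResult, DemandSet, SupplySet

__all__ = [
    "read_points",
    "write_points_geojson",
    "write_result",
    "write_metadata",
    "file_digest",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _points_from_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"id", "x", "y", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("x", "y", "value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col!r} at row {bad[0] + 2}")
        df[col] = vals
    return df


def _points_from_geojson(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for k, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: feature {k} is not a Point")
        props = feat.get("properties") or {}
        if "value" not in props:
            raise ValueError(f"{path}: feature {k} lacks a 'value' property")
        x, y = geom["coordinates"][:2]
        rows.append(
            {"id": props.get("id", feat.get("id", k)), "x": x, "y": y, "value": props["value"]}
        )
    return pd.DataFrame(rows, columns=["id", "x", "y", "value"])


def read_points(path, kind: str, aggregate_duplicates: bool = False):
    """Load a point layer as a typed demand or supply set.

    Parameters
    ----------
    path : str or Path
        CSV (``id,x,y,value``) or GeoJSON point layer.
    kind : str
        ``"demand"`` (value = inhabitants) or ``"supply"`` (value =
        capacity).
    aggregate_duplicates : bool
        For supply layers, merge rows at identical coordinates by summing
        capacities (co-located practices as one site).
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        df = _points_from_geojson(path)
    else:
        df = _points_from_csv(path)
    dup = df["id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate id {df.loc[dup, 'id'].iloc[0]!r} at row {dup.idxmax() + 2}")
    if kind == "demand":
        return DemandSet(df.rename(columns={"value": "pop"}))
    if kind == "supply":
        if aggregate_duplicates:
            df = (
                df.groupby(["x", "y"], as_index=False, sort=False)
                .agg(id=("id", "first"), value=("value", "sum"))
                [["id", "x", "y", "value"]]
            )
        return SupplySet(df.rename(columns={"value": "capacity"}))
    raise ValueError(f"kind must be 'demand' or 'supply', got {kind!r}")


def write_points_geojson(table: pd.DataFrame, value_col: str, path) -> None:
    """Write an ``id,x,y`` table as a GeoJSON point layer with a value property."""
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {"id": row.id, "value": getattr(row, value_col)},
        }
        for row in table.itertuples(index=False)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_result(result: AccessibilityResult, outdir, classes: pd.Series | None = None) -> dict:
    """Write result CSVs (demand indices + supply ratios) and return paths.

    The demand CSV has columns ``id,x,y,population,A`` plus
    ``quantile_class`` when ``classes`` is given; floats are written at
    full double precision.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    demand = result.demand.rename(columns={"pop": "population"})
    if classes is not None:
        demand = demand.assign(quantile_class=classes.to_numpy())
    paths = {"result": out / "result.csv", "ratios": out / "ratios.csv"}
    demand.to_csv(paths["result"], index=False, float_format=_FLOAT_FMT)
    result.ratios.to_csv(paths["ratios"], index=False, float_format=_FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}


def file_digest(path) -> str:
    """SHA-256 hex digest of a file, for run-metadata provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_metadata(metadata: dict, path) -> None:
    """Write the JSON run-metadata sidecar (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
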