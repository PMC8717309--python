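"""Readers and writers for the pipeline's text formats.

Trait tables arrive as point-decimal UTF-8 CSV (one row per species), GPS
fixes as Movebank-like CSV (individual_id, ISO 8601 timestamp, projected x/y
in meters), and landscapes as GeoJSON FeatureCollections whose features carry
``patch_id`` and ``landuse`` properties. Outputs are CSV/JSON plus a run
metadata record (package version, seed, config hash) so runs are
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from shapely.geometry import shape

from . import __version__
from .errors import ValidationError
from .mobility import Patch
from .traits import SeedTraitRecord

__all__ = [
    "read_trait_csv",
    "read_gps_csv",
    "read_landscape_geojson",
    "write_landscape_geojson",
    "write_outputs",
    "config_hash",
]

_TRAIT_REQUIRED = {"species", "seeds_fed", "control_germ_pct", "feces_germ"}
_TRAIT_OPTIONAL = {
    "genus", "length", "width", "height", "mass", "volume", "neophyte",
    "red_list", "germ_temp", "ei", "fi", "density", "area", "area_mass",
    "origin", "sgs",
}


def _parse_float(value: Any, column: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, str) and "," in value:
        raise ValidationError(
            f"row {row}, column {column!r}: comma decimal {value!r} "
            "(point-decimal CSV required)"
        )
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row}, column {column!r}: unparseable numeric cell {value!r}"
        ) from exc


def read_trait_csv(path: str | Path) -> list[SeedTraitRecord]:
    """Typed seed-trait records from a documented-schema CSV."""
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        raise ValidationError(f"{path}: empty trait table")
    cols = set(df.columns)
    missing = _TRAIT_REQUIRED - cols
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    unknown = cols - _TRAIT_REQUIRED - _TRAIT_OPTIONAL
    if unknown:
        raise ValidationError(f"{path}: unknown columns {sorted(unknown)}")

    records = []
    for i, row in enumerate(df.to_dict("records")):
        species = str(row["species"]).strip()
        if "genus" in row and isinstance(row.get("genus"), str):
            species = f"{row['genus'].strip()} {species}"

        def num(col: str) -> float | None:
            return _parse_float(row.get(col), col, i)

        neo = str(row.get("neophyte", "No")).strip().lower() in ("yes", "true", "1")
        records.append(
            SeedTraitRecord(
                species=species,
                seeds_fed=int(num("seeds_fed") or 0),
                control_germ_pct=num("control_germ_pct") or 0.0,
                feces_germ=int(num("feces_germ") or 0),
                length=num("length"),
                width=num("width"),
                height=num("height"),
                mass=num("mass"),
                volume=num("volume"),
                neophyte=neo,
                red_list=str(row.get("red_list", "-")).strip() or "-",
                germ_temp=str(row.get("germ_temp", "15/25")).strip(),
                ei=num("ei"),
                fi=num("fi"),
                density=num("density"),
                area=num("area"),
                area_mass=num("area_mass"),
            )
        )
    return records


def read_gps_csv(path: str | Path) -> pd.DataFrame:
    """GPS fixes: individual_id, timestamp (ISO 8601), projected x/y meters.

    Geographic (degree-range) coordinates are rejected — reproject upstream.
    Out-of-order rows are sorted per individual with a warning; duplicate
    timestamps within an individual are an error.
    """
    df = pd.read_csv(path)
    required = {"individual_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["t"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable ISO 8601 timestamps: {exc}") from exc
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if np.abs(xy[:, 0]).max(initial=0) <= 180 and np.abs(xy[:, 1]).max(initial=0) <= 90:
        raise ValidationError(
            f"{path}: coordinates look geographic (degrees); supply projected "
            "meters — this package performs no reprojection"
        )
    out = []
    for ind, sub in df.groupby("individual_id", sort=True):
        if sub["t"].duplicated().any():
            raise ValidationError(f"{path}: duplicate timestamps for individual {ind!r}")
        if not sub["t"].is_monotonic_increasing:
            warnings.warn(f"individual {ind!r}: timestamps out of order; sorting",
                          UserWarning, stacklevel=2)
            sub = sub.sort_values("t", kind="mergesort")
        out.append(sub)
    return (
        pd.concat(out)[["individual_id", "t", "x", "y"]].reset_index(drop=True)
    )


def read_landscape_geojson(path: str | Path) -> list[Patch]:
    """Patches from a GeoJSON FeatureCollection with patch_id/landuse properties."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    patches = []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if "patch_id" not in props or "landuse" not in props:
            raise ValidationError(
                f"{path}: feature {k} lacks patch_id/landuse properties"
            )
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValidationError(
                f"{path}: feature {k} ({props['patch_id']}): expected Polygon, "
                f"got {geom.geom_type}"
            )
        patches.append(
            Patch(patch_id=str(props["patch_id"]), landuse=str(props["landuse"]),
                  polygon=geom)
        )
    if not patches:
        raise ValidationError(f"{path}: no features")
    return patches


def write_landscape_geojson(patches: list[Patch], path: str | Path) -> None:
    features = []
    for p in patches:
        features.append(
            {
                "type": "Feature",
                "properties": {"patch_id": p.patch_id, "landuse": p.landuse},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[float(x), float(y)] for x, y in p.polygon.exterior.coords]
                    ],
                },
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_outputs(
    results: dict[str, Any], out_dir: str | Path, seed: int | None, config: dict
) -> list[Path]:
    """Write result tables/objects plus a run-metadata JSON.

    DataFrame values become ``<name>.csv``; everything else ``<name>.json``.
    Field order is deterministic; metadata records the package version, the
    seed and a hash of the configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, value in sorted(results.items()):
        if isinstance(value, pd.DataFrame):
            p = out / f"{name}.csv"
            value.to_csv(p, index=False)
        else:
            p = out / f"{name}.json"
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(value, fh, indent=1, sort_keys=True, cls=_JsonEncoder)
        written.append(p)
    meta = {
        "package": "harelink",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "files": [p.name for p in written],
    }
    mp = out / "run_metadata.json"
    with open(mp, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=str)
    written.append(mp)
    return written
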