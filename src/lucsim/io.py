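"""File formats: rasters (TIFF), property vectors (GeoJSON), tables, configs.

All rasters of a run live on one aligned grid, written as plain single- or
multi-band TIFF (band-interleaved, float32 / int32 / uint8).  Probability
maps use a uint8 0-100 encoding by default, which is exact on the m/100
lattice of a 100-iteration Monte Carlo run; float32 bands are used for
ensembles.  Property attributes round-trip through CSV and GeoJSON (cell
outlines merged with shapely); ledgers are CSV with a fixed header; configs
and run manifests are YAML, hashed for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .scenarios import PropertyMap

LEDGER_COLUMNS = ["property_id", "class", "region", "year", "loss_ha"]

PROPERTY_FIELDS = ["property_id", "area_ha", "size_class", "region", "lr_fraction"]


def write_raster(path, array: np.ndarray, nodata: float | None = None) -> None:
    """Write a 2-D (single-band) or 3-D (multi-band) raster as TIFF."""
    array = np.asarray(array)
    if array.ndim not in (2, 3):
        raise ValueError("raster must be 2-D or 3-D")
    meta = {"nodata": nodata} if nodata is not None else {}
    tifffile.imwrite(str(path), array, metadata=meta)


def read_raster(path) -> np.ndarray:
    return tifffile.imread(str(path))


def probability_to_uint8(prob: np.ndarray) -> np.ndarray:
    """Encode probabilities on the 0-100 integer scale (exact on m/100)."""
    return np.rint(np.asarray(prob, dtype=np.float64) * 100.0).astype(np.uint8)


def uint8_to_probability(encoded: np.ndarray) -> np.ndarray:
    return encoded.astype(np.float32) / np.float32(100.0)


def write_properties_csv(path, properties: PropertyMap) -> None:
    table = properties.table.reset_index(names="property_id")
    table.to_csv(path, index=False)


def read_properties_csv(path, ids: np.ndarray) -> PropertyMap:
    table = pd.read_csv(path)
    missing = set(PROPERTY_FIELDS) - set(table.columns)
    if missing:
        raise ValueError(f"property table missing fields {sorted(missing)}")
    table = table.set_index("property_id").sort_index()
    table.index.name = None
    return PropertyMap(ids, table)


def properties_to_geojson(path, properties: PropertyMap, cell_size: float = 1.0) -> None:
    """Write property outlines as GeoJSON polygons (cell unions).

    Cell (row, col) maps to the unit square [col, col+1] x [-row-1, -row]
    scaled by ``cell_size`` (y negated so north stays up).  Intended for the
    modest synthetic grids; attribute fields carry id/area/class/region/LR.
    """
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    ids = properties.ids
    for pid, row in properties.table.iterrows():
        cells = np.argwhere(ids == pid)
        boxes = [
            box(c * cell_size, -(r + 1) * cell_size, (c + 1) * cell_size, -r * cell_size)
            for r, c in cells
        ]
        geom = unary_union(boxes)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "property_id": int(pid),
                    "area_ha": float(row["area_ha"]),
                    "size_class": row["size_class"],
                    "region": row["region"],
                    "lr_fraction": float(row["lr_fraction"]),
                    "extra_protected_fraction": float(row["extra_protected_fraction"]),
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}), encoding="utf-8"
    )


def read_properties_geojson(path, ids: np.ndarray) -> PropertyMap:
    """Rebuild a PropertyMap from GeoJSON attributes plus the ID raster.

    Geometry is carried for interoperability; the grid-cell membership comes
    from the ID raster.  Missing schema fields (e.g. ``lr_fraction``) raise.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    rows = {}
    for feature in data.get("features", []):
        props = feature.get("properties", {})
        missing = set(PROPERTY_FIELDS) - set(props)
        if missing:
            raise ValueError(f"property feature missing fields {sorted(missing)}")
        rows[int(props["property_id"])] = {
            "area_ha": float(props["area_ha"]),
            "size_class": props["size_class"],
            "region": props["region"],
            "lr_fraction": float(props["lr_fraction"]),
            "extra_protected_fraction": float(props.get("extra_protected_fraction", 0.0)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return PropertyMap(ids, table)


def write_ledger(path, ledger: pd.DataFrame) -> None:
    missing = set(LEDGER_COLUMNS) - set(ledger.columns)
    if missing:
        raise ValueError(f"ledger missing columns {sorted(missing)}")
    ledger[LEDGER_COLUMNS].to_csv(path, index=False)


def read_ledger(path) -> pd.DataFrame:
    ledger = pd.read_csv(path)
    missing = set(LEDGER_COLUMNS) - set(ledger.columns)
    if missing:
        raise ValueError(f"ledger missing columns {sorted(missing)}")
    return ledger


def write_posterior_csv(path, posterior) -> None:
    """One row per retained draw, one column per parameter."""
    pd.DataFrame(posterior.draws, columns=posterior.param_names).to_csv(path, index=False)


def save_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True), encoding="utf-8")


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))


def config_hash(obj: dict) -> str:
    """Stable SHA-256 of a config mapping (canonical YAML)."""
    return hashlib.sha256(yaml.safe_dump(obj, sort_keys=True).encode()).hexdigest()


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
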