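"""Plain-format writers: CSV, GeoJSON, ESRI ASCII grid, model YAML.

All outputs are standard text formats so any stage can be re-run or consumed
standalone.  Tabular outputs carry a provenance header (``#``-prefixed YAML
lines) recording the stage and its parameters; ``read_table`` strips it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cokriging import CoKrigingModel, RiskSurface

__all__ = [
    "write_table",
    "read_table",
    "write_points_geojson",
    "write_lines_geojson",
    "write_esri_ascii",
    "read_esri_ascii",
    "write_model_yaml",
    "read_model_yaml",
]


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV with an optional ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for line in yaml.safe_dump(provenance, sort_keys=True).splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_points_geojson(df: pd.DataFrame, path, properties=None) -> None:
    """Waterbody points; ``properties`` lists the columns to carry along."""
    properties = properties or [c for c in df.columns if c not in ("x", "y")]
    feats = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [d["x"], d["y"]]},
                "properties": {k: _jsonable(d[k]) for k in properties},
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def write_lines_geojson(segments, path, id_field: str | None = "kittle_id") -> None:
    """Stream/road polylines as GeoJSON LineStrings."""
    feats = []
    for seg in segments:
        props = {}
        if id_field and hasattr(seg, id_field):
            props[id_field] = getattr(seg, id_field)
        if hasattr(seg, "road_class"):
            props["road_class"] = seg.road_class
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": np.asarray(seg.vertices, float).tolist(),
                },
                "properties": props,
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def write_esri_ascii(surface: RiskSurface, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid (row order: north to south)."""
    g = surface.grid
    lines = [
        f"ncols {g.nx}",
        f"nrows {g.ny}",
        f"xllcorner {g.origin[0]}",
        f"yllcorner {g.origin[1]}",
        f"cellsize {g.cell}",
        f"NODATA_value {nodata}",
    ]
    for iy in range(g.ny - 1, -1, -1):
        lines.append(" ".join(f"{v:.6g}" for v in surface.values[iy]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def read_esri_ascii(path) -> tuple[dict, np.ndarray]:
    """Header dict + value array (row 0 = southernmost, matching RiskSurface)."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].replace("_", "").isalpha():
        k, v = lines[i].split()
        header[k.lower()] = float(v)
        i += 1
    rows = [np.array(l.split(), dtype=float) for l in lines[i:] if l.strip()]
    return header, np.flipud(np.vstack(rows))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def write_model_yaml(model: CoKrigingModel, path, provenance: dict | None = None):
    doc = model.to_dict()
    if provenance:
        doc["provenance"] = provenance
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model_yaml(path) -> CoKrigingModel:
    return CoKrigingModel.from_dict(yaml.safe_load(Path(path).read_text()))
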