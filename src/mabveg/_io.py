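"""File I/O helpers: TIFF rasters, GeoJSON object polygons, CSV legends.

Rasters are plain TIFF with a JSON sidecar for the grid origin/pixel size;
vector output is GeoJSON in pixel coordinates (x = column, y = row).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping
from shapely.ops import polygonize, unary_union

__all__ = [
    "write_raster",
    "read_raster",
    "objects_to_geojson",
    "write_geojson",
]


def write_raster(path: str | Path, array: np.ndarray, **meta) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array), photometric="minisblack")
    if meta:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def _object_polygon(mask: np.ndarray):
    """Polygon(s) of a pixel mask from its boundary edge segments."""
    rows, cols = np.nonzero(mask)
    segs = []
    for r, c in zip(rows.tolist(), cols.tolist()):
        if r == 0 or not mask[r - 1, c]:
            segs.append(((c, r), (c + 1, r)))
        if r == mask.shape[0] - 1 or not mask[r + 1, c]:
            segs.append(((c, r + 1), (c + 1, r + 1)))
        if c == 0 or not mask[r, c - 1]:
            segs.append(((c, r), (c, r + 1)))
        if c == mask.shape[1] - 1 or not mask[r, c + 1]:
            segs.append(((c + 1, r), (c + 1, r + 1)))
    return unary_union(list(polygonize(segs)))


def objects_to_geojson(
    labels: np.ndarray, object_ids, properties: dict[int, dict] | None = None
) -> dict:
    """GeoJSON FeatureCollection of object polygons in pixel coordinates."""
    feats = []
    for oid in object_ids:
        geom = _object_polygon(labels == oid)
        props = {"object_id": int(oid)}
        if properties and oid in properties:
            props.update(properties[oid])
        feats.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(path: str | Path, collection: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(collection, sort_keys=True))
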