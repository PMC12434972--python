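"""Raster and vector I/O: multiband GeoTIFF and GeoJSON crown ROIs.

Rasters are written as 5-band float32 GeoTIFFs (band order B, G, R, RE,
NIR, recorded in the image description tag and validated on read) with
ModelPixelScale/ModelTiepoint tags carrying the planar local frame.
Crown ROIs travel as a GeoJSON FeatureCollection keyed by ``tree_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

from pestspec.cohort import BAND_NAMES

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_geotiff(path, raster: np.ndarray, resolution: float, origin) -> None:
    """Write a (5, H, W) reflectance raster with geo tags and band order."""
    raster = np.asarray(raster, dtype=np.float32)
    if raster.ndim != 3 or raster.shape[0] != len(BAND_NAMES):
        raise ValueError(f"raster must have shape ({len(BAND_NAMES)}, H, W)")
    x0, ytop = origin
    desc = json.dumps(
        {"bands": list(BAND_NAMES), "resolution": resolution, "origin": [x0, ytop]}
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (resolution, resolution, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, ytop, 0.0)),
    ]
    tifffile.imwrite(
        path,
        raster,
        photometric="minisblack",
        planarconfig="separate",
        description=desc,
        extratags=extratags,
    )


def read_geotiff(path):
    """Read a raster written by :func:`write_geotiff`.

    Returns ``(raster, resolution, origin)`` and refuses files whose
    band-order tag disagrees with the package convention.
    """
    with tifffile.TiffFile(path) as tif:
        raster = tif.asarray()
        page = tif.pages[0]
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
        scale = page.tags.get(_MODEL_PIXEL_SCALE)
        tie = page.tags.get(_MODEL_TIEPOINT)
        resolution = (
            float(scale.value[0])
            if scale is not None
            else float(meta.get("resolution", 1.0))
        )
        origin = (
            (float(tie.value[3]), float(tie.value[4]))
            if tie is not None
            else tuple(meta.get("origin", (0.0, float(raster.shape[-2]))))
        )
    bands = meta.get("bands")
    if bands is not None and tuple(bands) != BAND_NAMES:
        raise ValueError(
            f"band order {bands} does not match the expected {list(BAND_NAMES)}"
        )
    raster = np.asarray(raster, dtype=np.float32)
    if raster.ndim == 2:
        raster = raster[None]
    return raster, resolution, origin


def write_rois_geojson(path, rois, tree_ids) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"tree_id": str(tid)},
            "geometry": mapping(poly),
        }
        for tid, poly in zip(tree_ids, rois)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def read_rois_geojson(path):
    """Read crown ROIs; returns (list of polygons, list of tree ids)."""
    doc = json.loads(Path(path).read_text())
    polys, ids = [], []
    for feat in doc["features"]:
        polys.append(shape(feat["geometry"]))
        ids.append(feat["properties"]["tree_id"])
    return polys, ids
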