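"""Optional adapter: zonal band means from in-memory rasters and polygons.

Works on plain numpy band stacks with a north-up affine georeference
(origin + pixel size) and shapely polygons, using the pixel-center-in-polygon
rule.  Polygon coordinates and the raster grid must share the same CRS; no
reprojection is attempted.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .spectral import BANDS

__all__ = ["zonal_means_from_raster", "read_polygons_geojson"]


def read_polygons_geojson(path) -> dict[str, "shapely.Geometry"]:
    """Read plot polygons from a GeoJSON FeatureCollection, keyed by plot_id."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in payload["features"]:
        pid = feat.get("properties", {}).get("plot_id")
        if pid is None:
            raise ValueError("every feature needs a plot_id property")
        out[str(pid)] = shapely_shape(feat["geometry"])
    return out


def zonal_means_from_raster(bands: np.ndarray,
                            origin: tuple[float, float],
                            pixel_size: tuple[float, float],
                            polygons: Mapping[str, "shapely.Geometry"],
                            band_names: Sequence[str] = BANDS) -> pd.DataFrame:
    """Mean band reflectance per polygon, pixel-center-in-polygon rule.

    ``bands`` has shape (n_bands, rows, cols); ``origin`` is the (x, y) of
    the top-left corner of the top-left pixel; ``pixel_size`` is (dx, dy)
    with dy > 0 meaning rows run southward.  Polygons covering no pixel
    center are dropped with a warning column-free; returns a frame indexed
    by plot_id with one column per band.
    """
    bands = np.asarray(bands, dtype=float)
    if bands.ndim != 3 or bands.shape[0] != len(band_names):
        raise ValueError(f"bands must have shape ({len(band_names)}, rows, cols)")
    _, n_rows, n_cols = bands.shape
    x0, y0 = origin
    dx, dy = pixel_size
    xs = x0 + (np.arange(n_cols) + 0.5) * dx
    ys = y0 - (np.arange(n_rows) + 0.5) * dy
    gx, gy = np.meshgrid(xs, ys)

    rows = []
    for pid, geom in polygons.items():
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
        if not inside.any():
            continue
        means = bands.reshape(len(band_names), -1)[:, inside].mean(axis=1)
        rows.append({"plot_id": pid, **dict(zip(band_names, means))})
    return pd.DataFrame(rows, columns=["plot_id", *band_names]).set_index("plot_id")
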