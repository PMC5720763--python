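"""Gridded-surface geometry and map rendering.

Per-cell surfaces live as (lon, lat, value) centroid triples on a
regular lattice.  This module infers the cell size from the centroid
spacing, rasterizes triples into a north-up array, renders PNG maps
(colour and greyscale, with an optional coastline overlay), exports
rasters as ESRI ASCII grids (a plain-text GIS interchange format), and
crops a user-supplied coastline polygon file to a study extent.
Coordinates are WGS84 decimal degrees throughout and are taken as given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import shapely
import shapely.wkt
from shapely.geometry import box, shape

ALIGN_TOL = 1e-6  # degrees; centroid-to-lattice alignment tolerance


@dataclass
class CellGeometry:
    dx: float
    dy: float
    extent: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")


def _mode_gap(coords: np.ndarray, axis_name: str) -> float:
    uniq = np.unique(np.asarray(coords, dtype=float))
    if uniq.size < 2:
        raise ValueError(f"need >= 2 distinct {axis_name} values to infer cell size")
    gaps = np.round(np.diff(uniq), 9)
    vals, counts = np.unique(gaps, return_counts=True)
    # most frequent gap; ties broken toward the smallest gap
    return float(vals[counts == counts.max()].min())


def auto_cell_size(lons, lats) -> CellGeometry:
    """Infer cell size as the modal gap between sorted unique centroids,
    and the extent as the centroid bounds padded by half a cell."""
    dx = _mode_gap(np.asarray(lons), "longitude")
    dy = _mode_gap(np.asarray(lats), "latitude")
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    extent = (
        float(lons.min() - dx / 2),
        float(lons.max() + dx / 2),
        float(lats.min() - dy / 2),
        float(lats.max() + dy / 2),
    )
    return CellGeometry(dx=dx, dy=dy, extent=extent)


@dataclass
class Raster:
    """North-up value grid: row 0 is the northernmost row."""

    values: np.ndarray  # 2D, NaN = missing
    geom: CellGeometry


def rasterize_surface(lons, lats, values, geom: CellGeometry | None = None) -> Raster:
    """Place centroid triples onto the lattice; absent cells become NaN.

    Values are placed, never resampled.  A centroid more than 1e-6
    degrees off-lattice raises, naming the offending cell.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    values = np.asarray(values, dtype=float)
    if geom is None:
        geom = auto_cell_size(lons, lats)
    lon0 = geom.extent[0] + geom.dx / 2
    lat1 = geom.extent[3] - geom.dy / 2  # northernmost centroid
    fj = (lons - lon0) / geom.dx
    fi = (lat1 - lats) / geom.dy
    j = np.round(fj).astype(int)
    i = np.round(fi).astype(int)
    off = (np.abs(fj - j) * geom.dx > ALIGN_TOL) | (np.abs(fi - i) * geom.dy > ALIGN_TOL)
    if off.any():
        k = int(np.argmax(off))
        raise ValueError(
            f"centroid ({lons[k]}, {lats[k]}) is off the inferred lattice"
        )
    ncol = int(round((geom.extent[1] - geom.extent[0]) / geom.dx))
    nrow = int(round((geom.extent[3] - geom.extent[2]) / geom.dy))
    out = np.full((nrow, ncol), np.nan)
    out[i, j] = values
    return Raster(values=out, geom=geom)


def derasterize(raster: Raster) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of rasterize: (lon, lat, value) triples of non-missing cells."""
    geom = raster.geom
    nrow, ncol = raster.values.shape
    lon0 = geom.extent[0] + geom.dx / 2
    lat1 = geom.extent[3] - geom.dy / 2
    ii, jj = np.nonzero(~np.isnan(raster.values))
    return (
        lon0 + jj * geom.dx,
        lat1 - ii * geom.dy,
        raster.values[ii, jj],
    )


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    """Export as ESRI ASCII grid (.asc): text, readable by standard GIS."""
    geom = raster.geom
    nrow, ncol = raster.values.shape
    vals = np.where(np.isnan(raster.values), nodata, raster.values)
    lines = [
        f"ncols {ncol}",
        f"nrows {nrow}",
        f"xllcorner {geom.extent[0]:.10g}",
        f"yllcorner {geom.extent[2]:.10g}",
        f"cellsize {geom.dx:.10g}",
        f"nodata_value {nodata:.10g}",
    ]
    for row in vals:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_polygons(path) -> list:
    """Read coastline polygons from a GeoJSON (.json/.geojson) or WKT
    (.wkt) text file into shapely geometries."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in {".json", ".geojson"}:
            data = json.loads(text)
            if data.get("type") == "FeatureCollection":
                return [shape(f["geometry"]) for f in data["features"]]
            if data.get("type") == "Feature":
                return [shape(data["geometry"])]
            return [shape(data)]
        return [shapely.wkt.loads(line) for line in text.splitlines() if line.strip()]
    except Exception as exc:
        raise ValueError(f"cannot read polygon file {path}: {exc}") from exc


def crop_basemap(polygon_file, extent: tuple[float, float, float, float]) -> list:
    """Intersect every polygon with the extent rectangle
    (lon_min, lon_max, lat_min, lat_max).  An empty result is valid —
    the study area may be open ocean."""
    polys = read_polygons(polygon_file)
    rect = box(extent[0], extent[2], extent[1], extent[3])
    out = []
    for p in polys:
        clipped = p.intersection(rect)
        if not clipped.is_empty:
            out.append(clipped)
    return out


def render_map(
    raster: Raster,
    out_path,
    palette: str = "viridis",
    legend: str = "",
    coastline: list | None = None,
    greyscale: bool = False,
    title: str = "",
) -> None:
    """Render a raster to PNG.

    Missing cells draw in a distinct hatch-grey so absence of data is
    never confused with low values; greyscale uses a monotone-luminance
    colormap.  ``legend`` text (e.g. an effort-overlap line) is placed
    under the colorbar.  Rendering never modifies the raster values.
    """
    cmap = matplotlib.colormaps[("Greys" if greyscale else palette)].copy()
    cmap.set_bad("lightgrey")
    fig, ax = plt.subplots(figsize=(20, 16))
    im = ax.imshow(
        raster.values,
        origin="upper",
        extent=raster.geom.extent,
        cmap=cmap,
        interpolation="nearest",
        aspect="auto",
    )
    if coastline:
        rect = box(*[raster.geom.extent[i] for i in (0, 2, 1, 3)])
        for poly in coastline:
            clipped = poly.intersection(rect)
            if clipped.is_empty:
                continue
            geoms = getattr(clipped, "geoms", [clipped])
            for g in geoms:
                if g.geom_type == "Polygon":
                    xs, ys = g.exterior.xy
                    ax.fill(xs, ys, color="0.85", edgecolor="0.3", lw=0.5)
    cb = fig.colorbar(im, ax=ax)
    if legend:
        cb.set_label(legend)
    if title:
        ax.set_title(title)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.savefig(out_path, dpi=96)
    plt.close(fig)
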