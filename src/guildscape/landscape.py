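"""Habitat geometry: vector maps, rasterization and the analysis grid.

A habitat map arrives as polygons plus line features (hedgerows, tree rows,
water courses), each carrying an integer habitat-class code.  Lines are
buffered to thin polygons so narrow habitats survive the conversion to
raster, the two layers are merged, and the result is rasterized onto a
square grid by dominant-class assignment.  The grid is the substrate for
all landscape metrics.

Conventions
-----------
* Coordinates are continuous map units (metres) in one projected CRS;
  no reprojection is attempted.
* The grid origin is the lower-left corner of the feature bounding box;
  rows are stored north-up (row 0 is the northernmost row); cells are
  half-open ``[x, x + cell) x [y, y + cell)``.
* ``NODATA = -1`` marks cells covered by no feature; nodata cells are
  excluded from every metric.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, box, shape
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

NODATA = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HabitatVectorMap:
    """Polygon and line habitat features with integer class codes."""

    polygons: list  # list of (shapely Polygon/MultiPolygon, class_code)
    lines: list  # list of (shapely LineString, class_code)
    class_catalog: dict = field(default_factory=dict)  # class_code -> name
    crs_note: str = ""

    def __post_init__(self):
        for geom, code in list(self.polygons) + list(self.lines):
            if self.class_catalog and code not in self.class_catalog:
                raise ValueError(f"class code {code} not in class catalog")
            if not np.all(np.isfinite(geom.bounds)):
                raise ValueError("feature with non-finite coordinates")

    @property
    def bounds(self):
        geoms = [g for g, _ in self.polygons] + [g for g, _ in self.lines]
        if not geoms:
            raise ValueError("empty habitat map")
        xs0, ys0, xs1, ys1 = zip(*(g.bounds for g in geoms))
        return min(xs0), min(ys0), max(xs1), max(ys1)


@dataclass
class CategoricalRaster:
    """Gridded habitat classes.

    ``values`` is a 2-D integer array stored north-up: ``values[0, 0]`` is
    the north-west cell.  ``origin`` is the map coordinate of the grid's
    lower-left corner.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple = (0.0, 0.0)
    nodata: int = NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster grid must be 2-D and non-empty")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self):
        return self.values.shape

    def cell_centres(self):
        """(x, y) map coordinates of every cell centre, each shaped like the grid."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def circle_mask(self, centre, radius):
        """Boolean grid of cells whose centres lie within ``radius`` of ``centre``."""
        cx, cy = centre
        xs, ys = self.cell_centres()
        return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2


@dataclass
class SamplePlot:
    """Circular point-count plot (station centre + radius in metres)."""

    plot_id: str
    centre: tuple
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("plot radius must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def buffer_lines(lines, buffer_distance):
    """Buffer each (polyline, class_code) to a polygon of half-width ``buffer_distance``.

    Round caps.  Degenerate (zero-length) polylines are skipped with a
    warning.  Input order is preserved.
    """
    if not buffer_distance > 0:
        raise ValueError("buffer_distance must be positive")
    out = []
    for geom, code in lines:
        if geom.length == 0:
            logger.warning("skipping zero-length polyline (class %s)", code)
            continue
        out.append((geom.buffer(buffer_distance, quad_segs=64), code))
    return out


def rasterize(vmap, cell_size, line_priority=True, buffer_distance=5.0,
              origin=None, shape=None):
    """Convert a :class:`HabitatVectorMap` to a :class:`CategoricalRaster`.

    Each cell receives the class covering the largest fraction of its area
    (dominant-class assignment).  Exact coverage ties between classes go to
    the lowest class code.  With ``line_priority`` (default on), the best
    buffered-line class wins against the best polygon class whenever its
    coverage is at least as large, so narrow line habitats are not
    swallowed by the surrounding polygon.  Cells covered by no feature are
    nodata.
    """
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    if not vmap.polygons and not vmap.lines:
        raise ValueError("empty rasterization: habitat map has no features")

    buffered = buffer_lines(vmap.lines, buffer_distance) if vmap.lines else []
    feats = [(g, c, False) for g, c in vmap.polygons]
    feats += [(g, c, True) for g, c in buffered]

    if origin is None or shape is None:
        xs0, ys0, xs1, ys1 = zip(*(g.bounds for g, _, _ in feats))
        x0, y0 = min(xs0), min(ys0)
        ncols = max(1, int(math.ceil((max(xs1) - x0) / cell_size - 1e-9)))
        nrows = max(1, int(math.ceil((max(ys1) - y0) / cell_size - 1e-9)))
    else:
        x0, y0 = origin
        nrows, ncols = shape

    # coverage fraction of each cell, per class, split by polygon/line layer
    poly_cov = {}  # class -> 2-D array
    line_cov = {}
    cells = [box(x0 + j * cell_size, y0 + i * cell_size,
                 x0 + (j + 1) * cell_size, y0 + (i + 1) * cell_size)
             for i in range(nrows) for j in range(ncols)]
    tree = STRtree(cells)
    cell_area = cell_size * cell_size
    for geom, code, is_line in feats:
        store = line_cov if is_line else poly_cov
        cov = store.setdefault(code, np.zeros((nrows, ncols)))
        for idx in tree.query(geom, predicate="intersects"):
            a = geom.intersection(cells[idx]).area
            if a > 0:
                i, j = divmod(int(idx), ncols)
                # grid rows are north-up; cell row i counts from the bottom
                cov[nrows - 1 - i, j] += a / cell_area

    if not poly_cov and not line_cov:
        raise ValueError("empty rasterization: no feature intersects the grid")

    def best(store):
        codes = sorted(store)  # lowest code wins exact ties
        if not codes:
            return np.full((nrows, ncols), NODATA), np.zeros((nrows, ncols))
        stack = np.stack([np.minimum(store[c], 1.0) for c in codes])
        k = np.argmax(stack, axis=0)  # first max -> lowest code
        frac = np.take_along_axis(stack, k[None], axis=0)[0]
        code = np.asarray(codes)[k]
        code = np.where(frac > 0, code, NODATA)
        return code, frac

    pcode, pfrac = best(poly_cov)
    lcode, lfrac = best(line_cov)
    if line_priority:
        use_line = (lfrac > 0) & (lfrac >= pfrac)
    else:
        use_line = (lfrac > 0) & ((lfrac > pfrac) | ((lfrac == pfrac) & (lcode < pcode)))
    values = np.where(use_line, lcode, pcode)
    return CategoricalRaster(values, cell_size, origin=(x0, y0))


def composition(raster, mask=None):
    """Class-area proportions over non-nodata cells, as ``{class: fraction}``.

    ``mask`` restricts to a boolean cell subset; proportions sum to 1.
    """
    v = raster.values
    sel = v != raster.nodata
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    vals = v[sel]
    if vals.size == 0:
        raise ValueError("composition over an all-nodata region")
    codes, counts = np.unique(vals, return_counts=True)
    return {int(c): n / vals.size for c, n in zip(codes, counts)}


def representativeness(raster, plots):
    """Spearman rank correlation between plot-union composition and whole-map composition.

    Mirrors the representativeness check of a point-count design: the class
    proportions inside the union of all plot circles are rank-correlated
    with the proportions over the full raster.  Requires at least three
    classes overall; with fewer the rank correlation is ill-defined.
    """
    from .classify import spearman

    whole = composition(raster)
    if len(whole) < 3:
        raise ValueError("representativeness needs >= 3 habitat classes")
    union = np.zeros(raster.shape, dtype=bool)
    for p in plots:
        union |= raster.circle_mask(p.centre, p.radius)
    inside = composition(raster, mask=union)
    codes = sorted(whole)
    x = np.array([whole[c] for c in codes])
    y = np.array([inside.get(c, 0.0) for c in codes])
    return spearman(x, y)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_geojson(path, class_catalog=None):
    """Read a GeoJSON FeatureCollection into a :class:`HabitatVectorMap`.

    Every feature must carry an integer ``class_code`` property.  LineString
    features go to the line layer; (Multi)Polygons to the polygon layer.
    """
    with open(path) as fh:
        fc = json.load(fh)
    polys, lines = [], []
    for feat in fc.get("features", []):
        code = feat.get("properties", {}).get("class_code")
        if code is None:
            raise ValueError("feature without class_code property")
        geom = shape(feat["geometry"])
        if isinstance(geom, LineString) or geom.geom_type == "MultiLineString":
            lines.append((geom, int(code)))
        else:
            polys.append((geom, int(code)))
    return HabitatVectorMap(polys, lines, class_catalog or {})


def read_plots_csv(path):
    """Read plots from CSV with columns plot_id,x,y,radius."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SamplePlot(row["plot_id"],
                                  (float(row["x"]), float(row["y"])),
                                  float(row["radius"])))
    return out


def write_plots_csv(path, plots):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plot_id", "x", "y", "radius"])
        for p in plots:
            w.writerow([p.plot_id, p.centre[0], p.centre[1], p.radius])


def write_ascii_grid(path, raster, fmt="%d"):
    """Write an Esri ASCII grid (nodata declared in the header)."""
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]}\nyllcorner {raster.origin[1]}\n")
        fh.write(f"cellsize {raster.cell_size}\nnodata_value {raster.nodata}\n")
        for row in raster.values:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_ascii_grid(path, dtype=np.int64):
    """Read an Esri ASCII grid written by :func:`write_ascii_grid` (or any tool)."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=dtype)
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    return CategoricalRaster(
        data, header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=int(header.get("nodata_value", NODATA)))


def write_geotiff(path, raster):
    """Write a single-band GeoTIFF with pixel-scale and tie-point tags."""
    import tifffile

    x0, y0 = raster.origin
    nrows = raster.shape[0]
    top = y0 + nrows * raster.cell_size
    extratags = [
        (33550, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, x0, top, 0.0)),  # ModelTiepoint
        (42113, "s", 0, str(raster.nodata)),  # GDAL_NODATA
    ]
    tifffile.imwrite(path, raster.values.astype(np.int32), extratags=extratags)


def read_geotiff(path):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    cell = float(tags[33550][0]) if 33550 in tags else 1.0
    if 33922 in tags:
        tp = tags[33922]
        origin = (float(tp[3]), float(tp[4]) - data.shape[0] * cell)
    else:
        origin = (0.0, 0.0)
    nodata = int(float(tags[42113])) if 42113 in tags else NODATA
    return CategoricalRaster(np.asarray(data, dtype=np.int64), cell,
                             origin=origin, nodata=nodata)
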