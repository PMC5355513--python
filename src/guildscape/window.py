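"""Exhaustive circular moving-window metric surfaces and plot aggregation.

For every valid focal cell the metric is evaluated on the set of cells
whose centres lie within the window radius of the focal cell's centre
(inclusive).  Windows overlapping the raster edge simply use fewer cells —
no padding and no renormalization, matching the rule that the map border
is not treated as edge.  Focal nodata cells get no surface value.

The per-plot value of a metric is the unweighted mean of the defined
surface cells whose centres fall inside the plot circle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRIC_IDS, RegionMetrics

logger = logging.getLogger(__name__)

SURFACE_NODATA = -9999.0


@dataclass
class MetricSurface:
    metric_id: str
    values: np.ndarray  # float grid aligned to the source raster
    defined: np.ndarray  # boolean grid
    window_radius: float
    cell_size: float
    origin: tuple = (0.0, 0.0)

    def masked(self):
        out = np.where(self.defined, self.values, SURFACE_NODATA)
        return out


def window_offsets(radius, cell_size):
    """Row/column offsets of cells whose centres lie within ``radius``."""
    r = int(np.floor(radius / cell_size + 1e-12))
    d = np.arange(-r, r + 1)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    keep = (dr**2 + dc**2) * cell_size**2 <= radius**2 + 1e-9
    return dr[keep], dc[keep]


def _window_region(raster, row, col, dr, dc):
    """Sub-array and boolean mask for the window centred on (row, col)."""
    nrows, ncols = raster.shape
    rr, cc = row + dr, col + dc
    ok = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
    rr, cc = rr[ok], cc[ok]
    r0, r1 = rr.min(), rr.max()
    c0, c1 = cc.min(), cc.max()
    sub = raster.values[r0:r1 + 1, c0:c1 + 1]
    mask = np.zeros(sub.shape, dtype=bool)
    mask[rr - r0, cc - c0] = True
    return sub, mask


def _surfaces(raster, metric_ids, radius, focal=None, **params):
    """Shared driver: compute the requested metric surfaces at the focal
    cells (all valid cells when ``focal`` is None)."""
    if radius < raster.cell_size:
        raise ValueError("window radius must be at least one cell")
    dr, dc = window_offsets(radius, raster.cell_size)
    valid = raster.values != raster.nodata
    if focal is None:
        focal = valid
    else:
        focal = np.asarray(focal, dtype=bool) & valid

    vals = {m: np.zeros(raster.shape) for m in metric_ids}
    defined = {m: np.zeros(raster.shape, dtype=bool) for m in metric_ids}
    for row, col in np.argwhere(focal):
        sub, mask = _window_region(raster, row, col, dr, dc)
        mask = mask & (sub != raster.nodata)
        if not mask.any():
            continue
        rm = RegionMetrics(sub, raster.cell_size, raster.nodata, mask, **params)
        for mid in metric_ids:
            mv = rm.compute(mid)
            if mv.defined:
                vals[mid][row, col] = mv.value
                defined[mid][row, col] = True
    return {m: MetricSurface(m, vals[m], defined[m], radius,
                             raster.cell_size, raster.origin)
            for m in metric_ids}


def metric_surface(raster, metric_id, radius, **params):
    """Continuous surface of one metric by exhaustive moving-window sampling."""
    return _surfaces(raster, [metric_id], radius, **params)[metric_id]


def metric_surfaces(raster, metric_ids, radius, **params):
    """Surfaces for several metrics, sharing the per-window structural pass."""
    return _surfaces(raster, list(metric_ids), radius, **params)


def plot_value(surface, plot):
    """Unweighted mean of defined surface cells inside the plot circle."""
    from .landscape import CategoricalRaster

    helper = CategoricalRaster(np.zeros_like(surface.values, dtype=np.int64),
                               surface.cell_size, origin=surface.origin)
    sel = helper.circle_mask(plot.centre, plot.radius) & surface.defined
    if not sel.any():
        raise ValueError(f"plot {plot.plot_id} outside surface")
    return float(surface.values[sel].mean())


def plot_metrics_table(raster, plots, metric_ids=METRIC_IDS, radius=250.0,
                       plots_only=True, **params):
    """Plot x metric table of window-averaged landscape metrics.

    With ``plots_only`` (default) the window computation runs only at the
    cells inside some plot circle — bit-identical to the full surface on
    those cells, and far cheaper.  Missing entries (no defined cell in a
    plot) are NaN with a logged count.
    """
    if plots_only:
        focal = np.zeros(raster.shape, dtype=bool)
        for p in plots:
            focal |= raster.circle_mask(p.centre, p.radius)
    else:
        focal = None
    surfaces = _surfaces(raster, list(metric_ids), radius, focal=focal, **params)

    data = {}
    n_missing = 0
    for mid in metric_ids:
        col = []
        for p in plots:
            try:
                col.append(plot_value(surfaces[mid], p))
            except ValueError:
                col.append(np.nan)
                n_missing += 1
        data[mid] = col
    if n_missing:
        logger.warning("%d missing plot/metric entries", n_missing)
    table = pd.DataFrame(data, index=pd.Index([p.plot_id for p in plots],
                                              name="plot_id"))
    table.attrs["window_radius"] = radius
    table.attrs["params"] = dict(params)
    return table


def write_surface_ascii(path, surface):
    """Write a metric surface as an Esri ASCII grid (nodata -9999)."""
    from .landscape import CategoricalRaster, write_ascii_grid

    grid = np.where(surface.defined, surface.values, SURFACE_NODATA)
    fake = CategoricalRaster.__new__(CategoricalRaster)
    fake.values = grid
    fake.cell_size = surface.cell_size
    fake.origin = surface.origin
    fake.nodata = SURFACE_NODATA
    write_ascii_grid(path, fake, fmt="%.6g")
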