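"""Patch delineation and per-patch geometry on categorical rasters.

A patch is a maximal set of same-class cells connected under the
eight-cell neighbourhood rule (orthogonal and diagonal neighbours).
Patch perimeter counts every cell side adjacent to a different class,
to nodata, or to the region boundary; a patch truncated by a window
boundary therefore includes the truncation line in its perimeter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=int)

# contiguity template: centre 1, orthogonal neighbours 2, diagonal 1; sum = 13
_CONTIG_T = 13


@dataclass
class Patch:
    patch_id: int
    class_code: int
    area_cells: int
    area: float  # m^2
    perimeter: float  # m
    contiguity: float
    shape: float


@dataclass
class PatchSet:
    """Labelled patches of a raster region.

    ``labels`` is aligned to the source grid; 0 marks cells outside the
    region (nodata or masked out).  Patch ids are 1-based.
    """

    labels: np.ndarray
    patches: list
    cell_size: float

    def __len__(self):
        return len(self.patches)


def _region_mask(values, nodata, mask):
    m = values != nodata
    if mask is not None:
        m &= np.asarray(mask, dtype=bool)
    return m


def min_perimeter_sides(n):
    """Minimum perimeter (in cell sides) of any patch of n cells.

    4k for a k x k square; 4k + 2 while one extra row is incomplete;
    4k + 4 once the bounding square must grow.
    """
    k = int(math.isqrt(n))
    if k * k == n:
        return 4 * k
    if n <= k * (k + 1):
        return 4 * k + 2
    return 4 * k + 4


def label_patches(values, cell_size, nodata=-1, mask=None):
    """Label 8-connected same-class patches and compute per-patch geometry."""
    values = np.asarray(values)
    region = _region_mask(values, nodata, mask)
    if not region.any():
        raise ValueError("empty region: no valid cell to label")

    labels = np.zeros(values.shape, dtype=np.int64)
    classes = []
    next_id = 1
    for code in np.unique(values[region]):
        lab, n = ndimage.label(region & (values == code), structure=_EIGHT)
        labels[lab > 0] = lab[lab > 0] + (next_id - 1)
        classes.extend([int(code)] * n)
        next_id += n
    n_patches = next_id - 1

    areas = np.bincount(labels.ravel(), minlength=n_patches + 1)[1:]

    # perimeter: sides where the orthogonal neighbour has a different label
    # (different class, nodata, or outside the region/grid)
    perim = np.zeros(n_patches + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr:padded.shape[0] - 1 + dr,
                    1 + dc:padded.shape[1] - 1 + dc]
        diff = (core != nb) & (core > 0)
        perim += np.bincount(core[diff].ravel(), minlength=n_patches + 1)

    # contiguity template sums per cell, then patch means
    tsum = np.zeros(n_patches + 1, dtype=np.int64)
    same_orth = np.zeros(values.shape, dtype=np.int64)
    same_diag = np.zeros(values.shape, dtype=np.int64)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr:padded.shape[0] - 1 + dr,
                    1 + dc:padded.shape[1] - 1 + dc]
        same_orth += (core == nb) & (core > 0)
    for dr, dc in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        nb = padded[1 + dr:padded.shape[0] - 1 + dr,
                    1 + dc:padded.shape[1] - 1 + dc]
        same_diag += (core == nb) & (core > 0)
    cell_t = 1 + 2 * same_orth + same_diag
    tsum = np.bincount(labels.ravel(), weights=cell_t.ravel() * (labels.ravel() > 0),
                       minlength=n_patches + 1)[1:]

    patches = []
    for i in range(n_patches):
        n = int(areas[i])
        p_sides = int(perim[i + 1])
        contig = (tsum[i] / n - 1.0) / (_CONTIG_T - 1.0)
        shp = p_sides / min_perimeter_sides(n)
        patches.append(Patch(i + 1, classes[i], n, n * cell_size**2,
                             p_sides * cell_size, contig, shp))
    return PatchSet(labels, patches, cell_size)


def patch_contiguity(patch):
    """Contiguity index of a patch: 0 for a single pixel, -> 1 for large blocks."""
    return patch.contiguity


def patch_shape(patch):
    """Shape index of a patch: exactly 1 for any square, larger when irregular."""
    return patch.shape


def adjacency_counts(values, cell_size, nodata=-1, mask=None):
    """Cell-side adjacency tallies within a region.

    Returns ``(g, e, boundary_sides)`` where ``g[(k, l)]`` is the ordered
    count of orthogonal side adjacencies between classes k and l (each
    shared side counted once per direction, so like adjacencies appear
    doubled on the diagonal), ``e[(k, l)]`` for k < l is the unordered
    class-pair edge length in metres, and ``boundary_sides`` is the number
    of cell sides facing nodata or the region boundary.
    """
    values = np.asarray(values)
    region = _region_mask(values, nodata, mask)
    if not region.any():
        raise ValueError("empty region")

    g = {}
    e = {}
    boundary = 0
    vv = np.where(region, values, np.iinfo(np.int64).min)
    for axis in (0, 1):
        a = np.take(vv, range(vv.shape[axis] - 1), axis=axis)
        b = np.take(vv, range(1, vv.shape[axis]), axis=axis)
        ra = np.take(region, range(region.shape[axis] - 1), axis=axis)
        rb = np.take(region, range(1, region.shape[axis]), axis=axis)
        both = ra & rb
        ka, kb = a[both], b[both]
        lo = np.minimum(ka, kb)
        hi = np.maximum(ka, kb)
        pairs, counts = np.unique(np.stack([lo, hi]), axis=1, return_counts=True)
        for (k, l), n in zip(pairs.T, counts):
            k, l = int(k), int(l)
            g[(k, l)] = g.get((k, l), 0) + int(n) * (2 if k == l else 1)
            if k != l:
                g[(l, k)] = g.get((l, k), 0) + int(n)
                e[(k, l)] = e.get((k, l), 0.0) + int(n) * cell_size
        # sides where exactly one of the two cells is in the region
        boundary += int(np.count_nonzero(ra ^ rb))
    # grid-exterior sides of region cells
    for arr in (region[0, :], region[-1, :], region[:, 0], region[:, -1]):
        boundary += int(np.count_nonzero(arr))
    return g, e, boundary
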