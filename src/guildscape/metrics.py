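"""Landscape-level structure metrics on raster regions.

The sixteen metrics cover landscape composition (SIDI, PRD, LPI, ...) and
configuration (ED, LSI, CONTIG_MN, COHESION, ...).  All are computed on an
arbitrary region: a full raster, a rectangular block, or the circular cell
set of a moving window.  Notation:

    A       total region area (m^2), Z cells of side ``cell``
    a_i     patch areas (m^2), p_i patch perimeters (m), N patches
    P_k     class area proportions, m class richness
    e_kl    class-pair edge length (m), E = sum_{k<l} e_kl
    g_kl    ordered orthogonal cell-side adjacency counts

Border rule: by default the region boundary is *not* edge for ED/E/e_kl,
while LSI uses the total edge including the boundary (the raster LSI
definition); both behaviours are flag-controlled.  Patch perimeters always
include truncation by the region boundary.

Undefined cases (IJI with fewer than 3 classes, PAFRAC with fewer than 2
patches or degenerate perimeters, CONNECT with no same-class patch pair)
are reported with ``defined=False`` rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .patches import adjacency_counts, label_patches

METRIC_IDS = (
    "COHESION", "CONNECT", "CONTIG_MN", "DIVISION", "ED", "IJI", "LPI",
    "LSI", "MESH", "NP", "PAFRAC", "PD", "PLADJ", "PRD", "SHAPE_MN", "SIDI",
)

DEFAULT_CONNECT_THRESHOLD = 100.0  # m; not a published value — record in output


@dataclass
class MetricValue:
    metric_id: str
    value: float
    defined: bool = True


class RegionMetrics:
    """One-pass computation of all metrics on a raster region.

    Shares patch labelling and adjacency tallies across metrics, which is
    what makes exhaustive moving-window sampling affordable.
    """

    def __init__(self, values, cell_size, nodata=-1, mask=None,
                 connect_threshold=DEFAULT_CONNECT_THRESHOLD,
                 border_is_edge=False, lsi_include_boundary=True):
        self.values = np.asarray(values)
        self.cell = float(cell_size)
        self.nodata = nodata
        self.mask = mask
        self.connect_threshold = float(connect_threshold)
        self.border_is_edge = border_is_edge
        self.lsi_include_boundary = lsi_include_boundary

        self.patchset = label_patches(self.values, self.cell, nodata, mask)
        self.g, self.e, self.boundary_sides = adjacency_counts(
            self.values, self.cell, nodata, mask)

        ps = self.patchset.patches
        self.N = len(ps)
        self.n_cells = np.array([p.area_cells for p in ps])
        self.areas = np.array([p.area for p in ps])
        self.perims = np.array([p.perimeter for p in ps])
        self.classes = np.array([p.class_code for p in ps])
        self.Z = int(self.n_cells.sum())
        self.A = self.Z * self.cell**2
        self.class_codes = np.unique(self.classes)
        self.m = len(self.class_codes)
        class_cells = {c: self.n_cells[self.classes == c].sum()
                       for c in self.class_codes}
        self.P = {c: class_cells[c] / self.Z for c in self.class_codes}
        edge_sum = sum(self.e.values())
        self.E = edge_sum + (self.boundary_sides * self.cell
                             if border_is_edge else 0.0)
        self.E_star = edge_sum + self.boundary_sides * self.cell

    # -- individual metrics -------------------------------------------------

    def np_(self):
        return MetricValue("NP", float(self.N))

    def pd(self):
        return MetricValue("PD", self.N / self.A * 1e6)  # patches / 100 ha

    def ed(self):
        return MetricValue("ED", self.E / self.A * 1e4)  # m / ha

    def lpi(self):
        return MetricValue("LPI", 100.0 * self.areas.max() / self.A)

    def lsi(self):
        e = self.E_star if self.lsi_include_boundary else self.E
        return MetricValue("LSI", 0.25 * e / math.sqrt(self.A))

    def mesh(self):
        return MetricValue("MESH", (self.areas**2).sum() / self.A / 1e4)  # ha

    def division(self):
        return MetricValue("DIVISION", 1.0 - ((self.areas / self.A) ** 2).sum())

    def sidi(self):
        return MetricValue("SIDI", 1.0 - sum(p * p for p in self.P.values()))

    def prd(self):
        return MetricValue("PRD", self.m / self.A * 1e6)  # classes / 100 ha

    def pladj(self):
        like = sum(n for (k, l), n in self.g.items() if k == l)
        total = sum(self.g.values())
        if total == 0:
            return MetricValue("PLADJ", 0.0, defined=False)
        return MetricValue("PLADJ", 100.0 * like / total)

    def iji(self):
        edge_sum = sum(self.e.values())
        if self.m < 3 or edge_sum == 0:
            return MetricValue("IJI", float("nan"), defined=False)
        s = 0.0
        for v in self.e.values():
            f = v / edge_sum
            if f > 0:
                s += f * math.log(f)
        return MetricValue("IJI", -100.0 * s / math.log(0.5 * self.m * (self.m - 1)))

    def connect(self):
        pairs_total = 0
        joinings = 0
        coords = {p.patch_id: np.argwhere(self.patchset.labels == p.patch_id)
                  for p in self.patchset.patches}
        for c in self.class_codes:
            ids = [p.patch_id for p in self.patchset.patches if p.class_code == c]
            nk = len(ids)
            pairs_total += nk * (nk - 1) // 2
            for i in range(nk):
                for j in range(i + 1, nk):
                    xi, xj = coords[ids[i]], coords[ids[j]]
                    d2 = ((xi[:, None, :] - xj[None, :, :]) ** 2).sum(-1).min()
                    if math.sqrt(d2) * self.cell <= self.connect_threshold:
                        joinings += 1
        if pairs_total == 0:
            return MetricValue("CONNECT", float("nan"), defined=False)
        return MetricValue("CONNECT", 100.0 * joinings / pairs_total)

    def cohesion(self):
        if self.Z <= 1:
            return MetricValue("COHESION", float("nan"), defined=False)
        p_star = self.perims / self.cell  # cell sides
        num = p_star.sum()
        den = (p_star * np.sqrt(self.n_cells)).sum()
        val = 100.0 * (1.0 - num / den) / (1.0 - 1.0 / math.sqrt(self.Z))
        return MetricValue("COHESION", val)

    def contig_mn(self):
        return MetricValue("CONTIG_MN",
                           float(np.mean([p.contiguity for p in self.patchset.patches])))

    def shape_mn(self):
        return MetricValue("SHAPE_MN",
                           float(np.mean([p.shape for p in self.patchset.patches])))

    def pafrac(self):
        if self.N < 2:
            return MetricValue("PAFRAC", float("nan"), defined=False)
        ln_p = np.log(self.perims)
        ln_a = np.log(self.areas)
        vp = ln_p - ln_p.mean()
        ss = (vp**2).sum()
        if ss == 0:
            return MetricValue("PAFRAC", float("nan"), defined=False)
        beta = (vp * (ln_a - ln_a.mean())).sum() / ss
        if beta == 0:
            return MetricValue("PAFRAC", float("nan"), defined=False)
        return MetricValue("PAFRAC", 2.0 / beta)

    _DISPATCH = {
        "NP": np_, "PD": pd, "ED": ed, "LPI": lpi, "LSI": lsi, "MESH": mesh,
        "DIVISION": division, "SIDI": sidi, "PRD": prd, "PLADJ": pladj,
        "IJI": iji, "CONNECT": connect, "COHESION": cohesion,
        "CONTIG_MN": contig_mn, "SHAPE_MN": shape_mn, "PAFRAC": pafrac,
    }

    def compute(self, metric_id):
        try:
            fn = self._DISPATCH[metric_id]
        except KeyError:
            raise ValueError(f"unknown metric {metric_id!r}") from None
        return fn(self)

    def compute_all(self, metric_ids=METRIC_IDS):
        return {mid: self.compute(mid) for mid in metric_ids}


def compute_metric(metric_id, values, cell_size, nodata=-1, mask=None,
                   **params):
    """Compute one landscape metric on a region; see :class:`RegionMetrics`."""
    return RegionMetrics(values, cell_size, nodata, mask, **params).compute(metric_id)


def compute_all_metrics(values, cell_size, nodata=-1, mask=None,
                        metric_ids=METRIC_IDS, **params):
    """All requested metrics on one region, sharing the structural pass."""
    return RegionMetrics(values, cell_size, nodata, mask,
                         **params).compute_all(metric_ids)


def metrics_to_frame(results):
    """Tidy DataFrame (region_id, metric_id, value, defined) from
    ``{region_id: {metric_id: MetricValue}}``."""
    import pandas as pd

    rows = [(rid, mid, mv.value, mv.defined)
            for rid, d in results.items() for mid, mv in d.items()]
    return pd.DataFrame(rows, columns=["region_id", "metric_id", "value", "defined"])
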