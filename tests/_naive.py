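"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible — BFS flood
fill, explicit side enumeration, per-pair loops — deliberately sharing no
code with the package, so agreement is evidence and not tautology.
"""

import math
from collections import deque

import numpy as np


def flood_fill_patches(values, nodata=-1, mask=None):
    """8-connected same-class components by breadth-first search.

    Returns (labels, patch list) where each patch is a dict with class,
    cells, perimeter in sides.
    """
    nrows, ncols = values.shape
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    valid = mask & (values != nodata)
    labels = np.zeros((nrows, ncols), dtype=int)
    patches = []
    nid = 0
    for r in range(nrows):
        for c in range(ncols):
            if valid[r, c] and labels[r, c] == 0:
                nid += 1
                cells = []
                q = deque([(r, c)])
                labels[r, c] = nid
                while q:
                    rr, cc = q.popleft()
                    cells.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < nrows and 0 <= c2 < ncols
                                    and valid[r2, c2] and labels[r2, c2] == 0
                                    and values[r2, c2] == values[r, c]):
                                labels[r2, c2] = nid
                                q.append((r2, c2))
                perim = 0
                for rr, cc in cells:
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        r2, c2 = rr + dr, cc + dc
                        if not (0 <= r2 < nrows and 0 <= c2 < ncols):
                            perim += 1
                        elif not valid[r2, c2] or values[r2, c2] != values[r, c]:
                            perim += 1
                patches.append({"class": int(values[r, c]), "cells": cells,
                                "perimeter_sides": perim})
    return labels, patches


def min_perimeter(n):
    best = None
    k = int(math.floor(math.sqrt(n)))
    if k * k == n:
        return 4 * k
    if n <= k * (k + 1):
        return 4 * k + 2
    return 4 * k + 4


def contig_of_patch(values, cells):
    cellset = set(cells)
    total = 0.0
    for r, c in cells:
        v = 1.0
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) in cellset:
                v += 2.0
        for dr, dc in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            if (r + dr, c + dc) in cellset:
                v += 1.0
        total += v
    return (total / len(cells) - 1.0) / 12.0


def side_enumeration(values, nodata=-1, mask=None):
    """Every orthogonal cell-side adjacency, one at a time."""
    nrows, ncols = values.shape
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    valid = mask & (values != nodata)
    like = {}
    unlike = {}
    boundary = 0
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrows and 0 <= c2 < ncols) or not valid[r2, c2]:
                    continue
                a, b = int(values[r, c]), int(values[r2, c2])
                key = (min(a, b), max(a, b))
                if a == b:
                    like[key] = like.get(key, 0) + 1
                else:
                    unlike[key] = unlike.get(key, 0) + 1
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrows and 0 <= c2 < ncols) or not valid[r2, c2]:
                    boundary += 1
    return like, unlike, boundary


def all_metrics(values, cell, nodata=-1, mask=None, connect_threshold=100.0):
    """All sixteen metrics, straight from the formulas. NaN = undefined."""
    labels, patches = flood_fill_patches(values, nodata, mask)
    like, unlike, boundary = side_enumeration(values, nodata, mask)
    Z = sum(len(p["cells"]) for p in patches)
    A = Z * cell * cell
    N = len(patches)
    areas = [len(p["cells"]) * cell * cell for p in patches]
    perims = [p["perimeter_sides"] * cell for p in patches]
    classes = sorted({p["class"] for p in patches})
    m = len(classes)
    class_prop = {k: sum(len(p["cells"]) for p in patches if p["class"] == k) / Z
                  for k in classes}
    E = sum(unlike.values()) * cell
    E_star = E + boundary * cell

    out = {}
    out["NP"] = float(N)
    out["PD"] = N / A * 1e6
    out["ED"] = E / A * 1e4
    out["LPI"] = 100.0 * max(areas) / A
    out["LSI"] = 0.25 * E_star / math.sqrt(A)
    out["MESH"] = sum(a * a for a in areas) / A / 1e4
    out["DIVISION"] = 1.0 - sum((a / A) ** 2 for a in areas)
    out["SIDI"] = 1.0 - sum(p * p for p in class_prop.values())
    out["PRD"] = m / A * 1e6
    tot_adj = 2 * sum(like.values()) + 2 * sum(unlike.values())
    out["PLADJ"] = float("nan") if tot_adj == 0 else \
        100.0 * 2 * sum(like.values()) / tot_adj
    if m < 3 or E == 0:
        out["IJI"] = float("nan")
    else:
        s = 0.0
        for v in unlike.values():
            f = v * cell / E
            s += f * math.log(f)
        out["IJI"] = -100.0 * s / math.log(0.5 * m * (m - 1))
    # CONNECT
    pairs = 0
    joins = 0
    for k in classes:
        ps = [p for p in patches if p["class"] == k]
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                pairs += 1
                dmin = min(math.hypot(r1 - r2, c1 - c2)
                           for r1, c1 in ps[i]["cells"]
                           for r2, c2 in ps[j]["cells"]) * cell
                if dmin <= connect_threshold:
                    joins += 1
    out["CONNECT"] = float("nan") if pairs == 0 else 100.0 * joins / pairs
    if Z <= 1:
        out["COHESION"] = float("nan")
    else:
        pstar = [p / cell for p in perims]
        ncells = [len(p["cells"]) for p in patches]
        num = sum(pstar)
        den = sum(ps * math.sqrt(nc) for ps, nc in zip(pstar, ncells))
        out["COHESION"] = 100.0 * (1 - num / den) / (1 - 1 / math.sqrt(Z))
    out["CONTIG_MN"] = sum(contig_of_patch(values, p["cells"])
                           for p in patches) / N
    out["SHAPE_MN"] = sum(p["perimeter_sides"] / min_perimeter(len(p["cells"]))
                          for p in patches) / N
    if N < 2:
        out["PAFRAC"] = float("nan")
    else:
        lp = [math.log(p) for p in perims]
        la = [math.log(a) for a in areas]
        mp, ma = sum(lp) / N, sum(la) / N
        ss = sum((x - mp) ** 2 for x in lp)
        if ss == 0:
            out["PAFRAC"] = float("nan")
        else:
            beta = sum((x - mp) * (y - ma) for x, y in zip(lp, la)) / ss
            out["PAFRAC"] = float("nan") if beta == 0 else 2.0 / beta
    return out


def rank_average(v):
    """Average ranks with ties, by explicit counting."""
    v = list(v)
    out = []
    for x in v:
        less = sum(1 for y in v if y < x)
        eq = sum(1 for y in v if y == x)
        out.append(less + (eq + 1) / 2.0)
    return out


def spearman_rho(x, y):
    rx, ry = rank_average(x), rank_average(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def logistic_ml(X, y):
    """Direct likelihood maximization with scipy, independent of the fit path."""
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    D = np.column_stack([np.ones(len(y)), X])

    def nll(beta):
        eta = D @ beta
        return np.sum(np.logaddexp(0, eta) - y * eta)

    res = minimize(nll, np.zeros(D.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x
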