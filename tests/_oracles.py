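"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops straight from the definitions so
it shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_force_local_maxima(values, wy, wx, min_height):
    """Exhaustive per-pixel neighbourhood-maximum scan.

    A pixel is an apex iff it is >= min_height and equals the maximum of the
    (wy, wx) window centred on it, and is the row-major-first pixel among
    window ties.
    """
    nr, nc = values.shape
    hy, hx = wy // 2, wx // 2
    apexes = []
    for r in range(nr):
        for c in range(nc):
            v = values[r, c]
            if v < min_height:
                continue
            r0, r1 = max(0, r - hy), min(nr, r + hy + 1)
            c0, c1 = max(0, c - hx), min(nc, c + hx + 1)
            best = None
            for rr in range(r0, r1):
                for cc in range(c0, c1):
                    if best is None or values[rr, cc] > values[best]:
                        best = (rr, cc)
            if values[best] == v and best == (r, c):
                apexes.append((r, c))
    return apexes


def min_pairwise_distance(points):
    """O(n^2) all-pairs scan."""
    pts = np.asarray(points, dtype=float)
    best = np.inf
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.hypot(*(pts[i] - pts[j])))
            best = min(best, d)
    return best


def clipped_voronoi_adjacency(xy, width, height):
    """Ordinary (unweighted) Voronoi adjacency clipped to the plot window,
    from a computational-geometry library (shapely)."""
    from shapely.geometry import Point, box
    from shapely.ops import voronoi_diagram
    from shapely.geometry import MultiPoint

    xy = np.asarray(xy, dtype=float)
    plot = box(0, 0, width, height)
    cells = voronoi_diagram(MultiPoint([tuple(p) for p in xy]), envelope=plot)
    polys, owner = [], []
    for g in cells.geoms:
        clipped = g.intersection(plot)
        # map the cell back to its generating point
        dists = [g.distance(Point(tuple(p))) for p in xy]
        owner.append(int(np.argmin(dists)))
        polys.append(clipped)
    adj = set()
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersection(polys[j]).length > 0:
                adj.add(tuple(sorted((owner[i], owner[j]))))
    return adj


# -- straight-from-formula spatial structure indices -----------------------
def oracle_U(center_h, neighbor_h):
    return sum(1.0 for hj in neighbor_h if hj > center_h) / len(neighbor_h)


def oracle_W(azimuths):
    az = sorted(a % 360.0 for a in azimuths)
    n = len(az)
    gaps = [az[(i + 1) % n] - az[i] if i < n - 1 else az[0] + 360.0 - az[i] for i in range(n)]
    assert abs(sum(gaps) - 360.0) < 1e-9
    a0 = 360.0 / (n + 1)
    return sum(1.0 for g in gaps if g < a0) / n


def oracle_UCI(center_h, neighbor_h, distances):
    import math

    n = len(neighbor_h)
    total = 0.0
    for hj, d in zip(neighbor_h, distances):
        if hj > center_h:
            a1 = math.degrees(math.atan(center_h / d))
            a2 = math.degrees(math.atan(abs(center_h - hj) / d))
        else:
            a1 = math.degrees(math.atan(hj / d))
            a2 = 0.0
        total += a1 + a2
    return oracle_U(center_h, neighbor_h) / (180.0 * n) * total


def oracle_K(distances, neighbor_h):
    return sum(d / hj for d, hj in zip(distances, neighbor_h)) / len(distances)


def oracle_OP(center_h, neighbor_h, distances):
    return sum(1.0 for hj, d in zip(neighbor_h, distances) if d > abs(center_h - hj)) / len(distances)


def oracle_S(center_layer, neighbor_layers):
    z = len(set(neighbor_layers) | {center_layer})
    t = sum(1.0 for l in neighbor_layers if l == center_layer)
    return z / 3.0 * t / len(neighbor_layers)


def oracle_vif(X):
    """VIF of each column by explicit auxiliary regressions (lstsq)."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    out = []
    for i in range(k):
        y = X[:, i]
        others = np.column_stack([np.ones(n), np.delete(X, i, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1 - np.sum(resid**2) / sst
        out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return np.array(out)
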