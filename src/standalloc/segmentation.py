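"""Individual-tree detection and crown delineation on a CHM.

Tree apexes are found with a fixed-size local-maximum window swept over the
raster; crowns are delineated by marker-controlled watershed on the inverted
CHM with the apexes as markers (each crown becomes a drainage basin).
Detection is scored against a reference stem map with the detection rate
r = TP/(TP+FN), precision p = TP/(TP+FP) and F-score F = 2rp/(r+p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

from .raster import CHMRaster

__all__ = [
    "DetectionResult",
    "CrownMap",
    "detect_treetops",
    "segment_crowns",
    "extract_tree_params",
    "evaluate_detection",
    "select_window",
]


def _window_pixels(window_m: float, resolution: float) -> int:
    """Physical window size -> odd pixel count (rounded up)."""
    if window_m < resolution:
        raise ValueError(
            f"window ({window_m} m) smaller than one pixel ({resolution} m)"
        )
    n = int(np.ceil(window_m / resolution))
    return n if n % 2 == 1 else n + 1


def detect_treetops(
    chm: CHMRaster,
    window_x: float = 0.3,
    window_y: float = 0.3,
    min_height: float = 2.0,
) -> pd.DataFrame:
    """Detect tree apexes with a fixed-size moving-window local maximum.

    A pixel is an apex iff its value is >= ``min_height`` and is the strict
    maximum within the ``window_x`` x ``window_y`` (m) rectangle centred on
    it; exact ties within a window are broken in favour of the first pixel
    in row-major order.  Windows are converted to pixels by rounding up to
    an odd count.

    Returns a DataFrame with columns ``row, col, x, y, height``.
    """
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    v = chm.values
    empty = pd.DataFrame(columns=["row", "col", "x", "y", "height"])
    if v.size == 0:
        return empty
    wx = _window_pixels(window_x, chm.resolution)
    wy = _window_pixels(window_y, chm.resolution)
    # window (wy rows, wx cols): y size maps to rows, x size to columns
    maxed = ndimage.maximum_filter(v, size=(wy, wx), mode="constant", cval=-1.0)
    cand = np.argwhere((v >= min_height) & (v == maxed))
    if len(cand) == 0:
        return empty
    hy, hx = wy // 2, wx // 2
    nr, nc = v.shape
    keep = []
    for r, c in cand:  # row-major order from argwhere
        r0, r1 = max(0, r - hy), min(nr, r + hy + 1)
        c0, c1 = max(0, c - hx), min(nc, c + hx + 1)
        block = v[r0:r1, c0:c1]
        ties = np.argwhere(block == v[r, c])
        first = ties[0]  # row-major first among tied maxima in the window
        if (r0 + first[0], c0 + first[1]) == (r, c):
            keep.append((r, c))
    if not keep:
        return empty
    rows, cols = np.array(keep).T
    x, y = chm.pixel_to_world(rows, cols)
    return pd.DataFrame(
        {"row": rows, "col": cols, "x": x, "y": y, "height": v[rows, cols]}
    )


@dataclass
class CrownMap:
    """Watershed crown labels: 0 = background, label k = crown of apex k-1."""

    labels: np.ndarray
    apex_index: dict  # label -> positional apex index
    n_excluded: int = 0

    @property
    def pixel_counts(self) -> dict:
        lab, cnt = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def segment_crowns(
    chm: CHMRaster, apices: pd.DataFrame, min_height: float = 2.0
) -> CrownMap:
    """Marker-controlled watershed crown delineation.

    The CHM is inverted so crowns become drainage basins; apex pixels are the
    markers.  Pixels below ``min_height`` are background.
    """
    v = chm.values
    labels = np.zeros(v.shape, dtype=np.int32)
    if apices.empty:
        return CrownMap(labels=labels, apex_index={})
    rows = apices["row"].to_numpy(int)
    cols = apices["col"].to_numpy(int)
    below = v[rows, cols] < min_height
    if below.any():
        bad = apices.index[below].tolist()
        raise ValueError(f"apexes on background pixels (below {min_height} m): {bad}")
    markers = np.zeros(v.shape, dtype=np.int32)
    markers[rows, cols] = np.arange(1, len(apices) + 1)
    mask = v >= min_height
    labels = watershed(-v, markers=markers, mask=mask)
    return CrownMap(labels=labels, apex_index={i + 1: i for i in range(len(apices))})


def extract_tree_params(
    crowns: CrownMap, chm: CHMRaster, apices: pd.DataFrame
) -> pd.DataFrame:
    """Per-tree height and crown width from a crown map.

    Height is the CHM value at the apex pixel.  Crown width is the mean of
    the crown region's north-south and east-west extents (bounding extent
    through all crown pixels, in metres); a single-pixel crown has width one
    resolution.
    """
    out = []
    n_excluded = 0
    res = chm.resolution
    for label, idx in crowns.apex_index.items():
        pix = np.argwhere(crowns.labels == label)
        if len(pix) == 0:
            n_excluded += 1
            continue
        ns = (pix[:, 0].max() - pix[:, 0].min() + 1) * res
        ew = (pix[:, 1].max() - pix[:, 1].min() + 1) * res
        apex = apices.iloc[idx]
        out.append(
            {
                "tree_id": idx + 1,
                "x": apex["x"],
                "y": apex["y"],
                "height": chm.values[int(apex["row"]), int(apex["col"])],
                "crown_width": (ns + ew) / 2.0,
                "crown_area": len(pix) * res**2,
            }
        )
    crowns.n_excluded = n_excluded
    return pd.DataFrame(out)


@dataclass
class DetectionResult:
    """Detection scores: r = TP/(TP+FN), p = TP/(TP+FP), F = 2rp/(r+p)."""

    tp: int
    fp: int
    fn: int
    matches: list = field(default_factory=list, repr=False)

    @property
    def r(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def p(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def f(self) -> float:
        r, p = self.r, self.p
        if np.isnan(r) or np.isnan(p) or r + p == 0:
            return float("nan")
        return 2 * r * p / (r + p)

    @property
    def valid(self) -> bool:
        """False when the reference set was empty (rate undefined)."""
        return self.tp + self.fn > 0

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "DetectionResult":
        return cls(tp=tp, fp=fp, fn=fn)


def evaluate_detection(
    predicted: np.ndarray | pd.DataFrame,
    reference: np.ndarray | pd.DataFrame,
    match_radius: float = 2.0,
) -> DetectionResult:
    """Match detected apexes to reference trees and score detection.

    Greedy nearest-pair matching: candidate (prediction, reference) pairs
    within ``match_radius`` are taken in order of increasing distance, each
    side matched at most once.  TP = matched pairs, FN = unmatched reference
    trees, FP = unmatched predictions.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    pred = _as_xy(predicted)
    ref = _as_xy(reference)
    if len(ref) == 0 or len(pred) == 0:
        return DetectionResult(tp=0, fp=len(pred), fn=len(ref))
    tree = cKDTree(ref)
    pairs = tree.query_ball_point(pred, r=match_radius)
    cand = [
        (np.hypot(*(pred[i] - ref[j])), i, j)
        for i, js in enumerate(pairs)
        for j in js
    ]
    cand.sort()
    used_p: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for d, i, j in cand:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        matches.append((i, j, d))
    tp = len(matches)
    return DetectionResult(
        tp=tp, fp=len(pred) - tp, fn=len(ref) - tp, matches=matches
    )


def _as_xy(obj) -> np.ndarray:
    if isinstance(obj, pd.DataFrame):
        return obj[["x", "y"]].to_numpy(dtype=float)
    arr = np.asarray(obj, dtype=float)
    return arr.reshape(-1, 2)


def select_window(
    chm: CHMRaster,
    reference,
    candidate_windows,
    min_height: float = 2.0,
    match_radius: float = 2.0,
) -> tuple[tuple[float, float], dict]:
    """Pick the detection window maximising F over candidates.

    Ties are broken toward the smaller window area, then candidate order.
    Returns ``(best_window, {window: DetectionResult})``.
    """
    candidates = [tuple(w) for w in candidate_windows]
    if not candidates:
        raise ValueError("at least one candidate window is required")
    results = {}
    for w in candidates:
        apices = detect_treetops(chm, window_x=w[0], window_y=w[1], min_height=min_height)
        results[w] = evaluate_detection(apices, reference, match_radius=match_radius)
    best = max(
        enumerate(candidates),
        key=lambda iw: (
            -1.0 if np.isnan(results[iw[1]].f) else results[iw[1]].f,
            -iw[1][0] * iw[1][1],
            -iw[0],
        ),
    )[1]
    return best, results
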