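"""Outline resampling and the semilandmark-economy rule.

Outline curves digitized as dense polylines carry far more points than are
needed to represent their shape. Following the length-accuracy criterion of
classic outline morphometrics, the minimum number of equally spaced points is
the smallest ``n`` whose resampled polyline recovers at least a given fraction
(default 95%) of the dense outline's arc length. Using this economy rule keeps
simple curves from being over-sampled and complex curves from being
under-sampled.
"""

from __future__ import annotations

import numpy as np

__all__ = ["polyline_length", "resample_curve", "min_semilandmarks"]


def _as_polyline(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an (n, 2) array of 2D points")
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polyline contains non-finite coordinates")
    return pts


def polyline_length(points) -> float:
    """Total Euclidean arc length of an open polyline.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        Ordered vertices, n >= 2.
    """
    pts = _as_polyline(points)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_curve(points, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length intervals.

    The first and last output points coincide with the polyline endpoints.

    Parameters
    ----------
    points : array-like of shape (k, 2)
        Ordered polyline vertices, k >= 2.
    n : int
        Number of output points, n >= 2.

    Returns
    -------
    ndarray of shape (n, 2)
    """
    pts = _as_polyline(points)
    if n < 2:
        raise ValueError("n must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0.0:
        raise ValueError("degenerate zero-length polyline")
    target = np.linspace(0.0, total, n)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def min_semilandmarks(dense_curve, accuracy: float = 0.95) -> int:
    """Smallest point count measuring an outline's length to given accuracy.

    Returns the smallest ``n >= 2`` such that the length of the polyline
    through ``n`` equally spaced points on ``dense_curve`` is at least
    ``accuracy`` times the length of the dense curve itself. The dense input
    is treated as the true outline, so it should be sampled well above the
    resolution being sought.

    Chords inscribed in a curve never exceed its arc length, so the accuracy
    ratio is at most 1; for convex arcs it increases weakly with ``n`` and the
    increment-until-satisfied scan below terminates for accuracy < 1.
    """
    pts = _as_polyline(dense_curve)
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must be in (0, 1]")
    true_len = polyline_length(pts)
    if true_len <= 0.0:
        raise ValueError("degenerate zero-length curve")
    n_cap = max(1000, 2 * len(pts))
    n = 2
    while True:
        ratio = polyline_length(resample_curve(pts, n)) / true_len
        if ratio >= accuracy - 1e-12:
            return n
        n += 1
        if n > n_cap:
            raise RuntimeError(
                "accuracy criterion not reached; supply a denser curve or a "
                "lower accuracy target"
            )
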