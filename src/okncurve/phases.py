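"""Curve-phase partitioning: entry / cornering / exit from the yaw profile.

Trials are made comparable by projecting each trial's planar positions
onto a common reference trajectory (route distance in metres from the
start of the leg). Phase boundaries are then derived from the yaw-rate
profile: the steady *cornering* phase is the maximal contiguous interval
where yaw stays within a band around the plateau level, *entry* runs
from yaw onset to cornering start, and *exit* from cornering end to yaw
offset. The plateau rule is an algorithmic stand-in for a manual
choice based on median yaw rate; all thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ReferenceTrajectory:
    """Ordered planar reference path with cumulative route distance."""

    points: np.ndarray        # (m, 2) metres
    distances: np.ndarray     # (m,) metres, strictly increasing from >= 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("reference needs at least two planar points")
        if len(d) != len(pts):
            raise ValueError("distances must match points")
        if d[0] < 0 or np.any(np.diff(d) <= 0):
            raise ValueError("distances must be non-negative and strictly increasing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "distances", d)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "ReferenceTrajectory":
        pts = np.asarray(points, dtype=float)
        step = np.hypot(*np.diff(pts, axis=0).T)
        if np.any(step <= 0):
            raise ValueError("consecutive reference points must be distinct")
        return cls(pts, np.concatenate([[0.0], np.cumsum(step)]))


@dataclass(frozen=True)
class PhaseBounds:
    """Half-open route-distance intervals (metres) of the three phases,
    plus the corresponding sample index ranges of the analysed trial."""

    entry: tuple[float, float]
    cornering: tuple[float, float]
    exit: tuple[float, float]
    entry_idx: tuple[int, int]
    cornering_idx: tuple[int, int]
    exit_idx: tuple[int, int]


def map_to_reference(
    trial_positions: np.ndarray, reference: ReferenceTrajectory
) -> np.ndarray:
    """Project trial positions onto the reference route distance.

    Each trial point is projected perpendicularly onto the nearest
    reference segment and assigned the interpolated route distance of
    the projection; assignments are constrained to be non-decreasing in
    time, so backward GPS jitter cannot move the vehicle backwards along
    the route.
    """
    pos = np.asarray(trial_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) == 0:
        raise ValueError("trial positions must be a non-empty (n, 2) array")
    p0 = reference.points[:-1]
    seg = np.diff(reference.points, axis=0)
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    d0 = reference.distances[:-1]
    seg_d = np.diff(reference.distances)

    out = np.empty(len(pos))
    floor = 0.0
    for i, p in enumerate(pos):
        w = p - p0
        frac = np.clip(np.einsum("ij,ij->i", w, seg) / seg_len2, 0.0, 1.0)
        proj = p0 + frac[:, None] * seg
        dist2 = np.einsum("ij,ij->i", proj - p, proj - p)
        route = d0 + frac * seg_d
        # monotonic constraint: ignore candidates behind the current position
        ahead = route >= floor
        if ahead.any():
            k = int(np.flatnonzero(ahead)[np.argmin(dist2[ahead])])
            floor = float(route[k])
        out[i] = floor
    return out


def detect_phases(
    route_distance: np.ndarray,
    yaw: np.ndarray,
    t: np.ndarray | None = None,
    plateau_select_frac: float = 0.5,
    band_frac: float = 0.2,
    onset_frac: float = 0.1,
    smooth_window: float = 1.0,
) -> PhaseBounds:
    """Detect entry / cornering / exit phases from the yaw-rate profile.

    The yaw profile is first smoothed with a centred rolling median
    (window ``smooth_window`` seconds when ``t`` is given, else samples at
    an assumed 60 Hz) so sample-level yaw noise cannot fragment the
    plateau. The plateau level is the median of |yaw| over samples
    exceeding ``plateau_select_frac`` of the 95th-percentile |yaw|;
    cornering is the maximal contiguous interval with |yaw| within
    ``band_frac`` of the plateau; entry starts at the first sample with
    |yaw| at least ``onset_frac`` of the plateau, exit ends at the last
    such sample. On a linear ramp the smoothing is exact (the median of a
    centred window equals the centre value), so clean trapezoid profiles
    are unaffected.
    """
    d = np.asarray(route_distance, dtype=float)
    w = np.abs(np.asarray(yaw, dtype=float))
    if len(d) != len(w) or len(d) == 0:
        raise ValueError("route distance and yaw series must be equal-length, non-empty")
    if smooth_window > 0:
        dt = float(np.median(np.diff(t))) if t is not None and len(t) > 1 else 1.0 / 60.0
        win = max(1, int(round(smooth_window / dt)))
        if win > 1:
            import pandas as pd

            w = pd.Series(w).rolling(win, center=True, min_periods=1) \
                .median().to_numpy()
    p95 = np.percentile(w, 95)
    if p95 <= 0:
        raise ValueError("yaw rate is identically zero: no bend to segment")
    plateau = float(np.median(w[w >= plateau_select_frac * p95]))
    in_band = np.abs(w - plateau) <= band_frac * plateau

    # maximal contiguous in-band run
    best = (0, 0)
    i = 0
    n = len(w)
    while i < n:
        if in_band[i]:
            j = i
            while j < n and in_band[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    c0, c1 = best
    if c1 == c0:
        raise ValueError("no samples within the cornering band")

    active = np.flatnonzero(w >= onset_frac * plateau)
    e0 = int(min(active[0], c0))
    x1 = int(max(active[-1] + 1, c1))

    def interval(i0, i1):
        if i1 <= i0:
            lo = d[min(i0, n - 1)]
            return (float(lo), float(lo))
        hi = d[i1] if i1 < n else d[n - 1]
        return (float(d[i0]), float(hi))

    return PhaseBounds(
        entry=interval(e0, c0),
        cornering=interval(c0, c1),
        exit=interval(c1, x1),
        entry_idx=(e0, c0),
        cornering_idx=(c0, c1),
        exit_idx=(c1, x1),
    )
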