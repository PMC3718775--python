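"""Curvilinear self-motion geometry on a flat ground plane.

World frame: x/y in metres, mathematical angle convention (CCW from +x).
The driven bend is a *right-hand* curve: the vehicle travels clockwise
around the curve centre, so heading decreases over time while the yaw
rate is reported positive ("into the curve").

Vehicle (gaze) frame: horizontal angle ``h`` in degrees, positive toward
the inside of the curve (to the right of the instantaneous heading);
vertical angle ``v`` in degrees, positive up. The eye sits ``eye_height``
metres above the ground plane and looks horizontally at angle 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TELEMETRY_COLUMNS = ["t", "speed", "yaw", "x", "y", "heading"]


@dataclass(frozen=True)
class RoadModel:
    """Constant-radius bend: the vehicle's driven circle and the inner road edge.

    Parameters
    ----------
    center_x, center_y:
        Curve centre in metres.
    path_radius:
        Radius R of the circle the vehicle drives on, metres.
    inner_edge_radius:
        Radius r < R of the inside lane edge circle; the tangent from the
        eye to this circle defines the tangent point.
    eye_height:
        Eye height above the ground plane, metres.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    path_radius: float = 49.2
    inner_edge_radius: float = 47.2
    eye_height: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_edge_radius < self.path_radius):
            raise ValueError(
                "require 0 < inner_edge_radius < path_radius, got "
                f"r={self.inner_edge_radius}, R={self.path_radius}"
            )
        if self.eye_height <= 0.0:
            raise ValueError(f"eye_height must be positive, got {self.eye_height}")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y])


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-180, 180]."""
    return -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)


def generate_cornering_telemetry(
    road: RoadModel,
    speed: float,
    duration: float,
    sample_rate: float = 60.0,
    start_angle: float = 90.0,
    speed_wobble: float = 0.0,
    wobble_period: float = 8.0,
) -> pd.DataFrame:
    """Steady-state cornering telemetry on the driven circle.

    The vehicle moves clockwise (right-hand bend) on the circle of radius
    ``road.path_radius`` about the road centre. With ``speed_wobble == 0``
    the yaw rate is exactly constant at ``(speed / R)`` (converted to
    degrees/s) and the heading is tangent to the circle. A non-zero
    ``speed_wobble`` superimposes a sinusoidal fractional speed modulation
    (period ``wobble_period`` seconds), emulating the small
    throttle/steering variations of real cornering; positions remain on
    the circle.

    Returns a DataFrame with columns t, speed (m/s), yaw (deg/s),
    x, y (m), heading (deg).
    """
    if speed <= 0:
        raise ValueError(f"speed must be positive, got {speed}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    if not 0.0 <= speed_wobble < 1.0:
        raise ValueError(f"speed_wobble must be in [0, 1), got {speed_wobble}")

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    v = speed * (1.0 + speed_wobble * np.sin(2.0 * np.pi * t / wobble_period))
    r = road.path_radius
    # angular position on the circle (radians, CCW); clockwise motion
    omega_rad = v / r
    theta = np.deg2rad(start_angle) - np.concatenate(
        [[0.0], np.cumsum(0.5 * (omega_rad[1:] + omega_rad[:-1]) / sample_rate)]
    )
    x = road.center_x + r * np.cos(theta)
    y = road.center_y + r * np.sin(theta)
    heading = np.rad2deg(theta) - 90.0  # tangent, clockwise travel
    yaw = np.rad2deg(omega_rad)
    return pd.DataFrame(
        {"t": t, "speed": v, "yaw": yaw, "x": x, "y": y, "heading": heading}
    )


def generate_trial_telemetry(
    road: RoadModel,
    speed: float,
    entry_duration: float = 3.0,
    cornering_duration: float = 16.0,
    exit_duration: float = 3.0,
    straight_duration: float = 2.0,
    sample_rate: float = 60.0,
) -> pd.DataFrame:
    """A full curve trial: straight approach, yaw ramp-in, steady cornering,
    ramp-out, straight exit.

    The yaw-rate profile is trapezoidal with plateau ``speed / R``; the
    trajectory is obtained by integrating heading, so entry/exit are
    clothoid-like transitions rather than circular arcs. The road-model
    centre is ignored for path generation; use :func:`fit_road_model` to
    recover the road model matching the plateau circle.
    """
    if speed <= 0 or sample_rate <= 0:
        raise ValueError("speed and sample_rate must be positive")
    durs = (straight_duration, entry_duration, cornering_duration, exit_duration,
            straight_duration)
    if any(d < 0 for d in durs) or cornering_duration <= 0:
        raise ValueError("durations must be non-negative, cornering positive")

    total = sum(durs)
    n = int(round(total * sample_rate))
    t = np.arange(n) / sample_rate
    yaw_ss = np.rad2deg(speed / road.path_radius)
    t0 = straight_duration
    t1 = t0 + entry_duration
    t2 = t1 + cornering_duration
    t3 = t2 + exit_duration
    yaw = np.interp(t, [0.0, t0, t1, t2, t3, total], [0, 0, yaw_ss, yaw_ss, 0, 0])
    heading = -np.concatenate([[0.0], np.cumsum(0.5 * (yaw[1:] + yaw[:-1]) / sample_rate)])
    hx = np.cos(np.deg2rad(heading))
    hy = np.sin(np.deg2rad(heading))
    x = np.concatenate([[0.0], np.cumsum(0.5 * (hx[1:] + hx[:-1]) * speed / sample_rate)])
    y = np.concatenate([[0.0], np.cumsum(0.5 * (hy[1:] + hy[:-1]) * speed / sample_rate)])
    return pd.DataFrame(
        {"t": t, "speed": np.full(n, float(speed)), "yaw": yaw, "x": x, "y": y,
         "heading": heading}
    )


def fit_road_model(
    telemetry: pd.DataFrame,
    path_radius: float,
    lane_half_width: float = 2.0,
    eye_height: float = 1.2,
) -> RoadModel:
    """Road model whose centre matches the trial's steady-cornering circle.

    Takes the sample of maximum yaw rate and places the curve centre
    ``path_radius`` metres to the right of the heading at that sample.
    """
    i = int(np.argmax(np.abs(telemetry["yaw"].to_numpy())))
    head = np.deg2rad(telemetry["heading"].iloc[i])
    # inside of a right-hand bend = 90 deg clockwise of heading
    nx, ny = np.cos(head - np.pi / 2.0), np.sin(head - np.pi / 2.0)
    cx = telemetry["x"].iloc[i] + path_radius * nx
    cy = telemetry["y"].iloc[i] + path_radius * ny
    return RoadModel(cx, cy, path_radius, path_radius - lane_half_width, eye_height)


def vehicle_frame_angles(
    px: np.ndarray | float,
    py: np.ndarray | float,
    x: np.ndarray | float,
    y: np.ndarray | float,
    heading: np.ndarray | float,
    eye_height: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Angular position (h, v) of ground point(s) in the vehicle frame.

    h positive clockwise of heading (toward the inside of a right-hand
    bend); v negative below the horizontal eye line.
    """
    wx = np.asarray(px, dtype=float) - np.asarray(x, dtype=float)
    wy = np.asarray(py, dtype=float) - np.asarray(y, dtype=float)
    rho = np.hypot(wx, wy)
    bearing = np.rad2deg(np.arctan2(wy, wx))
    h = _wrap_deg(np.asarray(heading, dtype=float) - bearing)
    v = np.rad2deg(np.arctan2(-eye_height, rho))
    return h, v


def tangent_point_world(
    x: np.ndarray | float, y: np.ndarray | float, road: RoadModel,
    heading: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """World coordinates of the forward tangent point on the inner edge.

    Of the two tangency points from the eye to the inner-edge circle, the
    one ahead of the vehicle (positive projection on the heading) is
    returned.

    Raises ``ValueError`` when the vehicle is on or inside the inner edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    heading = np.asarray(heading, dtype=float)
    dx = x - road.center_x
    dy = y - road.center_y
    d = np.hypot(dx, dy)
    r = road.inner_edge_radius
    if np.any(d <= r):
        raise ValueError("vehicle on or inside the inner road edge (D <= r)")
    phi = np.arccos(r / d)  # angle at centre between CP and CT
    base = np.arctan2(dy, dx)
    cands = []
    for s in (+1.0, -1.0):
        a = base + s * phi
        cands.append((road.center_x + r * np.cos(a), road.center_y + r * np.sin(a)))
    hx = np.cos(np.deg2rad(heading))
    hy = np.sin(np.deg2rad(heading))
    proj = [ (tx - x) * hx + (ty - y) * hy for tx, ty in cands ]
    ahead = proj[0] >= proj[1]
    tx = np.where(ahead, cands[0][0], cands[1][0])
    ty = np.where(ahead, cands[0][1], cands[1][1])
    return tx, ty


def tangent_point_track(telemetry: pd.DataFrame, road: RoadModel) -> pd.DataFrame:
    """Angular track (h, v) of the tangent point over a telemetry series.

    For concentric circular motion the horizontal eccentricity is the
    closed-form ``90 - arcsin(r / D)`` degrees toward the inside, constant
    over time; the vertical angle is ``-arctan(eye_height / ground
    distance)``.
    """
    tx, ty = tangent_point_world(
        telemetry["x"].to_numpy(), telemetry["y"].to_numpy(), road,
        telemetry["heading"].to_numpy(),
    )
    h, v = vehicle_frame_angles(
        tx, ty, telemetry["x"].to_numpy(), telemetry["y"].to_numpy(),
        telemetry["heading"].to_numpy(), road.eye_height,
    )
    return pd.DataFrame({"t": telemetry["t"].to_numpy(), "h": h, "v": v})


def tangent_point_eccentricity(distance_to_center: float, road: RoadModel) -> float:
    """Closed-form horizontal TP eccentricity (degrees) at distance D from centre."""
    r = road.inner_edge_radius
    if distance_to_center <= r:
        raise ValueError("vehicle on or inside the inner road edge (D <= r)")
    return 90.0 - np.rad2deg(np.arcsin(r / distance_to_center))


def angular_track(
    point: tuple[float, float], telemetry: pd.DataFrame, road: RoadModel
) -> tuple[np.ndarray, np.ndarray]:
    """Vehicle-frame angular track (h, v) of a fixed world ground point."""
    return vehicle_frame_angles(
        point[0], point[1], telemetry["x"].to_numpy(), telemetry["y"].to_numpy(),
        telemetry["heading"].to_numpy(), road.eye_height,
    )


def optic_flow_at_point(
    point: tuple[float, float],
    state: pd.Series | dict,
    road: RoadModel,
) -> tuple[float, float]:
    """Analytic optic flow (dh/dt, dv/dt, degrees/s) of a fixed ground point.

    Uses the exact time derivative of the vehicle-frame angular position:
    with relative position W = Q - P, range rho = |W|, eye velocity
    vector Vvec and heading rate -omega (right-hand bend),

        dh/dt = -omega - d(bearing)/dt,
        d(bearing)/dt = (W_y Vvec_x - W_x Vvec_y) / rho^2,
        dv/dt = -e * (W . Vvec) / (rho (rho^2 + e^2))  [e = eye height].

    The point must be strictly ahead of the eye plane (positive projection
    of W on the heading), otherwise a ``ValueError`` is raised.
    """
    x, y = float(state["x"]), float(state["y"])
    heading = float(state["heading"])
    v = float(state["speed"])
    omega = float(state["yaw"])
    wx = point[0] - x
    wy = point[1] - y
    rho2 = wx * wx + wy * wy
    rho = np.sqrt(rho2)
    hx = np.cos(np.deg2rad(heading))
    hy = np.sin(np.deg2rad(heading))
    if wx * hx + wy * hy <= 0.0:
        raise ValueError("point at or behind the eye plane")
    vx, vy = v * hx, v * hy
    bearing_rate = np.rad2deg((wy * vx - wx * vy) / rho2)
    dh = -omega - bearing_rate
    e = road.eye_height
    dv = np.rad2deg(-e * (wx * vx + wy * vy) / (rho * (rho2 + e * e)))
    return float(dh), float(dv)


def future_path_point(
    telemetry: pd.DataFrame, idx: int, lookahead_arc: float, road: RoadModel
) -> tuple[float, float]:
    """World point on the future driven path ``lookahead_arc`` degrees of
    arc ahead of sample ``idx``.

    The arc is converted to path length (arc * R) and the point taken on
    the recorded future trajectory at that cumulative distance. Beyond the
    end of the series the path is extrapolated with the final curvature
    (yaw / speed; straight when the final yaw is negligible), so on
    concentric circular motion the target is exactly the point on the
    driven circle ``lookahead_arc`` ahead, at any sample.
    """
    x = telemetry["x"].to_numpy()
    y = telemetry["y"].to_numpy()
    step = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(step)])
    target_s = s[idx] + np.deg2rad(lookahead_arc) * road.path_radius
    if target_s >= s[-1]:
        extra = target_s - s[-1]
        head = np.deg2rad(telemetry["heading"].iloc[-1])
        speed = float(telemetry["speed"].iloc[-1])
        yaw_rad = np.deg2rad(float(telemetry["yaw"].iloc[-1]))
        if speed <= 0 or abs(yaw_rad) < 1e-9:
            return float(x[-1] + extra * np.cos(head)), float(y[-1] + extra * np.sin(head))
        radius = speed / abs(yaw_rad)
        sgn = 1.0 if yaw_rad > 0 else -1.0  # positive yaw = clockwise (right bend)
        # curve centre sits `radius` to the inside of the final heading
        cx = x[-1] + radius * np.cos(head - sgn * np.pi / 2.0)
        cy = y[-1] + radius * np.sin(head - sgn * np.pi / 2.0)
        a0 = np.arctan2(y[-1] - cy, x[-1] - cx)
        a = a0 - sgn * extra / radius
        return float(cx + radius * np.cos(a)), float(cy + radius * np.sin(a))
    j = int(np.searchsorted(s, target_s))
    if j == 0:
        return float(x[0]), float(y[0])
    # linear interpolation between samples j-1 and j
    span = s[j] - s[j - 1]
    w = 0.0 if span <= 0 else (target_s - s[j - 1]) / span
    return float(x[j - 1] + w * (x[j] - x[j - 1])), float(y[j - 1] + w * (y[j] - y[j - 1]))
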