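"""Strategy-conditioned synthetic gaze with known ground truth.

Emulates 60 Hz on-road gaze recordings during curve negotiation under
three gaze strategies:

``fp_track``
    Future-path tracking: gaze locks onto a fixed world point on the
    future driven path and follows its exact angular track (optokinetic
    slow phase); after an exponentially distributed dwell an
    instantaneous quick phase resets gaze to a new target a fixed arc
    ahead. On steady cornering the horizontal slow-phase velocity is
    exactly half the yaw rate, opposite the curve direction.
``gaze_poll``
    As ``fp_track``, but after a tracking episode gaze occasionally makes
    an out-and-back saccade pair to a second, more distal path target.
``tp_fixate``
    Gaze locked on the tangent point (optokinetic reflex suppressed);
    near-zero gaze velocity during steady cornering.

All strategies then add i.i.d. Gaussian axis-independent measurement
noise and replace samples with broadband outliers at a Poisson rate
(per-sample Bernoulli thinning of the rate). Quick phases are
instantaneous between-sample jumps, so ground-truth segment labelling is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    RoadModel,
    angular_track,
    future_path_point,
    generate_cornering_telemetry,
    tangent_point_track,
)

STRATEGIES = ("fp_track", "tp_fixate", "gaze_poll")

#: shortest permitted slow-phase dwell, in samples; a two-parameter line
#: needs at least 3 points, and real slow phases are rarely shorter than
#: a few tens of milliseconds.
MIN_DWELL_SAMPLES = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate the study conditions."""

    strategy: str = "fp_track"
    sample_rate: float = 60.0
    noise_sd: float = 0.5          # degrees, per axis
    outlier_rate: float = 0.5      # events / s
    outlier_range: float = 30.0    # degrees, uniform +-range
    dwell_mean: float = 0.5        # seconds, exponential slow-phase dwell
    # degrees of arc to the FP target; the default places targets just
    # beyond the tangent point (far zone), at ~2x the TP eccentricity
    lookahead_arc: float = 35.0
    poll_prob: float = 0.2         # out-saccade probability per reset
    poll_dwell: float = 0.3        # seconds spent on the distal target
    n_subjects: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.outlier_rate < 0:
            raise ValueError("outlier_rate must be non-negative")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be positive")
        if self.outlier_range <= 0:
            raise ValueError("outlier_range must be positive")


@dataclass
class GroundTruth:
    """True segmentation of a synthetic gaze series (test oracle).

    ``boundaries`` are the start indices of the true linear episodes
    (half-open spans; ``boundaries[k] .. boundaries[k+1]``), ``slopes``
    the per-episode least-squares slopes of the noise-free track in
    degrees/s, ``outlier_idx`` the samples replaced by outliers, and
    ``targets`` the tracked world point per episode (NaN for the tangent
    point episodes).
    """

    boundaries: np.ndarray
    slopes_h: np.ndarray
    slopes_v: np.ndarray
    outlier_idx: np.ndarray
    targets: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n_segments(self) -> int:
        return len(self.boundaries)

    def spans(self, n: int) -> list[tuple[int, int]]:
        ends = np.append(self.boundaries[1:], n)
        return [(int(s), int(e)) for s, e in zip(self.boundaries, ends)]


def _fit_slope(t: np.ndarray, y: np.ndarray) -> float:
    """OLS slope; exact for linear tracks, 0.0 for single-sample spans."""
    if len(t) < 2:
        return 0.0
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(tc, y - y.mean()) / denom)


#: fraction of the lookahead distance the vehicle may cover before the
#: generator forces a quick-phase reset; keeps tracked points well ahead
#: of the eye so slow phases stay close to linear.
MAX_DWELL_ARC_FRACTION = 0.7


def _plan_episodes(
    telemetry: pd.DataFrame,
    road: RoadModel,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int, str]]:
    """Episode plan: (start, end, kind) with kind in {'near', 'far'}.

    Dwells are Exponential(dwell_mean) truncated so the vehicle never
    covers more than ``MAX_DWELL_ARC_FRACTION`` of the lookahead distance
    within one slow phase.
    """
    n = len(telemetry)
    rate = config.sample_rate
    x = telemetry["x"].to_numpy()
    y = telemetry["y"].to_numpy()
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    lookahead_m = np.deg2rad(config.lookahead_arc) * road.path_radius
    episodes: list[tuple[int, int, str]] = []
    idx = 0
    while idx < n:
        k = max(MIN_DWELL_SAMPLES, int(round(rng.exponential(config.dwell_mean) * rate)))
        cap = int(np.searchsorted(s, s[idx] + MAX_DWELL_ARC_FRACTION * lookahead_m))
        cap = max(cap, idx + MIN_DWELL_SAMPLES)
        end = min(idx + k, cap, n)
        episodes.append((idx, end, "near"))
        idx = end
        if (
            config.strategy == "gaze_poll"
            and idx < n
            and rng.random() < config.poll_prob
        ):
            k2 = max(MIN_DWELL_SAMPLES, int(round(config.poll_dwell * rate)))
            end = min(idx + k2, n)
            episodes.append((idx, end, "far"))
            idx = end
    return episodes


def simulate_gaze(
    telemetry: pd.DataFrame,
    road: RoadModel,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a gaze series and its ground truth for one trial.

    Output is a pure function of (telemetry, road, config): the same seed
    yields a byte-identical series.
    """
    if len(telemetry) == 0:
        raise ValueError("telemetry must be non-empty")
    n = len(telemetry)
    t = telemetry["t"].to_numpy()
    rng = np.random.default_rng(config.seed)

    h = np.empty(n)
    v = np.empty(n)
    if config.strategy == "tp_fixate":
        track = tangent_point_track(telemetry, road)
        h[:] = track["h"].to_numpy()
        v[:] = track["v"].to_numpy()
        episodes = [(0, n, "near")]
        targets = np.full((1, 2), np.nan)
    else:
        episodes = _plan_episodes(telemetry, road, config, rng)
        targets = np.empty((len(episodes), 2))
        for k, (s, e, kind) in enumerate(episodes):
            arc = config.lookahead_arc * (2.0 if kind == "far" else 1.0)
            q = future_path_point(telemetry, s, arc, road)
            targets[k] = q
            th, tv = angular_track(q, telemetry, road)
            h[s:e] = th[s:e]
            v[s:e] = tv[s:e]

    boundaries = np.array([s for s, _, _ in episodes], dtype=int)
    slopes_h = np.array([_fit_slope(t[s:e], h[s:e]) for s, e, _ in episodes])
    slopes_v = np.array([_fit_slope(t[s:e], v[s:e]) for s, e, _ in episodes])

    if config.noise_sd > 0:
        h = h + rng.normal(0.0, config.noise_sd, n)
        v = v + rng.normal(0.0, config.noise_sd, n)
    p_out = config.outlier_rate / config.sample_rate
    out_mask = rng.random(n) < p_out
    outlier_idx = np.flatnonzero(out_mask)
    if len(outlier_idx):
        h[outlier_idx] = rng.uniform(-config.outlier_range, config.outlier_range,
                                     len(outlier_idx))
        v[outlier_idx] = rng.uniform(-config.outlier_range, config.outlier_range,
                                     len(outlier_idx))

    gaze = pd.DataFrame({"t": t, "h": h, "v": v, "valid": np.ones(n, dtype=int)})
    truth = GroundTruth(boundaries, slopes_h, slopes_v, outlier_idx, targets)
    return gaze, truth


@dataclass
class SubjectRun:
    """One simulated subject: telemetry, gaze, ground truth and true yaw."""

    subject: int
    telemetry: pd.DataFrame
    gaze: pd.DataFrame
    truth: GroundTruth
    yaw_mean: float


def simulate_cohort(
    road: RoadModel,
    config: SyntheticConfig,
    duration: float = 60.0,
    yaw_mean: float = 13.8,
    yaw_sd: float = 1.4,
    speed_wobble: float = 0.0,
) -> list[SubjectRun]:
    """Simulate ``config.n_subjects`` independent cornering trials.

    Per-subject yaw rates are drawn from Normal(yaw_mean, yaw_sd) deg/s
    (the study's steady-state cornering distribution) and converted to a
    speed on the fixed-radius bend. Subjects get independent child seeds
    derived from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    rng = np.random.default_rng(children[0])
    runs: list[SubjectRun] = []
    for i in range(config.n_subjects):
        yaw_i = float(rng.normal(yaw_mean, yaw_sd))
        yaw_i = max(yaw_i, 1.0)  # keep the bend a bend
        speed = np.deg2rad(yaw_i) * road.path_radius
        tel = generate_cornering_telemetry(
            road, speed, duration, config.sample_rate, speed_wobble=speed_wobble
        )
        sub_seed = int(children[i + 1].generate_state(1)[0] % (2**31 - 1))
        sub_cfg = replace(config, seed=sub_seed)
        gaze, truth = simulate_gaze(tel, road, sub_cfg)
        runs.append(SubjectRun(i, tel, gaze, truth, float(np.mean(tel["yaw"]))))
    return runs
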