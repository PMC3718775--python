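"""End-to-end cohort analysis: simulate -> segment -> phases -> statistics.

Composes the package's stages into a seeded, reproducible run that
mirrors the study design: a cohort of drivers negotiates a
constant-radius bend; their gaze is recorded, segmented into slow and
quick phases, referenced to the tangent point, and summarized as
velocity-space density modes, AOI catch percentages, and the half-yaw-
rate consistency statistics that differentiate future-path tracking
from tangent-point fixation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as okio
from .geometry import (
    RoadModel,
    fit_road_model,
    generate_cornering_telemetry,
    generate_trial_telemetry,
    tangent_point_track,
)
from .phases import PhaseBounds, ReferenceTrajectory, detect_phases, map_to_reference
from .segmentation import (
    SegmentationParams,
    classify_segments,
    fitted_positions,
    per_sample_velocity,
    segment_gaze,
)
from .stats import (
    aoi_catch_table,
    displacement_from_tp,
    entry_vs_cornering_sign_test,
    estimate_mode,
    hotelling_region,
    kde2d,
    silverman_bandwidth,
    sp_orientation_histogram,
    yaw_gaze_consistency,
)
from .synth import SubjectRun, SyntheticConfig, simulate_gaze

log = logging.getLogger("okncurve")


@dataclass
class RunConfig:
    """Full resolved configuration of a pipeline run."""

    outdir: str | None = None
    seed: int = 0
    road: RoadModel = field(default_factory=RoadModel)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    duration: float = 60.0            # cornering-phase duration, s
    yaw_mean: float = 13.8            # deg/s, cohort steady-state yaw
    yaw_sd: float = 1.4               # deg/s, between-subject spread
    speed_wobble: float = 0.0         # within-trial fractional speed modulation
    full_trial: bool = False          # include entry/exit ramps and straights
    position_bandwidth: float = 1.0   # deg, fixed KDE bandwidth for displacement
    grid_step: float = 0.25           # deg or deg/s, density grid resolution
    aoi_radii: tuple[int, ...] = tuple(range(2, 11))
    sign_test_radius: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key, sub in (("road", RoadModel), ("synth", SyntheticConfig),
                         ("seg", SegmentationParams)):
            if key in raw:
                kw[key] = sub(**raw.pop(key))
        kw.update(raw)
        return cls(**kw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["seed"] = self.seed
        return d


def _simulate_subject(cfg: RunConfig, subject: int, yaw_i: float,
                      sub_seed: int) -> SubjectRun:
    speed = np.deg2rad(yaw_i) * cfg.road.path_radius
    if cfg.full_trial:
        tel = generate_trial_telemetry(
            cfg.road, speed, cornering_duration=cfg.duration,
            sample_rate=cfg.synth.sample_rate,
        )
        road = fit_road_model(
            tel, cfg.road.path_radius,
            cfg.road.path_radius - cfg.road.inner_edge_radius,
            cfg.road.eye_height,
        )
    else:
        tel = generate_cornering_telemetry(
            cfg.road, speed, cfg.duration, cfg.synth.sample_rate,
            speed_wobble=cfg.speed_wobble,
        )
        road = cfg.road
    sub_cfg = dataclasses.replace(cfg.synth, seed=sub_seed)
    gaze, truth = simulate_gaze(tel, road, sub_cfg)
    run = SubjectRun(subject, tel, gaze, truth, float(np.mean(tel["yaw"])))
    run.road = road  # per-subject road model (trial trajectories re-centre it)
    return run


def analyze_subject(run: SubjectRun, road: RoadModel, cfg: RunConfig) -> dict:
    """Segment one subject's gaze and compute phase-resolved statistics."""
    result = classify_segments(segment_gaze(run.gaze, cfg.seg),
                               cfg.seg.qp_speed_threshold)
    vel = per_sample_velocity(result, run.gaze)
    fit = fitted_positions(result, run.gaze)
    tp = tangent_point_track(run.telemetry, road)

    phases = detect_phases(
        np.arange(len(run.telemetry), dtype=float),
        run.telemetry["yaw"].to_numpy(),
    )

    def phase_mask(idx_range):
        m = np.zeros(len(run.gaze), dtype=bool)
        m[idx_range[0]:idx_range[1]] = True
        return m

    corner = phase_mask(phases.cornering_idx)
    entry = phase_mask(phases.entry_idx)

    disp = displacement_from_tp(
        np.column_stack([fit["h"], fit["v"]]),
        np.column_stack([tp["h"], tp["v"]]),
    )
    okpos = fit["ok"].to_numpy()

    sp_mask = np.zeros(len(run.gaze), dtype=bool)
    for s in result.segments:
        if s.label == "SP":
            sp_mask[s.start_idx:s.end_idx] = True
    vel_ok = vel["ok"].to_numpy() & sp_mask & corner
    sp_vel = np.column_stack([vel["vel_h"], vel["vel_v"]])[vel_ok]

    bw = silverman_bandwidth(sp_vel)
    vel_density = kde2d(sp_vel, bw, grid_step=cfg.grid_step)
    vel_mode = estimate_mode(vel_density)

    pos_pts = disp[okpos & corner]
    pos_density = kde2d(pos_pts, cfg.position_bandwidth, grid_step=cfg.grid_step)
    pos_mode = estimate_mode(pos_density)

    aoi = {
        "cornering": aoi_catch_table(disp[okpos & corner], cfg.aoi_radii),
        "entry": (aoi_catch_table(disp[okpos & entry], cfg.aoi_radii)
                  if (okpos & entry).sum() > 0 else None),
    }
    yaw_corner = run.telemetry["yaw"].to_numpy()[corner]
    return {
        "result": result,
        "phases": phases,
        "vel_mode": vel_mode,
        "vel_bandwidth": bw,
        "pos_mode": pos_mode,
        "vel_density": vel_density,
        "pos_density": pos_density,
        "aoi": aoi,
        "yaw_mean_cornering": float(np.mean(yaw_corner)),
        "yaw_series": run.telemetry["yaw"].to_numpy()[vel_ok[:len(run.telemetry)]],
        "sp_speed_series": np.abs(vel["vel_h"].to_numpy()[vel_ok]),
        "n_sp_samples": int(vel_ok.sum()),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full cohort pipeline; returns the report dict.

    When ``config.outdir`` is set, writes per-subject CSVs and the JSON
    report there. Identical config + seed produces an identical report.
    """
    cfg = config
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        if not outdir.parent.exists():
            raise FileNotFoundError(f"output parent directory missing: {outdir.parent}")
        outdir.mkdir(exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.synth.n_subjects + 1)
    rng = np.random.default_rng(children[0])

    subjects = []
    reference: ReferenceTrajectory | None = None
    for i in range(cfg.synth.n_subjects):
        yaw_i = max(float(rng.normal(cfg.yaw_mean, cfg.yaw_sd)), 1.0)
        sub_seed = int(children[i + 1].generate_state(1)[0] % (2**31 - 1))
        run = _simulate_subject(cfg, i, yaw_i, sub_seed)
        log.info("subject %d: yaw %.2f deg/s, %d samples, seed %d",
                 i, run.yaw_mean, len(run.gaze), sub_seed)
        if reference is None:
            reference = ReferenceTrajectory.from_points(
                np.column_stack([run.telemetry["x"], run.telemetry["y"]]))
        route = map_to_reference(
            np.column_stack([run.telemetry["x"], run.telemetry["y"]]), reference)
        ana = analyze_subject(run, run.road, cfg)
        ana["route"] = route
        subjects.append((run, ana))
        if outdir is not None:
            okio.write_gaze_csv(run.gaze, outdir / f"subject{i:02d}_gaze.csv")
            okio.write_telemetry_csv(run.telemetry, outdir / f"subject{i:02d}_telemetry.csv")
            okio.write_ground_truth_csv(run.truth, len(run.gaze),
                                        outdir / f"subject{i:02d}_truth_segments.csv",
                                        outdir / f"subject{i:02d}_truth_outliers.csv")
            okio.write_segments_csv(ana["result"], run.gaze,
                                    outdir / f"subject{i:02d}_segments.csv",
                                    outdir / f"subject{i:02d}_outliers.csv")
            okio.write_phases_csv(ana["phases"], run.telemetry["t"].to_numpy(),
                                  outdir / f"subject{i:02d}_phases.csv")

    # cohort-level statistics
    vel_modes = np.array([a["vel_mode"].location for _, a in subjects])
    pos_modes = np.array([a["pos_mode"].location for _, a in subjects])
    yaw_means = np.array([a["yaw_mean_cornering"] for _, a in subjects])
    series = [(a["yaw_series"], a["sp_speed_series"]) for _, a in subjects]
    consistency = yaw_gaze_consistency(yaw_means, vel_modes[:, 0], series)

    sp_segments = [s for _, a in subjects for s in a["result"].segments
                   if s.label == "SP"]
    orient_counts, orient_edges, n_zero = sp_orientation_histogram(sp_segments)

    hotelling = hotelling_region(vel_modes) if len(vel_modes) >= 4 else None

    sign_p = None
    aoi_diffs = {}
    if all(a["aoi"]["entry"] is not None for _, a in subjects):
        for r in cfg.aoi_radii:
            diffs = np.array([
                a["aoi"]["entry"][r] - a["aoi"]["cornering"][r] for _, a in subjects
            ])
            aoi_diffs[int(r)] = {
                "mean_difference": float(diffs.mean()),
                "sign_test_p": entry_vs_cornering_sign_test(diffs)
                if np.any(diffs != 0) else None,
            }
        sign_p = aoi_diffs.get(cfg.sign_test_radius, {}).get("sign_test_p")

    report = {
        "config": cfg.resolved(),
        "n_subjects": len(subjects),
        "per_subject": [
            {
                "subject": run.subject,
                "yaw_mean_dps": a["yaw_mean_cornering"],
                "vel_mode_dps": list(a["vel_mode"].location),
                "pos_mode_deg": list(a["pos_mode"].location),
                "vel_bandwidth_dps": list(a["vel_bandwidth"]),
                "n_segments": len(a["result"].segments),
                "n_outliers": int(len(a["result"].outlier_idx)),
                "n_sp_samples": a["n_sp_samples"],
                "aoi_cornering_pct": a["aoi"]["cornering"],
                "aoi_entry_pct": a["aoi"]["entry"],
                "segmentation_score": a["result"].score,
            }
            for run, a in subjects
        ],
        "mean_modal_velocity_dps": [float(v) for v in vel_modes.mean(axis=0)],
        "mean_modal_position_deg": [float(v) for v in pos_modes.mean(axis=0)],
        "yaw_half_consistency": {
            "differences_dps": consistency.differences.tolist(),
            "mean_dps": consistency.mean,
            "ci95_dps": list(consistency.ci95),
            "shapiro_w": consistency.shapiro_w,
            "shapiro_p": consistency.shapiro_p,
            "per_subject_correlation": consistency.correlations.tolist(),
        },
        "sp_orientation_histogram": {
            "counts": orient_counts.tolist(),
            "bin_edges_deg": orient_edges.tolist(),
            "n_zero_velocity_excluded": n_zero,
        },
        "hotelling": None if hotelling is None else {
            "center_dps": hotelling.center.tolist(),
            "covariance": hotelling.covariance.tolist(),
            "n": hotelling.n,
            "critical_values": {str(lv): hotelling.critical_value(lv)
                                for lv in hotelling.levels},
            "origin_inside_95": bool(hotelling.contains(np.zeros(2), 0.95)),
        },
        "aoi_entry_minus_cornering": aoi_diffs or None,
        "sign_test_p": sign_p,
    }
    if outdir is not None:
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        log.info("report written to %s", outdir / "report.json")
    return report
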