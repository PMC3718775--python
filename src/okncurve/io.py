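"""CSV dialects for gaze, telemetry, ground truth, segments and phases.

All files are UTF-8 CSV with a header row and '.' decimal separator.
Units are encoded in the column names (s, deg, deg/s, m).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import Segment, SegmentationResult
from .synth import GroundTruth

GAZE_COLUMNS = ["t_s", "h_deg", "v_deg", "valid"]
TELEMETRY_COLUMNS = ["t_s", "speed_mps", "yaw_dps", "x_m", "y_m", "heading_deg"]


def write_gaze_csv(gaze: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "t_s": gaze["t"], "h_deg": gaze["h"], "v_deg": gaze["v"],
        "valid": gaze["valid"].astype(int),
    })
    out.to_csv(path, index=False)


def read_gaze_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV {path} missing columns: {sorted(missing)}")
    return pd.DataFrame({"t": df["t_s"], "h": df["h_deg"], "v": df["v_deg"],
                         "valid": df["valid"].astype(int)})


def write_telemetry_csv(telemetry: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "t_s": telemetry["t"], "speed_mps": telemetry["speed"],
        "yaw_dps": telemetry["yaw"], "x_m": telemetry["x"],
        "y_m": telemetry["y"], "heading_deg": telemetry["heading"],
    })
    out.to_csv(path, index=False)


def read_telemetry_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TELEMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"telemetry CSV {path} missing columns: {sorted(missing)}")
    return pd.DataFrame({"t": df["t_s"], "speed": df["speed_mps"],
                         "yaw": df["yaw_dps"], "x": df["x_m"], "y": df["y_m"],
                         "heading": df["heading_deg"]})


def write_ground_truth_csv(truth: GroundTruth, n_samples: int,
                           seg_path: str | Path, outlier_path: str | Path) -> None:
    spans = truth.spans(n_samples)
    pd.DataFrame({
        "segment_start_idx": [s for s, _ in spans],
        "segment_end_idx": [e for _, e in spans],
        "slope_h_dps": truth.slopes_h,
        "slope_v_dps": truth.slopes_v,
    }).to_csv(seg_path, index=False)
    pd.DataFrame({"idx": truth.outlier_idx}).to_csv(outlier_path, index=False)


def write_segments_csv(result: SegmentationResult, samples: pd.DataFrame,
                       seg_path: str | Path, outlier_path: str | Path) -> None:
    t = samples["t"].to_numpy()
    pd.DataFrame({
        "start_idx": [s.start_idx for s in result.segments],
        "end_idx": [s.end_idx for s in result.segments],
        "t_start_s": [t[s.start_idx] for s in result.segments],
        "t_end_s": [t[s.end_idx - 1] for s in result.segments],
        "slope_h_dps": [s.slope_h for s in result.segments],
        "slope_v_dps": [s.slope_v for s in result.segments],
        "intercept_h_deg": [s.intercept_h for s in result.segments],
        "intercept_v_deg": [s.intercept_v for s in result.segments],
        "label": [s.label or "" for s in result.segments],
    }).to_csv(seg_path, index=False)
    pd.DataFrame({"idx": result.outlier_idx}).to_csv(outlier_path, index=False)


def read_segments_csv(seg_path: str | Path, outlier_path: str | Path
                      ) -> SegmentationResult:
    df = pd.read_csv(seg_path)
    segs = [
        Segment(int(r.start_idx), int(r.end_idx), float(r.slope_h_dps),
                float(r.slope_v_dps), float(r.intercept_h_deg),
                float(r.intercept_v_deg), float(r.t_start_s),
                label=(str(r.label) if isinstance(r.label, str) and r.label else None))
        for r in df.itertuples()
    ]
    out = pd.read_csv(outlier_path)["idx"].to_numpy(dtype=int) \
        if Path(outlier_path).exists() else np.array([], dtype=int)
    return SegmentationResult(segs, out, float("nan"))


def write_phases_csv(bounds, t: np.ndarray, path: str | Path) -> None:
    rows = []
    for name, (d0, d1), (i0, i1) in (
        ("entry", bounds.entry, bounds.entry_idx),
        ("cornering", bounds.cornering, bounds.cornering_idx),
        ("exit", bounds.exit, bounds.exit_idx),
    ):
        t0 = t[i0] if i1 > i0 else np.nan
        t1 = t[i1 - 1] if i1 > i0 else np.nan
        rows.append({"phase": name, "dist_start_m": d0, "dist_end_m": d1,
                     "t_start_s": t0, "t_end_s": t1})
    pd.DataFrame(rows).to_csv(path, index=False)
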