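import numpy as np
import pandas as pd
import pytest

from okncurve.geometry import RoadModel, generate_cornering_telemetry


@pytest.fixture(scope="session")
def road():
    """Bend matching steady cornering at ~42.7 km/h and ~13.8 deg/s."""
    return RoadModel(path_radius=49.2, inner_edge_radius=47.2)


@pytest.fixture(scope="session")
def telemetry(road):
    """16 s of steady cornering at 11.86 m/s (the study's mean speed)."""
    return generate_cornering_telemetry(road, speed=11.86, duration=16.0)


@pytest.fixture(scope="session")
def long_telemetry(road):
    return generate_cornering_telemetry(road, speed=11.86, duration=60.0)


def gaze_frame(t, h, v, valid=None):
    n = len(t)
    return pd.DataFrame({
        "t": np.asarray(t, dtype=float),
        "h": np.asarray(h, dtype=float),
        "v": np.asarray(v, dtype=float),
        "valid": np.ones(n, dtype=int) if valid is None else np.asarray(valid),
    })
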