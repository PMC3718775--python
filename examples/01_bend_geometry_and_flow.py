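"""Geometry of a constant-radius bend: tangent-point eccentricity and
the optic-flow structure that separates steering models.

Builds the study bend (path radius 49.2 m, inner edge 47.2 m), drives it
at 42.7 km/h, and prints the three geometric facts the analysis rests
on: the yaw-rate identity omega = V/R, the stable tangent-point
eccentricity, and the flow field — vertical at the tangent point,
receding at exactly -omega/2 for any fixed point on the future path.
"""

import numpy as np

from okncurve import (
    RoadModel,
    generate_cornering_telemetry,
    optic_flow_at_point,
    tangent_point_track,
)
from okncurve.geometry import future_path_point, tangent_point_world

road = RoadModel(path_radius=49.2, inner_edge_radius=47.2)
speed = 42.7 / 3.6  # m/s
tel = generate_cornering_telemetry(road, speed, duration=16.0)

print(f"speed {speed * 3.6:.1f} km/h on R = {road.path_radius} m"
      f" -> yaw rate {tel['yaw'].iloc[0]:.2f} deg/s (omega = V/R)")

tp = tangent_point_track(tel, road)
print(f"tangent point eccentricity: {tp['h'].iloc[0]:.2f} deg from heading, "
      f"SD over the bend {tp['h'].std():.2e} deg (stationary, inside the "
      f"15-20 deg band drivers show in steady cornering)")

state = tel.iloc[300]
tx, ty = tangent_point_world(state["x"], state["y"], road, state["heading"])
dh, dv = optic_flow_at_point((float(tx), float(ty)), state, road)
print(f"optic flow AT the tangent point: ({dh:+.4f}, {dv:+.2f}) deg/s "
      "(vertical, downward: the TP sits on the flow-inversion circle)")

for arc in (20.0, 35.0, 50.0):
    q = future_path_point(tel, 300, arc, road)
    dh, dv = optic_flow_at_point(q, state, road)
    print(f"flow at future-path point {arc:4.0f} deg of arc ahead: "
          f"({dh:+.3f}, {dv:+.3f}) deg/s  (horizontal = -omega/2 = "
          f"{-state['yaw'] / 2:.3f}, independent of arc)")

print("\nTracking any future-path point therefore rotates gaze at half the")
print("yaw rate opposite the curve; fixating the tangent point predicts no")
print("horizontal gaze rotation. That asymmetry is what the pipeline measures.")
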