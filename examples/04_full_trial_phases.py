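"""A full curve trial: entry / cornering / exit phases and AOI catch.

Simulates a 4-subject cohort on complete trials (straight approach, yaw
ramp-in, steady cornering, ramp-out), detects curve phases from the yaw
profile, and compares tangent-point AOI catch between entry and
cornering — the classic area-of-interest view of "tangent point
orientation", with its exact binomial sign test.
"""

from okncurve import RunConfig, SyntheticConfig, run_pipeline

cfg = RunConfig(seed=0, duration=16.0, full_trial=True,
                synth=SyntheticConfig(n_subjects=4))
rep = run_pipeline(cfg)

sub = rep["per_subject"][0]
print(f"subject 0: yaw plateau {sub['yaw_mean_dps']:.1f} deg/s, "
      f"{sub['n_segments']} gaze segments")
print("\nAOI catch % (radius -> entry / cornering), subject 0:")
for r in (2, 4, 6, 8, 10):
    e = sub["aoi_entry_pct"][r]
    c = sub["aoi_cornering_pct"][r]
    print(f"  {r:2d} deg: {e:5.1f} / {c:5.1f}")

print("\ncohort entry-minus-cornering catch difference by radius:")
for r, d in rep["aoi_entry_minus_cornering"].items():
    p = d["sign_test_p"]
    print(f"  {int(r):2d} deg: {d['mean_difference']:+6.1f} points "
          f"(sign test p = {p if p is None else round(p, 3)})")

print("\nEven with gaze locked to far-zone future-path targets, mid-sized AOIs")
print("centred on the tangent point catch most samples in both phases — the")
print("AOI-overlap ambiguity that makes position-only measures a weak test of")
print("the gaze target. (With 4 subjects the exact sign test is, rightly,")
print("far from significant.)")
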