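"""Both event detectors on clean trajectories, plus sequence validation.

Uses the fast no-render path: analytic heel/toe trajectories go straight
into the marker-style and marker-less detectors, and the merged candidates
are validated against the normal gait-cycle order.
"""

from stridehall import (GaitProfile, detect_events_marker,
                        detect_events_markerless, generate_gait_trajectory,
                        validate_sequence)

gt = generate_gait_trajectory(GaitProfile(), duration=4.5, fps=60.0, seed=0)

for name, detect in (("marker-style", detect_events_marker),
                     ("marker-less", detect_events_markerless)):
    per_side = {}
    for side in ("left", "right"):
        per_side[side] = detect(gt.trajectories[(side, "heel")],
                                gt.trajectories[(side, "toe")], side)
    validated = validate_sequence(per_side["left"], per_side["right"])
    print(f"{name}: {len(validated)} validated events")
    for e in validated:
        truth = min((g.time for g in gt.events if g.code == e.code),
                    key=lambda t: abs(t - e.time))
        print(f"  {e.code}  t={e.time:5.3f}  (truth {truth:5.3f}, "
              f"error {1000 * (e.time - truth):+5.1f} ms)")

# On noiseless trajectories both detectors land within one frame of the
# analytic stance/swing transitions; the validator orders them into the
# LFO -> LFS -> RFO -> RFS cycle.
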