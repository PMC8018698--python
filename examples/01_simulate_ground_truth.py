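"""Generate a synthetic walking trial and inspect its ground truth.

Builds the analytic gait model (no rendering) and prints the exact event
times and per-cycle stride parameters the rest of the pipeline will be
scored against.
"""

from stridehall import GaitProfile, generate_gait_trajectory

profile = GaitProfile()  # 1.3 m stride, 0.55 s steps, 100 mm step width
gt = generate_gait_trajectory(profile, duration=4.5, fps=60.0, seed=0)

print("events (code, time s):")
for e in gt.events:
    print(f"  {e.code}  t={e.time:5.2f}  heel/toe y={e.position[1]:7.1f} mm")

print("\nanalytic per-cycle parameters:")
print(gt.parameters.table.round(3).to_string(index=False))

# Times follow from the profile: stride time = 2 x step time = 1.10 s,
# stance = 62% of that; lengths echo the profile (1300 mm stride).
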