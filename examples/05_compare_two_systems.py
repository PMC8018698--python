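"""Agreement statistics between two measurement systems.

Emulates comparing an optical reference against the depth-based system:
paired stride-length samples with noise and a few gross event-detection
failures, screened at two sigma before the error statistics.
"""

import numpy as np

from stridehall import compare_systems

rng = np.random.default_rng(0)
truth = rng.normal(1300.0, 60.0, 60)          # per-cycle stride lengths, mm
reference = truth + rng.normal(0, 3.0, 60)    # optical system: ~3 mm noise
test = truth + rng.normal(0, 12.0, 60)        # depth system: ~12 mm noise
test[[7, 23]] += 400.0                        # two mis-detected events

stats = compare_systems(reference, test)
print(f"n inliers      : {stats.n_inliers}  ({stats.inlier_pct:.1f}%)")
print(f"mean error     : {stats.e_mu:7.2f} mm (sigma {stats.e_sigma:.2f})")
print(f"abs mean error : {stats.e_mu_abs:7.2f} mm (sigma {stats.e_sigma_abs:.2f})")
print(f"error range    : [{stats.e_min:.2f}, {stats.e_max:.2f}] mm")
print(f"Pearson r      : {stats.pearson_r:.3f}")

# The two planted 400 mm failures fall outside two sigma of the error
# distribution and are excluded, so the statistics describe the system's
# tracking accuracy rather than its worst event-detection mistakes.
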