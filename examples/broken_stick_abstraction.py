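"""Summarise a high-resolution dive profile the way the tag firmware does.

The broken-stick algorithm keeps the 4 samples that, added greedily,
most reduce the vertical deviation between the profile and its
piecewise-linear reconstruction.
"""

import numpy as np

from driftforage import broken_stick, reconstruct, simulate_dive

rng = np.random.default_rng(3)
profile = simulate_dive({"seafloor": 2500.0, "dr_true": -0.2,
                         "drift_segment": (350.0, 420.0, -0.2)}, rng)

res = broken_stick(profile.times, profile.depths)
print(f"profile: {profile.depths.size} samples at "
      f"{profile.sampling_interval:.0f} s, max depth {profile.depths.max():.0f} m")
print("selected inflection points (t s, depth m):")
for t, d in zip(res.times[1:-1], res.depths[1:-1]):
    print(f"  {t:7.0f}  {d:7.1f}")
recon = reconstruct(res, profile.times)
print(f"max reconstruction error: {res.max_error:.3f} m "
      f"(brute-force check {np.abs(recon - profile.depths).max():.3f} m)")
print("-> 6 points stand in for the whole dive; for piecewise-linear dives")
print("   the summary is lossless, which is what the tag exploits.")
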