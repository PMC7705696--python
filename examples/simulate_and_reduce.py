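"""Simulate a three-distance measurement and reduce it to 1D.

Generates Poisson-noisy 128x128 detector frames at 1.5 m, 8 m and 39 m
(wavelength 6 A) from a known ground truth, separates the equatorial
anisotropic signal from the isotropic background in each frame, merges
the three configurations and writes the result as a 3-column text file.
"""

import numpy as np

from fibrilsans import (
    SyntheticSpec,
    WoodModelParams,
    generate_frames,
    reduce_frames,
    write_profile,
)

truth = WoodModelParams(a_cc=43.0, sigma_b=2.0 * np.sqrt(2.0) / 185.0)
spec = SyntheticSpec(truth=truth, seed=42)

frames, record = generate_frames(spec)
for f in frames:
    print(
        f"frame sdd={f.geometry.sdd / 1000:.1f} m: "
        f"{f.counts.sum():.3g} counts total"
    )

profile = reduce_frames(frames)
print(f"\nmerged equatorial profile: {len(profile)} points, "
      f"q = {profile.q[0]:.4f}-{profile.q[-1]:.4f} A^-1")
print("inter-configuration scale factors:",
      [f"{c:.3f}" for c in profile.meta["scale_factors"]])

write_profile(profile, "equatorial.dat")
print("written to equatorial.dat (q I sigma with # metadata header)")
print(
    "\nThe profile is the equator-band mean minus the isotropic level, "
    "so it isolates the\noriented lateral structure: fibril packing "
    "peak, bundle Gaussian, pore power law."
)
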