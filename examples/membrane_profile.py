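"""Leaflet height profile and curvature over a bumped 45 x 15 nm bilayer.

The generator prescribes a 1 nm Gaussian bump on a 45 nm bilayer; the
height profile (mean phosphate z per 1 nm bin along x, sampled every
200 ps) recovers it, and the derived curvature estimate is positive where
the leaflet bulges toward the protein side (+z).
"""

import numpy as np

from barmem.fields import aggregate_height_profiles, curvature_estimate, height_profile
from barmem.lipids import classify_lipids
from barmem.synthetic import HeightFieldSpec, SyntheticSpec, script_trajectory

spec = SyntheticSpec(
    seed=2,
    system="dimer_45x15x15",
    n_frames=50,
    n_replicates=3,
    include_protein=False,
    noise_sigma=0.05,
    height_field=HeightFieldSpec("gaussian_bump", amplitude=1.0, sigma=3.0, x0=22.5),
)
records = script_trajectory(spec)
inventory = classify_lipids(records[0].trajectory.topology)

profiles = [height_profile(r.trajectory, inventory, leaflet="upper") for r in records]
agg = aggregate_height_profiles(profiles)
kappa = curvature_estimate(agg)

print("bin_x_nm  mean_z_nm  sd_nm   curvature_1/nm")
for x, z, s, k in zip(agg.bin_centers[::4], agg.mean_z[::4], agg.sd[::4], kappa[::4]):
    print(f"{x:7.1f}  {z:9.3f}  {s:6.4f}  {k:+.4f}")

center = int(np.argmin(np.abs(agg.bin_centers - 22.5)))
print()
print(f"bump amplitude recovered: {agg.mean_z[center] - np.nanmean(agg.mean_z[1:4]):.3f} nm "
      "(prescribed 1.000 nm)")
print("positive curvature at the bump centre = leaflet bulging toward the protein side.")
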