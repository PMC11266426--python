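"""Protein-centred 2D lipid density map of a monomer system.

Maps the time-averaged PI(4,5)P2 number density around a membrane-bound
monomer in the protein-aligned frame (the protein diffuses and rotates;
averaging in the lab frame would smear any lipid enrichment pattern).
"""

import numpy as np

from barmem.fields import density_map_2d
from barmem.lipids import classify_lipids
from barmem.synthetic import SyntheticSpec, script_trajectory

spec = SyntheticSpec(seed=3, system="monomer_18nm", n_frames=40, n_replicates=1)
rec = script_trajectory(spec)[0]
inventory = classify_lipids(rec.trajectory.topology)

dm = density_map_2d(
    rec.trajectory, "PIP2", inventory, window_ps=1e9, bin_nm=1.0, alignment="protein_aligned"
)
print(f"grid: {dm.grid.shape[0]} x {dm.grid.shape[1]} bins of 1 nm^2, "
      f"{dm.n_frames_averaged} frames averaged")
print(f"mean density: {dm.grid.mean():.4f} lipids/nm^2, peak: {dm.grid.max():.4f}")
print(f"integral: {dm.integral():.1f} lipids "
      f"(= the {len(inventory.lipids_of_class('PIP2'))} PI(4,5)P2 lipids of the system)")
print()
print("The integral equals the per-frame lipid count of the class - number")
print("density is conserved by construction; enrichment shows up as peaks")
print("near the protein footprint at the grid centre in real trajectories.")
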