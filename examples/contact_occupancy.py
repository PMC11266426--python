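"""Residue-lipid contact occupancy on a scripted trajectory.

A monomer is held above an 18 nm MIM-like bilayer and residue 107 (one of
the basic membrane-binding cluster residues) is scripted to touch a
PI(4,5)P2 lipid for a known window. Occupancy is the longest continuous
contact run normalized by the time elapsed after the first
protein-phospholipid contact, so the printed value is exactly the
window-length fraction.
"""

from barmem.contacts import ContactParams, aggregate_occupancy, contact_series, occupancy_profile
from barmem.lipids import classify_lipids
from barmem.synthetic import ContactWindow, SyntheticSpec, script_trajectory

spec = SyntheticSpec(
    seed=1,
    system="monomer_18nm",
    n_frames=50,
    n_replicates=3,
    contact_schedule=[ContactWindow("A", 107, t_on=2000.0, t_off=6000.0, lipid_class="PIP2")],
)
records = script_trajectory(spec)

profiles = []
for rec in records:
    inventory = classify_lipids(rec.trajectory.topology)
    series = contact_series(rec.trajectory, ContactParams(cutoff=0.4), "PIP2", inventory)
    profiles.append(occupancy_profile(series))

agg = aggregate_occupancy(profiles)
for (chain, resseq), mean, sd in zip(agg.residue_keys, agg.mean, agg.sd):
    if mean > 0:
        print(f"residue {chain}/{resseq}: occupancy = {mean:.3f} +/- {sd:.3f} (n=3 replicates)")
print()
print("Contact frames 10..30 of 50, first contact at frame 10:")
print("  occupancy = 21 / (50 - 10) = 0.525; 1.0 would mean bound from")
print("  first contact to the end, 0.0 never bound.")
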