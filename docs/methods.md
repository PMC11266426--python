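# Methods

This note documents the models, conventions and numerical choices behind
`barmem`, and what the synthetic generators do and do not emulate.

## Units, coordinates, formats

Internal units are nm and ps everywhere; areas are reported in Å²
because crystallographic interface areas are conventionally printed in
Å². The coordinate system is right-handed with z as the membrane normal;
"upper" is the leaflet the protein binds. Boxes are orthorhombic only: a
GRO box line with non-zero off-diagonal components is refused, since all
the analyses here (minimum-image distances, xy binning, x profiles) are
defined on rectangular boxes and a silently skewed box is worse than a
refusal. A PDB `CRYST1` record with non-90° angles is *ignored with a
warning* rather than refused — a triclinic crystal cell is metadata of
the diffraction experiment, not a simulation box, and refusing it would
make most deposited structures unreadable.

PDB reading keeps the highest-occupancy alternate location (first on a
tie), reads the first model only and rejects insertion codes. The GRO
writer defaults to 4 decimals (field width 9) so that PDB-derived
coordinates (1e-4 nm precision) survive a GRO round trip exactly;
`decimals=3` restores the classic 8.3 layout. Chain ids, which GRO does
not carry, are encoded in the title line and restored on re-read.

The frame table is a deliberately plain CSV trajectory format
(`frame,time_ps,box_*,x0,y0,z0,…`), one row per frame, so that
trajectories are diff-able text; binary backends (XTC/DCD) can be
adapted via `trajectory_from_arrays`, which enforces the same contract
(strictly increasing, uniform frame times; dt uniform to 1e-6 relative).

## Lipid classes and markers

Lipids map to POPC, POPE, POPS, PI(4,5)P₂ (PIP2), cardiolipin (CDL) or
OTHER by residue name (common force-field aliases included; unmapped
names go to OTHER with a warning). Each lipid is reduced to one marker —
the phosphate phosphorus — except cardiolipin, whose marker is the
midpoint of its two phosphorus atoms. All field analyses use markers;
contact analyses use all heavy atoms of the lipid.

## Contacts and occupancy

Contact: minimum heavy-atom distance ≤ cutoff (default 0.4 nm) between
a residue and any lipid of the class, per frame, under the minimum-image
convention. The criterion is a *within*-cutoff test: an interaction
criterion phrased as a separation bound is read in its standard meaning,
distance at or below the threshold. Neighbour search uses a toroidal
k-d tree (`scipy.spatial.cKDTree` with `boxsize`), which is exact on
orthorhombic boxes; the test suite holds it against an O(N·M)
minimum-image scan.

Occupancy of residue r with a lipid class is

    occ(r) = k_max · dt / (T_total − t_first),

where `k_max` is the longest run of consecutive contact frames,
`T_total = n_frames · dt`, and `t_first` is the time of the first
contact between *any* residue and *any* phospholipid class (not just
the queried one). A run of k frames counts as k·dt — each frame
represents one sampling interval; the (k−1)·dt convention is available
via `run_convention="k-1"`. Values are clipped to [0, 1]; a residue in
contact from `t_first` to the end scores exactly 1. Occupancy is
invariant under uniform time rescaling. Replicate aggregation is the
element-wise mean ± sample SD (ddof = 1; undefined, reported NaN, for a
single replicate). Occupancy is emitted per lipid class; pooled-class
profiles can be obtained by querying each class and combining, since
the normalisation is shared through `t_first`.

## Leaflets, density maps, height profiles, curvature

Leaflet assignment defaults to the sign of (marker z − mean marker z)
per frame; a local-midplane variant (cell-wise mean over ~3 nm xy cells)
is available for strongly deformed bilayers where a tall bump crosses
the global mean — on the generator's ground truth the local method stays
exact where the global method starts misassigning.

Density maps histogram the class markers in the xy plane (default
0.2 nm bins), average counts per bin over the trailing time window
(default 100 ns) and divide by bin area. For monomer systems the default
frame is `protein_aligned`: each frame is recentred on the protein
heavy-atom centroid and rotated in-plane so the protein's first
principal xy axis lies along x — a freely diffusing, rotating protein
would otherwise smear all structure out of a lab-frame average. The
in-plane axis sign is fixed by requiring non-negative third moment
(skewness) of the projections, which makes the map deterministic and
invariant under global rotations of the input. The map integral equals
the mean per-frame lipid count of the class in the mapped region to
within edge effects (≤1%; exact for the unrotated full-box region).

Height profiles bin the selected leaflet's markers along x (default
1 nm bins), sampling every 200 ps — the sampling stride must be an
integer multiple of the frame spacing, anything else is an error rather
than a silent resample. Bins with no samples are flagged missing and
never interpolated. Replicates aggregate as mean ± SD (ddof=1) of the
single-replicate bin means. Binning the whole bilayer instead of one
leaflet (`selection="all"`) is supported; leaflet-restricted is the
default since the bound/unbound leaflets are the objects of interest.

Curvature is an explicitly *derived* estimate computed from the binned
means by central differences over the longest contiguous run of ≥5
usable bins: κ(x) = −z″/(1+z′²)^{3/2}. The sign convention is that κ>0
where the leaflet bulges toward +z, the protein side. A sampled circular
arc of radius R reproduces 1/R to well under 1% at 1 nm bins. The height
profile, not κ, is the primary output: the curvature profile of a
simulation is reported as binned phosphate positions, with κ as an
annotated derivative.

## Dimer geometry

Helix axes are the dominant principal direction (SVD) of the Cα cloud of
a residue range, oriented from low to high residue number; ≥10 Cα are
required, and gaps (disordered residues) are simply absent. The
inter-helix angle defaults to the acute convention arccos|a·b| — the
convention under which a classical BAR dimer's α2/α2' angle is ≈33° —
with a directed variant via flag. Default helix boundaries for the
FAM92A1 BAR domain: α1 2–61, α2 64–136 (kink annotated at Pro98), α3
142–211; helix ranges are inputs, not recomputed secondary structure.

Dimer extent: length is the spread of Cα projections on the first
principal axis; the bundle diameter is defined here as twice the RMS
radial Cα distance from that axis within the central 20% of the length
(the six-helix core). The diameter definition is this package's own;
published "ca." diameters are qualitative.

SASA uses Shrake–Rupley with a deterministic Fibonacci-spiral point set
(default 960 points) and a pinned Bondi-type radii table packaged as
`data/vdw_radii.json`; hydrogens are excluded from surface and
occlusion. Determinism matters because interface areas are SASA
differences: with a fixed point set, per-atom ΔSASA on complexation is
exactly non-negative. An isolated sphere is exact by construction; two
overlapping spheres match the closed-form spherical-cap solution to
≤0.5% at 960 points, and the quadrature error decreases with more
points.

Buried interface area follows the PISA convention,
(SASA(A)+SASA(B)−SASA(AB))/2; because published interface areas are
sometimes the summed unhalved quantity, the report carries both numbers
(`buried_area` and `total_buried_both_chains`) plus per-chain values.
Interface residues are those losing any area; the hydrophobic census
counts residues from a documented aliphatic/aromatic set with buried
fraction above a threshold (default 0.70). Hydrogen bonds across the
interface use a heavy-atom donor–acceptor distance criterion only
(default 3.5 Å, table in `data/hbond_donor_acceptor.json`): a ~2 Å
crystal structure has no hydrogens, so no angle term is applied, and
His/hydroxyl oxygens are typed as both donor and acceptor. Distance-only
counts are therefore upper-bound-ish relative to angle-filtered counts
and are treated as soft references.

## Concave angle

The crescent's opening is the angle at the centroid of a central
residue group subtended by two arm-tip group centroids, all from Cα
atoms. The defaults — tips = residues 132–136 of each chain (the distal
membrane-binding cluster), centre = residues 2–10 of both chains (the
six-helix bundle) — are a documented stand-in: the exact triplet used in
published figures of this kind is usually given pictorially, so the
groups are fully configurable and recorded in outputs. No smoothing by
default; an optional centred moving average records its window.

## Synthetic systems

The generators emulate the study conditions: an ≈18 nm cubic box with a
monomer placed 3.4 nm above the bilayer (binding-search systems), and a
45 × 15 × 15 nm box with the dimer 0.2 nm above (curvature systems);
frame spacing 200 ps; three replicates; bilayer composition
POPC:POPE:POPS:PIP2:CDL = 40:32:3:5:18 (the liposome recipe with its 2%
fluorescent tracer dropped and renormalised — the stand-in for the full
MIM composition table), area per lipid 0.65 nm² (literature-typical),
phosphate-to-phosphate thickness 3.8 nm.

Lipids are 3-point pseudo-molecules (marker P plus dressing atoms; CDL
has two P atoms 0.2 nm apart), placed on a jittered grid with
largest-remainder class counts and per-lipid z noise redrawn each frame
(default σ = 0.02 nm). The protein is a Cα rod dimer (two chains, arms
crossing at the requested inter-arm angle, tips toward the membrane)
whose residue numbers subsample the 2–211 range so the package's default
selections (tips 132–136, centre 2–10, cluster residue 107) resolve; 30
residues per arm gives 0.27 nm spacing, which is what makes scripted
single-residue contacts realizable (below). One topology is shared by
all replicates, as for MD replicates of one system; only the noise
streams differ, seeded as `default_rng([seed, replicate])` (PCG64), so
outputs are bit-identical for identical seeds.

Scripted contacts place a designated lipid of the scheduled class with
its nearest atom 0.32 nm from the scheduled residue's Cα during the
window, stacked along the local perpendicular to the arm axis. The
perpendicular direction keeps the distance to neighbouring residues at
√(0.27² + 0.32²) ≈ 0.42 nm > 0.4 nm for any arm tilt, and the protein is
lifted to ≥1 nm above the bilayer whenever a schedule is present, so the
realized contact matrix equals the schedule exactly. Angle ramps solve,
in closed form, for the arm half-opening δ at which the angle measured
at the configured group centroids equals the scheduled value
(tan²(φ/2)·(m_t−m_c)²·sin²δ = m_t²·cos²δ + Δy², with m_t, m_c the mean
along-arm distances of the tip and centre groups and Δy the inter-chain
offset), so zero-noise scheduled endpoints are reproduced exactly.

What the generator does **not** emulate: atomistic lipid geometry and
chemistry, lateral diffusion, protein internal dynamics beyond the
rigid ramp, solvent and ions, or any force-field physics. Passing tests
therefore demonstrate that the *analyses* are correct against known
ground truth — not that any biological conclusion about a real membrane
follows; real trajectories enter through the same I/O contracts.

A truncation detail: lipid grid sites are filled row-major and truncated
to the target count, which can leave the last ~1 x-bin of a profile
sparsely populated; such bins are flagged missing rather than padded.

## Problem sizes

Tests and the acceptance script run the generators at 5–100 frames and
~1000–2100 lipids per system — sizes chosen so the whole suite exercises
every stage, including three-replicate aggregation, in seconds on one
CPU, while leaving the statistical checks (95%-CI bump recovery at 100
frames, SD scaling) well-powered.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Hydrogen-bond detection is distance-only (no hydrogens, no angles).
* Secondary structure is not assigned; helix ranges are inputs.
* The 2D curvature tensor / Helfrich-type fits, lipid tilt and order
  parameters, and per-lipid residence-time distributions are out of
  scope.
* The crystal-lattice oligomerisation interface of BAR lattices is not
  enumerated; only the two-chain dimer interface is analysed.
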