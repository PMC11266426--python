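"""Seeded synthetic structures and trajectories with exact ground truth.

These generators stand in for microsecond all-atom simulations at desk
scale: a banana-shaped two-arm Cα dimer (or single-arm monomer) above a
point-lipid bilayer with the model mitochondrial-inner-membrane
composition, scripted residue–lipid contact schedules, prescribed leaflet
height fields, a prescribed concave-angle ramp, and three replicates with
independent seeded noise streams.

Lipids are 3-point pseudo-molecules (phosphorus marker plus dressing
atoms; cardiolipin carries two P atoms), not atomistic lipids: every
analysis in this package needs only head-group markers and heavy-atom
distances. Ground truth accompanies every generated object so tests
consume only (generated data, ground truth).

Determinism: all randomness flows from ``numpy.random.default_rng``
(PCG64) seeded with ``(seed, replicate_index)``; the same spec and seed
reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conformation import AngleGroups
from .core import Structure
from .io import trajectory_from_arrays

__all__ = [
    "HeightFieldSpec",
    "ContactWindow",
    "SyntheticSpec",
    "ReplicateRecord",
    "build_dimer",
    "build_monomer",
    "build_bilayer",
    "script_trajectory",
    "DEFAULT_COMPOSITION",
]

#: POPC : POPE : POPS : PI(4,5)P2 : cardiolipin = 40 : 32 : 3 : 5 : 18,
#: the liposome recipe with the 2% fluorescent tracer dropped, renormalised.
DEFAULT_COMPOSITION = {
    "POPC": 40 / 98,
    "POPE": 32 / 98,
    "POPS": 3 / 98,
    "PIP2": 5 / 98,
    "CDL": 18 / 98,
}

_SYSTEM_BOXES = {
    "monomer_18nm": np.array([18.0, 18.0, 18.0]),
    "dimer_45x15x15": np.array([45.0, 15.0, 15.0]),
}
_DEFAULT_OFFSETS = {"monomer_18nm": 3.4, "dimer_45x15x15": 0.2}

#: phosphate-to-phosphate bilayer thickness of the synthetic bilayer, nm
BILAYER_THICKNESS = 3.8

#: depth below the scheduled residue's Calpha at which the contact lipid's
#: nearest atom is placed (min distance 0.32 <= 0.35 nm => contact), and the
#: vertical stacking step for its remaining atoms
_CONTACT_DEPTH = 0.32
_CONTACT_STACK = 0.20


@dataclass
class HeightFieldSpec:
    """Prescribed leaflet height field h(x, y) in nm.

    kinds: ``flat``; ``gaussian_bump`` (amplitude, sigma, x0 along x);
    ``sinusoid`` (amplitude, wavelength along x).
    """

    kind: str = "flat"
    amplitude: float = 0.0
    sigma: float = 3.0
    x0: float = 0.0
    wavelength: float = 10.0

    def evaluate(self, x, y):
        x = np.asarray(x, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(x)
        if self.kind == "gaussian_bump":
            return self.amplitude * np.exp(-((x - self.x0) ** 2) / (2.0 * self.sigma**2))
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(2.0 * np.pi * x / self.wavelength)
        raise ValueError(f"unknown height field kind {self.kind!r}")


@dataclass
class ContactWindow:
    """Scripted contact: residue (chain, resseq) touches a lipid of
    ``lipid_class`` from ``t_on`` to ``t_off`` ps, inclusive at frame times."""

    chain: str
    resseq: int
    t_on: float
    t_off: float
    lipid_class: str


@dataclass
class SyntheticSpec:
    """Seeded recipe for synthetic systems (defaults mirror the study systems:
    an ≈18 nm cubic box with the protein 3.4 nm above the bilayer for monomer
    runs, a 45 × 15 × 15 nm box with the dimer 0.2 nm above for curvature
    runs, MIM-like composition, 200 ps frame spacing, three replicates)."""

    seed: int = 0
    system: str = "dimer_45x15x15"
    composition: Dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    area_per_lipid: float = 0.65          # nm², literature-typical
    height_field: HeightFieldSpec = dc_field(default_factory=HeightFieldSpec)
    noise_sigma: float = 0.02             # nm, per-lipid z roughness per frame
    protein_noise_sigma: float = 0.0      # nm, per-atom protein jitter per frame
    n_frames: int = 50
    dt_ps: float = 200.0
    protein_offset: Optional[float] = None
    n_replicates: int = 3
    contact_schedule: List[ContactWindow] = dc_field(default_factory=list)
    angle_ramp: Optional[Tuple[float, float]] = None
    include_protein: bool = True
    arm_angle_deg: float = 33.2
    total_length_nm: float = 15.0
    residues_per_arm: int = 30

    def __post_init__(self) -> None:
        if self.system not in _SYSTEM_BOXES:
            raise ValueError(f"unknown system {self.system!r}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition mole fractions sum to {total}, not 1")
        if self.n_frames < 1 or self.dt_ps <= 0:
            raise ValueError("need n_frames >= 1 and dt_ps > 0")
        t_end = (self.n_frames - 1) * self.dt_ps
        for w in self.contact_schedule:
            if not (0 <= w.t_on < w.t_off <= t_end):
                raise ValueError(
                    f"contact window [{w.t_on}, {w.t_off}] ps outside the simulated "
                    f"time span [0, {t_end}] ps"
                )

    @property
    def box(self) -> np.ndarray:
        return _SYSTEM_BOXES[self.system].copy()

    @property
    def offset(self) -> float:
        base = self.protein_offset if self.protein_offset is not None else _DEFAULT_OFFSETS[self.system]
        # a schedule needs headroom: unscheduled residues must stay > 0.6 nm
        # from every lipid, so the protein is lifted to at least 1.0 nm
        return max(base, 1.0) if self.contact_schedule else base


@dataclass
class ReplicateRecord:
    """One generated replicate plus its ground truth."""

    trajectory: Trajectory
    ground_truth: dict


# ---------------------------------------------------------------------------
# protein builders
# ---------------------------------------------------------------------------

def _resseq_numbers(residues_per_arm: int, first: int = 2, span: int = 209) -> np.ndarray:
    """Residue numbers subsampling the 2..211 range so the field's default
    selections (tips 132-136, vertex 2-10, cluster residue 107) resolve."""
    step = max(1, round(span / (residues_per_arm - 1)))
    return first + step * np.arange(residues_per_arm)


def _arm_fractions(residues_per_arm: int) -> np.ndarray:
    return np.arange(residues_per_arm) / (residues_per_arm - 1)


def _dimer_positions(
    arm_length: float, delta_rad: float, residues_per_arm: int, y_split: float = 0.15
) -> np.ndarray:
    """Cα + dressing positions for both chains, tips pointing toward -z.

    Layout per chain: u = (±cos δ, 0, -sin δ) from a shared origin; chains
    offset by ±y_split in y; dressing atoms CB/O sit along the upward arm
    normal so every heavy atom other than the Cα is farther from the
    membrane side. Returns (2 * residues_per_arm * 3, 3) in chain A then
    chain B order, three atoms (CA, CB, O) per residue.
    """
    c, s = math.cos(delta_rad), math.sin(delta_rad)
    t = _arm_fractions(residues_per_arm) * arm_length
    out = []
    for sign, y0 in ((1.0, y_split), (-1.0, -y_split)):
        u = np.array([sign * c, 0.0, -s])
        normal = np.array([sign * s, 0.0, c])  # upward, away from the bilayer
        ca = np.outer(t, u)
        ca[:, 1] += y0
        for i in range(residues_per_arm):
            out.append(ca[i])
            out.append(ca[i] + 0.10 * normal)
            out.append(ca[i] + 0.22 * normal)
    return np.array(out)


def _protein_structure(positions: np.ndarray, residues_per_arm: int, chains: Sequence[str]) -> Structure:
    resseq = _resseq_numbers(residues_per_arm)
    names, elements, resnames, seqs, chain_ids = [], [], [], [], []
    for cid in chains:
        for r in resseq:
            for name, element in (("CA", "C"), ("CB", "C"), ("O", "O")):
                names.append(name)
                elements.append(element)
                resnames.append("ALA")
                seqs.append(int(r))
                chain_ids.append(cid)
    return Structure(names, elements, resnames, seqs, chain_ids, positions)


def build_dimer(
    arm_length_nm: Optional[float] = None,
    arm_angle_deg: float = 33.2,
    residues_per_arm: int = 30,
    total_length_nm: Optional[float] = 15.0,
) -> Structure:
    """A banana-shaped two-arm Cα dimer with a prescribed inter-arm angle.

    ``arm_angle_deg`` is the acute angle between the two arm axes (the
    inter-α2-helix angle of the built structure). Either the arm length or
    the total end-to-end length along x may be prescribed; the default
    reproduces a 15 nm (150 Å) dimer at 33.2°. Chains are labelled A and B
    with residue numbers in the 2-211 range. Construction is deterministic.
    """
    if not 0.0 < arm_angle_deg < 180.0:
        raise ValueError("arm angle must be in (0, 180) degrees")
    if residues_per_arm < 10:
        raise ValueError("need at least 10 residues per arm")
    delta = math.radians(arm_angle_deg) / 2.0
    if arm_length_nm is None:
        if total_length_nm is None:
            raise ValueError("give arm_length_nm or total_length_nm")
        arm_length_nm = total_length_nm / (2.0 * math.cos(delta))
    positions = _dimer_positions(arm_length_nm, delta, residues_per_arm)
    return _protein_structure(positions, residues_per_arm, ("A", "B"))


def build_monomer(arm_length_nm: float = 7.5, residues_per_arm: int = 30) -> Structure:
    """A single straight arm (one chain, along +x), the monomer stand-in."""
    if residues_per_arm < 10:
        raise ValueError("need at least 10 residues per arm")
    t = _arm_fractions(residues_per_arm) * arm_length_nm
    out = []
    for ti in t:
        ca = np.array([ti, 0.0, 0.0])
        out.append(ca)
        out.append(ca + np.array([0.0, 0.0, 0.10]))
        out.append(ca + np.array([0.0, 0.0, 0.22]))
    return _protein_structure(np.array(out), residues_per_arm, ("A",))


# ---------------------------------------------------------------------------
# bilayer builder
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: Dict[str, float], n: int) -> Dict[str, int]:
    keys = list(fractions)
    exact = np.array([fractions[k] * n for k in keys])
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return dict(zip(keys, counts.tolist()))


def _lipid_atom_template(cls: str, leaflet_sign: float) -> List[Tuple[str, str, np.ndarray]]:
    """(name, element, offset) per atom; offsets relative to the marker point.
    ``leaflet_sign`` +1 for the upper leaflet (tails point down, -z)."""
    down = -leaflet_sign
    if cls == "CDL":
        return [
            ("P1", "P", np.array([-0.10, 0.0, 0.0])),
            ("P2", "P", np.array([0.10, 0.0, 0.0])),
            ("C1", "C", np.array([0.0, 0.0, 0.24 * down])),
        ]
    return [
        ("P", "P", np.array([0.0, 0.0, 0.0])),
        ("C1", "C", np.array([0.0, 0.0, 0.12 * down])),
        ("C2", "C", np.array([0.0, 0.0, 0.24 * down])),
    ]


def build_bilayer(spec: SyntheticSpec, rng: Optional[np.random.Generator] = None):
    """Point-lipid bilayer for ``spec`` → (Structure, ground_truth).

    Lipid count per leaflet is ``floor(box area / area_per_lipid)``; class
    counts follow largest-remainder rounding of the mole fractions. Marker
    z is midplane ± half-thickness + height_field(x, y) + one Gaussian
    noise draw of ``noise_sigma``. Ground truth records per-lipid leaflet
    labels, classes, noiseless base z and marker xy.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    box = spec.box
    n_per_leaflet = int(box[0] * box[1] / spec.area_per_lipid)
    if n_per_leaflet < 50:
        raise ValueError(f"box supports only {n_per_leaflet} lipids per leaflet (need >= 50)")
    counts = _largest_remainder_counts(spec.composition, n_per_leaflet)

    names, elements, resnames, seqs, chain_ids = [], [], [], [], []
    positions = []
    leaflet_labels, classes, base_z_list, marker_xy = [], [], [], []
    resseq = 0
    zmid = box[2] / 2.0
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        # deterministic jittered grid of marker sites
        nx = int(math.ceil(math.sqrt(n_per_leaflet * box[0] / box[1])))
        ny = int(math.ceil(n_per_leaflet / nx))
        gx, gy = box[0] / nx, box[1] / ny
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        sites = np.column_stack([(ix.ravel() + 0.5) * gx, (iy.ravel() + 0.5) * gy])
        sites = sites[:n_per_leaflet]
        sites = sites + rng.uniform(-0.1, 0.1, size=sites.shape)
        labels = np.concatenate([[k] * v for k, v in counts.items()])
        labels = labels[rng.permutation(n_per_leaflet)]
        base_z = zmid + sign * BILAYER_THICKNESS / 2.0 + spec.height_field.evaluate(
            sites[:, 0], sites[:, 1]
        )
        z = base_z + rng.normal(0.0, spec.noise_sigma, size=n_per_leaflet)
        for i in range(n_per_leaflet):
            resseq += 1
            cls = str(labels[i])
            marker = np.array([sites[i, 0], sites[i, 1], z[i]])
            for name, element, offset in _lipid_atom_template(cls, sign):
                names.append(name)
                elements.append(element)
                resnames.append(cls)
                seqs.append(resseq)
                chain_ids.append("M")
                positions.append(marker + offset)
            leaflet_labels.append(leaflet)
            classes.append(cls)
            base_z_list.append(base_z[i])
            marker_xy.append(sites[i])
    structure = Structure(
        names, elements, resnames, seqs, chain_ids, np.array(positions), box=box
    )
    atom_offsets = np.array(
        [
            [off for _, _, off in _lipid_atom_template(cls, 1.0 if lf == "upper" else -1.0)]
            for cls, lf in zip(classes, leaflet_labels)
        ]
    )  # (n_lipids, 3 atoms, 3), relative to the marker point
    ground_truth = {
        "leaflet": np.array(leaflet_labels, dtype=object),
        "lipid_class": np.array(classes, dtype=object),
        "base_z": np.array(base_z_list),
        "marker_xy": np.array(marker_xy),
        "atom_offsets": atom_offsets,
        "class_counts_per_leaflet": counts,
        "height_field": spec.height_field,
        "thickness": BILAYER_THICKNESS,
    }
    return structure, ground_truth


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

def _group_arm_distances(spec: SyntheticSpec, groups: AngleGroups, arm_length: float):
    """Mean along-arm distances (m_tip, m_center, y_split) of the angle groups."""
    resseq = _resseq_numbers(spec.residues_per_arm)
    t = _arm_fractions(spec.residues_per_arm) * arm_length

    def mean_dist(sel) -> float:
        vals = []
        for _, lo, hi in sel:
            vals.extend(t[(resseq >= lo) & (resseq <= hi)])
        if not vals:
            raise ValueError("angle group selects no synthetic residues")
        return float(np.mean(vals))

    return mean_dist(groups.arm_tip_a), mean_dist(groups.center)


def _delta_for_angle(phi_deg: float, m_tip: float, m_center: float, y_split: float) -> float:
    """Arm half-opening δ realizing a measured concave angle φ at the group
    centroids (closed form; see docs/methods.md)."""
    t2 = math.tan(math.radians(phi_deg) / 2.0) ** 2
    a = m_tip**2
    b = (m_tip - m_center) ** 2
    k = y_split**2
    num = b * t2 - k
    if num <= 0:
        raise ValueError(f"angle {phi_deg}° not realizable with these groups")
    c2 = num / (b * t2 + a)
    return math.acos(math.sqrt(min(1.0, c2)))


def script_trajectory(
    spec: SyntheticSpec, groups: Optional[AngleGroups] = None
) -> List[ReplicateRecord]:
    """Scripted replicate trajectories realizing the spec's ground truth.

    Frames realize the contact schedule exactly (the designated lipid's
    atoms are stacked vertically below the scheduled residue's Cα starting
    at 0.32 nm during its window, and sit in the bilayer otherwise), the
    angle ramp (rigid arm rotation solved so the angle measured at the
    configured group centroids equals the scheduled value), and per-lipid
    z noise redrawn each frame from the (seed, replicate) stream.
    """
    groups = groups or AngleGroups()
    y_split = 0.15
    delta0 = math.radians(spec.arm_angle_deg) / 2.0
    arm_length = spec.total_length_nm / (2.0 * math.cos(delta0))
    records: List[ReplicateRecord] = []
    times = np.arange(spec.n_frames) * spec.dt_ps

    if spec.angle_ramp is not None and spec.system != "dimer_45x15x15":
        raise ValueError("angle ramp needs the dimer system")

    # one shared topology for all replicates (as for MD replicates of one
    # system); only the per-frame noise streams differ between replicates
    bilayer, bl_truth = build_bilayer(spec, rng=np.random.default_rng([spec.seed]))

    for rep in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, rep])
        n_bl = bilayer.n_atoms

        # -- protein topology and per-frame ideal geometry ------------------
        if spec.include_protein:
            if spec.system == "monomer_18nm":
                protein = build_monomer(arm_length_nm=7.5, residues_per_arm=spec.residues_per_arm)
                phi_sched = None
            else:
                protein = build_dimer(
                    arm_angle_deg=spec.arm_angle_deg,
                    residues_per_arm=spec.residues_per_arm,
                    total_length_nm=spec.total_length_nm,
                )
                if spec.angle_ramp is not None:
                    a0, a1 = spec.angle_ramp
                    ramp = a0 + (a1 - a0) * (np.arange(spec.n_frames) / max(1, spec.n_frames - 1))
                    phi_sched = ramp
                else:
                    phi_sched = None
            m_tip = m_center = None
            if phi_sched is not None:
                m_tip, m_center = _group_arm_distances(spec, groups, arm_length)
            # placement: protein centred in xy, lowest atom offset above the
            # highest possible upper-leaflet marker
            top_z = float(
                bl_truth["base_z"][bl_truth["leaflet"] == "upper"].max() + 4.0 * spec.noise_sigma
            )
            box = spec.box
            center_xy = box[:2] / 2.0

            def protein_positions(frame_idx: int) -> np.ndarray:
                if phi_sched is not None:
                    delta = _delta_for_angle(float(phi_sched[frame_idx]), m_tip, m_center, y_split)
                    pos = _dimer_positions(arm_length, delta, spec.residues_per_arm, y_split)
                elif spec.system == "monomer_18nm":
                    pos = protein.positions.copy()
                else:
                    pos = _dimer_positions(arm_length, delta0, spec.residues_per_arm, y_split)
                pos = pos - np.array([pos[:, 0].mean(), pos[:, 1].mean(), 0.0])
                pos = pos + np.array([center_xy[0], center_xy[1], 0.0])
                pos[:, 2] += top_z + spec.offset - pos[:, 2].min()
                return pos

            topology_positions = np.vstack([protein_positions(0), bilayer.positions])
            topology = Structure(
                names=np.concatenate([protein.names, bilayer.names]),
                elements=np.concatenate([protein.elements, bilayer.elements]),
                residue_names=np.concatenate([protein.residue_names, bilayer.residue_names]),
                residue_seqs=np.concatenate([protein.residue_seqs, bilayer.residue_seqs]),
                chain_ids=np.concatenate([protein.chain_ids, bilayer.chain_ids]),
                positions=topology_positions,
                box=spec.box,
            )
            n_prot = protein.n_atoms
        else:
            topology = bilayer
            n_prot = 0
            phi_sched = None

        # -- designated contact lipids -------------------------------------
        lipid_first_atom = {}  # lipid resseq -> first atom row in bilayer part
        row = 0
        lipid_resseqs = []
        for i, cls in enumerate(bl_truth["lipid_class"]):
            lipid_resseqs.append(i + 1)
            lipid_first_atom[i + 1] = row
            row += 3
        designated: Dict[int, int] = {}  # schedule entry index -> lipid index (0-based)
        used: set = set()
        for k, w in enumerate(spec.contact_schedule):
            candidates = np.flatnonzero(
                (bl_truth["lipid_class"] == w.lipid_class) & (bl_truth["leaflet"] == "upper")
            )
            candidates = [c for c in candidates if c not in used]
            if not candidates:
                raise ValueError(f"no free upper-leaflet lipid of class {w.lipid_class!r}")
            designated[k] = int(candidates[0])
            used.add(int(candidates[0]))

        sched_ca: Dict[int, int] = {}  # entry index -> protein Calpha atom row
        for k, w in enumerate(spec.contact_schedule):
            idx = topology.select(chain=w.chain, resseq_range=(w.resseq, w.resseq), names=["CA"])
            if len(idx) == 0:
                raise ValueError(f"scheduled residue {w.chain}/{w.resseq} not in topology")
            sched_ca[k] = int(idx[0])

        def contact_direction(chain: str, frame_idx: int) -> np.ndarray:
            """Downward unit vector perpendicular to the chain's arm axis.

            Perpendicular placement keeps the distance from the contact
            lipid to the *neighbouring* residues at sqrt(spacing² + depth²)
            (> cutoff) for any arm tilt, so the schedule realizes exactly.
            """
            if spec.system == "monomer_18nm":
                return np.array([0.0, 0.0, -1.0])
            if phi_sched is not None:
                delta = _delta_for_angle(float(phi_sched[frame_idx]), m_tip, m_center, y_split)
            else:
                delta = delta0
            sign = 1.0 if chain == "A" else -1.0
            return np.array([-sign * math.sin(delta), 0.0, -math.cos(delta)])

        # -- frames ---------------------------------------------------------
        n_atoms = topology.n_atoms
        positions = np.empty((spec.n_frames, n_atoms, 3))
        boxes = np.tile(spec.box, (spec.n_frames, 1))
        base_z = bl_truth["base_z"]
        n_lipids = len(base_z)
        offsets = bl_truth["atom_offsets"]            # (n_lipids, 3, 3)
        marker_xy = bl_truth["marker_xy"]
        for f in range(spec.n_frames):
            if n_prot:
                prot = protein_positions(f)
                if spec.protein_noise_sigma > 0:
                    prot = prot + rng.normal(0.0, spec.protein_noise_sigma, size=prot.shape)
                positions[f, :n_prot] = prot
            # lipids rebuilt from the noiseless base with fresh per-lipid z noise
            z_noise = rng.normal(0.0, spec.noise_sigma, size=n_lipids)
            markers = np.column_stack([marker_xy[:, 0], marker_xy[:, 1], base_z + z_noise])
            positions[f, n_prot:] = (markers[:, None, :] + offsets).reshape(-1, 3)
            # scheduled contacts override the designated lipids
            t = times[f]
            for k, w in enumerate(spec.contact_schedule):
                if w.t_on <= t <= w.t_off:
                    ca = positions[f, sched_ca[k]]
                    direction = contact_direction(w.chain, f)
                    li = designated[k]
                    a0_row = n_prot + lipid_first_atom[li + 1]
                    for j in range(3):
                        positions[f, a0_row + j] = ca + (
                            _CONTACT_DEPTH + j * _CONTACT_STACK
                        ) * direction
        traj = trajectory_from_arrays(topology, times, boxes, positions)

        # -- ground truth ----------------------------------------------------
        truth = dict(bl_truth)
        truth["n_protein_atoms"] = n_prot
        truth["angle_deg"] = None if phi_sched is None else np.asarray(phi_sched, dtype=float)
        truth["contact_schedule"] = list(spec.contact_schedule)
        truth["designated_lipids"] = designated
        if spec.contact_schedule:
            truth["t_first_ps"] = float(
                min(times[times >= w.t_on][0] for w in spec.contact_schedule)
            )
        else:
            truth["t_first_ps"] = None
        truth["replicate"] = rep
        records.append(ReplicateRecord(trajectory=traj, ground_truth=truth))
    return records
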