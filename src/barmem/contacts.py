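"""Residue–lipid contacts and the normalized occupancy statistic.

A residue is in contact with a lipid class in a frame when the minimum
heavy-atom distance between the residue and any lipid of that class is at
or below the cutoff (default 0.4 nm), measured under the minimum-image
convention in the orthorhombic periodic box.

Occupancy of a residue with a lipid class is the longest continuous
contact period, normalized to the simulation time remaining after the
first contact between *any* residue and *any* phospholipid:

    occupancy = (longest run of k consecutive contact frames) * dt
                / (T_total - t_first_global)

so a residue that stays bound from the first global contact to the end
scores 1 and a residue that never touches a lipid scores 0. A run of k
frames counts as k*dt by default (each frame represents one sampling
interval); the (k-1)*dt convention is available via ``run_convention``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Structure, Trajectory
from .io import AMINO_ACIDS
from .lipids import PHOSPHOLIPID_CLASSES, LipidInventory

logger = logging.getLogger("barmem")

__all__ = [
    "ContactParams",
    "ContactSeries",
    "OccupancyProfile",
    "BindingSiteAnnotation",
    "min_distance",
    "contact_series",
    "occupancy_profile",
    "aggregate_occupancy",
    "longest_true_run",
]


@dataclass
class ContactParams:
    """Contact criterion: heavy-atom minimum distance ≤ ``cutoff`` (nm)."""

    cutoff: float = 0.4
    atom_scope: str = "heavy_atoms"
    pbc: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.atom_scope != "heavy_atoms":
            raise ValueError("only heavy_atoms scope is supported")


@dataclass
class BindingSiteAnnotation:
    """Named residue sets; defaults are the two basic membrane-binding clusters."""

    sites: dict = field(
        default_factory=lambda: {"cluster1": (107, 109, 110), "cluster2": (132, 134, 136)}
    )

    def validate(self, topology: Structure) -> None:
        present = set(int(r) for r in topology.residue_seqs)
        for name, residues in self.sites.items():
            missing = [r for r in residues if r not in present]
            if missing:
                raise ValueError(f"binding site {name!r}: residues {missing} not in topology")


@dataclass
class ContactSeries:
    """Boolean residue × frame contact record for one lipid class."""

    residue_keys: List[Tuple[str, int]]     # (chain, resseq)
    lipid_class: str
    matrix: np.ndarray                       # bool (n_residues, n_frames)
    t0: float                                # ps
    dt: float                                # ps
    n_frames: int
    t_first_global: Optional[float]          # ps; None if no phospholipid contact ever

    @property
    def first_contact_frame(self) -> Optional[int]:
        if self.t_first_global is None:
            return None
        return int(round((self.t_first_global - self.t0) / self.dt))


@dataclass
class OccupancyProfile:
    """Per-residue occupancy in [0, 1] for one lipid class (or pooled)."""

    residue_keys: List[Tuple[str, int]]
    lipid_class: str
    values: np.ndarray
    mean: Optional[np.ndarray] = None        # set by aggregate_occupancy
    sd: Optional[np.ndarray] = None
    n_replicates: int = 1


def min_distance(
    frame: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    pbc: bool = True,
) -> float:
    """Minimum distance (nm) between two atom groups in one frame.

    With ``pbc`` the minimum-image convention on the frame's orthorhombic
    box is used (exact, via a toroidal k-d tree).
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("min_distance: empty atom group")
    pa = frame.positions[group_a]
    pb = frame.positions[group_b]
    if pbc:
        frame.require_periodic()
        box = frame.box
        tree = cKDTree(np.mod(pb, box), boxsize=box)
        d, _ = tree.query(np.mod(pa, box), k=1)
    else:
        tree = cKDTree(pb)
        d, _ = tree.query(pa, k=1)
    return float(np.min(d))


def _protein_residues(topology: Structure) -> List[Tuple[Tuple[str, int], np.ndarray]]:
    """(chain, resseq) keys with heavy-atom index arrays, in topology order."""
    heavy = topology.heavy_mask
    out = []
    for (chain, resseq, resname), idx in topology.residue_groups().items():
        if resname not in AMINO_ACIDS:
            continue
        h = idx[heavy[idx]]
        if len(h):
            out.append(((chain, resseq), h))
    if not out:
        raise ValueError("topology contains no protein residues")
    return out


def _per_atom_contact(frame: Frame, atom_idx: np.ndarray, lipid_atoms: np.ndarray,
                      cutoff: float, pbc: bool) -> np.ndarray:
    """Boolean per protein atom: within cutoff of any lipid atom."""
    pa = frame.positions[atom_idx]
    pl = frame.positions[lipid_atoms]
    if pbc:
        frame.require_periodic()
        box = frame.box
        tree = cKDTree(np.mod(pl, box), boxsize=box)
        d, _ = tree.query(np.mod(pa, box), k=1, distance_upper_bound=np.inf)
    else:
        tree = cKDTree(pl)
        d, _ = tree.query(pa, k=1)
    return d <= cutoff


def contact_series(
    traj: Trajectory,
    params: ContactParams,
    lipid_class: str,
    inventory: LipidInventory,
) -> ContactSeries:
    """Per-residue, per-frame contact record with one lipid class.

    ``t_first_global`` is computed jointly over *all* phospholipid classes
    (not just the queried one), matching the occupancy normalisation.
    """
    if not traj.has_dt:
        raise ValueError("contact analysis needs a multi-frame trajectory with defined dt")
    topology = traj.topology
    residues = _protein_residues(topology)
    lipid_atoms = inventory.heavy_atoms_of_class(topology, lipid_class)
    if len(lipid_atoms) == 0:
        raise ValueError(f"no lipids of class {lipid_class!r} in topology")
    all_phos = [
        inventory.heavy_atoms_of_class(topology, c)
        for c in PHOSPHOLIPID_CLASSES
        if len(inventory.lipids_of_class(c))
    ]
    all_phos_atoms = np.concatenate(all_phos)

    protein_atoms = np.concatenate([idx for _, idx in residues])
    # map protein atom rows back to residue rows for a reduceat-style any()
    res_slices = np.cumsum([0] + [len(idx) for _, idx in residues])

    n_res, n_frames = len(residues), traj.n_frames
    matrix = np.zeros((n_res, n_frames), dtype=bool)
    first_frame: Optional[int] = None
    for f, frame in enumerate(traj.frames):
        per_atom = _per_atom_contact(frame, protein_atoms, lipid_atoms, params.cutoff, params.pbc)
        matrix[:, f] = np.logical_or.reduceat(per_atom, res_slices[:-1])
        # empty residues cannot occur (filtered above)
        if first_frame is None:
            if lipid_class in PHOSPHOLIPID_CLASSES and matrix[:, f].any():
                first_frame = f
            else:
                any_phos = _per_atom_contact(
                    frame, protein_atoms, all_phos_atoms, params.cutoff, params.pbc
                )
                if any_phos.any():
                    first_frame = f
    t_first = None if first_frame is None else float(traj.times[first_frame])
    return ContactSeries(
        residue_keys=[key for key, _ in residues],
        lipid_class=lipid_class,
        matrix=matrix,
        t0=traj.t0,
        dt=traj.dt,
        n_frames=n_frames,
        t_first_global=t_first,
    )


def longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest run of True in a 1-D boolean array."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def occupancy_profile(series: ContactSeries, run_convention: str = "k") -> OccupancyProfile:
    """The normalized longest-run occupancy per residue.

    ``run_convention="k"`` counts a run of k contact frames as k·dt
    (default); ``"k-1"`` as (k-1)·dt. Values are clipped to [0, 1].
    With no phospholipid contact anywhere, an all-zero profile is
    returned with a warning.
    """
    if run_convention not in ("k", "k-1"):
        raise ValueError(f"unknown run convention {run_convention!r}")
    n_res = len(series.residue_keys)
    if series.t_first_global is None:
        logger.warning(
            "no protein-phospholipid contact in the whole trajectory; occupancy is all zero"
        )
        return OccupancyProfile(series.residue_keys, series.lipid_class, np.zeros(n_res))
    f_first = series.first_contact_frame
    denom_frames = series.n_frames - f_first  # (T_total - t_first) / dt
    values = np.zeros(n_res)
    for r in range(n_res):
        k = longest_true_run(series.matrix[r])
        run_frames = k if run_convention == "k" else max(0, k - 1)
        values[r] = run_frames / denom_frames if denom_frames > 0 else 0.0
    return OccupancyProfile(
        residue_keys=series.residue_keys,
        lipid_class=series.lipid_class,
        values=np.clip(values, 0.0, 1.0),
    )


def aggregate_occupancy(profiles: Sequence[OccupancyProfile]) -> OccupancyProfile:
    """Element-wise replicate mean ± sample SD (ddof=1) of occupancy profiles.

    With a single profile the SD is undefined and returned as NaN.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.residue_keys != ref.residue_keys or p.lipid_class != ref.lipid_class:
            raise ValueError("profiles have mismatched residue index or lipid class")
    stack = np.stack([p.values for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.full(ref.values.shape, np.nan)
    return OccupancyProfile(
        residue_keys=ref.residue_keys,
        lipid_class=ref.lipid_class,
        values=mean,
        mean=mean,
        sd=sd,
        n_replicates=len(profiles),
    )
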