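"""Lipid classification and head-group marker positions.

Lipid molecules are mapped to the five classes of the model mitochondrial
inner membrane — POPC, POPE, POPS, PI(4,5)P₂ and cardiolipin — plus OTHER
for anything unmapped. Each lipid is reduced to a single marker point, the
phosphate phosphorus atom; cardiolipin, which carries two phosphates, is
marked by the midpoint of its two P atoms. All field and contact analyses
operate on these markers or on the lipid's heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import Frame, Structure
from .io import AMINO_ACIDS

logger = logging.getLogger("barmem")

__all__ = ["LIPID_CLASSES", "LipidClassMap", "LipidInventory", "classify_lipids"]

LIPID_CLASSES = ("POPC", "POPE", "POPS", "PIP2", "CDL", "OTHER")

#: classes counted as phospholipids for the "first point of interaction"
#: normalisation (everything but OTHER)
PHOSPHOLIPID_CLASSES = ("POPC", "POPE", "POPS", "PIP2", "CDL")

_DEFAULT_RESIDUE_MAP = {
    "POPC": "POPC",
    "POPE": "POPE",
    "POPS": "POPS",
    "PIP2": "PIP2",
    "POP2": "PIP2",  # CHARMM-GUI residue name for PI(4,5)P2
    "SAPI": "PIP2",
    "CDL": "CDL",
    "CDL2": "CDL",
    "CL": "CDL",
    "TOCL": "CDL",
}


@dataclass
class LipidClassMap:
    """residue_name → lipid class, plus the per-class marker rule.

    The marker rule is "first phosphorus atom" for single-phosphate classes
    and "midpoint of the two phosphorus atoms" for cardiolipin.
    """

    residue_to_class: Dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_RESIDUE_MAP))

    def lipid_class(self, residue_name: str) -> str:
        return self.residue_to_class.get(residue_name, "OTHER")


@dataclass
class LipidInventory:
    """Per-lipid classification result over a fixed topology.

    ``marker_atoms[i]`` holds the topology indices of the marker atom(s) of
    lipid ``i`` (one P, or the two P atoms of a cardiolipin whose midpoint
    is the marker); ``atom_indices[i]`` all atoms of that lipid.
    """

    keys: List[Tuple[str, int, str]]          # (chain, resseq, resname)
    classes: np.ndarray                        # str array, one per lipid
    marker_atoms: List[np.ndarray]
    atom_indices: List[np.ndarray]

    @property
    def n_lipids(self) -> int:
        return len(self.keys)

    def lipids_of_class(self, lipid_class: str) -> np.ndarray:
        return np.flatnonzero(self.classes == lipid_class)

    def marker_positions(self, positions: np.ndarray, lipid_indices=None) -> np.ndarray:
        """Marker points (n, 3) from a coordinate array of the full topology."""
        idx = range(self.n_lipids) if lipid_indices is None else lipid_indices
        return np.array([positions[self.marker_atoms[i]].mean(axis=0) for i in idx]).reshape(-1, 3)

    def heavy_atoms_of_class(self, structure: Structure, lipid_class: str) -> np.ndarray:
        """All heavy-atom topology indices of lipids of one class."""
        heavy = structure.heavy_mask
        out = [
            self.atom_indices[i][heavy[self.atom_indices[i]]]
            for i in self.lipids_of_class(lipid_class)
        ]
        if not out:
            return np.array([], dtype=int)
        return np.concatenate(out)


def classify_lipids(topology: Structure, class_map: LipidClassMap | None = None) -> LipidInventory:
    """Classify every non-protein residue of ``topology`` into a lipid class.

    Unmapped residue names go to OTHER with a logged warning. A mapped
    class whose marker rule needs phosphorus raises if the residue has no
    P atom; cardiolipin needs at least two.
    """
    class_map = class_map or LipidClassMap()
    keys: List[Tuple[str, int, str]] = []
    classes: List[str] = []
    marker_atoms: List[np.ndarray] = []
    atom_indices: List[np.ndarray] = []
    warned: set = set()
    for (chain, resseq, resname), idx in topology.residue_groups().items():
        if resname in AMINO_ACIDS:
            continue
        cls = class_map.lipid_class(resname)
        if cls == "OTHER" and resname not in warned:
            logger.warning("residue name %r not in lipid class map; classified as OTHER", resname)
            warned.add(resname)
        p_atoms = idx[np.array([topology.elements[i] == "P" for i in idx], dtype=bool)]
        if cls == "CDL":
            if len(p_atoms) < 2:
                raise ValueError(
                    f"cardiolipin residue {chain}/{resname}{resseq} has {len(p_atoms)} P atoms; "
                    "its marker is the midpoint of two phosphates"
                )
            markers = p_atoms[:2]
        elif cls != "OTHER":
            if len(p_atoms) == 0:
                raise ValueError(
                    f"lipid residue {chain}/{resname}{resseq} (class {cls}) has no phosphorus atom "
                    "for the head-group marker"
                )
            markers = p_atoms[:1]
        else:
            markers = idx[:1]  # OTHER: first atom stands in; not used by analyses
        keys.append((chain, resseq, resname))
        classes.append(cls)
        marker_atoms.append(markers)
        atom_indices.append(idx)
    if not keys:
        raise ValueError("topology contains no lipid residues")
    return LipidInventory(
        keys=keys,
        classes=np.asarray(classes, dtype=object),
        marker_atoms=marker_atoms,
        atom_indices=atom_indices,
    )
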