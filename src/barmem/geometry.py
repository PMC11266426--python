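"""Helix axes, inter-helix angles and overall dimer extent.

The BAR dimer's crescent geometry is summarised by (i) per-helix principal
axes fitted to Cα coordinates, (ii) the angle between the long α2 helices
of the two chains — the field's standard proxy for BAR-domain intrinsic
curvature (≈33° for classical BAR domains, ≈10° for the flatter F-BARs) —
and (iii) the dimer's end-to-end length and central bundle diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import Structure

__all__ = [
    "HelixSpec",
    "DEFAULT_HELIX_RANGES",
    "helix_axis",
    "interhelix_angle",
    "dimer_extent",
]

#: Helix boundaries of the FAM92A1 BAR domain (residue_seq, inclusive):
#: α1 2-61, α2 64-136 (kinked at Pro98), α3 142-211.
DEFAULT_HELIX_RANGES = {"alpha1": (2, 61), "alpha2": (64, 136), "alpha3": (142, 211)}

#: Annotated kink position within α2.
ALPHA2_KINK_RESIDUE = 98

_NM_TO_ANGSTROM = 10.0


@dataclass
class HelixSpec:
    """A fitted helix axis: unit direction, centroid (nm) and provenance."""

    chain_id: str
    residue_range: Tuple[int, int]
    axis: np.ndarray
    centroid: np.ndarray
    n_calpha_used: int


def _principal_axis(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    return vt[0], centroid


def helix_axis(structure: Structure, chain: str, residue_range: Tuple[int, int]) -> HelixSpec:
    """Fit a helix axis as the dominant principal direction of the Cα cloud.

    The axis is oriented from low to high residue number. Gaps in the range
    are tolerated (disordered residues are simply absent); at least 10 Cα
    atoms are required for a meaningful fit.
    """
    idx = structure.select(chain=chain, resseq_range=residue_range, names=["CA"])
    if len(idx) < 10:
        raise ValueError(
            f"chain {chain} residues {residue_range[0]}-{residue_range[1]}: "
            f"only {len(idx)} Calpha atoms (need >= 10)"
        )
    order = np.argsort(structure.residue_seqs[idx], kind="stable")
    idx = idx[order]
    coords = structure.positions[idx]
    axis, centroid = _principal_axis(coords)
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return HelixSpec(
        chain_id=chain,
        residue_range=tuple(residue_range),
        axis=axis / np.linalg.norm(axis),
        centroid=centroid,
        n_calpha_used=len(idx),
    )


def interhelix_angle(a: HelixSpec, b: HelixSpec, convention: str = "acute") -> float:
    """Angle between two helix axes in degrees.

    ``convention="acute"`` (default) reports arccos(|a·b|) in [0, 90], the
    convention under which the FAM92A1 α2/α2' angle is 33.2°;
    ``convention="directed"`` keeps axis orientation, giving [0, 180].
    """
    dot = float(np.dot(a.axis, b.axis))
    if convention == "acute":
        dot = abs(dot)
    elif convention != "directed":
        raise ValueError(f"unknown convention {convention!r}")
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))


def dimer_extent(structure: Structure, central_fraction: float = 0.2) -> Tuple[float, float]:
    """(length Å, bundle diameter Å) of the dimer from its Cα atoms.

    Length is the extent of Cα projections on the first principal axis.
    The bundle diameter is defined as twice the RMS radial Cα distance from
    that axis, restricted to the central ``central_fraction`` of the
    length — i.e. the six-helix dimerisation core, not the thin arm tips.
    Both are invariant under rigid motion.
    """
    idx = structure.select(names=["CA"])
    if len(idx) < 3:
        raise ValueError(f"dimer_extent needs >= 3 Calpha atoms, found {len(idx)}")
    coords = structure.positions[idx]
    axis, centroid = _principal_axis(coords)
    proj = (coords - centroid) @ axis
    length_nm = float(proj.max() - proj.min())
    mid = 0.5 * (proj.max() + proj.min())
    central = np.abs(proj - mid) <= 0.5 * central_fraction * length_nm
    radial = (coords - centroid) - np.outer(proj, axis)
    r = np.linalg.norm(radial[central], axis=1)
    diameter_nm = 0.0 if len(r) == 0 else 2.0 * float(np.sqrt(np.mean(r**2)))
    return length_nm * _NM_TO_ANGSTROM, diameter_nm * _NM_TO_ANGSTROM
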