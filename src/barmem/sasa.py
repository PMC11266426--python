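"""Solvent-accessible surface area by the Shrake–Rupley method.

A deterministic Fibonacci-spiral point set is placed on each atom's
probe-expanded sphere; points inside any neighbouring expanded sphere are
buried and the exposed fraction scales the sphere area. Determinism
matters here: interface buried areas are differences of SASA values, and a
fixed point set makes ΔSASA exactly non-negative atom by atom.

Radii come from a pinned table (Bondi-type values, packaged as
``data/vdw_radii.json``); probe radius defaults to the water probe 1.4 Å.
Input coordinates are nm (package convention); areas are returned in Å².
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .core import Structure

__all__ = ["vdw_radii", "fibonacci_sphere", "shrake_rupley", "total_sasa"]

_NM_TO_ANGSTROM = 10.0


@lru_cache(maxsize=1)
def vdw_radii() -> dict:
    """The packaged van der Waals radii table (Å), element symbol → radius."""
    text = resources.files("barmem.data").joinpath("vdw_radii.json").read_text()
    table = json.loads(text)
    return {k.upper(): float(v) for k, v in table.items() if not k.startswith("_")}


@lru_cache(maxsize=8)
def fibonacci_sphere(n_points: int) -> np.ndarray:
    """``n_points`` near-uniform unit vectors on the sphere (golden spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


def shrake_rupley(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict | None = None,
) -> np.ndarray:
    """Per-atom SASA in Å² for the heavy atoms of ``structure``.

    Hydrogens are excluded from both the surface and the occlusion set and
    get area 0. Unknown elements raise, listing every offending atom.
    """
    table = radii if radii is not None else vdw_radii()
    heavy = structure.heavy_mask
    idx = np.flatnonzero(heavy)
    if len(idx) == 0:
        raise ValueError("structure has no heavy atoms")
    unknown = [
        f"atom {i} {structure.names[i]} ({structure.elements[i]})"
        for i in idx
        if structure.elements[i] not in table
    ]
    if unknown:
        raise ValueError("no van der Waals radius for: " + "; ".join(unknown))
    centers = structure.positions[idx] * _NM_TO_ANGSTROM
    expanded = np.array([table[structure.elements[i]] for i in idx]) + probe
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(centers)
    r_max = float(expanded.max())
    areas_heavy = np.zeros(len(idx))
    for a in range(len(idx)):
        neighbours = tree.query_ball_point(centers[a], expanded[a] + r_max)
        neighbours = [b for b in neighbours if b != a]
        pts = centers[a] + expanded[a] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for b in neighbours:
            d2 = np.einsum("ij,ij->i", pts - centers[b], pts - centers[b])
            exposed &= d2 >= expanded[b] ** 2
        areas_heavy[a] = exposed.sum() / n_points * 4.0 * np.pi * expanded[a] ** 2
    areas = np.zeros(structure.n_atoms)
    areas[idx] = areas_heavy
    return areas


def total_sasa(structure: Structure, probe: float = 1.4, n_points: int = 960) -> float:
    """Total SASA in Å²."""
    return float(shrake_rupley(structure, probe=probe, n_points=n_points).sum())
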