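"""Dimer interface analysis: buried area, residue census, hydrogen bonds.

Buried interface area follows the PISA convention: half the total SASA
lost on complex formation, ``(SASA(A) + SASA(B) - SASA(AB)) / 2``. The
per-chain buried areas and their sum are also reported, since published
interface areas are sometimes the summed (unhalved) quantity.

Hydrogen bonds across the interface are detected by a heavy-atom
donor–acceptor distance criterion only (default 3.5 Å): a crystal
structure at ~2 Å resolution carries no hydrogens, so no angle term is
applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import Structure
from .sasa import shrake_rupley

__all__ = [
    "InterfaceReport",
    "HBond",
    "HYDROPHOBIC_RESIDUES",
    "interface_area",
    "interface_hbonds",
]

_NM_TO_ANGSTROM = 10.0

#: Aliphatic/aromatic side chains counted in the hydrophobic census.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY", "TYR"}
)


@lru_cache(maxsize=1)
def _donor_acceptor_table() -> dict:
    text = resources.files("barmem.data").joinpath("hbond_donor_acceptor.json").read_text()
    return json.loads(text)


@dataclass
class HBond:
    donor: Tuple[str, int, str, str]      # (chain, resseq, resname, atom)
    acceptor: Tuple[str, int, str, str]
    distance: float                        # Å


@dataclass
class InterfaceReport:
    buried_area: float                     # Å², PISA convention (ΔSASA / 2)
    per_chain_buried: Dict[str, float]     # Å² per chain set label
    total_buried_both_chains: float        # Å², summed (unhalved) buried area
    interface_residues: List[dict]         # chain, resseq, resname, buried_fraction
    hydrophobic_count_at_threshold: int
    hydrophobic_threshold: float
    hbonds: List[HBond] = field(default_factory=list)

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)


def _chain_subset(structure: Structure, chains: Sequence[str]) -> Structure:
    idx = structure.select(chains=chains)
    if len(idx) == 0:
        raise ValueError(f"no atoms in chain(s) {list(chains)}")
    return structure.subset(idx)


def _per_residue_sums(structure: Structure, areas: np.ndarray) -> Dict[Tuple[str, int, str], float]:
    out: Dict[Tuple[str, int, str], float] = {}
    for key, idx in structure.residue_groups().items():
        out[key] = float(areas[idx].sum())
    return out


def interface_area(
    structure: Structure,
    chains_a: Sequence[str],
    chains_b: Sequence[str],
    probe: float = 1.4,
    n_points: int = 960,
    hydrophobic_threshold: float = 0.70,
    d_max_hbond: float = 3.5,
) -> InterfaceReport:
    """Buried interface area and residue census between two chain sets.

    A residue is an interface residue when it loses any solvent-accessible
    area on complexation; its buried fraction is ΔSASA divided by its SASA
    in the isolated chain. The hydrophobic census counts residues from
    :data:`HYDROPHOBIC_RESIDUES` whose buried fraction exceeds
    ``hydrophobic_threshold`` (default 0.70). Hydrogen bonds across the
    interface are included in the report.
    """
    set_a, set_b = set(chains_a), set(chains_b)
    if not set_a or not set_b:
        raise ValueError("both chain sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"chain sets overlap: {sorted(set_a & set_b)}")
    present = set(structure.chain_ids)
    missing = (set_a | set_b) - present
    if missing:
        raise ValueError(f"chain id(s) not in structure: {sorted(missing)}")

    sub_a = _chain_subset(structure, sorted(set_a))
    sub_b = _chain_subset(structure, sorted(set_b))
    complex_idx = structure.select(chains=sorted(set_a | set_b))
    sub_ab = structure.subset(complex_idx)

    areas_a = shrake_rupley(sub_a, probe=probe, n_points=n_points)
    areas_b = shrake_rupley(sub_b, probe=probe, n_points=n_points)
    areas_ab = shrake_rupley(sub_ab, probe=probe, n_points=n_points)

    sasa_a, sasa_b, sasa_ab = areas_a.sum(), areas_b.sum(), areas_ab.sum()
    buried = float(sasa_a + sasa_b - sasa_ab) / 2.0

    res_alone = {**_per_residue_sums(sub_a, areas_a), **_per_residue_sums(sub_b, areas_b)}
    res_complex = _per_residue_sums(sub_ab, areas_ab)
    interface_residues = []
    hydrophobic_count = 0
    per_chain: Dict[str, float] = {"+".join(sorted(set_a)): 0.0, "+".join(sorted(set_b)): 0.0}
    for key, alone in res_alone.items():
        delta = alone - res_complex.get(key, 0.0)
        if delta <= 0.0:
            continue
        chain, resseq, resname = key
        label = "+".join(sorted(set_a)) if chain in set_a else "+".join(sorted(set_b))
        per_chain[label] += delta
        fraction = min(1.0, delta / alone) if alone > 0 else 0.0
        interface_residues.append(
            {"chain": chain, "resseq": resseq, "resname": resname, "buried_fraction": fraction}
        )
        if resname in HYDROPHOBIC_RESIDUES and fraction > hydrophobic_threshold:
            hydrophobic_count += 1
    interface_residues.sort(key=lambda r: (r["chain"], r["resseq"]))

    return InterfaceReport(
        buried_area=buried,
        per_chain_buried=per_chain,
        total_buried_both_chains=float(sum(per_chain.values())),
        interface_residues=interface_residues,
        hydrophobic_count_at_threshold=hydrophobic_count,
        hydrophobic_threshold=hydrophobic_threshold,
        hbonds=interface_hbonds(structure, sorted(set_a), sorted(set_b), d_max=d_max_hbond),
    )


def _donor_acceptor_indices(structure: Structure, idx: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    table = _donor_acceptor_table()
    donors, acceptors = [], []
    for i in idx:
        name = str(structure.names[i])
        resname = str(structure.residue_names[i])
        if name in table["backbone_donors"] or name in table["sidechain_donors"].get(resname, ()):
            donors.append(i)
        if name in table["backbone_acceptors"] or name in table["sidechain_acceptors"].get(resname, ()):
            acceptors.append(i)
    return np.asarray(donors, dtype=int), np.asarray(acceptors, dtype=int)


def interface_hbonds(
    structure: Structure,
    chains_a: Sequence[str],
    chains_b: Sequence[str],
    d_max: float = 3.5,
) -> List[HBond]:
    """Cross-interface donor–acceptor pairs within ``d_max`` Å.

    Both directions (donor in A / acceptor in B and vice versa) are
    scanned; the same atom pair acting in both roles (e.g. two hydroxyls)
    is reported once, as the direction found first.
    """
    idx_a = structure.select(chains=chains_a)
    idx_b = structure.select(chains=chains_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("chain selection resolved to no atoms")
    bonds: List[HBond] = []
    seen_pairs: set = set()

    def atom_id(i: int) -> Tuple[str, int, str, str]:
        return (
            str(structure.chain_ids[i]),
            int(structure.residue_seqs[i]),
            str(structure.residue_names[i]),
            str(structure.names[i]),
        )

    for don_side, acc_side in ((idx_a, idx_b), (idx_b, idx_a)):
        donors, _ = _donor_acceptor_indices(structure, don_side)
        _, acceptors = _donor_acceptor_indices(structure, acc_side)
        if len(donors) == 0 or len(acceptors) == 0:
            continue
        tree = cKDTree(structure.positions[acceptors] * _NM_TO_ANGSTROM)
        for d in donors:
            near = tree.query_ball_point(structure.positions[d] * _NM_TO_ANGSTROM, d_max)
            for j in near:
                a = int(acceptors[j])
                pair = frozenset((int(d), a))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                dist = float(
                    np.linalg.norm(structure.positions[d] - structure.positions[a]) * _NM_TO_ANGSTROM
                )
                bonds.append(HBond(donor=atom_id(int(d)), acceptor=atom_id(a), distance=dist))
    bonds.sort(key=lambda b: b.distance)
    return bonds
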