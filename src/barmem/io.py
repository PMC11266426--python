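"""Readers and writers for PDB, GRO and the frame-table trajectory format.

Conventions
-----------
* PDB files are fixed-column with coordinates in Å; they are converted to
  nm on read. Only the first MODEL is read; insertion codes are rejected;
  for alternate locations the highest-occupancy conformer is kept (first
  wins on a tie).
* GRO files are fixed-width with coordinates already in nm; velocities are
  ignored. Only orthorhombic (3-component) box lines are supported —
  a 9-component box with non-zero off-diagonal terms is refused.
* The frame table is a plain CSV trajectory interchange format:
  ``frame,time_ps,box_x_nm,box_y_nm,box_z_nm,x0,y0,z0,x1,...`` with one
  row per frame and 3N coordinate columns in topology atom order. It is
  deliberately text-only so trajectories are diff-able; binary readers
  (XTC/DCD) can be plugged in behind the same :class:`~barmem.core.Trajectory`
  contract via :func:`trajectory_from_arrays`.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AtomRecord, Frame, Structure, Trajectory

logger = logging.getLogger("barmem")

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_gro",
    "write_gro",
    "read_frame_table",
    "write_frame_table",
    "trajectory_from_arrays",
    "PdbParseError",
    "GroParseError",
]

_ANGSTROM_PER_NM = 10.0

# Standard amino-acid residue names; used to infer "protein" atoms elsewhere.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)


class PdbParseError(ValueError):
    pass


class GroParseError(ValueError):
    pass


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name when columns 77-78 are absent."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "SE", "BR", "CL", "NA", "CA"} and len(name.strip()) <= 2:
        # only trust two-letter symbols when the name itself is that short;
        # "CA" in a protein residue is a calcium *name* collision we avoid
        # by requiring the bare two-character name (ions), not "CA " in cols 13+
        return two
    return stripped[0].upper()


def read_pdb(path) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure` (coordinates nm).

    Keeps the highest-occupancy alternate location (first on a tie), reads
    the first MODEL only, and rejects insertion codes. A CRYST1 record with
    all angles 90° sets an orthorhombic box; a triclinic cell is ignored
    with a warning (a crystal cell is not a simulation box).
    """
    atoms: list[AtomRecord] = []
    # key (chain, resseq, atom name) -> (occupancy, list position) for altloc resolution
    seen: dict = {}
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.strip() == "ENDMDL":
                break
            if rec == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                    al, be, ga = (float(line[33:40]), float(line[40:47]), float(line[47:54]))
                except ValueError as exc:
                    raise PdbParseError(f"{path}: line {lineno}: malformed CRYST1 record") from exc
                if max(abs(al - 90), abs(be - 90), abs(ga - 90)) < 1e-6 and min(a, b, c) > 1.0:
                    box = np.array([a, b, c]) / _ANGSTROM_PER_NM
                else:
                    logger.warning("%s: non-orthorhombic CRYST1 cell ignored (not a simulation box)", path)
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError(f"{path}: line {lineno}: truncated ATOM/HETATM record")
            icode = line[26]
            if icode != " ":
                raise PdbParseError(f"{path}: line {lineno}: insertion codes are not supported")
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21].strip()
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_field = line[54:60].strip()
                occupancy = float(occ_field) if occ_field else 1.0
            except ValueError as exc:
                raise PdbParseError(f"{path}: line {lineno}: malformed ATOM/HETATM record") from exc
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            if not element:
                element = _element_from_name(line[12:16])
            if not chain:
                chain = "X"
            atom = AtomRecord(
                index=len(atoms),
                name=name,
                element=element,
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain,
                position=np.array([x, y, z]) / _ANGSTROM_PER_NM,
            )
            if altloc != " ":
                key = (chain, resseq, resname, name)
                if key in seen:
                    prev_occ, pos = seen[key]
                    if occupancy > prev_occ:
                        atom.index = atoms[pos].index
                        atoms[pos] = atom
                        seen[key] = (occupancy, pos)
                    continue
                seen[key] = (occupancy, len(atoms))
            atoms.append(atom)
    if not atoms:
        raise PdbParseError(f"{path}: no ATOM/HETATM records found")
    for i, a in enumerate(atoms):
        a.index = i
    return Structure.from_atoms(atoms, box=box, source_units="angstrom")


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as fixed-column PDB (coordinates converted nm→Å)."""
    with open(path, "w") as fh:
        if structure.box is not None:
            a, b, c = structure.box * _ANGSTROM_PER_NM
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        serial = 0
        for atom in structure.atoms():
            serial += 1
            x, y, z = atom.position * _ANGSTROM_PER_NM
            name = atom.name
            # PDB alignment rule: 1-3 char names start in column 14 unless
            # the element symbol is two characters
            if len(name) < 4 and len(atom.element) < 2:
                name = f" {name}"
            fh.write(
                f"ATOM  {serial:5d} {name:<4s} {atom.residue_name:<3s} {atom.chain_id[:1]}"
                f"{atom.residue_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}\n"
            )
        fh.write("END\n")


def read_gro(path) -> Structure:
    """Read a GROMACS GRO file (coordinates in nm; velocities ignored).

    Chain ids are not part of the GRO format; all atoms get chain ``"X"``
    unless the title line carries a ``chains=`` hint written by
    :func:`write_gro`, in which case per-residue chain ids are restored.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GroParseError(f"{path}: too short to be a GRO file")
    title = lines[0]
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise GroParseError(f"{path}: line 2: atom count not an integer") from exc
    if len(lines) < 2 + n_atoms + 1:
        raise GroParseError(
            f"{path}: header promises {n_atoms} atoms but file has only {len(lines) - 3} atom lines"
        )
    chain_hint: dict[int, str] = {}
    if "chains=" in title:
        # format: chains=A:1-210,B:211-420  (atom index ranges, 1-based)
        spec = title.split("chains=")[1].split()[0]
        for part in spec.split(","):
            cid, rng = part.split(":")
            lo, hi = (int(v) for v in rng.split("-"))
            for i in range(lo, hi + 1):
                chain_hint[i] = cid
    atoms: list[AtomRecord] = []
    for k in range(n_atoms):
        lineno = 3 + k
        line = lines[2 + k]
        if len(line) < 20:
            raise GroParseError(f"{path}: line {lineno}: truncated atom line")
        try:
            resseq = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            fields = line[20:].split()
            if len(fields) < 3:
                raise ValueError("fewer than 3 coordinate fields")
            x, y, z = (float(v) for v in fields[:3])
        except ValueError as exc:
            raise GroParseError(f"{path}: line {lineno}: malformed coordinate line") from exc
        atoms.append(
            AtomRecord(
                index=k,
                name=name,
                element=_element_from_name(name),
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain_hint.get(k + 1, "X"),
                position=np.array([x, y, z]),
            )
        )
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) not in (3, 9):
        raise GroParseError(f"{path}: line {3 + n_atoms}: box line must have 3 or 9 fields")
    box_vals = [float(v) for v in box_fields]
    if len(box_vals) == 9 and any(abs(v) > 1e-12 for v in box_vals[3:]):
        raise GroParseError(f"{path}: triclinic box is not supported (orthorhombic only)")
    box = np.array(box_vals[:3])
    if np.all(box == 0):
        box = None
    return Structure.from_atoms(atoms, box=box, source_units="nm")


def write_gro(structure: Structure, path, title: str = "barmem", decimals: int = 4) -> None:
    """Write a GRO file.

    ``decimals`` sets the coordinate precision (field width ``decimals+5``);
    the default of 4 preserves PDB-derived coordinates (1e-4 nm) exactly,
    while ``decimals=3`` emits the classic fixed 8.3 layout. Chain ids are
    encoded in the title line so a barmem round trip retains them.
    """
    w = decimals + 5
    # contiguous runs of equal chain id -> atom index ranges (1-based)
    runs = []
    start = 0
    for i in range(1, structure.n_atoms + 1):
        if i == structure.n_atoms or structure.chain_ids[i] != structure.chain_ids[start]:
            runs.append(f"{structure.chain_ids[start]}:{start + 1}-{i}")
            start = i
    with open(path, "w") as fh:
        fh.write(f"{title} chains={','.join(runs)}\n")
        fh.write(f"{structure.n_atoms:5d}\n")
        for atom in structure.atoms():
            x, y, z = atom.position
            fh.write(
                f"{atom.residue_seq % 100000:5d}{atom.residue_name:<5s}{atom.name:>5s}"
                f"{(atom.index + 1) % 100000:5d}{x:{w}.{decimals}f}{y:{w}.{decimals}f}{z:{w}.{decimals}f}\n"
            )
        if structure.box is not None:
            bx, by, bz = structure.box
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")
        else:
            fh.write(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}\n")


# ---------------------------------------------------------------------------
# frame table
# ---------------------------------------------------------------------------

def frame_table_columns(n_atoms: int) -> list[str]:
    cols = ["frame", "time_ps", "box_x_nm", "box_y_nm", "box_z_nm"]
    for i in range(n_atoms):
        cols += [f"x{i}", f"y{i}", f"z{i}"]
    return cols


def write_frame_table(traj: Trajectory, path) -> None:
    """Write a trajectory as a frame-table CSV (deterministic byte output)."""
    n = traj.topology.n_atoms
    with open(path, "w") as fh:
        fh.write(",".join(frame_table_columns(n)) + "\n")
        for k, fr in enumerate(traj.frames):
            vals = [f"{k}", f"{fr.time:.6g}"] + [f"{v:.10g}" for v in fr.box]
            vals += [f"{v:.10g}" for v in fr.positions.ravel()]
            fh.write(",".join(vals) + "\n")


def read_frame_table(path, topology: Structure) -> Trajectory:
    """Read a frame-table CSV into a :class:`Trajectory` over ``topology``.

    Enforces uniform time spacing; the offending frame index is named when
    spacing is non-uniform or out of order.
    """
    df = pd.read_csv(path)
    n = topology.n_atoms
    expected = 5 + 3 * n
    if df.shape[1] != expected:
        raise ValueError(
            f"{path}: {df.shape[1]} columns but topology with {n} atoms needs {expected}"
        )
    coords = df.iloc[:, 5:].to_numpy(dtype=float)
    frames = []
    for k in range(len(df)):
        frames.append(
            Frame(
                time=float(df.iloc[k, 1]),
                box=df.iloc[k, 2:5].to_numpy(dtype=float),
                positions=coords[k].reshape(n, 3),
            )
        )
    return Trajectory(topology, frames)


def trajectory_from_arrays(
    topology: Structure,
    times_ps: Sequence[float],
    boxes: np.ndarray,
    positions: np.ndarray,
) -> Trajectory:
    """Adapter hook: build a Trajectory from raw arrays.

    Any trajectory backend (e.g. an XTC/DCD reader) can produce
    ``times_ps`` (n_frames,), ``boxes`` (n_frames, 3) and ``positions``
    (n_frames, n_atoms, 3) in nm/ps and obtain an object satisfying the
    same contract as the frame-table reader.
    """
    boxes = np.asarray(boxes, dtype=float)
    positions = np.asarray(positions, dtype=float)
    frames = [
        Frame(time=float(t), box=boxes[k], positions=positions[k])
        for k, t in enumerate(times_ps)
    ]
    return Trajectory(topology, frames)
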