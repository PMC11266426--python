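"""Core data model: structures, frames, trajectories.

All coordinates are stored in nanometres and all times in picoseconds,
regardless of the units of the source file. Printed areas use Å² because
that is the unit crystallographic interface areas are reported in; the
conversion happens at the reporting boundary, never internally.

A :class:`Structure` is a fixed set of atoms with chain/residue identity;
a :class:`Trajectory` is a time-ordered, uniformly spaced sequence of
:class:`Frame` coordinate sets over that fixed topology with an
orthorhombic periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Frame",
    "Trajectory",
    "HEAVY_ELEMENTS",
]

#: Elements treated as heavy atoms (everything but hydrogen/deuterium).
HEAVY_ELEMENTS = None  # sentinel; heaviness is defined as element not in {"H", "D"}

_HYDROGEN = frozenset({"H", "D"})


def _as_box(box) -> Optional[np.ndarray]:
    if box is None:
        return None
    box = np.asarray(box, dtype=float).reshape(3)
    return box


@dataclass
class AtomRecord:
    """One atom: identity plus a position in nm."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index} ({self.name}): non-finite position")


class Structure:
    """An ordered collection of atoms with optional orthorhombic box.

    Internally column-oriented (parallel numpy arrays) so that selections
    and geometry are vectorised; :meth:`atoms` yields row-oriented
    :class:`AtomRecord` views for convenience.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_seqs: Sequence[int],
        chain_ids: Sequence[str],
        positions: np.ndarray,
        box=None,
        source_units: str = "nm",
    ):
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_seqs = np.asarray(residue_seqs, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.box = _as_box(box)
        self.source_units = source_units
        n = len(self.names)
        for arr, what in [
            (self.elements, "elements"),
            (self.residue_names, "residue_names"),
            (self.residue_seqs, "residue_seqs"),
            (self.chain_ids, "chain_ids"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{what}: length {len(arr)} != {n} atoms")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions shape {self.positions.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in structure")
        if any(not c for c in self.chain_ids):
            raise ValueError("empty chain id in structure")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord], box=None, source_units: str = "nm") -> "Structure":
        atoms = list(atoms)
        if not atoms:
            raise ValueError("empty structure")
        return cls(
            names=[a.name for a in atoms],
            elements=[a.element for a in atoms],
            residue_names=[a.residue_name for a in atoms],
            residue_seqs=[a.residue_seq for a in atoms],
            chain_ids=[a.chain_id for a in atoms],
            positions=np.array([a.position for a in atoms], dtype=float),
            box=box,
            source_units=source_units,
        )

    # -- basic protocol ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                index=i,
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.residue_names[i]),
                residue_seq=int(self.residue_seqs[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.positions[i].copy(),
            )

    def subset(self, mask_or_indices) -> "Structure":
        idx = np.asarray(mask_or_indices)
        return Structure(
            names=self.names[idx],
            elements=self.elements[idx],
            residue_names=self.residue_names[idx],
            residue_seqs=self.residue_seqs[idx],
            chain_ids=self.chain_ids[idx],
            positions=self.positions[idx],
            box=None if self.box is None else self.box.copy(),
            source_units=self.source_units,
        )

    # -- selections --------------------------------------------------------
    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e not in _HYDROGEN for e in self.elements], dtype=bool)

    def select(
        self,
        chain: Optional[str] = None,
        chains: Optional[Sequence[str]] = None,
        resseq_range: Optional[tuple] = None,
        names: Optional[Sequence[str]] = None,
        residue_names: Optional[Sequence[str]] = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Return atom indices matching all given filters (AND semantics)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_ids == chain
        if chains is not None:
            mask &= np.isin(self.chain_ids, list(chains))
        if resseq_range is not None:
            lo, hi = resseq_range
            mask &= (self.residue_seqs >= lo) & (self.residue_seqs <= hi)
        if names is not None:
            mask &= np.isin(self.names, list(names))
        if residue_names is not None:
            mask &= np.isin(self.residue_names, list(residue_names))
        if heavy_only:
            mask &= self.heavy_mask
        return np.flatnonzero(mask)

    def residue_groups(self) -> "dict[tuple[str, int, str], np.ndarray]":
        """Map (chain_id, residue_seq, residue_name) -> atom index array, in file order."""
        groups: dict = {}
        for i in range(self.n_atoms):
            key = (str(self.chain_ids[i]), int(self.residue_seqs[i]), str(self.residue_names[i]))
            groups.setdefault(key, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}


@dataclass
class Frame:
    """One snapshot: time (ps), orthorhombic box (nm), per-atom positions (nm)."""

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = _as_box(self.box)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    def require_periodic(self) -> None:
        if self.box is None or np.any(self.box <= 0):
            raise ValueError(
                f"frame at t={self.time} ps: periodic analysis requested but box is "
                f"{None if self.box is None else tuple(self.box)}"
            )


class Trajectory:
    """Uniformly time-spaced frames over a fixed topology.

    ``dt`` is validated to be uniform to a relative tolerance of 1e-6;
    a single-frame trajectory is legal but has no ``dt`` and is refused by
    time-normalised analyses.
    """

    _DT_RTOL = 1e-6

    def __init__(self, topology: Structure, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory with no frames")
        n = topology.n_atoms
        for k, fr in enumerate(frames):
            if fr.positions.shape[0] != n:
                raise ValueError(
                    f"frame {k}: {fr.positions.shape[0]} positions but topology has {n} atoms"
                )
        times = np.array([fr.time for fr in frames], dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ValueError(f"frame times not strictly increasing at frame index {bad}")
        if len(frames) > 1:
            dts = np.diff(times)
            dt = dts[0]
            off = np.abs(dts - dt) / dt
            if np.any(off > self._DT_RTOL):
                bad = int(np.argmax(off > self._DT_RTOL)) + 1
                raise ValueError(f"non-uniform time spacing at frame index {bad}")
            self._dt: Optional[float] = float(dt)
        else:
            self._dt = None
        self.topology = topology
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        """Uniform frame spacing in ps; undefined for a single-frame trajectory."""
        if self._dt is None:
            raise ValueError("dt undefined for a single-frame trajectory")
        return self._dt

    @property
    def has_dt(self) -> bool:
        return self._dt is not None

    @property
    def t0(self) -> float:
        return float(self.times[0])

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([fr.positions for fr in self.frames])
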