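"""Dimer concave-angle dynamics.

The opening of the BAR dimer's concave face is tracked over time as the
angle at a central residue-group centroid subtended by the centroids of
the two distal arm tips, all computed from Cα atoms. A decrease of this
angle over a simulation reports a flattening of the crescent (loss of
intrinsic curvature); an increase reports deepening.

The exact residue triplet is configurable; the defaults use the distal
membrane-binding cluster (residues 132-136) of each chain as the arm tips
and the N-terminal residues 2-10 of both chains — the six-helix-bundle
core — as the vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import Frame, Structure, Trajectory

__all__ = ["AngleGroups", "AngleSeries", "group_centroid", "angle_series", "aggregate_angle_series"]

#: a residue selection: list of (chain_id or None, first_resseq, last_resseq)
ResidueSelection = List[Tuple[Optional[str], int, int]]


@dataclass
class AngleGroups:
    """Three disjoint Cα selections: arm tip A, vertex (center), arm tip B."""

    arm_tip_a: ResidueSelection = field(default_factory=lambda: [("A", 132, 136)])
    center: ResidueSelection = field(default_factory=lambda: [("A", 2, 10), ("B", 2, 10)])
    arm_tip_b: ResidueSelection = field(default_factory=lambda: [("B", 132, 136)])

    def resolve(self, topology: Structure) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for label, sel in (("arm_tip_a", self.arm_tip_a), ("center", self.center),
                           ("arm_tip_b", self.arm_tip_b)):
            idx: list = []
            for chain, lo, hi in sel:
                part = topology.select(chain=chain, resseq_range=(lo, hi), names=["CA"])
                idx.extend(part.tolist())
            if not idx:
                raise ValueError(f"selection {label!r} resolves to no Calpha atoms")
            out.append(np.unique(idx))
        a, c, b = out
        for x, y, lx, ly in ((a, c, "arm_tip_a", "center"), (a, b, "arm_tip_a", "arm_tip_b"),
                             (c, b, "center", "arm_tip_b")):
            if np.intersect1d(x, y).size:
                raise ValueError(f"selections {lx!r} and {ly!r} overlap")
        return a, c, b


@dataclass
class AngleSeries:
    times: np.ndarray                # ps
    angles: np.ndarray               # degrees, (0, 180]
    smoothing_window: Optional[int] = None
    mean: Optional[np.ndarray] = None
    sd: Optional[np.ndarray] = None
    n_replicates: int = 1


def group_centroid(frame: Frame, atom_indices: np.ndarray) -> np.ndarray:
    """Unweighted mean position (nm) of a resolved atom selection."""
    atom_indices = np.asarray(atom_indices, dtype=int)
    if len(atom_indices) == 0:
        raise ValueError("empty selection for centroid")
    return frame.positions[atom_indices].mean(axis=0)


def _angle_deg(tip_a: np.ndarray, center: np.ndarray, tip_b: np.ndarray) -> float:
    u = tip_a - center
    v = tip_b - center
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("coincident centroids: angle undefined")
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))))


def angle_series(
    traj: Trajectory,
    groups: AngleGroups | None = None,
    smoothing_window: Optional[int] = None,
) -> AngleSeries:
    """The concave angle per frame, optionally smoothed.

    Smoothing is a centered moving average of the given odd window length;
    none is applied by default.
    """
    groups = groups or AngleGroups()
    ia, ic, ib = groups.resolve(traj.topology)
    angles = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        try:
            angles[f] = _angle_deg(
                group_centroid(frame, ia), group_centroid(frame, ic), group_centroid(frame, ib)
            )
        except ValueError as exc:
            raise ValueError(f"frame {f} (t={frame.time} ps): {exc}") from exc
    if smoothing_window is not None:
        if smoothing_window < 1 or smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be a positive odd integer")
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        padded = np.pad(angles, pad, mode="edge")
        angles = np.convolve(padded, kernel, mode="valid")
    return AngleSeries(times=traj.times.copy(), angles=angles, smoothing_window=smoothing_window)


def aggregate_angle_series(series: Sequence[AngleSeries]) -> AngleSeries:
    """Per-time-point replicate mean ± sample SD (ddof=1)."""
    if not series:
        raise ValueError("no series to aggregate")
    ref = series[0]
    for s in series[1:]:
        if len(s.times) != len(ref.times) or not np.allclose(s.times, ref.times):
            raise ValueError("series have mismatched time bases")
    stack = np.stack([s.angles for s in series])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(series) > 1 else np.full_like(mean, np.nan)
    return AngleSeries(
        times=ref.times.copy(),
        angles=mean,
        mean=mean,
        sd=sd,
        n_replicates=len(series),
    )
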