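"""Membrane fields: leaflet assignment, 2D lipid density maps, and the
binned leaflet height profile with a derived curvature estimate.

The height profile is the primary observable — the mean phosphate z per
1 nm bin along the membrane long axis (x), sampled every 200 ps — and the
signed curvature κ(x) is an explicitly labelled derived estimate computed
from it by finite differences. Sign convention: κ > 0 where the leaflet
bulges toward +z, the side the protein binds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import Structure, Trajectory
from .io import AMINO_ACIDS
from .lipids import LipidInventory

__all__ = [
    "DensityMap2D",
    "HeightProfile",
    "assign_leaflets",
    "density_map_2d",
    "height_profile",
    "aggregate_height_profiles",
    "curvature_estimate",
]


@dataclass
class DensityMap2D:
    """Time-averaged lipid number density (lipids/nm²) in the xy-plane."""

    lipid_class: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    grid: np.ndarray                 # (nx, ny), lipids / nm²
    window_ps: Tuple[float, float]   # (t_start, t_end) averaged over
    alignment: str
    n_frames_averaged: int

    def integral(self) -> float:
        """Σ grid · bin_area — the mean lipid count inside the mapped region."""
        dx = np.diff(self.x_edges)[:, None]
        dy = np.diff(self.y_edges)[None, :]
        return float((self.grid * dx * dy).sum())


@dataclass
class HeightProfile:
    """Mean phosphate z per bin along x; bins with no samples are flagged missing."""

    bin_centers: np.ndarray          # nm
    mean_z: np.ndarray               # nm; NaN where missing
    counts: np.ndarray               # samples per bin (markers × frames)
    leaflet: str
    bin_nm: float
    sd: Optional[np.ndarray] = None  # across replicates, set by aggregate
    n_replicates: int = 1

    @property
    def missing(self) -> np.ndarray:
        return self.counts == 0


def assign_leaflets(
    marker_positions: np.ndarray,
    method: str = "global",
    local_cell_nm: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Split lipid markers into (upper, lower) leaflet index arrays.

    ``global`` (default): sign of z minus the instantaneous mean marker z.
    ``local``: sign of z minus a local midplane, the mean marker z of the
    xy-cell the lipid falls in (cell size ``local_cell_nm``) — robust for
    strongly curved bilayers where a bumped region crosses the global mean.
    """
    pts = np.asarray(marker_positions, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("leaflet assignment needs at least two lipid markers")
    z = pts[:, 2]
    if np.ptp(z) < 1e-9:
        raise ValueError("all lipid markers at one z: not a bilayer")
    if method == "global":
        mid = z.mean()
        upper = np.flatnonzero(z > mid)
        lower = np.flatnonzero(z <= mid)
    elif method == "local":
        ix = np.floor(pts[:, 0] / local_cell_nm).astype(int)
        iy = np.floor(pts[:, 1] / local_cell_nm).astype(int)
        mid = np.empty(len(pts))
        for cell in set(zip(ix.tolist(), iy.tolist())):
            mask = (ix == cell[0]) & (iy == cell[1])
            mid[mask] = z[mask].mean()
        upper = np.flatnonzero(z > mid)
        lower = np.flatnonzero(z <= mid)
    else:
        raise ValueError(f"unknown leaflet method {method!r}")
    if len(upper) == 0 or len(lower) == 0:
        raise ValueError("leaflet assignment produced an empty leaflet")
    return upper, lower


def _protein_heavy_atoms(topology: Structure) -> np.ndarray:
    mask = np.isin(topology.residue_names, list(AMINO_ACIDS)) & topology.heavy_mask
    return np.flatnonzero(mask)


def _wrap_centered(delta: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Wrap xy displacements into [-L/2, L/2)."""
    return delta - box_xy * np.round(delta / box_xy)


def density_map_2d(
    traj: Trajectory,
    lipid_class: str,
    inventory: LipidInventory,
    window_ps: float = 100_000.0,
    bin_nm: float = 0.2,
    alignment: str = "protein_aligned",
) -> DensityMap2D:
    """Time-averaged 2D number density of one lipid class in the xy-plane.

    The last ``window_ps`` of the trajectory is averaged. With
    ``protein_centered`` each frame is recentred on the protein's
    heavy-atom centroid; ``protein_aligned`` additionally rotates the
    frame in-plane so the protein's first principal xy-axis lies along x
    (the protein diffuses and rotates freely on the bilayer — a lab-frame
    map of a monomer system would smear out all structure). The in-plane
    axis sign is fixed by a third-moment rule so the map is reproducible
    and invariant to global rotations of the input.
    """
    lipids = inventory.lipids_of_class(lipid_class)
    if len(lipids) == 0:
        raise ValueError(f"no lipids of class {lipid_class!r}")
    if alignment not in ("none", "protein_centered", "protein_aligned"):
        raise ValueError(f"unknown alignment {alignment!r}")
    t_end = traj.times[-1]
    sel = np.flatnonzero(traj.times >= t_end - window_ps - 1e-9)
    if len(sel) == 0:
        raise ValueError("averaging window contains no frames")
    box_xy = traj.frames[int(sel[0])].box[:2]
    if alignment == "none":
        x_edges = np.arange(0.0, box_xy[0] + bin_nm * 0.5, bin_nm)
        y_edges = np.arange(0.0, box_xy[1] + bin_nm * 0.5, bin_nm)
    else:
        half = max(box_xy) / 2.0
        x_edges = np.arange(-half, half + bin_nm * 0.5, bin_nm)
        y_edges = x_edges.copy()
    protein = _protein_heavy_atoms(traj.topology) if alignment != "none" else None
    if alignment != "none" and len(protein) == 0:
        raise ValueError("protein-relative alignment requested but topology has no protein")

    acc = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    for f in sel:
        frame = traj.frames[int(f)]
        markers = inventory.marker_positions(frame.positions, lipids)[:, :2]
        if alignment == "none":
            xy = np.mod(markers, frame.box[:2])
        else:
            cog = frame.positions[protein][:, :2].mean(axis=0)
            xy = _wrap_centered(markers - cog, frame.box[:2])
            if alignment == "protein_aligned":
                prot_xy = _wrap_centered(frame.positions[protein][:, :2] - cog, frame.box[:2])
                _, _, vt = np.linalg.svd(prot_xy, full_matrices=False)
                u = vt[0]
                proj = prot_xy @ u
                if np.sum(proj**3) < 0:  # deterministic sign: positive skew toward +x
                    u = -u
                rot = np.array([[u[0], u[1]], [-u[1], u[0]]])
                xy = xy @ rot.T
        h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(x_edges, y_edges))
        acc += h
    grid = acc / len(sel) / (bin_nm * bin_nm)
    return DensityMap2D(
        lipid_class=lipid_class,
        x_edges=x_edges,
        y_edges=y_edges,
        grid=grid,
        window_ps=(float(traj.times[int(sel[0])]), float(t_end)),
        alignment=alignment,
        n_frames_averaged=len(sel),
    )


def _sampling_stride(traj: Trajectory, sample_every_ps: float) -> int:
    if not traj.has_dt:
        raise ValueError("profile sampling needs a multi-frame trajectory")
    ratio = sample_every_ps / traj.dt
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-6:
        raise ValueError(
            f"sampling interval {sample_every_ps} ps is not an integer multiple of dt={traj.dt} ps"
        )
    return stride


def height_profile(
    traj: Trajectory,
    inventory: LipidInventory,
    leaflet: str = "upper",
    bin_nm: float = 1.0,
    sample_every_ps: float = 200.0,
    leaflet_method: str = "global",
    selection: str = "leaflet",
) -> HeightProfile:
    """Mean phosphate z per bin along the membrane long axis (x).

    Leaflets are assigned per sampled frame. ``selection="all"`` bins the
    markers of the whole bilayer instead of one leaflet (both readings of
    the analysis are supported; leaflet-restricted is the default).
    Bins with no samples are flagged missing, never interpolated.
    """
    if bin_nm <= 0:
        raise ValueError("bin width must be positive")
    if leaflet not in ("upper", "lower"):
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
    stride = _sampling_stride(traj, sample_every_ps)
    frames = traj.frames[::stride]
    box_x = frames[0].box[0]
    edges = np.arange(0.0, box_x + bin_nm * 0.5, bin_nm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sums = np.zeros(len(centers))
    counts = np.zeros(len(centers), dtype=int)
    for frame in frames:
        markers = inventory.marker_positions(frame.positions)
        if selection == "leaflet":
            upper, lower = assign_leaflets(markers, method=leaflet_method)
            pick = upper if leaflet == "upper" else lower
            pts = markers[pick]
        elif selection == "all":
            pts = markers
        else:
            raise ValueError(f"unknown selection {selection!r}")
        x = np.mod(pts[:, 0], box_x)
        which = np.clip(np.digitize(x, edges) - 1, 0, len(centers) - 1)
        np.add.at(sums, which, pts[:, 2])
        np.add.at(counts, which, 1)
    mean_z = np.full(len(centers), np.nan)
    nz = counts > 0
    mean_z[nz] = sums[nz] / counts[nz]
    return HeightProfile(
        bin_centers=centers,
        mean_z=mean_z,
        counts=counts,
        leaflet=leaflet if selection == "leaflet" else "both",
        bin_nm=bin_nm,
    )


def aggregate_height_profiles(profiles: Sequence[HeightProfile]) -> HeightProfile:
    """Replicate mean ± sample SD (ddof=1) per bin of single-replicate means."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.bin_centers) != len(ref.bin_centers) or p.leaflet != ref.leaflet:
            raise ValueError("profiles have mismatched bins or leaflet")
    stack = np.stack([p.mean_z for p in profiles])
    with warnings.catch_warnings():
        # bins missing in every replicate stay NaN by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if len(profiles) > 1 else np.full_like(mean, np.nan)
    counts = np.sum([p.counts for p in profiles], axis=0)
    return HeightProfile(
        bin_centers=ref.bin_centers.copy(),
        mean_z=mean,
        counts=counts,
        leaflet=ref.leaflet,
        bin_nm=ref.bin_nm,
        sd=sd,
        n_replicates=len(profiles),
    )


def curvature_estimate(profile: HeightProfile) -> np.ndarray:
    """Signed curvature κ(x) = -z″ / (1 + z′²)^{3/2} per bin (1/nm).

    Positive κ means the leaflet bulges toward +z (toward the protein).
    Computed by central finite differences on the binned means over the
    longest contiguous run of non-missing bins (≥5 required); other bins
    are NaN.
    """
    good = ~profile.missing & np.isfinite(profile.mean_z)
    # longest contiguous run of usable bins
    padded = np.concatenate([[False], good, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    if len(edges) == 0:
        raise ValueError("no usable bins for curvature")
    starts, ends = edges[::2], edges[1::2]
    best = int(np.argmax(ends - starts))
    lo, hi = int(starts[best]), int(ends[best])
    if hi - lo < 5:
        raise ValueError(f"need >= 5 consecutive non-missing bins, longest run has {hi - lo}")
    z = profile.mean_z[lo:hi]
    h = profile.bin_nm
    dz = np.gradient(z, h)
    d2z = np.gradient(dz, h)
    kappa = np.full(len(profile.mean_z), np.nan)
    kappa[lo:hi] = -d2z / (1.0 + dz**2) ** 1.5
    return kappa
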