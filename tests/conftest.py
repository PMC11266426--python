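"""Shared fixtures: small synthetic systems generated at test time."""

import numpy as np
import pytest

from barmem.core import Structure
from barmem.synthetic import ContactWindow, HeightFieldSpec, SyntheticSpec, script_trajectory


@pytest.fixture(scope="session")
def monomer_contact_replicate():
    """One monomer-system replicate with a scripted PIP2 contact window."""
    spec = SyntheticSpec(
        seed=11,
        system="monomer_18nm",
        n_frames=20,
        n_replicates=1,
        contact_schedule=[ContactWindow("A", 107, 800.0, 2400.0, "PIP2")],
    )
    return script_trajectory(spec)[0]


@pytest.fixture(scope="session")
def bump_replicates():
    """Three dimer-system replicates over a Gaussian-bump bilayer."""
    spec = SyntheticSpec(
        seed=7,
        system="dimer_45x15x15",
        n_frames=40,
        n_replicates=3,
        height_field=HeightFieldSpec("gaussian_bump", amplitude=1.0, sigma=3.0, x0=22.5),
        noise_sigma=0.05,
    )
    return script_trajectory(spec)


def single_atom_structure(element="C", position=(0.0, 0.0, 0.0), chain="A"):
    return Structure(
        names=["X"],
        elements=[element],
        residue_names=["UNK"],
        residue_seqs=[1],
        chain_ids=[chain],
        positions=np.array([position], dtype=float),
    )


def two_sphere_structure(separation_nm, elements=("C", "C")):
    """Two pseudo-atoms on the x axis, one per chain."""
    return Structure(
        names=["X1", "X2"],
        elements=list(elements),
        residue_names=["UNK", "UNK"],
        residue_seqs=[1, 2],
        chain_ids=["A", "B"],
        positions=np.array([[0.0, 0.0, 0.0], [separation_nm, 0.0, 0.0]]),
    )


def random_rotation(rng):
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def brute_force_min_distance(pa, pb, box=None):
    """O(N*M) minimum-image minimum distance, the independent oracle."""
    delta = pa[:, None, :] - pb[None, :, :]
    if box is not None:
        delta = delta - box * np.round(delta / box)
    return float(np.sqrt((delta**2).sum(axis=2)).min())
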