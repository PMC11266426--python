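"""The synthetic generators: composition, determinism, ground-truth contracts."""

import numpy as np
import pytest

from barmem.geometry import dimer_extent, helix_axis, interhelix_angle
from barmem.io import read_frame_table, read_gro, write_frame_table, write_gro
from barmem.lipids import classify_lipids
from barmem.synthetic import (
    ContactWindow,
    HeightFieldSpec,
    SyntheticSpec,
    build_bilayer,
    build_dimer,
    build_monomer,
    script_trajectory,
)


def test_dimer_angle_round_trip():
    d = build_dimer(arm_angle_deg=33.2)
    a = helix_axis(d, "A", (64, 136))
    b = helix_axis(d, "B", (64, 136))
    assert interhelix_angle(a, b) == pytest.approx(33.2, abs=0.5)


@pytest.mark.parametrize("angle", [10.0, 33.2, 54.0, 80.0])
def test_dimer_angle_round_trip_across_range(angle):
    d = build_dimer(arm_angle_deg=angle)
    a = helix_axis(d, "A", (64, 136))
    b = helix_axis(d, "B", (64, 136))
    assert interhelix_angle(a, b) == pytest.approx(angle, abs=0.5)


def test_dimer_length_round_trip():
    d = build_dimer(total_length_nm=15.0)
    length, _ = dimer_extent(d)
    assert length == pytest.approx(150.0, abs=2.0)


def test_dimer_validation():
    with pytest.raises(ValueError, match="angle"):
        build_dimer(arm_angle_deg=0.0)
    with pytest.raises(ValueError, match="residues"):
        build_dimer(residues_per_arm=5)


def test_dimer_deterministic_gro_bytes(tmp_path):
    p1, p2 = tmp_path / "a.gro", tmp_path / "b.gro"
    write_gro(build_dimer(), p1)
    write_gro(build_dimer(), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_monomer_is_single_chain():
    m = build_monomer()
    assert set(m.chain_ids) == {"A"}
    assert helix_axis(m, "A", (2, 211)).axis == pytest.approx([1.0, 0.0, 0.0], abs=1e-9)


def test_composition_largest_remainder_exact_ratio():
    from barmem.synthetic import DEFAULT_COMPOSITION, _largest_remainder_counts

    # the 40:32:3:5:18 ratio over 980 lipids gives exact integer counts
    assert _largest_remainder_counts(DEFAULT_COMPOSITION, 980) == {
        "POPC": 400, "POPE": 320, "POPS": 30, "PIP2": 50, "CDL": 180,
    }
    # at any leaflet size the counts sum exactly and track the fractions
    spec = SyntheticSpec(seed=0, system="monomer_18nm")
    _, truth = build_bilayer(spec)
    counts = truth["class_counts_per_leaflet"]
    n = sum(counts.values())
    for cls, frac in DEFAULT_COMPOSITION.items():
        assert abs(counts[cls] - frac * n) < 1.0


def test_composition_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        SyntheticSpec(composition={"POPC": 0.5, "POPE": 0.4})


def test_flat_noiseless_leaflets_at_identical_z():
    spec = SyntheticSpec(seed=1, system="monomer_18nm", noise_sigma=0.0)
    structure, truth = build_bilayer(spec)
    inv = classify_lipids(structure)
    markers = inv.marker_positions(structure.positions)
    upper = truth["leaflet"] == "upper"
    assert np.ptp(markers[upper][:, 2]) <= 1e-9
    assert np.ptp(markers[~upper][:, 2]) <= 1e-9
    assert markers[upper][:, 2].mean() - markers[~upper][:, 2].mean() == pytest.approx(3.8)


def test_cardiolipin_built_with_two_phosphates():
    spec = SyntheticSpec(seed=1, system="monomer_18nm")
    structure, truth = build_bilayer(spec)
    inv = classify_lipids(structure)
    cdl = inv.lipids_of_class("CDL")
    assert len(cdl) == 2 * truth["class_counts_per_leaflet"]["CDL"]
    assert all(len(inv.marker_atoms[i]) == 2 for i in cdl)


def test_bilayer_too_small_rejected():
    with pytest.raises(ValueError, match="50"):
        build_bilayer(SyntheticSpec(seed=0, system="monomer_18nm", area_per_lipid=50.0))


def test_replicates_bit_identical_for_same_seed(tmp_path):
    spec = SyntheticSpec(seed=42, system="monomer_18nm", n_frames=4, n_replicates=2)
    r1 = script_trajectory(spec)
    r2 = script_trajectory(spec)
    for a, b in zip(r1, r2):
        assert np.array_equal(a.trajectory.positions_array(), b.trajectory.positions_array())
    f1, f2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
    write_frame_table(r1[0].trajectory, f1)
    write_frame_table(r2[0].trajectory, f2)
    assert f1.read_bytes() == f2.read_bytes()


def test_replicates_differ_from_each_other():
    spec = SyntheticSpec(seed=42, system="monomer_18nm", n_frames=4, n_replicates=2)
    r = script_trajectory(spec)
    assert not np.array_equal(
        r[0].trajectory.positions_array(), r[1].trajectory.positions_array()
    )


def test_generated_files_reread_through_io(tmp_path):
    spec = SyntheticSpec(seed=3, system="monomer_18nm", n_frames=3, n_replicates=1)
    rec = script_trajectory(spec)[0]
    gro = tmp_path / "top.gro"
    write_gro(rec.trajectory.topology, gro)
    top2 = read_gro(gro)
    assert np.abs(top2.positions - rec.trajectory.topology.positions).max() <= 1e-4
    table = tmp_path / "traj.csv"
    write_frame_table(rec.trajectory, table)
    traj2 = read_frame_table(table, top2)
    assert traj2.dt == rec.trajectory.dt
    assert np.abs(traj2.positions_array() - rec.trajectory.positions_array()).max() <= 1e-4


def test_schedule_outside_span_rejected():
    with pytest.raises(ValueError, match="outside"):
        SyntheticSpec(
            system="monomer_18nm", n_frames=5, dt_ps=200.0,
            contact_schedule=[ContactWindow("A", 107, 0.0, 2000.0, "PIP2")],
        )


def test_empty_schedule_gives_zero_contact_matrix():
    from barmem.contacts import ContactParams, contact_series, occupancy_profile

    spec = SyntheticSpec(seed=6, system="monomer_18nm", n_frames=6, n_replicates=1)
    rec = script_trajectory(spec)[0]
    inv = classify_lipids(rec.trajectory.topology)
    series = contact_series(rec.trajectory, ContactParams(), "POPC", inv)
    assert not series.matrix.any()
    assert series.t_first_global is None
    assert occupancy_profile(series).values.max() == 0.0


def test_gaussian_bump_amplitude_recovered(bump_replicates):
    """height_profile recovers the prescribed 1 nm bump within noise error."""
    from barmem.fields import height_profile

    rec = bump_replicates[0]
    inv = classify_lipids(rec.trajectory.topology)
    prof = height_profile(rec.trajectory, inv, leaflet="upper")
    center = np.argmin(np.abs(prof.bin_centers - 22.5))
    edge = np.nanmean(prof.mean_z[[1, 2, 3]])
    amplitude = prof.mean_z[center] - edge
    # ~25 markers/bin x 40 frames; allow 3x the standard error plus
    # field variation across the centre bin (~2% of the amplitude)
    se = 0.05 / np.sqrt(25 * 40)
    assert amplitude == pytest.approx(1.0, abs=3 * se + 0.03)
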