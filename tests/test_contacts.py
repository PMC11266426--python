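"""Contact detection under periodic boundaries and the occupancy statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barmem.contacts import (
    ContactParams,
    ContactSeries,
    aggregate_occupancy,
    contact_series,
    longest_true_run,
    min_distance,
    occupancy_profile,
)
from barmem.core import Frame
from barmem.lipids import classify_lipids
from barmem.synthetic import ContactWindow, SyntheticSpec, script_trajectory
from conftest import brute_force_min_distance


def _frame(pa, pb, box):
    pos = np.vstack([pa, pb])
    return Frame(time=0.0, box=np.asarray(box, dtype=float), positions=pos), \
        np.arange(len(pa)), np.arange(len(pa), len(pa) + len(pb))


def test_minimum_image_across_boundary():
    frame, ia, ib = _frame(np.array([[0.05, 0.5, 0.5]]), np.array([[0.95, 0.5, 0.5]]), [1.0, 1.0, 1.0])
    assert min_distance(frame, ia, ib, pbc=True) == pytest.approx(0.1)
    assert min_distance(frame, ia, ib, pbc=False) == pytest.approx(0.9)


def test_coincident_atoms_distance_zero():
    frame, ia, ib = _frame(np.array([[0.3, 0.3, 0.3]]), np.array([[0.3, 0.3, 0.3]]), [1, 1, 1])
    assert min_distance(frame, ia, ib) == 0.0


def test_empty_group_rejected():
    frame, ia, ib = _frame(np.array([[0.3, 0.3, 0.3]]), np.array([[0.5, 0.5, 0.5]]), [1, 1, 1])
    with pytest.raises(ValueError, match="empty"):
        min_distance(frame, ia, np.array([], dtype=int))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_tree_min_distance_equals_brute_force(seed):
    """Grid/tree neighbour search against the O(N*M) minimum-image oracle."""
    rng = np.random.default_rng(seed)
    box = rng.uniform(2.0, 6.0, 3)
    pa = rng.uniform(-box, 2 * box, size=(rng.integers(1, 50), 3))
    pb = rng.uniform(-box, 2 * box, size=(rng.integers(1, 50), 3))
    frame, ia, ib = _frame(pa, pb, box)
    assert min_distance(frame, ia, ib, pbc=True) == pytest.approx(
        brute_force_min_distance(pa, pb, box), abs=1e-12
    )


def brute_force_occupancy(contact_row, f_first, n_frames):
    """Exhaustive run-length scan oracle under the k*dt duration convention."""
    best = run = 0
    for c in contact_row:
        run = run + 1 if c else 0
        best = max(best, run)
    return best / (n_frames - f_first)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_longest_run_matches_scan(seed):
    rng = np.random.default_rng(seed)
    row = rng.random(rng.integers(1, 40)) < 0.4
    best = run = 0
    for c in row:
        run = run + 1 if c else 0
        best = max(best, run)
    assert longest_true_run(row) == best


def _series(matrix, f_first, dt=1000.0):
    matrix = np.asarray(matrix, dtype=bool)
    return ContactSeries(
        residue_keys=[("A", i) for i in range(matrix.shape[0])],
        lipid_class="PIP2",
        matrix=matrix,
        t0=0.0,
        dt=dt,
        n_frames=matrix.shape[1],
        t_first_global=None if f_first is None else f_first * dt,
    )


def test_occupancy_limits():
    always = np.ones((1, 10), dtype=bool)
    assert occupancy_profile(_series(always, 0)).values[0] == 1.0
    never = np.zeros((1, 10), dtype=bool)
    s = _series(never, None)
    assert occupancy_profile(s).values[0] == 0.0


def test_occupancy_example_against_run_length_oracle():
    # 10 frames, dt = 1 ns, first global contact at frame 2,
    # residue contact frames {3,4,5,6}
    row = np.zeros(10, dtype=bool)
    row[[3, 4, 5, 6]] = True
    got = occupancy_profile(_series(row[None, :], 2)).values[0]
    assert got == pytest.approx(brute_force_occupancy(row, 2, 10))
    assert got == pytest.approx(4 / 8)


def test_occupancy_from_first_contact_to_end_is_one():
    row = np.zeros(12, dtype=bool)
    row[4:] = True
    assert occupancy_profile(_series(row[None, :], 4)).values[0] == 1.0


def test_k_minus_one_convention_flag():
    row = np.zeros(10, dtype=bool)
    row[[3, 4, 5, 6]] = True
    got = occupancy_profile(_series(row[None, :], 2), run_convention="k-1").values[0]
    assert got == pytest.approx(3 / 8)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_adding_contacts_never_decreases_occupancy(seed):
    """Monotonicity with t_first and frame count held fixed."""
    rng = np.random.default_rng(seed)
    n = 30
    row = rng.random(n) < 0.3
    s1 = _series(row[None, :], 0)
    v1 = occupancy_profile(s1).values[0]
    extra = row.copy()
    flip = rng.integers(0, n)
    extra[flip] = True
    v2 = occupancy_profile(_series(extra[None, :], 0)).values[0]
    assert v2 >= v1


def test_occupancy_invariant_under_time_rescaling():
    row = np.zeros(20, dtype=bool)
    row[[5, 6, 7, 12, 13]] = True
    v1 = occupancy_profile(_series(row[None, :], 3, dt=200.0)).values[0]
    v2 = occupancy_profile(_series(row[None, :], 3, dt=7.0)).values[0]
    assert v1 == pytest.approx(v2, rel=1e-12)


def test_scripted_schedule_is_reproduced_exactly(monomer_contact_replicate):
    rec = monomer_contact_replicate
    traj = rec.trajectory
    inv = classify_lipids(traj.topology)
    series = contact_series(traj, ContactParams(), "PIP2", inv)
    row = series.residue_keys.index(("A", 107))
    expected = (traj.times >= 800.0) & (traj.times <= 2400.0)
    assert np.array_equal(series.matrix[row], expected)
    others = np.delete(np.arange(len(series.residue_keys)), row)
    assert not series.matrix[others].any()
    assert series.t_first_global == rec.ground_truth["t_first_ps"]


def test_t_first_global_spans_all_classes(monomer_contact_replicate):
    """Querying POPC still normalises by the first PIP2 contact."""
    traj = monomer_contact_replicate.trajectory
    inv = classify_lipids(traj.topology)
    series = contact_series(traj, ContactParams(), "POPC", inv)
    assert not series.matrix.any()
    assert series.t_first_global == 800.0


def test_cutoff_limiting_cases(monomer_contact_replicate):
    traj = monomer_contact_replicate.trajectory
    inv = classify_lipids(traj.topology)
    tiny = contact_series(traj, ContactParams(cutoff=1e-6), "PIP2", inv)
    assert not tiny.matrix.any()
    huge = contact_series(traj, ContactParams(cutoff=100.0), "PIP2", inv)
    assert huge.matrix.all()


def test_aggregate_mean_sd():
    row = np.zeros(10, dtype=bool)
    row[[3, 4]] = True
    p1 = occupancy_profile(_series(row[None, :], 0))
    row2 = np.zeros(10, dtype=bool)
    row2[[3, 4, 5, 6]] = True
    p2 = occupancy_profile(_series(row2[None, :], 0))
    agg = aggregate_occupancy([p1, p2, p1])
    vals = np.array([0.2, 0.4, 0.2])
    assert agg.mean[0] == pytest.approx(vals.mean())
    assert agg.sd[0] == pytest.approx(vals.std(ddof=1))
    same = aggregate_occupancy([p1, p1, p1])
    assert same.sd[0] == pytest.approx(0.0, abs=1e-12)
    single = aggregate_occupancy([p1])
    assert np.isnan(single.sd[0])
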