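"""Capture counting/kinetics, RMSD/Rg, clustering, interactions, t-test."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy import stats as sps

from sorbscreen import trajectory as trj
from sorbscreen.fixtures import gen_capture_traj


def brute_force_min_distance(lig, mat, box):
    """Independent all-pairs minimum-image distance (plain loops)."""
    best = math.inf
    for a in lig:
        for b in mat:
            d = 0.0
            for k in range(3):
                dx = a[k] - b[k]
                dx -= box[k] * round(dx / box[k])
                d += dx * dx
            best = min(best, math.sqrt(d))
    return best


# ---------------------------------------------------------------------------
# Capture counting
# ---------------------------------------------------------------------------

def test_far_copy_not_captured(make_trajectory):
    coords = [[[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]]]
    t = make_trajectory(coords, box=(500, 500, 500),
                        groups={"matrix": [0], "copy_0": [1]})
    series = trj.capture_count(t, ["copy_0"])
    assert series.counts.tolist() == [0]


def test_inclusive_boundary_at_exact_cutoff(make_trajectory):
    coords = [[[10.0, 10.0, 10.0], [13.5, 10.0, 10.0], [13.6, 10.0, 10.0]]]
    t = make_trajectory(coords, groups={"matrix": [0], "copy_0": [1],
                                        "copy_1": [2]})
    series = trj.capture_count(t, ["copy_0", "copy_1"], cutoff=3.5)
    assert series.counts.tolist() == [1]  # 3.5 in, 3.6 out


def test_hand_built_frame_matches_brute_force(rng):
    box = np.array([60.0, 60.0, 60.0])
    mat = rng.uniform(20, 40, size=(30, 3))
    counts_expected = 0
    groups = {"matrix": np.arange(30)}
    coords = [mat]
    for i in range(10):
        # 6 copies planted within the cutoff of some matrix atom, 4 far away
        if i < 6:
            base = mat[rng.integers(30)]
            offset = rng.normal(size=3)
            offset *= rng.uniform(0.5, 3.4) / np.linalg.norm(offset)
            pos = base + offset
        else:
            pos = mat.mean(axis=0) + np.array([25.0 + i, 0.0, 0.0])
        coords.append(pos[None])
        groups[f"copy_{i}"] = np.array([30 + i])
    all_coords = np.concatenate(coords)[None]
    t = trj.Trajectory(all_coords, np.ones(40), ["C"] * 40, groups, box,
                       np.array([0.0]))
    copy_groups = [f"copy_{i}" for i in range(10)]
    series = trj.capture_count(t, copy_groups, cutoff=3.5)
    for i in range(10):
        d = brute_force_min_distance(all_coords[0, [30 + i]], all_coords[0, :30], box)
        counts_expected += d <= 3.5
    assert series.counts[0] == counts_expected == 6


def test_kdtree_equals_brute_force_under_periodicity(rng):
    box = np.array([20.0, 25.0, 30.0])
    mat = rng.uniform(-10, 40, size=(25, 3))  # spills outside the box
    lig = rng.uniform(-10, 40, size=(8, 3))
    groups = {"matrix": np.arange(25),
              **{f"copy_{i}": np.array([25 + i]) for i in range(8)}}
    coords = np.concatenate([mat, lig])[None]
    t = trj.Trajectory(coords, np.ones(33), ["C"] * 33, groups, box,
                       np.array([0.0]))
    copies = [f"copy_{i}" for i in range(8)]
    fast = trj.capture_count(t, copies, cutoff=6.0, method="kdtree")
    slow = trj.capture_count(t, copies, cutoff=6.0, method="brute")
    assert fast.counts.tolist() == slow.counts.tolist()
    for i in range(8):
        d_oracle = brute_force_min_distance(lig[i:i + 1], mat, box)
        d_pkg = trj.min_matrix_distance(lig[i:i + 1], mat, box)
        assert d_pkg == pytest.approx(d_oracle, rel=1e-12)


def test_empty_and_overlapping_groups_rejected(make_trajectory):
    t = make_trajectory([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]],
                        groups={"matrix": [0], "copy_0": [1], "bad": []})
    with pytest.raises(ValueError, match="empty"):
        trj.capture_count(t, ["bad"])
    with pytest.raises(ValueError, match="overlaps"):
        trj.capture_count(t, ["matrix"])


def test_capture_com_mode(make_trajectory):
    # two-atom copy: atoms at 2 and 6 from the matrix, centre of mass at 4
    coords = [[[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [6.0, 0.0, 0.0]]]
    t = make_trajectory(coords, groups={"matrix": [0], "copy_0": [1, 2]})
    atom = trj.capture_count(t, ["copy_0"], cutoff=3.5, mode="atom")
    com = trj.capture_count(t, ["copy_0"], cutoff=3.5, mode="com")
    assert atom.counts.tolist() == [1]
    assert com.counts.tolist() == [0]


# ---------------------------------------------------------------------------
# Capture half-time
# ---------------------------------------------------------------------------

def series(times, counts, n=10):
    return trj.CaptureSeries(np.asarray(times, float), np.asarray(counts),
                             n_copies=n, cutoff=3.5)


def test_halftime_interpolates_between_frames():
    assert trj.capture_halftime(series([10.0, 12.0], [4, 6])) == 11.0


def test_halftime_zero_when_reached_at_start():
    assert trj.capture_halftime(series([0.0, 1.0], [5, 5])) == 0.0


def test_halftime_infinite_when_never_reached():
    assert trj.capture_halftime(series([0.0, 1.0, 2.0], [0, 1, 2])) == math.inf


def test_halftime_odd_copies_uses_ceiling():
    s = trj.CaptureSeries(np.array([0.0, 1.0]), np.array([1, 2]),
                          n_copies=3, cutoff=3.5)
    assert trj.capture_halftime(s) == 1.0  # threshold ceil(3/2) = 2


# ---------------------------------------------------------------------------
# RMSD / Rg
# ---------------------------------------------------------------------------

def test_rmsd_zero_against_itself(rng):
    x = rng.normal(size=(1, 20, 3)) * 5
    t = trj.Trajectory(np.repeat(x, 3, axis=0), np.ones(20), ["C"] * 20,
                       {"all": np.arange(20)}, np.full(3, 100.0),
                       np.arange(3, dtype=float))
    out = trj.rmsd_series(t, "all")
    assert out.values == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)


def test_rmsd_translation_without_alignment_is_pythagorean(rng):
    x0 = rng.normal(size=(10, 3))
    x1 = x0 + np.array([3.0, 4.0, 0.0])
    t = trj.Trajectory(np.stack([x0, x1]), np.ones(10), ["C"] * 10,
                       {"all": np.arange(10)}, np.full(3, 100.0),
                       np.arange(2, dtype=float))
    out = trj.rmsd_series(t, "all", align=False)
    assert out.values[1] == pytest.approx(5.0, rel=1e-12)


def test_rmsd_alignment_removes_rigid_motion(rng):
    x0 = rng.normal(size=(15, 3)) * 4
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
    x1 = rot.apply(x0) + np.array([5.0, -2.0, 7.0])
    t = trj.Trajectory(np.stack([x0, x1]), np.ones(15), ["C"] * 15,
                       {"all": np.arange(15)}, np.full(3, 100.0),
                       np.arange(2, dtype=float))
    out = trj.rmsd_series(t, "all", align=True)
    assert out.values[1] == pytest.approx(0.0, abs=1e-9)


def test_rmsd_alignment_needs_three_atoms(make_trajectory):
    t = make_trajectory([[[0, 0, 0], [1, 0, 0]]], groups={"sel": [0, 1]})
    with pytest.raises(ValueError, match="3 atoms"):
        trj.rmsd_series(t, "sel", align=True)


def test_rg_two_unit_masses():
    coords = [[[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]]
    t = trj.Trajectory(np.array(coords), np.ones(2), ["C"] * 2,
                       {"all": np.arange(2)}, np.full(3, 100.0),
                       np.array([0.0]))
    assert trj.rg_series(t, "all").values[0] == pytest.approx(5.0)


def test_rg_single_atom_is_zero(make_trajectory):
    t = make_trajectory([[[3.0, 4.0, 5.0]]])
    assert trj.rg_series(t, "all").values[0] == 0.0


def test_rg_matches_direct_summation(rng):
    n = 100
    x = rng.normal(size=(1, n, 3)) * 10
    w = rng.uniform(1, 20, size=n)
    t = trj.Trajectory(x, w, ["C"] * n, {"all": np.arange(n)},
                       np.full(3, 100.0), np.array([0.0]))
    com = sum(w[i] * x[0, i] for i in range(n)) / w.sum()
    rg2 = sum(w[i] * np.dot(x[0, i] - com, x[0, i] - com) for i in range(n)) / w.sum()
    assert trj.rg_series(t, "all").values[0] == pytest.approx(math.sqrt(rg2),
                                                              rel=1e-10)


def test_rg_and_rmsd_invariant_under_global_rigid_motion(rng):
    x = rng.normal(size=(4, 12, 3)) * 3
    rot = Rotation.from_euler("zyx", [1.0, 0.5, -0.7])
    moved = np.array([rot.apply(f) + np.array([10.0, -4.0, 2.0]) for f in x])
    common = dict(masses=np.ones(12), elements=["C"] * 12,
                  groups={"all": np.arange(12)}, box=np.full(3, 100.0),
                  times=np.arange(4, dtype=float))
    t1 = trj.Trajectory(coords=x, **common)
    t2 = trj.Trajectory(coords=moved, **common)
    np.testing.assert_allclose(trj.rg_series(t1, "all").values,
                               trj.rg_series(t2, "all").values, rtol=1e-10)
    np.testing.assert_allclose(trj.rmsd_series(t1, "all").values,
                               trj.rmsd_series(t2, "all").values, atol=1e-9)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_singleton_clusters_when_k_equals_frames(rng):
    m = np.abs(rng.normal(size=(6, 6)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    result = trj.cluster_frames(m, n_clusters=6, seed=0)
    assert sorted(result.labels.tolist()) == list(range(6))
    assert sorted(result.representatives.tolist()) == list(range(6))


def test_planted_partition_recovered():
    # two blobs of frames: small distances within, large across
    n = 10
    m = np.full((n, n), 50.0)
    m[:5, :5] = 1.0
    m[5:, 5:] = 1.0
    m += np.arange(n)[None] * 1e-3  # break ties
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    result = trj.cluster_frames(m, n_clusters=2, seed=1)
    assert len(set(result.labels[:5])) == 1
    assert len(set(result.labels[5:])) == 1
    assert result.labels[0] != result.labels[5]


def test_exactly_k_nonempty_clusters_with_member_representatives(rng):
    n = 30
    m = np.abs(rng.normal(size=(n, n)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    for k in (2, 7, 20):
        result = trj.cluster_frames(m, n_clusters=k, seed=5)
        assert len(np.unique(result.labels)) == k
        for label, rep in enumerate(result.representatives):
            assert result.labels[rep] == label


def test_same_seed_same_representatives(rng):
    m = np.abs(rng.normal(size=(15, 15)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    r1 = trj.cluster_frames(m, n_clusters=4, seed=42)
    r2 = trj.cluster_frames(m, n_clusters=4, seed=42)
    assert r1.representatives.tolist() == r2.representatives.tolist()


def test_cluster_input_validation(rng):
    with pytest.raises(ValueError, match="n_clusters"):
        trj.cluster_frames(np.zeros((3, 3)), n_clusters=4)
    bad = np.ones((3, 3))
    with pytest.raises(ValueError, match="symmetric"):
        trj.cluster_frames(bad, n_clusters=2)


# ---------------------------------------------------------------------------
# Hydrogen bonds / salt bridges
# ---------------------------------------------------------------------------

def test_ideal_linear_hbond_counts_one():
    # O-H...O colinear, H...A = 1.9 Å, D-H = 1.0 Å
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.9, 0.0, 0.0]])
    assert trj.hbond_count(coords, donors=[(0, 1)], acceptors=[2]) == 1


def test_distant_acceptor_not_bonded():
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    assert trj.hbond_count(coords, donors=[(0, 1)], acceptors=[2]) == 0


def test_bent_geometry_rejected_by_angle():
    # acceptor at 90 degrees from the D-H axis, within distance
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.5, 0.0]])
    assert trj.hbond_count(coords, donors=[(0, 1)], acceptors=[2]) == 0


def test_hand_built_frame_with_three_qualifying_pairs(rng):
    coords = []
    donors, acceptors = [], []
    # three ideal donor/acceptor trios along separated axes
    for i in range(3):
        base = np.array([20.0 * i, 0.0, 0.0])
        coords += [base, base + [1.0, 0, 0], base + [2.9, 0, 0]]
        donors.append((3 * i, 3 * i + 1))
        acceptors.append(3 * i + 2)
    # seven decoy acceptors far away
    for j in range(7):
        coords.append(np.array([5.0 * j, 50.0, 0.0]))
        acceptors.append(9 + j)
    count = trj.hbond_count(np.array(coords), donors, acceptors)
    assert count == 3


def test_donor_without_bound_hydrogen_raises():
    coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="bound hydrogen"):
        trj.hbond_count(coords, donors=[(0, 1)], acceptors=[])
    with pytest.raises(ValueError, match="distinct"):
        trj.hbond_count(coords, donors=[(0, 0)], acceptors=[])


@pytest.mark.parametrize("distance,expected", [(3.0, 1), (5.0, 0)])
def test_saltbridge_cutoff(distance, expected):
    coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    count = trj.saltbridge_count(coords, cation_groups=[[0]], anion_groups=[[1]])
    assert count == expected


def test_saltbridge_counts_one_per_group_pair():
    coords = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],   # cation group 0 (two atoms)
        [30.0, 0.0, 0.0],                   # cation group 1
        [3.0, 0.0, 0.0],                    # anion group 0: near cat 0
        [32.0, 0.0, 0.0],                   # anion group 1: near cat 1
    ])
    count = trj.saltbridge_count(coords, cation_groups=[[0, 1], [2]],
                                 anion_groups=[[3], [4]])
    assert count == 2  # one bridge per qualifying pair, not per atom pair


def test_interaction_series_echoes_criteria(make_trajectory):
    coords = [[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.9, 0.0, 0.0]]] * 2
    t = make_trajectory(coords)
    out = trj.interaction_series(t, donors=[(0, 1)], acceptors=[2],
                                 cation_groups=[[0]], anion_groups=[[2]])
    assert out.hb_counts.tolist() == [1, 1]
    assert out.sb_counts.tolist() == [1, 1]
    assert out.criteria["hb"]["ha_cutoff"] == 2.8
    assert out.criteria["sb_cutoff"] == 4.0


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------

def test_identical_samples_give_t0_p1():
    a = [np.array([1, 2, 3])]
    assert trj.compare_capture(a, a) == (0.0, 1.0)


def test_constant_equal_samples_give_t0_p1():
    a = [np.array([2, 2]), np.array([2, 2])]
    assert trj.compare_capture(a, a) == (0.0, 1.0)


def test_ttest_matches_pooled_variance_closed_form():
    a, b = np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0])
    t, p = trj.compare_capture([a], [b])
    # textbook pooled-variance computation
    sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
    t_exp = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert t == pytest.approx(t_exp, rel=1e-12)
    assert p == pytest.approx(2 * sps.t.sf(t_exp, df=4), rel=1e-12)


def test_replicates_are_pooled_per_frame():
    a = [np.array([5, 6]), np.array([7, 8])]
    b = [np.array([1, 2]), np.array([3, 4])]
    t_pooled, _ = trj.compare_capture(a, b)
    t_flat, _ = trj.compare_capture([np.array([5, 6, 7, 8])],
                                    [np.array([1, 2, 3, 4])])
    assert t_pooled == t_flat


def test_too_few_observations_rejected():
    with pytest.raises(ValueError, match="2 observations"):
        trj.compare_capture([np.array([1])], [np.array([1, 2])])


# ---------------------------------------------------------------------------
# Fixture pair: scheduled captures are self-verifying
# ---------------------------------------------------------------------------

def test_capture_fixture_ground_truth_matches_analysis():
    schedule = {0: 0, 1: 5, 2: 12, 3: None, 4: 20}
    traj, truth = gen_capture_traj(schedule, n_frames=25, seed=9)
    copies = sorted(g for g in traj.groups if g.startswith("copy_"))
    measured = trj.capture_count(traj, copies, cutoff=3.5)
    assert measured.counts.tolist() == truth.counts.tolist()
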