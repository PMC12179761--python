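"""Ellipsoid construction and fixed-composition shell extraction."""

import numpy as np
import pytest

from shellpick.emcs import (
    build_ellipsoid,
    determine_M,
    ellipsoid_metric,
    emcs_extract,
)
from shellpick.errors import EmptyShellError, TopologyError
from shellpick.synthetic import alanine_water_spec, generate
from shellpick.trajectory_io import Trajectory


def gyration_oracle(coords):
    """Independently coded gyration tensor + eigensolve (explicit loops)."""
    center = coords.mean(axis=0)
    t = np.zeros((3, 3))
    for p in coords:
        d = p - center
        for i in range(3):
            for j in range(3):
                t[i, j] += d[i] * d[j]
    t /= len(coords)
    import scipy.linalg

    evals, evecs = scipy.linalg.eigh(t)
    return evals[::-1], evecs[:, ::-1]


def test_single_atom_solute_gives_padding_sphere():
    e = build_ellipsoid(np.array([[1.0, 2.0, 3.0]]), padding=3.0)
    assert np.allclose(e.center, [1, 2, 3])
    assert np.allclose(e.semi_axes, 0.0)
    # metric against the padded sphere of radius 3
    assert np.isclose(ellipsoid_metric(np.array([4.0, 2, 3]), e), 1.0)
    assert ellipsoid_metric(np.array([1.0, 2, 3]), e) == 0.0


def test_collinear_solute_major_axis_and_padding_floor():
    coords = np.array([[-2.0, 0, 0], [0, 0, 0], [2.0, 0, 0]])
    e = build_ellipsoid(coords, padding=1.0)
    assert np.isclose(abs(e.axes[0] @ [1, 0, 0]), 1.0)
    # degenerate directions fall back to the padding alone
    assert np.isclose(e.semi_axes[1] + e.padding, 1.0)
    assert np.isclose(e.semi_axes[2] + e.padding, 1.0)
    # all solute atoms inside before padding
    assert np.isclose(e.semi_axes[0], 2.0)


def test_axes_match_gyration_oracle(rng):
    coords = rng.normal(size=(10, 3)) * [3.0, 2.0, 1.0]
    e = build_ellipsoid(coords, padding=0.5)
    evals, evecs = gyration_oracle(coords)
    for i in range(3):
        dot = abs(e.axes[i] @ evecs[:, i])
        assert np.isclose(dot, 1.0, atol=1e-9)


def test_metric_center_and_surface():
    coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0],
                       [0, -1.0, 0], [0, 0, 0.5], [0, 0, -0.5]])
    e = build_ellipsoid(coords, padding=2.0)
    assert ellipsoid_metric(e.center, e) == 0.0
    surface = e.center + e.axes[0] * (e.semi_axes[0] + e.padding)
    assert np.isclose(ellipsoid_metric(surface, e), 1.0, atol=1e-12)


def test_metric_classification_matches_rotate_and_test_oracle(rng):
    coords = rng.normal(size=(8, 3)) * [2.5, 1.5, 1.0]
    e = build_ellipsoid(coords, padding=1.0)
    points = rng.uniform(-6, 6, size=(100, 3))
    semi = e.semi_axes + e.padding
    for p in points:
        local = e.axes @ (p - e.center)  # explicit rotate
        oracle = sum((local[i] / semi[i]) ** 2 for i in range(3))
        assert (ellipsoid_metric(p, e) <= 1.0) == (oracle <= 1.0)
        assert np.isclose(ellipsoid_metric(p, e), oracle, atol=1e-9)


def test_empty_solute_rejected():
    with pytest.raises(TopologyError):
        build_ellipsoid(np.empty((0, 3)))


class TestDetermineM:
    def _traj_with_counts(self, small_fixture):
        _, traj, _, _ = small_fixture
        return traj

    def test_median_statistic_floor(self, monkeypatch, small_fixture):
        import shellpick.emcs as emcs_mod

        traj = self._traj_with_counts(small_fixture)
        counts = np.array([3, 4, 4, 5])

        def fake_metrics(traj, padding, scale, reference_point):
            metrics = np.full((4, 6), 1.5)
            for f, c in enumerate(counts):
                metrics[f, :c] = 0.5
            return None, None, metrics, None

        monkeypatch.setattr(emcs_mod, "_frame_metrics", fake_metrics)
        assert determine_M(traj) == 4
        assert determine_M(traj, statistic="min") == 3

    def test_fifteen_solvent_convention(self, monkeypatch, small_fixture):
        """A shell of 15 molecules in every frame fixes M = 15."""
        import shellpick.emcs as emcs_mod

        traj = self._traj_with_counts(small_fixture)

        def fake_metrics(traj, padding, scale, reference_point):
            metrics = np.full((10, 20), 1.5)
            metrics[:, :15] = 0.5
            return None, None, metrics, None

        monkeypatch.setattr(emcs_mod, "_frame_metrics", fake_metrics)
        assert determine_M(traj) == 15

    def test_empty_shell_error(self, small_fixture):
        _, traj, _, _ = small_fixture
        sub = Trajectory(traj.topology, traj.coordinates[:5])
        with pytest.raises(EmptyShellError):
            determine_M(sub, padding=1e-6, scale=1e-6)


def brute_force_ranking(traj, frame, padding, scale):
    """Per-frame distance-rank oracle: explicit ellipsoid + sorted()."""
    solute = traj.coordinates[frame][traj.solute_indices]
    e = build_ellipsoid(solute, padding=padding, scale=scale)
    entries = []
    for mol_id, idx in sorted(traj.solvent_molecules.items()):
        cog = traj.coordinates[frame][idx].mean(axis=0)
        entries.append((ellipsoid_metric(cog, e), mol_id))
    entries.sort()
    return [m for _, m in entries]


def test_extraction_matches_distance_rank_oracle(small_fixture):
    _, traj, _, _ = small_fixture
    sub = Trajectory(traj.topology, traj.coordinates[:50])
    m = 6
    cluster = emcs_extract(sub, M=m, padding=3.0)
    for f in range(sub.n_frames):
        oracle = brute_force_ranking(sub, f, 3.0, 1.0)[:m]
        assert list(cluster.solvent_ids[f]) == oracle


def test_every_frame_has_exactly_m_slots(small_fixture):
    _, traj, _, _ = small_fixture
    cluster = emcs_extract(traj, M=9)
    assert cluster.solvent_ids.shape == (traj.n_frames, 9)
    assert cluster.solvent_coords.shape[:2] == (traj.n_frames, 9)


def test_tie_broken_toward_lower_molecule_id(small_fixture):
    _, traj, _, _ = small_fixture
    coords = traj.coordinates[:1].copy()
    mols = traj.solvent_molecules
    ids = sorted(mols)
    # put molecules 3 and 2 exactly at the solute center: both at metric
    # zero, a perfect tie that must resolve toward the lower molecule id
    center = coords[0][traj.solute_indices].mean(axis=0)
    coords[0, mols[ids[2]]] = center
    coords[0, mols[ids[1]]] = center
    sub = Trajectory(traj.topology, coords)
    cluster = emcs_extract(sub, M=1, padding=30.0)
    assert cluster.solvent_ids[0, 0] == ids[1]


def test_selection_invariant_under_rigid_motion(small_fixture, rng):
    _, traj, _, _ = small_fixture
    sub = Trajectory(traj.topology, traj.coordinates[:20].copy())
    base = emcs_extract(sub, M=7)
    theta = 1.1
    r = np.array(
        [[np.cos(theta), -np.sin(theta), 0],
         [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]]
    )
    moved = Trajectory(
        traj.topology, sub.coordinates @ r.T + np.array([5.0, -3.0, 2.0])
    )
    rotated = emcs_extract(moved, M=7)
    assert np.array_equal(base.solvent_ids, rotated.solvent_ids)


def test_shrinking_padding_never_increases_counts(small_fixture):
    _, traj, _, _ = small_fixture
    sub = Trajectory(traj.topology, traj.coordinates[:30])
    from shellpick.emcs import _frame_metrics

    counts = []
    for padding in (6.0, 4.0, 2.0, 1.0):
        _, _, metrics, _ = _frame_metrics(sub, padding, 1.0, "cog")
        counts.append((metrics <= 1.0).sum(axis=1))
    for tighter, wider in zip(counts[1:], counts[:-1]):
        assert np.all(tighter <= wider)


def test_m_must_be_below_solvent_count(small_fixture):
    _, traj, _, _ = small_fixture
    with pytest.raises(ValueError):
        emcs_extract(traj, M=traj.n_solvent)


def test_cluster_save_load_round_trip(tmp_path, small_fixture):
    _, traj, _, _ = small_fixture
    sub = Trajectory(traj.topology, traj.coordinates[:5])
    cluster = emcs_extract(sub, M=5)
    path = tmp_path / "c.h5"
    cluster.save(path)
    from shellpick.emcs import ClusterTrajectory

    back = ClusterTrajectory.load(path)
    assert np.array_equal(back.solvent_ids, cluster.solvent_ids)
    assert np.allclose(back.solvent_coords, cluster.solvent_coords)
    assert back.provenance["M"] == 5
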