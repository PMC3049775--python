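import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from helix_unravel.geometry import (
    DegenerateSelectionError,
    distance_series,
    kabsch,
    rg_series,
    rmsd_series,
    superpose,
)
from helix_unravel.topology import Conformation
from helix_unravel.trajectory import AtomSelection, Trajectory


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-5, 5, 3)
    return R, t


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        R, t = kabsch(P, P)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rz.T + np.array([1.0, 2.0, 3.0])
        R, t = kabsch(P, Q)
        np.testing.assert_allclose(R, Rz, atol=1e-12)
        np.testing.assert_allclose(P @ R.T + t, Q, atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_scipy_align_vectors(self):
        """Independent oracle: scipy's least-squares rotation solver."""
        rng = np.random.default_rng(2)
        P = rng.normal(size=(40, 3))
        Q = P @ _random_rigid(3)[0].T + rng.normal(scale=0.1, size=(40, 3))
        R, t = kabsch(P, Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-8)

    def test_matches_rotation_grid_search(self):
        """Brute-force oracle: post-fit RMSD is the minimum over a fine grid
        of rotations about the z axis for a planar-motion problem."""
        rng = np.random.default_rng(4)
        P = rng.normal(size=(8, 3))
        Rz = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        Q = P @ Rz.T
        R, t = kabsch(P, Q)
        fit = np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1)))
        best = np.inf
        for ang in np.linspace(0, 360, 3601):
            G = Rotation.from_euler("z", ang, degrees=True).as_matrix()
            Pg = P @ G.T
            off = Q.mean(0) - Pg.mean(0)
            best = min(best, np.sqrt(np.mean(np.sum((Pg + off - Q) ** 2, 1))))
        assert fit <= best + 1e-3

    def test_degenerate_selection_rejected(self, wt_topology, ideal_helix):
        collinear = AtomSelection(atoms=((15, "N"), (15, "CA"), (15, "C")))
        line = np.zeros((ideal_helix.topology.n_atoms, 3))
        line[:, 0] = np.arange(len(line))  # all atoms on the x axis
        flat = Conformation(wt_topology, line)
        with pytest.raises(DegenerateSelectionError):
            superpose(flat, flat, AtomSelection(13, 26, "all"))


class TestRMSD:
    def test_reference_trajectory_is_zero(self, helix_trajectory, ideal_helix):
        ts = rmsd_series(helix_trajectory, ideal_helix)
        np.testing.assert_allclose(ts.values, 0.0, atol=1e-9)

    def test_single_atom_displacement_closed_form(self, wt_topology,
                                                  ideal_helix):
        """Displacing one of the 40 measured atoms by d with a frozen fit
        gives RMSD d/sqrt(40)."""
        d = 1.7
        coords = ideal_helix.coords.copy()
        # displace backbone O of residue 20 (inside 15-24 backbone selection)
        coords[wt_topology.atom_index(20, "O")] += np.array([0, 0, d])
        traj = Trajectory(wt_topology, coords[None], stride_ps=10.0)
        # freeze the fit on undisplaced atoms so no re-superposition occurs
        fit = AtomSelection(atoms=tuple(
            (r, a) for r in range(13, 27) for a in ("N", "CA", "C")
        ))
        ts = rmsd_series(traj, ideal_helix, fit_selection=fit)
        assert ts.values[0] == pytest.approx(d / np.sqrt(40), rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, wt_topology, ideal_helix, seed):
        """RMSD is unchanged when all frames undergo one rigid motion."""
        R, t = _random_rigid(seed)
        rng = np.random.default_rng(seed)
        noisy = ideal_helix.coords + rng.normal(scale=0.3,
                                                size=ideal_helix.coords.shape)
        traj = Trajectory(wt_topology, noisy[None], stride_ps=10.0)
        moved = Trajectory(wt_topology, (noisy @ R.T + t)[None], stride_ps=10.0)
        a = rmsd_series(traj, ideal_helix).values
        b = rmsd_series(moved, ideal_helix).values
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestRg:
    def test_single_atom_is_zero(self, wt_topology, ideal_helix):
        traj = Trajectory(wt_topology, ideal_helix.coords[None], stride_ps=10.0)
        sel = AtomSelection(atoms=((16, "NZ"),))
        assert rg_series(traj, sel).values[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses_give_half_distance(self, wt_topology,
                                                 ideal_helix):
        coords = ideal_helix.coords.copy()
        ia = wt_topology.atom_index(17, "CD1")
        ib = wt_topology.atom_index(17, "CD2")
        coords[ia] = (0.0, 0.0, 0.0)
        coords[ib] = (3.0, 0.0, 0.0)
        traj = Trajectory(wt_topology, coords[None], stride_ps=10.0)
        sel = AtomSelection(atoms=((17, "CD1"), (17, "CD2")))
        assert rg_series(traj, sel).values[0] == pytest.approx(1.5, rel=1e-12)

    def test_extended_chain_is_larger_than_helix(self, wt_topology):
        from helix_unravel.builder import build_ideal_helix

        helix = build_ideal_helix(wt_topology)
        ext = build_ideal_helix(wt_topology, -140.0, 135.0)
        t_h = Trajectory(wt_topology, helix.coords[None], stride_ps=10.0)
        t_e = Trajectory(wt_topology, ext.coords[None], stride_ps=10.0)
        assert rg_series(t_e).values[0] > rg_series(t_h).values[0] + 2.0

    def test_rigid_motion_invariance(self, wt_topology, ideal_helix):
        R, t = _random_rigid(11)
        t_a = Trajectory(wt_topology, ideal_helix.coords[None], stride_ps=10.0)
        t_b = Trajectory(wt_topology, (ideal_helix.coords @ R.T + t)[None],
                         stride_ps=10.0)
        assert rg_series(t_a).values[0] == pytest.approx(
            rg_series(t_b).values[0], rel=1e-12)


class TestDistances:
    def test_three_four_five_triangle(self, wt_topology, ideal_helix):
        coords = ideal_helix.coords.copy()
        coords[wt_topology.atom_index(16, "NZ")] = (0.0, 0.0, 0.0)
        coords[wt_topology.atom_index(23, "CG")] = (3.0, 4.0, 0.0)
        traj = Trajectory(wt_topology, coords[None], stride_ps=10.0)
        ts = distance_series(traj, (16, "NZ"), (23, "CG"))
        assert ts.values[0] == pytest.approx(5.0, rel=1e-12)

    def test_coincident_atoms_are_zero(self, wt_topology, ideal_helix):
        coords = ideal_helix.coords.copy()
        coords[wt_topology.atom_index(23, "CG")] = coords[
            wt_topology.atom_index(16, "NZ")]
        traj = Trajectory(wt_topology, coords[None], stride_ps=10.0)
        assert distance_series(traj, (16, "NZ"), (23, "CG")).values[0] == 0.0

    def test_unknown_atom_lists_valid_names(self, helix_trajectory):
        from helix_unravel.topology import TopologyError

        with pytest.raises(TopologyError, match="valid names"):
            distance_series(helix_trajectory, (16, "QQ"), (23, "CG"))
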