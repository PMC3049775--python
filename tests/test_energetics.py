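import numpy as np
import pytest

from helix_unravel.energetics import (
    COULOMB_CONSTANT,
    DEFAULT_CUTOFF,
    energy_profile,
    energy_series,
    group_energy,
    pair_energy,
    per_residue_group_energies,
    residue_interaction_matrix,
)
from helix_unravel.topology import NONPOLAR_RESIDUES, Conformation
from helix_unravel.trajectory import Trajectory

NO_LJ = (0.0, 0.0)


class TestPairEnergy:
    def test_zero_at_cutoff_with_zero_slope(self):
        lj = (0.12, 2.1)
        assert pair_energy(0.5, -0.5, lj, lj, 12.0) == 0.0
        # central-difference radial derivative at the cutoff vanishes
        h = 1e-5
        dv = (pair_energy(0.5, -0.5, lj, lj, 12.0 + h)
              - pair_energy(0.5, -0.5, lj, lj, 12.0 - h)) / (2 * h)
        assert abs(dv) < 1e-6

    def test_coulomb_force_shift_closed_form(self):
        """Unit charges without LJ at 6 A: (332.0716/6) * (1 - 0.5)^2."""
        val = pair_energy(1.0, 1.0, NO_LJ, NO_LJ, 6.0)
        assert val == pytest.approx(COULOMB_CONSTANT / 6.0 * 0.25, rel=1e-12)
        assert val == pytest.approx(13.836, abs=1e-3)

    def test_beyond_cutoff_is_exactly_zero(self):
        lj = (0.1, 2.0)
        assert pair_energy(1.0, -1.0, lj, lj, 13.0) == 0.0
        assert pair_energy(1.0, -1.0, lj, lj, 120.0) == 0.0

    def test_continuous_across_cutoff(self):
        lj = (0.12, 2.1)
        just_in = pair_energy(0.3, -0.4, lj, lj, DEFAULT_CUTOFF - 1e-7)
        assert abs(just_in) < 1e-9

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(1.0, 1.0, NO_LJ, NO_LJ, 0.0)
        with pytest.raises(ValueError):
            pair_energy(1.0, 1.0, NO_LJ, NO_LJ, -1.0)

    def test_lorentz_berthelot_combination(self):
        """LJ minimum sits at r = rmin_i/2 + rmin_j/2 with depth sqrt(ei ej),
        modulated by the force-shift factor."""
        lj_i, lj_j = (0.04, 1.8), (0.16, 2.2)
        rmin = 4.0
        shift = (1 - rmin / DEFAULT_CUTOFF) ** 2
        val = pair_energy(0.0, 0.0, lj_i, lj_j, rmin)
        assert val == pytest.approx(-np.sqrt(0.04 * 0.16) * shift, rel=1e-12)


class TestResidueMatrix:
    def test_symmetric_zero_diagonal(self, ideal_helix):
        m = residue_interaction_matrix(ideal_helix)
        assert m.shape == (14, 14)
        np.testing.assert_allclose(m, m.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, wt_topology, ideal_helix):
        """Naive double loop over atom pairs with the same exclusion rule."""
        m = residue_interaction_matrix(ideal_helix)
        params = wt_topology.parameter_arrays()
        excluded = wt_topology.exclusion_mask()
        X = ideal_helix.coords
        # restrict the oracle to a 4-residue block to keep it tiny
        block = (15, 16, 17, 18)
        atoms = [(i, res.number, atom) for i, res, atom in
                 wt_topology.iter_atoms() if res.number in block]
        brute = {}
        for i, ra, atom_a in atoms:
            for j, rb, atom_b in atoms:
                if j <= i or ra == rb or excluded[i, j]:
                    continue
                r = np.linalg.norm(X[i] - X[j])
                if r >= DEFAULT_CUTOFF:
                    continue
                e = pair_energy(atom_a.charge, atom_b.charge,
                                (atom_a.epsilon, atom_a.rmin_half),
                                (atom_b.epsilon, atom_b.rmin_half), r)
                key = tuple(sorted((ra, rb)))
                brute[key] = brute.get(key, 0.0) + e
        for (ra, rb), expected in brute.items():
            assert m[ra - 13, rb - 13] == pytest.approx(expected, abs=1e-9)

    def test_distant_residues_have_zero_entry(self, wt_topology, ideal_helix):
        coords = ideal_helix.coords.copy()
        # move residue 26 (plus cap) far away from residue 13
        for atom in wt_topology.residue(26).atoms:
            coords[wt_topology.atom_index(26, atom.name)] += 500.0
        m = residue_interaction_matrix(Conformation(wt_topology, coords))
        assert m[0, 13] == 0.0

    def test_invariant_under_rigid_motion(self, wt_topology, ideal_helix):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [10, 60, -30], degrees=True).as_matrix()
        moved = Conformation(wt_topology, ideal_helix.coords @ R.T - 7.0)
        np.testing.assert_allclose(residue_interaction_matrix(moved),
                                   residue_interaction_matrix(ideal_helix),
                                   atol=1e-8)


class TestGroupEnergy:
    def test_half_sum(self):
        assert group_energy([2.0] * 7) == pytest.approx(7.0)
        assert group_energy(np.zeros(7)) == 0.0

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            group_energy([1.0] * 6)
        with pytest.raises(ValueError):
            group_energy(np.zeros((7, 2)))

    def test_double_counting_identity(self, ideal_helix):
        """E_np-np equals half the sum of per-residue nonpolar terms and the
        once-per-pair sum of the matrix block."""
        m = residue_interaction_matrix(ideal_helix)
        per_res = per_residue_group_energies(m, "nonpolar")
        half_sum = group_energy(list(per_res.values()))
        cols = [n - 13 for n in NONPOLAR_RESIDUES]
        block = m[np.ix_(cols, cols)]
        assert half_sum == pytest.approx(block.sum() / 2.0, abs=1e-9)
        pair_sum = sum(block[i, j] for i in range(7) for j in range(i + 1, 7))
        assert half_sum == pytest.approx(pair_sum, abs=1e-6)


class TestEnergySeries:
    def test_constant_for_static_trajectory(self, helix_trajectory):
        prof = energy_profile(helix_trajectory)
        for ts in prof.values():
            assert np.ptp(ts.values) == pytest.approx(0.0, abs=1e-9)

    def test_breakdown_consistency(self, helix_trajectory):
        series = energy_series(helix_trajectory)
        assert len(series) == helix_trajectory.n_frames
        for bd in series:
            assert bd.e_npnp == pytest.approx(
                group_energy(list(bd.per_residue_npnp.values())), abs=1e-6)
            np.testing.assert_allclose(bd.residue_matrix,
                                       bd.residue_matrix.T, atol=1e-10)
            # total counts every pair once
            assert bd.e_total == pytest.approx(bd.residue_matrix.sum() / 2.0,
                                               abs=1e-9)

    def test_profile_matches_series(self, helix_trajectory):
        prof = energy_profile(helix_trajectory)
        series = energy_series(helix_trajectory)
        np.testing.assert_allclose(prof["e_npnp"].values,
                                   [b.e_npnp for b in series], atol=1e-9)
        np.testing.assert_allclose(prof["e_pp"].values,
                                   [b.e_pp for b in series], atol=1e-9)
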