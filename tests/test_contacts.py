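import numpy as np
import pytest

from surfagg.core import Box, Frame, Trajectory
from surfagg.contacts import hydrogen_bond_map, residue_contact_map
from surfagg.langevin import make_bead_system
from surfagg.synthetic import (SyntheticSpec, build_antiparallel_dimer,
                               build_peptide, make_system, plant_configuration)

from conftest import random_frame

BOX = Box.solution((20.0, 20.0, 20.0))
F19 = 3  # zero-based residue index of the first phenylalanine


def one_frame_traj(system, coords):
    return Trajectory(system, [Frame(0.0, coords, BOX)])


class TestResidueContactMap:
    def test_planted_f19_f19_contact_only(self):
        system = make_system(2)
        tpl = build_peptide("beta")
        far = tpl + np.array([0.0, 0.0, 3.0])
        # move both F19 side-chain pseudo-atoms to a remote spot where they
        # touch each other and nothing else
        cb_rows = np.flatnonzero((system.names == "CB")
                                 & (system.residue_pos == 4))
        coords = np.vstack([tpl, far]) + 5.0
        coords[cb_rows[0]] = (12.0, 12.0, 12.0)
        coords[cb_rows[1]] = (12.0, 12.0, 12.35)
        cmap = residue_contact_map(one_frame_traj(system, coords), window_ps=None)
        expected = np.zeros((7, 7))
        expected[F19, F19] = 1.0
        assert np.array_equal(cmap.matrix, expected)
        assert cmap.labels[F19] == "F19"

    def test_all_far_gives_zero_map(self):
        system = make_system(3)
        tpl = build_peptide("beta")
        coords = np.vstack([tpl, tpl + (0, 0, 3.0), tpl + (0, 0, 6.0)]) + 5.0
        cmap = residue_contact_map(one_frame_traj(system, coords), window_ps=None)
        assert np.all(cmap.matrix == 0.0)

    def test_matches_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            system, frame = random_frame(3, rng, box_l=3.0)
            traj = Trajectory(system, [frame])
            cmap = residue_contact_map(traj, window_ps=None)
            # independent oracle: explicit loops over atoms and 27 images,
            # symmetrised per unordered peptide pair
            from conftest import brute_force_min_image
            R = system.residues_per_peptide
            acc = np.zeros((R, R))
            for i in range(3):
                for j in range(i + 1, 3):
                    hit = np.zeros((R, R), dtype=bool)
                    for a in range(1, R + 1):
                        for b in range(1, R + 1):
                            ia = [k for k in system.residue_atoms[i][a]
                                  if system.heavy[k]]
                            jb = [k for k in system.residue_atoms[j][b]
                                  if system.heavy[k]]
                            if any(brute_force_min_image(
                                    frame.coords[x], frame.coords[y],
                                    frame.box.lengths,
                                    frame.box.periodic) < 0.4
                                    for x in ia for y in jb):
                                hit[a - 1, b - 1] = True
                    acc += (hit | hit.T)
            acc /= 3  # 3 peptide pairs, 1 frame
            assert np.allclose(cmap.matrix, acc, atol=1e-12)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(31)
        system, frame = random_frame(4, rng, box_l=3.0)
        traj = Trajectory(system, [frame])
        m1 = residue_contact_map(traj, window_ps=None, cutoff=0.35).matrix
        m2 = residue_contact_map(traj, window_ps=None, cutoff=0.50).matrix
        assert np.all(m2 >= m1 - 1e-15)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(37)
        system, frame = random_frame(4, rng, box_l=3.0)
        cmap = residue_contact_map(Trajectory(system, [frame]), window_ps=None)
        perm = rng.permutation(4)
        coords2 = frame.coords.copy()
        for p in range(4):
            coords2[system.peptide_atoms[perm[p]]] = \
                frame.coords[system.peptide_atoms[p]]
        cmap2 = residue_contact_map(
            Trajectory(system, [Frame(0.0, coords2, frame.box)]), window_ps=None)
        assert np.allclose(cmap.matrix, cmap2.matrix, atol=1e-12)


class TestHydrogenBondMap:
    def hbond_fixture(self, d_no: float):
        """Two far-apart peptides with one engineered N-H...O geometry:
        collinear, at donor-acceptor distance ``d_no``."""
        system = make_system(2)
        tpl = build_peptide("beta")
        coords = np.vstack([tpl, tpl + np.array([0.0, 0.0, 4.0])]) + 6.0
        res = 4  # use residue 4's backbone N/H (donor) and O (acceptor)
        n_row = [k for k in system.residue_atoms[0][res]
                 if system.names[k] == "N"][0]
        h_row = [k for k in system.residue_atoms[0][res]
                 if system.names[k] == "H"][0]
        o_row = [k for k in system.residue_atoms[1][res]
                 if system.names[k] == "O"][0]
        coords[n_row] = (3.0, 3.0, 3.0)
        coords[h_row] = (3.0 + 0.101, 3.0, 3.0)
        coords[o_row] = (3.0 + d_no, 3.0, 3.0)
        return system, coords, res

    def test_collinear_bond_counted(self):
        system, coords, res = self.hbond_fixture(0.29)
        hmap = hydrogen_bond_map(one_frame_traj(system, coords), window_ps=None)
        assert hmap.matrix[res - 1, res - 1] == pytest.approx(1.0)
        assert hmap.matrix.sum() == pytest.approx(1.0)

    def test_distance_failure_not_counted(self):
        system, coords, _ = self.hbond_fixture(0.36)
        hmap = hydrogen_bond_map(one_frame_traj(system, coords), window_ps=None)
        assert hmap.matrix.sum() == 0.0

    def test_angle_failure_not_counted(self):
        system, coords, res = self.hbond_fixture(0.29)
        h_row = [k for k in system.residue_atoms[0][res]
                 if system.names[k] == "H"][0]
        # put H perpendicular to the D->A axis: angle 90 degrees
        coords[h_row] = (3.0, 3.0 + 0.101, 3.0)
        hmap = hydrogen_bond_map(one_frame_traj(system, coords), window_ps=None)
        assert hmap.matrix.sum() == 0.0

    def test_antiparallel_sheet_concentrates_on_antidiagonal(self):
        system, frame = build_antiparallel_dimer()
        hmap = hydrogen_bond_map(Trajectory(system, [frame]), window_ps=None)
        total = hmap.matrix.sum()
        assert total > 0
        R = 7
        anti = sum(hmap.matrix[a, b] for a in range(R) for b in range(R)
                   if abs((a + b) - (R - 1)) <= 1)
        assert anti / total > 0.9

    def test_bound_by_donor_count(self):
        system, frame = build_antiparallel_dimer()
        hmap = hydrogen_bond_map(Trajectory(system, [frame]), window_ps=None)
        # 7 backbone donors per peptide, 2 directed pairs
        assert hmap.matrix.sum() <= 2 * 7

    def test_topology_without_hydrogens_rejected(self):
        system = make_bead_system(2)
        coords = np.zeros((system.n_atoms, 3))
        coords[:, 0] = np.arange(system.n_atoms) * 0.38
        with pytest.raises(ValueError, match="hydrogen"):
            hydrogen_bond_map(one_frame_traj(system, coords), window_ps=None)
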