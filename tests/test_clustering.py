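import numpy as np
import pytest

from surfagg.core import Box, Frame, Trajectory
from surfagg.clustering import (largest_oligomer_series, min_heavy_distance,
                                partition_frame, peptide_contact,
                                size_histogram)
from surfagg.synthetic import SyntheticSpec, build_peptide, make_system, plant_configuration

from conftest import random_frame, union_find_partition

BOX = Box.solution((20.0, 20.0, 20.0))


def point_peptides(z_offsets, with_h=False):
    """Minimal peptides of one heavy atom (plus optionally one hydrogen)
    each, at the stated z positions: pairwise heavy distances are exactly
    the z gaps."""
    from surfagg.core import MolecularSystem
    n = len(z_offsets)
    names, elements, rpos, resn, pep, coords = [], [], [], [], [], []
    for p, z in enumerate(z_offsets):
        names.append("CA"); elements.append("C")
        rpos.append(1); resn.append("GLY"); pep.append(p)
        coords.append((0.0, 0.0, z))
        if with_h:
            names.append("HA"); elements.append("H")
            rpos.append(1); resn.append("GLY"); pep.append(p)
            coords.append((5.0, 5.0 + p, z))  # parked far away
    system = MolecularSystem(names=names, elements=elements, residue_pos=rpos,
                             resnames=resn, peptide_index=pep)
    return system, Frame(0.0, np.array(coords), BOX)


class TestPeptideContact:
    def test_strictly_below_cutoff_is_contact(self):
        system, frame = point_peptides([0.0, 0.39])
        assert min_heavy_distance(frame, system, 0, 1) == pytest.approx(0.39)
        assert peptide_contact(frame, system, 0, 1)

    def test_exactly_at_cutoff_is_not_contact(self):
        system, frame = point_peptides([0.0, 0.40])
        assert min_heavy_distance(frame, system, 0, 1) == 0.40
        assert not peptide_contact(frame, system, 0, 1)

    def test_hydrogen_proximity_does_not_count(self):
        system, frame = point_peptides([0.0, 0.5], with_h=True)
        coords = frame.coords.copy()
        # hydrogens of both peptides 0.3 nm apart, heavy atoms still 0.5 apart
        h_rows = np.flatnonzero(~system.heavy)
        coords[h_rows[0]] = (8.0, 8.0, 0.0)
        coords[h_rows[1]] = (8.0, 8.0, 0.3)
        frame = Frame(0.0, coords, BOX)
        assert min_heavy_distance(frame, system, 0, 1) == 0.5
        assert not peptide_contact(frame, system, 0, 1)

    def test_same_peptide_rejected(self):
        system, frame = point_peptides([0.0, 1.0])
        with pytest.raises(ValueError):
            peptide_contact(frame, system, 0, 0)


class TestPartitionFrame:
    def test_transitivity_chains_clusters(self):
        system, frame = point_peptides([0.0, 0.35, 0.70, 5.0])
        part = partition_frame(frame, system)
        assert part.clusters == [(0, 1, 2), (3,)]

    def test_no_contacts_gives_singletons(self):
        system, frame = point_peptides([0.0, 1.0, 2.0])
        part = partition_frame(frame, system)
        assert part.clusters == [(0,), (1,), (2,)]
        assert part.contact_pairs == []

    def test_matches_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            system, frame = random_frame(6, rng, box_l=3.5)
            part = partition_frame(frame, system)
            edges = [(i, j) for i in range(6) for j in range(i + 1, 6)
                     if min_heavy_distance(frame, system, i, j) < 0.4]
            assert [tuple(c) for c in part.clusters] == \
                union_find_partition(6, edges)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        system, frame = random_frame(5, rng, box_l=3.0)
        part = partition_frame(frame, system)
        perm = rng.permutation(5)
        coords2 = frame.coords.copy()
        for p in range(5):
            coords2[system.peptide_atoms[perm[p]]] = \
                frame.coords[system.peptide_atoms[p]]
        part2 = partition_frame(Frame(0.0, coords2, frame.box), system)
        relabeled = sorted((tuple(sorted(perm[list(c)])) for c in part.clusters),
                           key=lambda c: (-len(c), c[0]))
        assert [tuple(c) for c in part2.clusters] == relabeled

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            system, frame = random_frame(5, rng, box_l=3.0)
            sizes = [partition_frame(frame, system, c).largest_size
                     for c in (0.3, 0.4, 0.5, 0.7)]
            assert sizes == sorted(sizes)


class TestSeriesAndHistogram:
    def make_traj(self, per_frame_partitions, nmol=4):
        spec = SyntheticSpec(nmol=nmol, n_frames=len(per_frame_partitions),
                             partitions=per_frame_partitions, stride_ps=1000.0)
        traj, _ = plant_configuration(spec)
        return traj

    def test_planted_monomers_then_tetramer(self):
        parts = [[[0], [1], [2], [3]]] * 5 + [[[0, 1, 2, 3]]] * 5
        traj = self.make_traj(parts)
        assert list(largest_oligomer_series(traj)) == [1] * 5 + [4] * 5

    def test_single_peptide_constant_series(self):
        spec = SyntheticSpec(nmol=1, n_frames=4)
        traj, _ = plant_configuration(spec)
        assert list(largest_oligomer_series(traj)) == [1, 1, 1, 1]

    def test_pure_state_histogram(self):
        traj = self.make_traj([[[0, 1, 2, 3]]] * 4)
        hist = size_histogram(traj, window_ps=None)
        assert hist.p(4) == pytest.approx(1.0, abs=1e-12)
        assert hist.probabilities[:3] == pytest.approx([0, 0, 0], abs=1e-12)

    def test_mixture_histogram_peptide_weighted(self):
        parts = [[[0, 1], [2, 3]]] * 2 + [[[0, 1, 2, 3]]] * 2
        hist = size_histogram(self.make_traj(parts), window_ps=None)
        assert hist.p(2) == pytest.approx(0.5, abs=1e-12)
        assert hist.p(4) == pytest.approx(0.5, abs=1e-12)

    def test_mixture_histogram_cluster_weighted(self):
        parts = [[[0, 1], [2, 3]]] * 2 + [[[0, 1, 2, 3]]] * 2
        hist = size_histogram(self.make_traj(parts), window_ps=None,
                              weighting="cluster")
        # 4 dimers + 2 tetramers observed across the window
        assert hist.p(2) == pytest.approx(4 / 6, abs=1e-12)
        assert hist.p(4) == pytest.approx(2 / 6, abs=1e-12)

    def test_planted_composition_recovered_exactly(self):
        parts = ([[[0], [1], [2], [3], [4], [5]]] * 2
                 + [[[0, 1, 2], [3, 4], [5]]] * 3)
        traj = self.make_traj(parts, nmol=6)
        hist = size_histogram(traj, window_ps=None)
        # 30 peptide-frame samples: 12+3 monomers, 6 in dimers, 9 in trimers
        assert hist.p(1) == pytest.approx(15 / 30, abs=1e-12)
        assert hist.p(2) == pytest.approx(6 / 30, abs=1e-12)
        assert hist.p(3) == pytest.approx(9 / 30, abs=1e-12)
        assert hist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_histogram_sums_to_one(self):
        rng = np.random.default_rng(17)
        system, frame = random_frame(6, rng, box_l=3.0)
        traj = Trajectory(system, [frame])
        hist = size_histogram(traj, window_ps=None)
        assert hist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_short_trajectory_needs_explicit_window(self):
        traj = self.make_traj([[[0, 1, 2, 3]]] * 3)
        with pytest.raises(ValueError, match="window"):
            size_histogram(traj, window_ps=100_000.0)
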