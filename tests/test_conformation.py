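import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from surfagg.core import Box, Frame, Trajectory
from surfagg.conformation import (ReferenceDistances, backbone_dihedrals,
                                  drmsd, drmsd_histograms, load_reference,
                                  quadrant_of, ramachandran,
                                  reference_from_coordinates, torsion_angle)
from surfagg.synthetic import (ATOMS_PER_RESIDUE, SyntheticSpec, _assemble,
                               _build_backbone, build_peptide, make_system,
                               plant_configuration)

BOX = Box.solution((20.0, 20.0, 20.0))


def collinear_reference(r=7, spacing=0.38):
    coords = np.zeros((r, 3))
    coords[:, 0] = np.arange(r) * spacing
    return coords


class TestReferenceDistances:
    def test_collinear_chain_distance_pattern(self):
        ref = reference_from_coordinates(collinear_reference(), "chain")
        assert ref.n_pairs == 21
        assert len(ref.distances) == 21
        # distances are multiples of 0.38 nm: six of each separation 1..6
        seps = sorted(np.round(ref.distances / 0.38).astype(int))
        assert seps == sorted(sum(([k] * (7 - k) for k in range(1, 7)), []))
        assert np.allclose(sorted(ref.distances)[:6], [0.38] * 6, atol=1e-12)

    def test_duplicate_coordinates_rejected(self):
        coords = collinear_reference()
        coords[3] = coords[2]
        with pytest.raises(ValueError, match="duplicate"):
            reference_from_coordinates(coords, "bad")

    def test_needs_three_residues(self):
        with pytest.raises(ValueError):
            reference_from_coordinates(np.zeros((2, 3)), "tiny")

    def test_text_file_round_trip(self, tmp_path):
        ref = reference_from_coordinates(collinear_reference(), "chain")
        path = tmp_path / "ref.dat"
        path.write_text("# chain reference, nm\n" +
                        "\n".join(f"{d:.12f}" for d in ref.distances) + "\n")
        loaded = load_reference(str(path), "chain")
        assert loaded.n_residues == 7
        assert np.allclose(loaded.distances, ref.distances, atol=1e-12)


class TestDRMSD:
    def test_identity_is_zero(self):
        ca = build_peptide("beta")[2::ATOMS_PER_RESIDUE]
        ref = reference_from_coordinates(ca, "self")
        assert drmsd(ca, ref) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_and_mirror_invariance(self):
        ca = build_peptide("beta")[2::ATOMS_PER_RESIDUE]
        ref = reference_from_coordinates(ca, "self")
        rng = np.random.default_rng(13)
        for k in range(100):
            rot = Rotation.random(random_state=k).as_matrix()
            if k % 2:
                rot = rot @ np.diag([1, 1, -1.0])  # improper: mirror
            moved = ca @ rot.T + rng.uniform(-5, 5, 3)
            assert drmsd(moved, ref) == pytest.approx(0.0, abs=1e-10)

    def test_golden_value_perpendicular_displacement(self):
        """Reference: collinear 0.38 nm chain; query: last Ca displaced
        perpendicular by 0.38 nm.  Expected value from an explicit 21-pair
        sum, independent of the implementation's vectorised path."""
        ref_coords = collinear_reference()
        query = ref_coords.copy()
        query[-1, 1] += 0.38
        acc, n = 0.0, 0
        for p in range(7):
            for q in range(p + 1, 7):
                r_ref = np.linalg.norm(ref_coords[p] - ref_coords[q])
                r_qry = np.linalg.norm(query[p] - query[q])
                acc += (r_qry - r_ref) ** 2
                n += 1
        expected_a = np.sqrt(acc / n) * 10.0
        ref = reference_from_coordinates(ref_coords, "chain")
        assert n == 21
        assert drmsd(query, ref) == pytest.approx(expected_a, abs=1e-10)
        # frozen magnitude of the golden value (Angstrom)
        assert expected_a == pytest.approx(0.4430, abs=2e-4)

    def test_brute_force_agreement_random_pairs(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            a = rng.normal(scale=0.5, size=(7, 3))
            b = rng.normal(scale=0.5, size=(7, 3))
            ref = reference_from_coordinates(b, "b")
            acc = sum((np.linalg.norm(a[p] - a[q]) - np.linalg.norm(b[p] - b[q])) ** 2
                      for p in range(7) for q in range(p + 1, 7))
            assert drmsd(a, ref) == pytest.approx(np.sqrt(acc / 21) * 10, abs=1e-10)

    def test_residue_count_mismatch_rejected(self):
        ref = reference_from_coordinates(collinear_reference(), "chain")
        with pytest.raises(ValueError, match="residues"):
            drmsd(np.zeros((5, 3)), ref)

    def test_symmetry_as_pseudometric(self):
        rng = np.random.default_rng(41)
        a = rng.normal(scale=0.5, size=(7, 3))
        b = rng.normal(scale=0.5, size=(7, 3))
        dab = drmsd(a, reference_from_coordinates(b, "b"))
        dba = drmsd(b, reference_from_coordinates(a, "a"))
        assert dab == pytest.approx(dba, abs=1e-12)


class TestDRMSDHistograms:
    def test_frozen_at_reference_gives_delta_at_zero(self):
        traj, _ = plant_configuration(SyntheticSpec(nmol=2, n_frames=3))
        ca0 = traj[0].coords[traj.system.calpha_of_peptide(0)]
        ref = reference_from_coordinates(ca0, "self")
        series = drmsd_histograms(traj, [ref], window_ps=None)["self"]
        assert series.histogram[0] == pytest.approx(1.0)
        assert series.mass_below(0.1) == pytest.approx(1.0)

    def test_planted_mixture_is_bimodal(self):
        traj, _ = plant_configuration(SyntheticSpec(
            nmol=4, n_frames=2, conformations=["beta", "beta", "bent", "bent"]))
        ca_beta = traj[0].coords[traj.system.calpha_of_peptide(0)]
        ref = reference_from_coordinates(ca_beta, "beta")
        series = drmsd_histograms(traj, [ref], window_ps=None)["beta"]
        assert series.mass_below(0.5) == pytest.approx(0.5, abs=1e-12)

    def test_beta_ensemble_scores_below_1A_against_beta_reference(self):
        from surfagg.synthetic import canonical_references
        refs = list(canonical_references().values())
        beta_traj, _ = plant_configuration(
            SyntheticSpec(nmol=3, n_frames=2, noise_nm=0.01, seed=5))
        out = drmsd_histograms(beta_traj, refs, window_ps=None)
        assert out["fibril"].mass_below(1.0) > out["surface"].mass_below(1.0)
        assert out["fibril"].mass_below(1.0) > 0.9


class TestTorsionsAndRamachandran:
    def test_four_point_torsion_at_180(self):
        p = [(-1.0, 1.0, 0.0), (-1.0, 0.0, 0.0), (1.0, 0.0, 0.0), (1.0, -1.0, 0.0)]
        assert abs(torsion_angle(*p)) == pytest.approx(180.0, abs=1e-10)

    def test_matches_mdanalysis_torsions(self):
        from MDAnalysis.lib.distances import calc_dihedrals
        rng = np.random.default_rng(19)
        for _ in range(25):
            p = rng.normal(size=(4, 3))
            want = float(np.degrees(calc_dihedrals(
                p[0][None], p[1][None], p[2][None], p[3][None]))[0])
            # MDAnalysis computes in float32: compare at that precision
            assert torsion_angle(*p) == pytest.approx(want, abs=1e-4)

    def test_planted_beta_dihedrals_recovered(self):
        traj, _ = plant_configuration(SyntheticSpec(nmol=2, n_frames=1))
        for (_, phi, psi) in backbone_dihedrals(traj[0], traj.system, 0):
            assert phi == pytest.approx(-139.0, abs=1e-8)
            assert psi == pytest.approx(135.0, abs=1e-8)

    def test_planted_beta_occupies_upper_left(self):
        traj, _ = plant_configuration(SyntheticSpec(nmol=2, n_frames=2))
        density = ramachandran(traj, window_ps=None)
        assert density.quadrant_occupancy["upper_left"] == 1.0
        assert density.density.sum() == pytest.approx(1.0)

    def test_planted_alpha_occupies_lower_left(self):
        r = 7
        coords = _assemble(_build_backbone([-57.0] * r, [-47.0] * r))
        system = make_system(1)
        traj = Trajectory(system, [Frame(0.0, coords + 5.0, BOX)])
        density = ramachandran(traj, window_ps=None)
        assert density.quadrant_occupancy["lower_left"] == 1.0

    def test_gaussian_planted_dihedrals_recovered(self):
        """Analysis dihedrals equal the planted draws exactly, so the
        estimated mean matches the sample mean to numerical precision and
        the population mean within CLT error."""
        rng = np.random.default_rng(8)
        mu_phi, mu_psi, sd = -120.0, 120.0, 8.0
        r = 7
        frames, planted = [], []
        system = make_system(1)
        for i in range(40):
            phis = rng.normal(mu_phi, sd, r)
            psis = rng.normal(mu_psi, sd, r)
            coords = _assemble(_build_backbone(list(phis), list(psis)))
            frames.append(Frame(float(i), coords + 5.0, BOX))
            planted.extend((phis[k], psis[k]) for k in range(1, r - 1))
        traj = Trajectory(system, frames)
        density = ramachandran(traj, window_ps=None)
        got = density.samples
        want = np.array(planted)
        assert np.allclose(np.sort(got[:, 0]), np.sort(want[:, 0]), atol=1e-8)
        n = len(want)
        assert abs(got[:, 0].mean() - mu_phi) < 4 * sd / np.sqrt(n) + 1e-6
        assert abs(got[:, 1].mean() - mu_psi) < 4 * sd / np.sqrt(n) + 1e-6

    def test_quadrant_assignment(self):
        assert quadrant_of(-139, 135) == "upper_left"
        assert quadrant_of(-57, -47) == "lower_left"
        assert quadrant_of(60, 45) == "upper_right"
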