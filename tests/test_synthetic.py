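"""Generators: planted ground truth, determinism, infeasibility errors."""

import numpy as np
import pytest

from gpianchor.io import read_multi_gro, write_multi_gro
from gpianchor.selections import select
from gpianchor.solvation import hydration_number
from gpianchor.synthetic import (BilayerSpec, SyntheticError, TiltProcess,
                                 VonMisesMixture, build_bilayer_lattice,
                                 build_glycan_conformers,
                                 generate_clustered_ensemble,
                                 generate_tilt_trajectory, gpi_core_template,
                                 place_waters, random_templates,
                                 sample_dihedral_series)
from gpianchor.torsions import classify_rotamer


class TestBilayer:
    def test_8x8_counts(self):
        top, frame, truth = build_bilayer_lattice(BilayerSpec(), seed=0)
        resids = set(top.residue_ids.tolist())
        assert len(resids) == 128
        tops = sum(1 for v in truth["leaflets"].values() if v == "top")
        assert tops == 64

    def test_same_seed_identical(self):
        _, f1, _ = build_bilayer_lattice(BilayerSpec(), seed=3)
        _, f2, _ = build_bilayer_lattice(BilayerSpec(), seed=3)
        assert np.array_equal(f1.coordinates, f2.coordinates)

    def test_box_too_small_raises(self):
        with pytest.raises(SyntheticError, match="too small"):
            build_bilayer_lattice(BilayerSpec(nx=8, ny=8, box=(2.0, 2.0, 10.0)),
                                  seed=0)


class TestDihedralSampling:
    def test_single_component_all_gg(self):
        mix = VonMisesMixture(centers=(300.0,), kappas=(20.0,), weights=(1.0,))
        s = sample_dihedral_series(mix, 2000, seed=1)
        assert np.all(classify_rotamer(s) == "gg")

    def test_planted_weights_recovered(self):
        mix = VonMisesMixture()   # 70/25/5
        s = sample_dihedral_series(mix, 50000, seed=2)
        labels = classify_rotamer(s)
        for state, w in zip(("gg", "gt", "tg"), (0.70, 0.25, 0.05)):
            assert abs(np.mean(labels == state) - w) <= 0.015

    def test_same_seed_reproduces_exactly(self):
        mix = VonMisesMixture()
        a = sample_dihedral_series(mix, 500, seed=9)
        b = sample_dihedral_series(mix, 500, seed=9)
        assert np.array_equal(a, b)

    def test_bad_weights_rejected(self):
        with pytest.raises(SyntheticError):
            VonMisesMixture(weights=(0.5, 0.2, 0.2))


class TestGlycanConformers:
    def _assign(self, n, rng=None, value=180.0):
        tpl = gpi_core_template()
        assign = {}
        for link, ang in tpl.settable:
            vals = rng.uniform(0, 360, n) if rng is not None \
                else np.full(n, value)
            assign.setdefault(link, {})[ang] = vals
        return tpl, assign

    def test_identical_assignments_zero_rmsd(self):
        from gpianchor.clustering import pairwise_rmsd_matrix
        tpl, assign = self._assign(2)
        traj = build_glycan_conformers(tpl, assign)
        m = pairwise_rmsd_matrix(traj.coordinate_array(),
                                 np.arange(traj.topology.n_atoms))
        assert m[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_planted_mixture_survives_pipeline(self):
        from gpianchor.torsions import extract_torsions, rotamer_populations
        tpl = gpi_core_template()
        n = 5000
        assign = {}
        for link, ang in tpl.settable:
            assign.setdefault(link, {})[ang] = np.full(n, 180.0)
        omega = sample_dihedral_series(VonMisesMixture(), n, seed=4)
        assign["Man2-a16-Man1"]["omega"] = omega
        traj = build_glycan_conformers(tpl, assign)
        link = next(l for l in tpl.linkages if l.name == "Man2-a16-Man1")
        pops = rotamer_populations(extract_torsions(traj, link))
        labels = classify_rotamer(omega)
        for state in ("gg", "gt", "tg"):
            assert pops[state] == pytest.approx(
                100.0 * np.mean(labels == state), abs=1e-9)

    def test_missing_assignment_rejected(self):
        tpl, assign = self._assign(1)
        del assign["Man2-a16-Man1"]["omega"]
        with pytest.raises(SyntheticError, match="omega"):
            build_glycan_conformers(tpl, assign)

    def test_round_trips_through_multi_gro(self, tmp_path, rng):
        tpl, assign = self._assign(3, rng=rng)
        traj = build_glycan_conformers(tpl, assign)
        p = tmp_path / "glycan.multi_gro"
        write_multi_gro(traj, p)
        back = read_multi_gro(p)
        assert back.n_frames == 3
        assert np.max(np.abs(back.coordinate_array()
                             - traj.coordinate_array())) <= 0.0005


class TestPlaceWaters:
    def _solute(self):
        tpl, = [gpi_core_template()]
        assign = {}
        for link, ang in tpl.settable:
            assign.setdefault(link, {})[ang] = np.array([180.0])
        traj = build_glycan_conformers(tpl, assign, box=(8.0, 8.0, 8.0))
        return traj.topology, traj[0]

    def test_targets_met_exactly(self):
        top, frame = self._solute()
        targets = {2: 5, 4: 3, 6: 2}
        new_top, new_frame = place_waters(top, frame, targets, 20, seed=3)
        waters = select(new_top, "name OW")
        for rid, want in targets.items():
            res = select(new_top, f"resid {rid} and not role water")
            assert hydration_number(new_frame, res, waters, 0.3) == want

    def test_untargeted_residues_dry(self):
        top, frame = self._solute()
        new_top, new_frame = place_waters(top, frame, {6: 4}, 15, seed=5)
        waters = select(new_top, "name OW")
        for rid in (1, 2, 3, 4, 5):
            res = select(new_top, f"resid {rid} and not role water")
            assert hydration_number(new_frame, res, waters, 0.3) == 0

    def test_zero_targets_all_dry(self):
        top, frame = self._solute()
        new_top, new_frame = place_waters(top, frame, {}, 10, seed=1)
        waters = select(new_top, "name OW")
        for rid in range(1, 7):
            res = select(new_top, f"resid {rid} and not role water")
            assert hydration_number(new_frame, res, waters, 0.3) == 0

    def test_same_seed_identical(self):
        top, frame = self._solute()
        _, f1 = place_waters(top, frame, {2: 3}, 10, seed=8)
        _, f2 = place_waters(top, frame, {2: 3}, 10, seed=8)
        assert np.array_equal(f1.coordinates, f2.coordinates)

    def test_infeasible_packing_raises(self):
        top, frame = self._solute()
        with pytest.raises(SyntheticError, match="infeasible|exceed"):
            place_waters(top, frame, {2: 2000}, 3000, seed=0, max_tries=50)


class TestClusteredEnsemble:
    def test_label_counts_match_request(self):
        templates = random_templates(3, 15, spread=0.6, seed=1)
        ens, labels = generate_clustered_ensemble(
            templates, 0.02, (10, 7, 5), seed=2)
        assert ens.shape == (22, 15, 3)
        assert np.bincount(labels).tolist() == [10, 7, 5]

    def test_single_template_single_cluster(self):
        from gpianchor.clustering import gromos_cluster, pairwise_rmsd_matrix
        templates = random_templates(1, 10, spread=0.5, seed=3)
        ens, _ = generate_clustered_ensemble(templates, 0.01, (12,), seed=4)
        res = gromos_cluster(pairwise_rmsd_matrix(ens, np.arange(10)), 0.3)
        assert len(res.clusters) == 1

    def test_too_close_templates_rejected(self):
        t = random_templates(1, 10, spread=0.5, seed=5)
        templates = np.concatenate([t, t + 1e-4])
        with pytest.raises(SyntheticError, match="too close"):
            generate_clustered_ensemble(templates, 0.01, (5, 5), seed=6)

    def test_oversized_sigma_rejected(self):
        templates = random_templates(2, 10, spread=0.8, seed=7)
        with pytest.raises(SyntheticError, match="sigma"):
            generate_clustered_ensemble(templates, 0.06, (5, 5), seed=8,
                                        cutoff=0.3)


class TestTiltTrajectory:
    def test_construction_equals_truth(self):
        traj, truth = generate_tilt_trajectory(
            TiltProcess(80.0, 10.0, 0.5), 200, seed=1)
        from gpianchor.orientation import TiltSpec, tilt_series
        series = tilt_series(traj, TiltSpec("t", "name R1", "name R5"))
        assert np.max(np.abs(series.values - truth)) < 1e-9

    def test_constant_process(self):
        traj, truth = generate_tilt_trajectory(
            TiltProcess(80.0, 1e-9, 0.0), 50, seed=2)
        assert np.allclose(truth, 80.0, atol=1e-6)

    def test_boundary_guard(self):
        with pytest.raises(SyntheticError, match="boundary"):
            TiltProcess(mean=170.0, sd=10.0).sample(10, seed=0)

    def test_round_trips_through_multi_gro(self, tmp_path):
        traj, _ = generate_tilt_trajectory(
            TiltProcess(80.0, 10.0, 0.5), 20, seed=3)
        p = tmp_path / "rod.multi_gro"
        write_multi_gro(traj, p)
        back = read_multi_gro(p)
        assert back.n_frames == 20
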