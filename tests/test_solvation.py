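"""Hydrogen bonds, hydration counts and contact maps vs O(N^2) oracles."""

import numpy as np
import pytest

from gpianchor.selections import select
from gpianchor.solvation import (ContactMap, HBondCriterion, SolvationError,
                                 atom_contact_frequency, contact_map,
                                 find_hbonds, hbond_count_distribution,
                                 hydration_number)
from gpianchor.system import AtomSet, Frame, Topology, Trajectory


def brute_min_image_dist(a, b, box):
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                best = min(best, np.linalg.norm(
                    b + np.array([i, j, k]) * box - a))
    return best


def random_system(rng, n_res_a=3, n_res_b=3, atoms_per=3, box=2.0):
    records = []
    for r in range(n_res_a):
        records += [(f"A{i}", "GPA", r + 1) for i in range(atoms_per)]
    for r in range(n_res_b):
        records += [(f"B{i}", "GPB", n_res_a + r + 1)
                    for i in range(atoms_per)]
    top = Topology.from_records(records)
    coords = rng.uniform(0, box, size=(len(records), 3))
    return top, Frame(coords, [box, box, box])


class TestFindHbonds:
    def _donor_acceptor(self, da_dist, hda_angle_deg):
        """O-H donor at origin region plus one acceptor at the given
        distance and H-D-A angle."""
        records = [("OD", "DON", 1), ("HD", "DON", 1), ("OA", "ACC", 2)]
        top = Topology.from_records(records)
        # donor at the origin keeps the D-A distance exactly representable
        base = np.zeros(3)
        ang = np.radians(hda_angle_deg)
        coords = np.array([base,
                           base + [0.1, 0.0, 0.0],
                           base + da_dist * np.array(
                               [np.cos(ang), np.sin(ang), 0.0])])
        frame = Frame(coords, [5.0, 5.0, 5.0])
        donors = select(top, "name OD")
        acceptors = select(top, "name OA")
        return frame, donors, {0: [1]}, acceptors

    def test_detected_inside_criterion(self):
        frame, d, h, a = self._donor_acceptor(0.28, 10.0)
        assert find_hbonds(frame, d, h, a) == [(0, 1, 2)]

    def test_rejected_by_angle(self):
        frame, d, h, a = self._donor_acceptor(0.28, 40.0)
        assert find_hbonds(frame, d, h, a) == []

    def test_rejected_by_distance(self):
        frame, d, h, a = self._donor_acceptor(0.36, 10.0)
        assert find_hbonds(frame, d, h, a) == []

    def test_boundary_distance_inclusive(self):
        frame, d, h, a = self._donor_acceptor(0.35, 0.0)
        assert find_hbonds(frame, d, h, a) == [(0, 1, 2)]

    def test_donor_without_hydrogen_raises(self):
        frame, d, h, a = self._donor_acceptor(0.28, 10.0)
        with pytest.raises(SolvationError, match="hydrogen"):
            find_hbonds(frame, d, {}, a)

    def test_intra_residue_pairs_excluded(self):
        records = [("OD", "DON", 1), ("HD", "DON", 1), ("OA", "DON", 1)]
        top = Topology.from_records(records)
        coords = np.array([[1, 1, 1], [1.1, 1, 1], [1.28, 1, 1]])
        frame = Frame(coords, [5, 5, 5])
        assert find_hbonds(frame, select(top, "name OD"), {0: [1]},
                           select(top, "name OA")) == []

    def test_matches_brute_force_on_random_frames(self, rng):
        crit = HBondCriterion()
        for _ in range(30):
            records = ([("OD", "DON", i + 1) for i in range(4)] +
                       [("HD", "DON", i + 1) for i in range(4)] +
                       [("OA", "ACC", 5 + i) for i in range(6)])
            top = Topology.from_records(records)
            box = 1.2
            coords = rng.uniform(0, box, size=(14, 3))
            frame = Frame(coords, [box] * 3)
            donors = select(top, "name OD")
            hydrogens = {i: [4 + i] for i in range(4)}
            acceptors = select(top, "name OA")
            got = find_hbonds(frame, donors, hydrogens, acceptors, crit)
            want = []
            for d in range(4):
                for a in range(8, 14):
                    dv = np.array([brute_min_image_dist(
                        coords[d], coords[a], np.array([box] * 3))])
                    if dv[0] > crit.distance_cutoff:
                        continue
                    # angle via minimum-image displacement vectors
                    from gpianchor.geometry import minimum_image_displacement
                    vda = minimum_image_displacement(coords[d], coords[a],
                                                     [box] * 3)
                    vdh = minimum_image_displacement(coords[d], coords[4 + d],
                                                     [box] * 3)
                    cos = np.dot(vda, vdh) / (np.linalg.norm(vda)
                                              * np.linalg.norm(vdh))
                    if np.degrees(np.arccos(np.clip(cos, -1, 1))) <= crit.angle_cutoff:
                        want.append((d, 4 + d, a))
            assert got == sorted(want)


class TestHydration:
    def _system(self, water_positions, box=5.0):
        records = [("C1", "Ino", 1), ("C2", "Ino", 1)]
        records += [("OW", "SOL", 2 + i) for i in range(len(water_positions))]
        top = Topology.from_records(records)
        coords = np.vstack([[[1.0, 1.0, 1.0], [1.2, 1.0, 1.0]],
                            np.asarray(water_positions, float)])
        frame = Frame(coords, [box] * 3)
        return (frame, select(top, "resname Ino"),
                select(top, "name OW"))

    def test_boundary_0_3_nm(self):
        frame, res, wat = self._system([[1.0, 1.29, 1.0]])
        assert hydration_number(frame, res, wat, 0.3) == 1
        frame, res, wat = self._system([[1.0, 1.31, 1.0]])
        assert hydration_number(frame, res, wat, 0.3) == 0

    def test_oxygen_near_three_atoms_counted_once(self):
        frame, res, wat = self._system([[1.1, 1.05, 1.0]])
        assert hydration_number(frame, res, wat, 0.3) == 1

    def test_translation_invariance_modulo_box(self, rng):
        frame, res, wat = self._system(rng.uniform(0, 5, size=(20, 3)))
        base = hydration_number(frame, res, wat, 0.3)
        shift = rng.uniform(0, 5, 3)
        moved = Frame(np.mod(frame.coordinates + shift, frame.box), frame.box)
        assert hydration_number(moved, res, wat, 0.3) == base

    def test_matches_brute_force_double_loop(self, rng):
        box = np.array([1.5, 1.5, 1.5])
        for _ in range(50):
            n_w = int(rng.integers(5, 40))
            records = [("C1", "Ino", 1), ("C2", "Ino", 1), ("C3", "Ino", 1)]
            records += [("OW", "SOL", 2 + i) for i in range(n_w)]
            top = Topology.from_records(records)
            coords = rng.uniform(0, 1.5, size=(3 + n_w, 3))
            frame = Frame(coords, box)
            res = select(top, "resname Ino")
            wat = select(top, "name OW")
            got = hydration_number(frame, res, wat, 0.3)
            want = sum(
                1 for w in range(3, 3 + n_w)
                if any(brute_min_image_dist(coords[r], coords[w], box) <= 0.3
                       for r in range(3)))
            assert got == want


class TestContactMap:
    def _pair_traj(self, distances, box=5.0):
        """One A residue and one B residue, separated per frame."""
        records = [("A0", "GPA", 1), ("B0", "GPB", 2)]
        top = Topology.from_records(records)
        frames = []
        for t, d in enumerate(distances):
            coords = np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]])
            frames.append(Frame(coords, [box] * 3, time=float(t)))
        traj = Trajectory(top, frames)
        return traj, [select(top, "resname GPA", label="A")], \
            [select(top, "resname GPB", label="B")]

    def test_single_frame_inside_outside(self):
        traj, ga, gb = self._pair_traj([0.4])
        assert contact_map(traj, ga, gb, 0.5).values[0, 0] == 1.0
        traj, ga, gb = self._pair_traj([0.6])
        assert contact_map(traj, ga, gb, 0.5).values[0, 0] == 0.0

    def test_boundary_0_5_inclusive(self):
        traj, ga, gb = self._pair_traj([0.5])
        assert contact_map(traj, ga, gb, 0.5).values[0, 0] == 1.0

    def test_fraction_semantics(self):
        traj, ga, gb = self._pair_traj([0.4, 0.8])
        assert contact_map(traj, ga, gb, 0.5).values[0, 0] == 0.5

    def test_transpose_symmetry(self, rng):
        top, frame = random_system(rng)
        traj = Trajectory(top, [frame])
        ga = [select(top, f"resid {i + 1}", label=f"A{i}") for i in range(3)]
        gb = [select(top, f"resid {i + 4}", label=f"B{i}") for i in range(3)]
        ab = contact_map(traj, ga, gb, 0.5).values
        ba = contact_map(traj, gb, ga, 0.5).values
        assert np.array_equal(ab, ba.T)

    def test_monotone_in_cutoff(self, rng):
        top, frame = random_system(rng)
        traj = Trajectory(top, [frame])
        ga = [select(top, f"resid {i + 1}") for i in range(3)]
        gb = [select(top, f"resid {i + 4}") for i in range(3)]
        prev = None
        for cutoff in (0.2, 0.35, 0.5, 0.8):
            vals = contact_map(traj, ga, gb, cutoff).values
            if prev is not None:
                assert np.all(vals >= prev)
            prev = vals

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            top, frame = random_system(rng, box=1.2)
            traj = Trajectory(top, [frame])
            ga = [select(top, f"resid {i + 1}") for i in range(3)]
            gb = [select(top, f"resid {i + 4}") for i in range(3)]
            got = contact_map(traj, ga, gb, 0.5).values
            box = frame.box
            want = np.zeros((3, 3))
            for i, sa in enumerate(ga):
                for j, sb in enumerate(gb):
                    hit = any(
                        brute_min_image_dist(frame.coordinates[p],
                                             frame.coordinates[q], box) <= 0.5
                        for p in sa.indices for q in sb.indices)
                    want[i, j] = float(hit)
            assert np.array_equal(got, want)

    def test_empty_trajectory_rejected(self):
        top = Topology.from_records([("A0", "GPA", 1)])
        with pytest.raises(SolvationError):
            contact_map(Trajectory(top, []),
                        [AtomSet(top, [0])], [AtomSet(top, [0])])


class TestAtomContactFrequency:
    def test_never_and_always(self):
        records = [("A0", "GPA", 1), ("A1", "GPA", 1), ("B0", "GPB", 2)]
        top = Topology.from_records(records)
        frames = [Frame(np.array([[1, 1, 1], [3, 3, 3], [1.3, 1, 1]]),
                        [6, 6, 6], time=t) for t in range(4)]
        traj = Trajectory(top, frames)
        freq = atom_contact_frequency(traj, select(top, "resname GPA"),
                                      select(top, "resname GPB"), 0.5)
        assert freq[0] == 1.0 and freq[1] == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            top, frame = random_system(rng, box=1.2)
            traj = Trajectory(top, [frame])
            target = select(top, "resname GPA")
            probe = select(top, "resname GPB")
            got = atom_contact_frequency(traj, target, probe, 0.5)
            box = frame.box
            want = np.array([
                float(any(brute_min_image_dist(frame.coordinates[t],
                                               frame.coordinates[p], box) <= 0.5
                          for p in probe.indices))
                for t in target.indices])
            assert np.array_equal(got, want)

    def test_row_max_consistency_with_contact_map(self, rng):
        top, frame = random_system(rng, box=1.2)
        traj = Trajectory(top, [frame])
        ga = [select(top, f"resid {i + 1}") for i in range(3)]
        probe = select(top, "resname GPB")
        gb = [probe]
        cm = contact_map(traj, ga, gb, 0.5)
        for i, sa in enumerate(ga):
            freq = atom_contact_frequency(traj, sa, probe, 0.5)
            assert freq.max() == pytest.approx(cm.values[i].max())


class TestHbondDistribution:
    def test_planted_two_bonds_every_frame(self):
        records = [("OD", "DON", 1), ("HD", "DON", 1),
                   ("OA", "ACC", 2), ("OB", "ACC", 3)]
        top = Topology.from_records(records)
        base = np.array([1.0, 1.0, 1.0])
        coords = np.array([base, base + [0.1, 0, 0],
                           base + [0.28, 0.02, 0], base + [0.28, -0.02, 0]])
        frames = [Frame(coords, [5, 5, 5], time=t) for t in range(5)]
        traj = Trajectory(top, frames)
        dist = hbond_count_distribution(
            traj, select(top, "resid 1"), select(top, "resname ACC"),
            select(top, "name OD"), {0: [1]}, select(top, "resname ACC"))
        assert list(dist["count"]) == [2]
        assert dist["probability"].iloc[0] == 1.0

    def test_no_polar_partner_all_zero(self):
        records = [("OD", "DON", 1), ("HD", "DON", 1), ("OA", "ACC", 2)]
        top = Topology.from_records(records)
        coords = np.array([[1, 1, 1], [1.1, 1, 1], [3, 3, 3]])
        traj = Trajectory(top, [Frame(coords, [5, 5, 5])])
        dist = hbond_count_distribution(
            traj, select(top, "resid 1"), select(top, "resname ACC"),
            select(top, "name OD"), {0: [1]}, select(top, "resname ACC"))
        assert list(dist["count"]) == [0]

    def test_empty_partner_rejected(self):
        records = [("OD", "DON", 1), ("HD", "DON", 1)]
        top = Topology.from_records(records)
        traj = Trajectory(top, [Frame(np.array([[1, 1, 1], [1.1, 1, 1]]),
                                      [5, 5, 5])])
        with pytest.raises(SolvationError, match="empty"):
            hbond_count_distribution(
                traj, select(top, "resid 1"), select(top, "name XX"),
                select(top, "name OD"), {0: [1]}, select(top, "name OD"))
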