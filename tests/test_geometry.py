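"""Superposition, center-of-mass distances and rotamer flexibility."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ifacedyn.geometry import (
    center_of_mass,
    com_distance_series,
    dihedral_angle,
    kabsch_superpose,
    place_internal,
    rotamer_flexibility,
)
from ifacedyn.structio import DomainSelection, StructureModel, Trajectory, make_atom


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-9)
        assert res.rmsd <= 1e-9

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(12, 3))
        r0 = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = pts @ r0.T + np.array([1.0, -2.0, 3.0])
        res = kabsch_superpose(pts, moved)
        np.testing.assert_allclose(res.rotation, r0, atol=1e-6)
        assert res.rmsd <= 1e-6

    def test_rotation_always_proper(self, rng):
        # near-planar configurations must not yield reflections
        for _ in range(20):
            pts = rng.normal(size=(8, 3)) * np.array([1.0, 1.0, 1e-4])
            ref = rng.normal(size=(8, 3))
            res = kabsch_superpose(pts, ref)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_invariant_under_common_rigid_transform(self, rng):
        mob = rng.normal(size=(10, 3))
        ref = mob + rng.normal(0, 0.2, size=(10, 3))
        base = kabsch_superpose(mob, ref).rmsd
        for _ in range(10):
            rot = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            t = rng.normal(size=3)
            moved = kabsch_superpose(mob @ rot.T + t, ref @ rot.T + t).rmsd
            assert moved == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_weighted_fit_uses_weights(self, rng):
        mob = rng.normal(size=(6, 3))
        ref = mob.copy()
        ref[0] += 5.0  # outlier
        heavy_on_rest = np.array([1e-6] + [1.0] * 5)
        res = kabsch_superpose(mob, ref, weights=heavy_on_rest)
        # fit should ignore the outlier: remaining points map almost exactly
        fitted = res.apply(mob)
        assert np.abs(fitted[1:] - ref[1:]).max() < 1e-3


def atom_line(serial, name, res_seq, coord, chain="A", res="ALA"):
    return make_atom(serial, name, res, chain, res_seq, coord)


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        m = StructureModel([atom_line(1, "C", 1, (0, 0, 0)), atom_line(2, "C", 2, (2, 0, 0))])
        np.testing.assert_allclose(center_of_mass(m), [1, 0, 0])

    def test_mass_weighting(self):
        # carbon (12.011) at x=0 and 3 carbons' worth at x=4 via sulfur-free trick:
        # use explicit masses 12.011 vs 3*12.011 by three stacked atoms
        atoms = [atom_line(1, "C", 1, (0, 0, 0))]
        atoms += [atom_line(2 + i, f"C{i+1}" if i else "C", 2 + i, (4, 0, 0)) for i in range(3)]
        m = StructureModel(atoms)
        assert center_of_mass(m)[0] == pytest.approx(3.0)

    def test_matches_direct_summation(self, toy_complex, toy_layout):
        sub_sel = toy_layout.dom_a
        com = center_of_mass(toy_complex, sub_sel)
        masses, coords = [], []
        for a in toy_complex.atoms:
            if sub_sel.contains(a) and not a.is_hydrogen:
                masses.append(a.mass)
                coords.append(a.coord)
        expected = np.einsum("i,ij->j", masses, np.array(coords)) / np.sum(masses)
        np.testing.assert_allclose(com, expected, atol=1e-9)

    def test_hydrogens_excluded_by_default(self):
        m = StructureModel([atom_line(1, "C", 1, (0, 0, 0)), atom_line(2, "H", 1, (9, 9, 9))])
        np.testing.assert_allclose(center_of_mass(m), [0, 0, 0])


def two_body_trajectory(distances, dt=0.002):
    frames = []
    for t, d in enumerate(distances):
        frames.append(StructureModel([
            atom_line(1, "C", 1, (0.0, 0.0, 0.0), chain="A"),
            atom_line(2, "C", 1, (float(d), 0.0, 0.0), chain="B"),
        ], model_id=t))
    return Trajectory(frames, dt=dt)


class TestComDistanceSeries:
    dom_a = DomainSelection("A", 1, 1)
    dom_b = DomainSelection("B", 1, 1)

    def test_static_trajectory_constant(self):
        traj = two_body_trajectory([5.0] * 8)
        s = com_distance_series(traj, self.dom_a, self.dom_b)
        assert s.sd == 0.0 and s.mean == pytest.approx(5.0)

    def test_generator_parameter_recovery(self, rng):
        d = rng.normal(30.0, 0.3, size=500)
        s = com_distance_series(two_body_trajectory(d), self.dom_a, self.dom_b)
        assert s.mean == pytest.approx(30.0, abs=0.05)

    def test_permutation_invariance(self, rng):
        d = rng.normal(30.0, 0.5, size=50)
        s1 = com_distance_series(two_body_trajectory(d), self.dom_a, self.dom_b)
        s2 = com_distance_series(two_body_trajectory(d[::-1]), self.dom_a, self.dom_b)
        assert s1.mean == pytest.approx(s2.mean, abs=1e-12)
        assert s1.sd == pytest.approx(s2.sd, abs=1e-12)

    def test_summary_consistent_with_values(self, rng):
        d = rng.normal(30.0, 0.5, size=64)
        s = com_distance_series(two_body_trajectory(d), self.dom_a, self.dom_b)
        assert s.mean == pytest.approx(float(np.mean(s.values)), abs=1e-12)
        assert s.sd == pytest.approx(float(np.std(s.values, ddof=1)), abs=1e-12)


class TestRotamerFlexibility:
    def build_residue_frames(self, rng, n_frames, sigma, rigid_transforms=False):
        """One Arg-bearing mini-chain; optional rigid motion and side-chain noise."""
        from ifacedyn.mutate import build_side_chain

        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.458, 0.0, 0.0])
        c = np.array([2.0, 1.4, 0.0])
        side = build_side_chain("ARG", n, ca, c, (-60.0, 180.0, 180.0, 180.0))
        atoms = [atom_line(1, "N", 281, n, res="ARG"), atom_line(2, "CA", 281, ca, res="ARG"),
                 atom_line(3, "C", 281, c, res="ARG")]
        atoms += [atom_line(4 + i, nm, 281, xyz, res="ARG") for i, (nm, xyz) in enumerate(side)]
        # alignment anchors: extra CA atoms on other residues
        anchors = [atom_line(20 + i, "CA", 300 + i, np.array(xyz))
                   for i, xyz in enumerate([(6, 0, 0), (0, 6, 0), (0, 0, 6), (6, 6, 0)])]
        base = StructureModel(atoms + anchors)
        side_names = {nm for nm, _ in side}
        frames = [base]
        for t in range(1, n_frames):
            coords = base.coords.copy()
            if sigma > 0:
                for i, a in enumerate(base.atoms):
                    if a.name in side_names:
                        coords[i] += rng.normal(0, sigma, 3)
            if rigid_transforms:
                rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
                coords = coords @ rot.T + rng.normal(size=3)
            frames.append(base.with_coords(coords, model_id=t))
        return Trajectory(frames, dt=0.1), len(side_names)

    def test_rigid_motion_removed_by_superposition(self, rng):
        traj, _ = self.build_residue_frames(rng, 6, sigma=0.0, rigid_transforms=True)
        s = rotamer_flexibility(traj, DomainSelection("A", 281, 281))
        assert s.values[0] == 0.0
        np.testing.assert_allclose(s.values, 0.0, atol=1e-9)

    def test_matches_monte_carlo_expectation(self, rng):
        """Isotropic per-atom jitter: mean RMSD within 15% of an MC oracle."""
        sigma = 0.4
        traj, n_side = self.build_residue_frames(rng, 200, sigma=sigma)
        s = rotamer_flexibility(traj, DomainSelection("A", 281, 281))
        # independent oracle: E[sqrt(mean_k |eps_k|^2)] by direct simulation
        oracle_rng = np.random.default_rng(99)
        draws = oracle_rng.normal(0, sigma, size=(20000, n_side, 3))
        expected = np.sqrt((draws ** 2).sum(axis=2).mean(axis=1)).mean()
        assert s.mean_rmsd == pytest.approx(expected, rel=0.15)

    def test_higher_jitter_larger_rmsd(self, rng):
        lo, _ = self.build_residue_frames(np.random.default_rng(7), 30, sigma=0.1)
        hi, _ = self.build_residue_frames(np.random.default_rng(7), 30, sigma=0.5)
        sel = DomainSelection("A", 281, 281)
        assert rotamer_flexibility(hi, sel).mean_rmsd > rotamer_flexibility(lo, sel).mean_rmsd


class TestDihedral:
    def test_roundtrip_with_placement(self, rng):
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 3))
            tor = float(rng.uniform(-179.9, 180))
            d = place_internal(a, b, c, 1.5, 109.0, tor)
            got = dihedral_angle(a, b, c, d)
            assert (got - tor + 180) % 360 - 180 == pytest.approx(0.0, abs=1e-7)

    def test_against_independent_formula(self, rng):
        """Cross-check against the normal-vector arccos formula with signed volume."""
        def oracle(p0, p1, p2, p3):
            n1 = np.cross(p1 - p0, p2 - p1)
            n2 = np.cross(p2 - p1, p3 - p2)
            cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            sign = math.copysign(1.0, np.dot(np.cross(n1, n2), p2 - p1))
            return sign * ang

        for _ in range(100):
            pts = rng.normal(size=(4, 3))
            got = dihedral_angle(*pts)
            want = oracle(*pts)
            assert (got - want + 180) % 360 - 180 == pytest.approx(0.0, abs=1e-9)
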