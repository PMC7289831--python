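"""Surface areas, buried interface area and contact detection."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ifacedyn.interface import (
    buried_area,
    buried_area_series,
    contact_diff,
    detect_contacts,
    sasa,
    sphere_points,
    timepoint_indices,
)
from ifacedyn.structio import DomainSelection, StructureModel, Trajectory, make_atom


def carbon(serial, res_seq, coord, chain="A", name="C", res="ALA"):
    return make_atom(serial, name, res, chain, res_seq, coord)


def two_sphere_closed_form(d, r1, r2):
    """Exact accessible area of two intersecting expanded spheres."""
    total = 0.0
    for r, other in ((r1, r2), (r2, r1)):
        if d >= r + other:
            total += 4 * math.pi * r * r
            continue
        x = (d * d + r * r - other * other) / (2 * d)
        cap = 2 * math.pi * r * (r - x)
        total += 4 * math.pi * r * r - cap
    return total


class TestSasa:
    def test_isolated_atom_analytic(self):
        m = StructureModel([carbon(1, 1, (0, 0, 0))])
        r = sasa(m, probe_radius=1.4, n_points=960)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert r.total == pytest.approx(analytic, rel=0.005)
        assert r.total == pytest.approx(sum(r.per_residue.values()), abs=1e-6)

    def test_fully_caged_atom_zero(self):
        # icosahedral cage at 2.0 A: every lattice point of the central atom
        # falls inside a neighbour's expanded sphere
        phi = (1 + math.sqrt(5)) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [(0, a, b), (a, b, 0), (b, 0, a)]
        verts = 2.0 * np.array(verts) / np.linalg.norm(verts[0])
        atoms = [carbon(1, 1, (0, 0, 0))]
        atoms += [carbon(2 + i, 2 + i, v) for i, v in enumerate(verts)]
        r = sasa(StructureModel(atoms), 1.4, 960)
        assert r.per_atom[0] == 0.0

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5, 6.0])
    def test_two_sphere_closed_form(self, d):
        m = StructureModel([carbon(1, 1, (0, 0, 0)), carbon(2, 2, (d, 0, 0))])
        got = sasa(m, 1.4, 960).total
        want = two_sphere_closed_form(d, 3.1, 3.1)
        assert got == pytest.approx(want, rel=0.01)

    def test_monotone_under_added_neighbours(self):
        center = carbon(1, 1, (0, 0, 0))
        neighbours = [(3.0, 0, 0), (0, 3.0, 0), (0, 0, 3.0), (-3.0, 0, 0)]
        prev = math.inf
        for k in range(len(neighbours) + 1):
            atoms = [center] + [carbon(2 + i, 2 + i, v) for i, v in enumerate(neighbours[:k])]
            area = sasa(StructureModel(atoms), 1.4, 960).per_atom[0]
            assert area <= prev + 1e-9
            prev = area

    def test_quadrature_convergence(self):
        m = StructureModel([carbon(1, 1, (0, 0, 0)), carbon(2, 2, (2.5, 0, 0))])
        a1 = sasa(m, 1.4, 960).total
        a2 = sasa(m, 1.4, 1920).total
        assert abs(a2 - a1) / a1 < 0.003

    def test_lattice_is_deterministic_and_unit(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, sphere_points(960))


class TestBuriedArea:
    dom_a = DomainSelection("A", 1, 5)
    dom_b = DomainSelection("B", 1, 5)

    def dimer(self, gap):
        atoms = [carbon(i + 1, i + 1, (i * 1.8, 0, 0), chain="A") for i in range(5)]
        atoms += [carbon(6 + i, i + 1, (i * 1.8, gap, 0), chain="B") for i in range(5)]
        return StructureModel(atoms)

    def test_separated_domains_zero(self):
        # beyond 2*(r_max + probe) no occlusion is possible
        m = self.dimer(gap=2 * (1.7 + 1.4) + 1.0)
        assert buried_area(m, self.dom_a, self.dom_b) == 0.0

    def test_symmetric_under_domain_swap(self):
        m = self.dimer(gap=4.0)
        b1 = buried_area(m, self.dom_a, self.dom_b)
        b2 = buried_area(m, self.dom_b, self.dom_a)
        assert b1 == pytest.approx(b2, abs=1e-9)
        assert b1 > 0

    def test_overlapping_selections_rejected(self):
        m = self.dimer(gap=4.0)
        with pytest.raises(ValueError):
            buried_area(m, self.dom_a, DomainSelection("A", 3, 5))

    def test_matches_refined_lattice(self):
        m = self.dimer(gap=4.0)
        coarse = buried_area(m, self.dom_a, self.dom_b, n_points=960)
        fine = buried_area(m, self.dom_a, self.dom_b, n_points=3840)
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_series_static_trajectory(self):
        m = self.dimer(gap=4.0)
        traj = Trajectory([m.with_coords(m.coords, model_id=i) for i in range(10)], dt=0.1)
        s = buried_area_series(traj, self.dom_a, self.dom_b, n_timepoints=10, n_points=240)
        assert len(s.values) == 10
        np.testing.assert_allclose(s.values, s.values[0])
        assert s.mean == pytest.approx(s.values[0])

    def test_larger_separation_smaller_area(self):
        near = buried_area(self.dimer(4.0), self.dom_a, self.dom_b, n_points=480)
        far = buried_area(self.dimer(5.2), self.dom_a, self.dom_b, n_points=480)
        assert far < near

    def test_timepoint_spacing_rule(self):
        assert timepoint_indices(500, 10) == [0, 55, 111, 166, 222, 277, 333, 388, 444, 499]
        assert timepoint_indices(10, 10) == list(range(10))
        with pytest.raises(ValueError):
            timepoint_indices(5, 10)


def minimal_pair(dist, name_a="NH1", res_a="ARG", name_b="OD1", res_b="ASP"):
    return StructureModel([
        make_atom(1, name_a, res_a, "A", 1, (0.0, 0.0, 0.0)),
        make_atom(2, name_b, res_b, "B", 2, (dist, 0.0, 0.0)),
    ])


class TestContacts:
    dom_a = DomainSelection("A", 1, 1)
    dom_b = DomainSelection("B", 2, 2)

    def test_salt_bridge_within_threshold(self):
        recs = detect_contacts(minimal_pair(3.2), self.dom_a, self.dom_b)
        assert len(recs) == 1
        assert recs[0].kind == "saltbridge"
        assert recs[0].distance == pytest.approx(3.2)

    def test_salt_bridge_beyond_threshold_absent(self):
        assert detect_contacts(minimal_pair(4.5), self.dom_a, self.dom_b) == []

    def test_salt_pair_not_duplicated_as_hbond(self):
        recs = detect_contacts(minimal_pair(3.2), self.dom_a, self.dom_b)
        assert [r.kind for r in recs] == ["saltbridge"]

    def test_hydroxyl_hbond(self):
        m = minimal_pair(3.3, name_a="OG", res_a="SER", name_b="O", res_b="ALA")
        recs = detect_contacts(m, self.dom_a, self.dom_b)
        assert [r.kind for r in recs] == ["hbond"]
        assert detect_contacts(minimal_pair(3.6, "OG", "SER", "O", "ALA"),
                               self.dom_a, self.dom_b) == []

    def test_carbon_pairs_ignored(self):
        m = minimal_pair(3.0, name_a="CB", res_a="ALA", name_b="CB", res_b="ALA")
        assert detect_contacts(m, self.dom_a, self.dom_b) == []

    def test_hydrogen_angle_criterion(self):
        # donor H pointing away from the acceptor kills the bond
        base = [
            make_atom(1, "OG", "SER", "A", 1, (0.0, 0.0, 0.0)),
            make_atom(2, "O", "ALA", "B", 2, (3.2, 0.0, 0.0)),
        ]
        h_toward = make_atom(3, "HG", "SER", "A", 1, (0.95, 0.0, 0.0))
        h_away = make_atom(3, "HG", "SER", "A", 1, (-0.95, 0.0, 0.0))
        with_toward = StructureModel(base + [h_toward])
        with_away = StructureModel(base + [h_away])
        assert len(detect_contacts(with_toward, self.dom_a, self.dom_b)) == 1
        assert detect_contacts(with_away, self.dom_a, self.dom_b) == []

    def test_invariant_under_rigid_transform(self, toy_complex, toy_layout, rng):
        before = detect_contacts(toy_complex, toy_layout.dom_a, toy_layout.dom_b)
        rot = Rotation.random(random_state=5).as_matrix()
        moved = toy_complex.with_coords(toy_complex.coords @ rot.T + np.array([10.0, -3.0, 7.0]))
        after = detect_contacts(moved, toy_layout.dom_a, toy_layout.dom_b)
        assert [(r.kind, r.atom_a, r.atom_b) for r in before] == \
               [(r.kind, r.atom_a, r.atom_b) for r in after]
        np.testing.assert_allclose([r.distance for r in before],
                                   [r.distance for r in after], atol=1e-9)


class TestContactDiff:
    def test_identical_lists_empty_diff(self):
        recs = detect_contacts(minimal_pair(3.2), DomainSelection("A", 1, 1),
                               DomainSelection("B", 2, 2))
        d = contact_diff(recs, recs)
        assert d.lost == [] and d.gained == []
        assert len(d.retained) == 1

    def test_lost_salt_bridge(self):
        sel_a, sel_b = DomainSelection("A", 1, 1), DomainSelection("B", 2, 2)
        wt = detect_contacts(minimal_pair(3.2), sel_a, sel_b)
        mut = detect_contacts(minimal_pair(4.5), sel_a, sel_b)
        d = contact_diff(wt, mut)
        assert len(d.lost) == 1 and d.lost[0][0] == "saltbridge"

    def test_disjoint_lists(self):
        sel_a, sel_b = DomainSelection("A", 1, 1), DomainSelection("B", 2, 2)
        wt = detect_contacts(minimal_pair(3.2), sel_a, sel_b)
        mut = detect_contacts(minimal_pair(3.3, "OG", "SER", "O", "ALA"), sel_a, sel_b)
        d = contact_diff(wt, mut)
        assert len(d.lost) == 1 and len(d.gained) == 1 and d.retained == []
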