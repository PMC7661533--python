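import itertools

import numpy as np
import pytest

from capsidkit.interfaces import (
    axis_neighborhood_report,
    buried_surface_area,
    capsid_buried_area,
    contact_network,
    shrake_rupley_sasa,
    sphere_spiral_points,
)
from capsidkit.structure_io import StructureModel
from capsidkit.synthetic_data import make_interface_fixture

from conftest import make_atom

ISOLATED_CARBON_SASA = 4.0 * np.pi * (1.7 + 1.4) ** 2  # 120.76 Å²


class TestSpiralPoints:
    def test_unit_norm(self):
        pts = sphere_spiral_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_deterministic(self):
        np.testing.assert_array_equal(sphere_spiral_points(96), sphere_spiral_points(96))

    def test_centroid_near_origin(self):
        assert np.linalg.norm(sphere_spiral_points(960).mean(axis=0)) < 1e-2


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        result = shrake_rupley_sasa([make_atom()])
        assert result.total == pytest.approx(ISOLATED_CARBON_SASA, rel=0.01)

    def test_distant_pair_unoccluded(self):
        atoms = [make_atom(serial=1), make_atom(serial=2, position=(10.0, 0, 0))]
        result = shrake_rupley_sasa(atoms)
        for area in result.per_atom_area:
            assert area == pytest.approx(ISOLATED_CARBON_SASA, rel=0.01)

    def test_two_sphere_cap_formula(self):
        fx = make_interface_fixture("two_spheres", radius_a=5.0, radius_b=8.0, distance=12.0)
        measured = buried_surface_area(
            fx.set_a, fx.set_b, probe=fx.probe, radii_table=fx.radii_table, n_points=2000
        )
        assert measured == pytest.approx(fx.expected_bsa, rel=fx.tolerance)

    def test_total_equals_sum(self):
        atoms = [make_atom(serial=i, position=(i * 2.0, 0, 0)) for i in range(5)]
        result = shrake_rupley_sasa(atoms)
        assert result.total == pytest.approx(float(result.per_atom_area.sum()), abs=1e-6)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="Qq"):
            shrake_rupley_sasa([make_atom(element="Qq")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa([])

    def test_occluders_never_increase_area(self):
        rng = np.random.default_rng(11)
        base = [make_atom(serial=i, position=p) for i, p in enumerate(rng.normal(size=(8, 3)) * 3)]
        before = shrake_rupley_sasa(base).per_atom_area
        extra = base + [make_atom(serial=99, position=(1.0, 1.0, 1.0))]
        after = shrake_rupley_sasa(extra).per_atom_area[: len(base)]
        assert np.all(after <= before + 1e-9)

    def test_point_doubling_convergence(self):
        rng = np.random.default_rng(4)
        atoms = [make_atom(serial=i, position=p) for i, p in enumerate(rng.normal(size=(20, 3)) * 4)]
        coarse = shrake_rupley_sasa(atoms, n_points=960).total
        fine = shrake_rupley_sasa(atoms, n_points=1920).total
        assert abs(fine - coarse) / fine < 0.01

    def test_determinism(self):
        atoms = [make_atom(serial=i, position=(i * 1.8, 0.2 * i, 0)) for i in range(6)]
        one = shrake_rupley_sasa(atoms).per_atom_area
        two = shrake_rupley_sasa(atoms).per_atom_area
        np.testing.assert_array_equal(one, two)


class TestBuriedArea:
    def test_far_apart_is_zero(self):
        a = [make_atom(serial=1)]
        b = [make_atom(serial=2, position=(50.0, 0, 0))]
        assert buried_surface_area(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        a = [make_atom(serial=1)]
        b = [make_atom(serial=2, position=(3.0, 0, 0))]
        assert buried_surface_area(a, b) == buried_surface_area(b, a)

    def test_overlapping_sets_rejected(self):
        shared = make_atom()
        with pytest.raises(ValueError, match="disjoint"):
            buried_surface_area([shared], [shared])

    def test_two_slab_planar_interface(self):
        fx = make_interface_fixture("two_slabs")
        measured = buried_surface_area(
            fx.set_a, fx.set_b, probe=fx.probe, radii_table=fx.radii_table, n_points=480
        )
        assert measured == pytest.approx(fx.expected_bsa, rel=fx.tolerance)


class TestCapsidBuriedArea:
    def test_non_contacting_au_is_zero(self, icos_ops):
        # a tight cluster well inside a fundamental wedge (>90 Å from any
        # symmetry image at this radius): no copy touches another
        anchor = 200.0 * np.array([0.16285, -0.18299, -0.96953])
        au = StructureModel(
            atoms=[make_atom(serial=i, position=anchor + np.array([dx, 0.0, 0.0]))
                   for i, dx in enumerate((0.0, 1.5))]
        )
        assert capsid_buried_area(au, icos_ops) == pytest.approx(0.0, abs=1e-9)

    def test_total_mode_scales_by_30(self, icos_ops):
        au = StructureModel(
            atoms=[make_atom(serial=1, position=(0.0, 0.0, 60.0)),
                   make_atom(serial=2, position=(2.0, 0.0, 60.0))]
        )
        per_au = capsid_buried_area(au, icos_ops, mode="per_asym_unit_neighbors", n_points=240)
        total = capsid_buried_area(au, icos_ops, mode="total", n_points=240)
        assert total == pytest.approx(per_au * 30.0, rel=1e-9)

    def test_unknown_mode(self, icos_ops):
        au = StructureModel(atoms=[make_atom()])
        with pytest.raises(ValueError, match="mode"):
            capsid_buried_area(au, icos_ops, mode="bogus")


class TestContactNetwork:
    def test_single_edge_min_distance(self):
        res_a = [make_atom(serial=1, res_seq=1, chain_id="A", position=(0, 0, 0)),
                 make_atom(serial=2, name="CB", res_seq=1, chain_id="A", position=(1.0, 0, 0))]
        res_b = [make_atom(serial=3, res_seq=2, chain_id="B", position=(4.5, 0, 0))]
        edges = contact_network(None, res_a, res_b, cutoff=4.0)
        assert len(edges) == 1
        assert edges[0].min_distance == pytest.approx(3.5)
        assert edges[0].n_atom_pairs == 1

    def test_cutoff_zero_empty(self):
        a = [make_atom(serial=1)]
        b = [make_atom(serial=2, position=(1.0, 0, 0))]
        assert contact_network(None, a, b, cutoff=0.0) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        group_a, group_b = [], []
        for i in range(400):
            group_a.append(make_atom(serial=i, chain_id="A", res_seq=i // 4,
                                     position=rng.uniform(0, 30, size=3)))
        for i in range(400):
            group_b.append(make_atom(serial=1000 + i, chain_id="B", res_seq=i // 4,
                                     position=rng.uniform(0, 30, size=3)))
        cutoff = 4.0
        edges = contact_network(None, group_a, group_b, cutoff=cutoff)
        # exhaustive oracle
        brute: dict = {}
        for a, b in itertools.product(group_a, group_b):
            d = float(np.linalg.norm(a.position - b.position))
            if d <= cutoff:
                key = ((a.chain_id, a.res_seq, a.res_name), (b.chain_id, b.res_seq, b.res_name))
                prev = brute.get(key)
                brute[key] = (min(prev[0], d), prev[1] + 1) if prev else (d, 1)
        assert len(edges) == len(brute)
        for edge in edges:
            expected_d, expected_n = brute[(edge.residue_a, edge.residue_b)]
            assert edge.min_distance == pytest.approx(expected_d, abs=1e-9)
            assert edge.n_atom_pairs == expected_n


class TestAxisNeighborhood:
    def test_five_fold_dominated_by_planted_chain(self, icos_ops):
        from capsidkit.icosahedral_symmetry import find_axes

        five = next(a for a in find_axes(icos_ops) if a.order == 5)
        three = next(a for a in find_axes(icos_ops) if a.order == 3)
        au = StructureModel(atoms=[
            make_atom(serial=1, chain_id="X", position=five.direction * 100.0),
            make_atom(serial=2, chain_id="Y", position=three.direction * 100.0),
        ])
        report = axis_neighborhood_report(au, icos_ops, radius_shell=10.0)
        assert report[5][0][0] == "X"
        assert report[3][0][0] == "Y"

    def test_empty_neighborhoods(self, icos_ops):
        # single atom nowhere near any axis within a tight shell radius
        au = StructureModel(atoms=[make_atom(position=(100.0, 43.0, 27.0))])
        report = axis_neighborhood_report(au, icos_ops, radius_shell=0.5)
        assert all(entries == [] for entries in report.values())
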