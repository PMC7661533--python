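import numpy as np
import pytest

from capsidkit.capsid_geometry import (
    build_geometry_report,
    inner_outer_radius,
    radial_profile,
    sphere_inner_volume,
    volume_per_nucleotide,
    voxel_cavity_volume,
)
from capsidkit.structure_io import StructureModel
from capsidkit.synthetic_data import ShellSpec, make_shell_capsid

from conftest import make_atom

# Comparative reference rows: (inner diameter nm, raw genome nt, printed
# inner volume 1e3 nm3, printed volume per nt nm3)
REFERENCE_ROWS = [
    ("nora", 24.2, 12333, 7.4, 0.59),
    ("triatoma", 22.8, 9010, 6.2, 0.67),
    ("iapv", 22.8, 9487, 6.2, 0.64),
    ("crpv", 21.6, 9185, 5.3, 0.56),
    ("cva9", 19.6, 7400, 3.9, 0.52),
]


class TestRadialProfile:
    def test_shell_extents(self, small_shell_expanded, small_shell):
        profile = radial_profile(small_shell_expanded, center=np.zeros(3))
        truth = small_shell.ground_truth
        assert profile.r_min == pytest.approx(truth.r_min, abs=1e-9)
        assert profile.r_max == pytest.approx(truth.r_max, abs=1e-9)
        assert profile.r_min >= truth.inner_radius - 1e-9
        assert profile.r_max <= truth.outer_radius + 1e-9

    def test_counts_conserved(self, small_shell_expanded):
        profile = radial_profile(small_shell_expanded)
        assert int(profile.counts.sum()) == len(small_shell_expanded.atoms)

    def test_single_atom_at_center(self):
        model = StructureModel(atoms=[make_atom(position=(0, 0, 0))])
        profile = radial_profile(model, center=np.zeros(3))
        assert profile.r_min == 0.0
        assert profile.r_max == 0.0

    def test_bad_bin_width(self, tiny_model):
        with pytest.raises(ValueError, match="bin_width"):
            radial_profile(tiny_model, bin_width=0.0)


class TestInnerOuterRadius:
    def test_shell_defaults_recover_radii(self, small_shell_expanded):
        profile = radial_profile(small_shell_expanded, center=np.zeros(3))
        inner, outer = inner_outer_radius(profile)
        assert inner == pytest.approx(100.0, abs=2.0)
        assert outer == pytest.approx(130.0, abs=2.0)
        assert outer - inner == pytest.approx(30.0, abs=2.0)

    def test_single_radius(self):
        atoms = [
            make_atom(serial=i, position=(50.0 * np.cos(t), 50.0 * np.sin(t), 0.0))
            for i, t in enumerate(np.linspace(0, 2 * np.pi, 20, endpoint=False))
        ]
        profile = radial_profile(StructureModel(atoms=atoms), center=np.zeros(3))
        inner, outer = inner_outer_radius(profile)
        assert inner == pytest.approx(50.0, abs=1e-9)
        assert outer == pytest.approx(50.0, abs=1e-9)

    def test_extreme_percentiles_exact(self, small_shell_expanded):
        profile = radial_profile(small_shell_expanded, center=np.zeros(3))
        inner, outer = inner_outer_radius(profile, inner_pct=0, outer_pct=100)
        assert inner == pytest.approx(profile.r_min, abs=1e-9)
        assert outer == pytest.approx(profile.r_max, abs=1e-9)

    def test_bad_percentiles(self, small_shell_expanded):
        profile = radial_profile(small_shell_expanded)
        with pytest.raises(ValueError):
            inner_outer_radius(profile, inner_pct=50, outer_pct=10)


class TestSphereVolume:
    @pytest.mark.parametrize(
        "label,diameter,_nt,volume,_vpn", REFERENCE_ROWS,
        ids=[r[0] for r in REFERENCE_ROWS],
    )
    def test_reference_inner_volumes(self, label, diameter, _nt, volume, _vpn):
        assert round(sphere_inner_volume(diameter), 1) == volume

    def test_zero(self):
        assert sphere_inner_volume(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sphere_inner_volume(-1.0)

    def test_cubic_scaling(self):
        assert sphere_inner_volume(20.0) == pytest.approx(
            8.0 * sphere_inner_volume(10.0), rel=1e-12
        )

    def test_strictly_increasing(self):
        diameters = np.linspace(0.1, 40, 50)
        volumes = [sphere_inner_volume(d) for d in diameters]
        assert all(b > a for a, b in zip(volumes, volumes[1:]))


class TestVolumePerNucleotide:
    @pytest.mark.parametrize(
        "label,diameter,genome_nt,_vol,expected", REFERENCE_ROWS,
        ids=[r[0] for r in REFERENCE_ROWS],
    )
    def test_reference_values(self, label, diameter, genome_nt, _vol, expected):
        volume = sphere_inner_volume(diameter)
        assert round(volume_per_nucleotide(volume, genome_nt), 2) == expected

    def test_zero_volume(self):
        assert volume_per_nucleotide(0.0, 1000) == 0.0

    def test_bad_genome(self):
        with pytest.raises(ValueError):
            volume_per_nucleotide(1.0, 0)

    def test_recovers_inner_volume(self):
        volume = sphere_inner_volume(24.2)
        vpn = volume_per_nucleotide(volume, 12333)
        assert vpn * (12333 + 200) == pytest.approx(volume * 1000.0, rel=1e-12)


class TestVoxelCavity:
    def test_dense_shell_matches_analytic_sphere(self, dense_shell_expanded):
        atom_radius = 4.0
        cavity = voxel_cavity_volume(dense_shell_expanded, voxel=2.0, atom_radius=atom_radius)
        assert cavity.ok
        expected = (4.0 / 3.0) * np.pi * (100.0 - atom_radius) ** 3 / 1e6
        assert cavity.volume == pytest.approx(expected, rel=0.05)

    def test_voxel_refinement_converges(self, dense_shell_expanded):
        coarse = voxel_cavity_volume(dense_shell_expanded, voxel=2.0, atom_radius=4.0)
        fine = voxel_cavity_volume(dense_shell_expanded, voxel=1.0, atom_radius=4.0)
        assert abs(fine.volume - coarse.volume) / fine.volume < 0.02

    def test_leaky_shell_flagged(self, icos_ops):
        sparse = make_shell_capsid(
            ShellSpec(inner_radius=100.0, outer_radius=101.0, atoms_per_au=20, seed=5)
        )
        from capsidkit.icosahedral_symmetry import expand_capsid

        cavity = voxel_cavity_volume(
            expand_capsid(sparse.au, sparse.ops), voxel=2.0, atom_radius=2.0
        )
        assert cavity.escaped
        assert cavity.volume == 0.0

    def test_solid_center_flagged(self):
        atoms = [make_atom(serial=i, position=p) for i, p in enumerate(
            [(0, 0, 0), (3, 0, 0), (0, 3, 0), (0, 0, 3)]
        )]
        cavity = voxel_cavity_volume(
            StructureModel(atoms=atoms), voxel=1.0, atom_radius=3.0,
            center=np.zeros(3),
        )
        assert cavity.no_cavity
        assert cavity.volume == 0.0

    def test_bad_voxel_size(self, tiny_model):
        with pytest.raises(ValueError):
            voxel_cavity_volume(tiny_model, voxel=0.1)


class TestGeometryReport:
    def test_shell_fixture_closed_forms(self, small_shell):
        report = build_geometry_report(
            small_shell.au, small_shell.ops, genome_nt=10000, label="shell",
        )
        assert report.inner_diameter == pytest.approx(20.0, abs=0.4)  # 2x100 Å in nm
        assert report.outer_diameter == pytest.approx(26.0, abs=0.4)
        assert report.inner_volume == pytest.approx(
            (np.pi / 6.0) * report.inner_diameter**3 / 1000.0, rel=1e-12
        )
        assert report.genome_size == pytest.approx(10.2)
        assert report.volume_per_nt == pytest.approx(
            report.inner_volume * 1000.0 / 10200.0, rel=1e-12
        )

    def test_determinism(self, small_shell):
        one = build_geometry_report(small_shell.au, small_shell.ops, 10000, "x")
        two = build_geometry_report(small_shell.au, small_shell.ops, 10000, "x")
        assert one.rounded() == two.rounded()
        assert one.inner_diameter == two.inner_diameter

    def test_rounding_precision(self, small_shell):
        row = build_geometry_report(small_shell.au, small_shell.ops, 10000, "x").rounded()
        assert row["inner_diameter_nm"] == round(row["inner_diameter_nm"], 1)
        assert row["volume_per_nt_nm3"] == round(row["volume_per_nt_nm3"], 2)

    def test_off_center_warning(self, caplog, icos_ops, small_shell):
        import logging
        from dataclasses import replace as _replace

        shifted = StructureModel(
            atoms=[a.moved_to(a.position + np.array([5.0, 0, 0])) for a in small_shell.au.atoms]
        )
        with caplog.at_level(logging.WARNING, logger="capsidkit.capsid_geometry"):
            build_geometry_report(shifted, None, 10000, "shifted")
        # AU alone (no expansion) is far off-centre -> warned
        assert any("centroid" in rec.message for rec in caplog.records)
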