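import numpy as np
import pytest

from pegconf import (
    Conformer,
    SurfaceConfig,
    build_ideal_helix,
    build_ideal_linear,
    hydrophobic_fraction,
    sasa,
    sav,
)
from pegconf.surface import SurfaceReport, golden_spiral_points, shrake_rupley, union_volume

R_C = 1.70  # Bondi carbon radius
PROBE = 1.4
SPHERE_AREA = 4.0 * np.pi * (R_C + PROBE) ** 2
SPHERE_VOLUME = 4.0 / 3.0 * np.pi * (R_C + PROBE) ** 3


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([R_C]), PROBE, 960)
        assert area[0] == pytest.approx(SPHERE_AREA, rel=0.01)

    def test_far_separated_spheres_are_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = shrake_rupley(coords, np.full(2, R_C), PROBE, 960)
        assert areas.sum() == pytest.approx(2 * SPHERE_AREA, rel=0.01)

    def test_caged_atom_is_buried(self):
        # icosahedron of carbons at 2.0 Å fully occludes the centre
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array(
            [p for s1 in (-1, 1) for s2 in (-1, 1)
             for p in ([0, s1, s2 * phi], [s1, s2 * phi, 0], [s2 * phi, 0, s1])],
            dtype=float,
        )
        verts *= 2.0 / np.linalg.norm(verts[0])
        coords = np.vstack([[0.0, 0.0, 0.0], verts])
        areas = shrake_rupley(coords, np.full(len(coords), R_C), PROBE, 960)
        assert areas[0] == 0.0

    def test_occlusion_is_monotone_in_added_atoms(self):
        base = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        more = np.vstack([base, [[0.0, 3.0, 0.0]]])
        a2 = shrake_rupley(base, np.full(2, R_C), PROBE, 960)
        a3 = shrake_rupley(more, np.full(3, R_C), PROBE, 960)
        assert np.all(a3[:2] <= a2 + 1e-9)

    def test_point_density_convergence(self, helix6):
        _, rep_lo = sasa(helix6, SurfaceConfig(n_sphere_points=960))
        _, rep_hi = sasa(helix6, SurfaceConfig(n_sphere_points=1920))
        assert rep_hi.sas_total == pytest.approx(rep_lo.sas_total, rel=0.005)

    def test_agreement_with_independent_implementation(self, helix6):
        """Cross-check against biotite's rolling-probe SASA."""
        import biotite.structure as bst

        from pegconf.io import _conformer_to_atom_array

        per_atom, _ = sasa(helix6)
        arr = _conformer_to_atom_array(helix6)
        cfg = SurfaceConfig()
        radii = np.array([cfg.vdw_radii[e] for e in arr.element])
        reference = bst.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=960)
        assert per_atom.sum() == pytest.approx(float(np.nansum(reference)), rel=0.01)

    def test_missing_radius_names_the_element(self, helix6):
        cfg = SurfaceConfig(vdw_radii={"C": 1.70, "O": 1.52})  # no H
        with pytest.raises(KeyError, match="'H'"):
            sasa(helix6, cfg)

    def test_golden_spiral_points_are_unit_and_spread(self):
        pts = golden_spiral_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestGroupDecomposition:
    def test_group_sums_equal_total_exactly(self, helix6):
        per_atom, rep = sasa(helix6)
        assert rep.sas_ch + rep.sas_o + rep.sas_oh == pytest.approx(
            rep.sas_total, rel=1e-12
        )
        assert per_atom.sum() == pytest.approx(rep.sas_total, rel=1e-9)

    def test_hydrophobic_fraction_definition(self):
        rep = SurfaceReport(sas_ch=60.0, sas_o=30.0, sas_oh=10.0)
        assert hydrophobic_fraction(rep) == pytest.approx(0.6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            hydrophobic_fraction(SurfaceReport(0.0, 0.0, 0.0))

    def test_helix_more_hydrophobic_than_linear(self, crystal):
        for n in (6, 20, 40):
            _, h = sasa(build_ideal_helix(n, crystal))
            _, l = sasa(build_ideal_linear(n, crystal))
            assert h.hydrophobic_fraction > l.hydrophobic_fraction

    def test_end_group_dilution_with_chain_length(self, crystal):
        _, short = sasa(build_ideal_linear(6, crystal))
        _, long = sasa(build_ideal_linear(40, crystal))
        assert long.hydrophobic_fraction > short.hydrophobic_fraction

    def test_waters_occlude_but_contribute_no_surface(self, helix6):
        from pegconf import hydrate_fixture

        hyd = hydrate_fixture(
            helix6, [(helix6.topology.ether_oxygens[0], "acceptor")], seed=2
        )
        _, dry = sasa(hyd, include_waters=False)
        _, wet = sasa(hyd, include_waters=True)
        assert wet.sas_total < dry.sas_total


class TestSolventAccessibleVolume:
    def test_isolated_sphere_volume(self):
        v = union_volume(np.zeros((1, 3)), np.array([R_C + PROBE]), 0.2)
        assert v == pytest.approx(SPHERE_VOLUME, rel=0.02)

    def test_coincident_spheres_count_once(self):
        one = union_volume(np.zeros((1, 3)), np.array([R_C + PROBE]), 0.2)
        two = union_volume(np.zeros((2, 3)), np.full(2, R_C + PROBE), 0.2)
        assert two == pytest.approx(one, rel=1e-12)

    def test_grid_convergence_on_conformer(self, helix6):
        v_default = sav(helix6, SurfaceConfig(grid_spacing=0.4))
        v_fine = sav(helix6, SurfaceConfig(grid_spacing=0.2))
        assert v_default == pytest.approx(v_fine, rel=0.01)

    def test_sav_bounded_below_by_largest_sphere(self, helix6):
        assert sav(helix6) >= SPHERE_VOLUME * 0.98

    def test_insufficient_resolution_rejected(self, helix6):
        with pytest.raises(ValueError, match="grid_spacing"):
            sav(helix6, SurfaceConfig(grid_spacing=1.5))


class TestRigidMotion:
    """Translation is exact; rotation is invariant to sampling tolerance."""

    def test_translation_exact(self, helix6):
        moved = Conformer(helix6.topology, helix6.coords + [13.0, -4.0, 8.0])
        _, a = sasa(helix6)
        _, b = sasa(moved)
        assert b.sas_total == a.sas_total
        assert b.sas_ch == a.sas_ch

    def test_rotation_within_sampling_tolerance(self, helix6):
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=3).as_matrix()
        moved = Conformer(helix6.topology, helix6.coords @ rot.T)
        _, a = sasa(helix6)
        _, b = sasa(moved)
        assert b.sas_total == pytest.approx(a.sas_total, rel=0.005)
        assert sav(moved) == pytest.approx(sav(helix6), rel=0.01)


def test_surface_config_validation():
    with pytest.raises(ValueError):
        SurfaceConfig(probe_radius=0.0)
    with pytest.raises(ValueError):
        SurfaceConfig(n_sphere_points=10)
    with pytest.raises(ValueError):
        SurfaceConfig(vdw_radii={"C": -1.0})
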