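"""Elastic-foundation contact model: mesh construction, constitutive law,
surface geometry and the axis-depth solver (with closed-form oracles on
degenerate meshes)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medialknee.contact import (
    CartilageMaterial,
    ContactSolverError,
    KneeGeometry,
    build_mesh,
    element_strain,
    element_stress,
    femoral_surface_height,
    solve_contact,
)


class TestBuildMesh:
    def test_default_mesh_element_count(self, default_mesh):
        assert default_mesh.n_elements == 7326
        assert default_mesh.geometry.element_spacing == 0.5

    def test_custom_grid_count_and_area(self):
        geom = KneeGeometry(mesh_dims=(10, 10), element_spacing=1.0)
        mesh = build_mesh(geom)
        assert mesh.n_elements == 100
        assert mesh.element_area == pytest.approx(1.0)

    def test_zero_coverage_all_uncovered(self):
        mesh = build_mesh(KneeGeometry(meniscus_coverage=0.0))
        assert not mesh.covered.any()
        assert (mesh.modulus == 4.0).all()  # tibial rule, uncovered

    def test_covered_fraction_within_one_element_row(self, default_mesh):
        # whole mirror-symmetric tie groups are kept, so the fraction can
        # overshoot by at most one rim of elements
        target = default_mesh.geometry.meniscus_coverage
        row = max(default_mesh.geometry.mesh_dims) / default_mesh.n_elements
        assert abs(default_mesh.covered_fraction - target) <= row + 1e-12

    def test_coverage_is_peripheral(self, default_mesh):
        # the plateau centre lies outside the meniscus
        centre = np.unravel_index(
            np.argmin(default_mesh.x_ap**2 + default_mesh.y_ml**2),
            default_mesh.x_ap.shape,
        )
        assert not default_mesh.covered[centre]
        assert default_mesh.covered[0, 0]  # extreme corner is covered

    @pytest.mark.parametrize(
        "rule, covered_E, uncovered_E",
        [
            ("tibial", 10.1, 4.0),
            ("series", 2 / (1 / 8.6 + 1 / 10.1), 2 / (1 / 8.6 + 1 / 4.0)),
            ("arithmetic", (8.6 + 10.1) / 2, (8.6 + 4.0) / 2),
        ],
    )
    def test_modulus_rules(self, rule, covered_E, uncovered_E):
        mesh = build_mesh(material=CartilageMaterial(modulus_rule=rule))
        assert mesh.modulus[mesh.covered].mean() == pytest.approx(covered_E)
        assert mesh.modulus[~mesh.covered].mean() == pytest.approx(uncovered_E)


class TestConstitutiveLaw:
    @pytest.mark.parametrize(
        "compression, thickness, expected",
        [(0.0, 5.0, 0.0), (1.1, 5.0, 0.22), (2.5, 5.0, 0.5)],
    )
    def test_strain_ratio(self, compression, thickness, expected):
        assert element_strain(compression, thickness) == pytest.approx(expected)

    def test_full_compression_is_singular(self):
        with pytest.raises(ValueError):
            element_strain(5.0, 5.0)

    def test_zero_strain_zero_stress(self):
        assert element_stress(0.0, 10.1) == 0.0

    def test_log_identity_point(self):
        # eps = 1 - 1/e makes -ln(1 - eps) exactly 1
        assert element_stress(1.0 - math.exp(-1.0), 1.0) == pytest.approx(1.0)

    def test_operating_point_consistency(self):
        # stress/strain pairs on the published operating curve imply
        # E ~ 10.2 MPa: -E ln(1 - 0.21) = 2.40
        E = 2.40 / (-math.log(1 - 0.21))
        assert E == pytest.approx(10.19, abs=0.01)
        assert element_stress(0.21, E) == pytest.approx(2.40, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=0.95))
    @settings(max_examples=50, deadline=None)
    def test_stress_nonnegative_increasing_convex(self, eps):
        E = 10.1
        s = element_stress(eps, E)
        assert s >= 0.0
        h = 1e-4
        if eps + 2 * h < 1.0:
            s1 = element_stress(eps + h, E)
            s2 = element_stress(eps + 2 * h, E)
            assert s1 > s or eps == 0.0 and s1 >= s
            assert (s2 - s1) >= (s1 - s) - 1e-12  # convexity

    def test_invalid_strain_rejected(self):
        with pytest.raises(ValueError):
            element_stress(1.0, 10.0)
        with pytest.raises(ValueError):
            element_stress(-0.1, 10.0)


class TestFemoralSurface:
    def test_unloaded_gap_at_contact_centre_equals_thickness(self):
        geom = KneeGeometry()
        h = femoral_surface_height(0.0, 0.0, 20.0, 0.0, geom)
        assert h == pytest.approx(geom.cartilage_thickness)

    def test_mediolateral_sagitta_difference(self):
        # with a 20 mm femoral arc inside the 21 mm tibial arc, moving 5 mm
        # off-centre opens the gap by the difference of circular sagittas
        geom = KneeGeometry(femoral_frontal_radius=20.0)
        at0 = femoral_surface_height(0.0, 0.0, 0.0, 0.0, geom)
        at5 = femoral_surface_height(0.0, 5.0, 0.0, 0.0, geom)
        sagitta = lambda R, c: R - math.sqrt(R * R - c * c)
        expected = sagitta(20.0, 5.0) - sagitta(21.0, 5.0)
        assert at5 - at0 == pytest.approx(expected, abs=1e-12)

    def test_axis_depth_translates_rigidly(self):
        geom = KneeGeometry()
        up = femoral_surface_height(3.0, 2.0, 10.0, 0.0, geom)
        down = femoral_surface_height(3.0, 2.0, 10.0, 0.75, geom)
        assert up - down == pytest.approx(0.75)

    def test_anterior_arc_gives_larger_footprint(self, reference_load_n):
        # below the transition flexion the flatter 35 mm arc engages more
        # cartilage than the 18.9 mm posterior arc at the same force
        low = solve_contact(reference_load_n, 10.0)
        high = solve_contact(reference_load_n, 60.0)
        assert low.loaded_area > high.loaded_area
        assert low.peak_strain < high.peak_strain


class TestSolveContact:
    def test_zero_target_unloaded(self, default_mesh):
        sol = solve_contact(0.0, 20.0, mesh=default_mesh)
        assert sol.total_force == 0.0
        assert sol.peak_strain == 0.0
        assert sol.loaded_area == 0.0

    def test_single_spring_closed_form(self, single_spring):
        # one element: F = -E A ln(1 - d/h)  =>  d = h (1 - exp(-F/(E A)))
        E = float(single_spring.modulus.ravel()[0])
        A = single_spring.element_area
        h = single_spring.geometry.cartilage_thickness
        for target in (1.0, 5.0, 12.0):
            sol = solve_contact(target, 0.0, mesh=single_spring, tol=1e-9)
            expected = h * (1.0 - math.exp(-target / (E * A)))
            assert sol.axis_depth == pytest.approx(expected, rel=1e-6)
            assert sol.total_force == pytest.approx(target, abs=1e-6)

    def test_two_spring_closed_form(self):
        # two springs at +-0.5 mm share a common (tiny) gap by symmetry,
        # so F = -(E1 + E2) A ln(1 - (d - g)/h) inverts in closed form
        geom = KneeGeometry(mesh_dims=(2, 1), element_spacing=1.0)
        mesh = build_mesh(geom)
        E_sum = float(mesh.modulus.sum())
        A = mesh.element_area
        h = geom.cartilage_thickness
        gap = femoral_surface_height(0.5, 0.0, 0.0, 0.0, geom) - h
        target = 8.0
        sol = solve_contact(target, 0.0, mesh=mesh, tol=1e-9)
        expected = gap + h * (1.0 - math.exp(-target / (E_sum * A)))
        assert sol.axis_depth == pytest.approx(expected, rel=1e-6)

    def test_force_monotone_in_depth(self, default_mesh):
        shallow = solve_contact(500.0, 20.0, mesh=default_mesh)
        deep = solve_contact(2000.0, 20.0, mesh=default_mesh)
        assert deep.axis_depth > shallow.axis_depth
        assert deep.peak_strain > shallow.peak_strain

    def test_residual_within_tolerance(self, default_mesh, reference_load_n):
        sol = solve_contact(reference_load_n, 20.0, mesh=default_mesh, tol=0.5)
        assert abs(sol.total_force - reference_load_n) <= 0.5

    def test_stress_field_symmetric_mediolaterally(self, default_mesh):
        sol = solve_contact(1500.0, 20.0, mesh=default_mesh)
        np.testing.assert_allclose(
            sol.stress, sol.stress[:, ::-1], rtol=0, atol=1e-12
        )

    def test_strain_below_one_stress_zero_where_unloaded(self, default_mesh):
        sol = solve_contact(2500.0, 20.0, mesh=default_mesh)
        assert sol.peak_strain < 1.0
        unloaded = sol.compression == 0.0
        assert np.all(sol.stress[unloaded] == 0.0)
        assert np.all(sol.stress[~unloaded] > 0.0)

    def test_stressed_volume_is_loaded_area_times_thickness(
        self, default_mesh, reference_load_n
    ):
        sol = solve_contact(reference_load_n, 20.0, mesh=default_mesh)
        assert sol.stressed_volume == pytest.approx(
            sol.loaded_area * default_mesh.geometry.cartilage_thickness
        )
        # the weakest-link effective volume only discounts, never inflates
        assert 0.0 < sol.weibull_effective_volume < sol.stressed_volume

    def test_unreachable_target_reports_max_force(self, single_spring):
        with pytest.raises(ContactSolverError, match="maximum achievable"):
            solve_contact(1e7, 0.0, mesh=single_spring)

    def test_negative_target_rejected(self, default_mesh):
        with pytest.raises(ValueError):
            solve_contact(-1.0, 20.0, mesh=default_mesh)

    def test_grid_convergence_of_peak_stress(self, reference_load_n):
        coarse = solve_contact(reference_load_n, 20.0, KneeGeometry())
        fine_geom = KneeGeometry(element_spacing=0.25, mesh_dims=(222, 132))
        fine = solve_contact(reference_load_n, 20.0, fine_geom)
        rel = abs(fine.peak_stress - coarse.peak_stress) / fine.peak_stress
        assert rel < 0.02
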