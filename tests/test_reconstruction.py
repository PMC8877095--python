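import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bowlrecon.annotations import RulerAnnotation
from bowlrecon.camera import CameraIntrinsics, ray_angle
from bowlrecon.model import HalfProfile, revolve
from bowlrecon.reconstruction import (
    CrossSection,
    RayFan,
    ReconstructionError,
    fit_borders,
    flat_bottom_residuals,
    initial_rays,
    inter_ray_angles,
    objective_J,
    optimize_rays,
    pair_and_measure,
    rays_to_cross_section,
    reconstruct,
    symmetrize,
)
from bowlrecon.simulate import ParametricBowl, simulate_ruler_annotation

from conftest import flat_plate_annotation


def horizontal_border_annotation(k, n=9, gap_mm=2.0, spacing_px=40.0):
    """Landmarks on two horizontal lines y' = -+gap/2 (downward-y plane)."""
    x = (np.arange(n) - (n - 1) / 2) * spacing_px
    y_up = np.full(n, -gap_mm / 2 / k.sy)
    y_lo = np.full(n, +gap_mm / 2 / k.sy)
    mid = n // 2
    return RulerAnnotation(
        upper=np.column_stack([x, y_up]),
        lower=np.column_stack([x, y_lo]),
        spacing=12.7,
        width=19.0,
        flat_bottom=np.array([mid - 1, mid, mid + 1]),
        image_width=k.image_width,
        image_height=k.image_height,
    )


class TestFitBorders:
    def test_horizontal_lines(self, unit_intrinsics):
        a = horizontal_border_annotation(unit_intrinsics, gap_mm=2.0)
        fit = fit_borders(a, unit_intrinsics)
        x = np.linspace(-100, 100, 11)
        assert np.allclose(fit.upper(x), -1.0, atol=1e-9)
        assert np.allclose(fit.lower(x), 1.0, atol=1e-9)
        assert np.allclose(fit.midline(x), 0.0, atol=1e-9)

    def test_degree_reduced_with_few_landmarks(self, unit_intrinsics):
        a = horizontal_border_annotation(unit_intrinsics, n=5)
        with pytest.warns(UserWarning, match="degree reduced"):
            fit = fit_borders(a, unit_intrinsics)
        assert fit.degree == 3

    def test_duplicate_abscissae(self, unit_intrinsics):
        a = horizontal_border_annotation(unit_intrinsics)
        a.upper[1, 0] = a.upper[0, 0]
        with pytest.raises(ReconstructionError, match="duplicate"):
            fit_borders(a, unit_intrinsics)

    def test_simulated_landmarks_on_curves(self, noiseless_mid_sim):
        sim, cfg = noiseless_mid_sim
        fit = fit_borders(sim.annotation, cfg.intrinsics)
        # borders are smooth: residual well below the observed tape width
        from bowlrecon.camera import pixel_to_plane

        w_mid = np.median(
            pixel_to_plane(sim.annotation.lower, cfg.intrinsics)[:, 1]
            - pixel_to_plane(sim.annotation.upper, cfg.intrinsics)[:, 1]
        )
        assert fit.max_residual < 0.05 * w_mid


class TestPairAndMeasure:
    def test_parallel_borders_width(self, unit_intrinsics):
        a = horizontal_border_annotation(unit_intrinsics, gap_mm=2.0)
        fan = pair_and_measure(a, unit_intrinsics, fit_borders(a, unit_intrinsics))
        assert np.allclose(fan.W, 2.0, atol=1e-9)

    def test_V_antisymmetric_for_symmetric_annotation(self, unit_intrinsics):
        a = horizontal_border_annotation(unit_intrinsics)
        fan = pair_and_measure(a, unit_intrinsics, fit_borders(a, unit_intrinsics))
        assert np.allclose(fan.V + fan.V[::-1], 0.0, atol=1e-9)

    def test_flat_plate_widths_equal(self, intrinsics):
        a = flat_plate_annotation(intrinsics, depth_mm=400.0)
        fan = pair_and_measure(a, intrinsics, fit_borders(a, intrinsics))
        assert np.ptp(fan.W) < 1e-9


class TestInitialRays:
    def test_substitution(self, unit_intrinsics):
        fan = RayFan(V=np.array([1.0, 0.0]), W=np.array([0.19, 0.19]),
                     flat_bottom=np.array([0]))
        r0 = initial_rays(fan, 19.0, unit_intrinsics)  # f = 3 mm
        assert np.allclose(r0, 300.0)

    def test_inverse_proportionality(self, unit_intrinsics):
        fan1 = RayFan(V=np.array([1.0, 0.0]), W=np.array([0.1, 0.1]),
                      flat_bottom=np.array([0]))
        fan2 = RayFan(V=np.array([1.0, 0.0]), W=np.array([0.2, 0.2]),
                      flat_bottom=np.array([0]))
        assert np.allclose(
            initial_rays(fan1, 19.0, unit_intrinsics),
            2 * initial_rays(fan2, 19.0, unit_intrinsics),
        )

    def test_flat_plate_depth(self, intrinsics):
        # r0 * cos(alpha) recovers the plate depth to 0.5 mm for a plate
        # subtending small ray angles (slant-vs-depth difference is O(alpha^2))
        a = flat_plate_annotation(intrinsics, depth_mm=400.0, spacing_mm=5.0)
        fan = pair_and_measure(a, intrinsics, fit_borders(a, intrinsics))
        r0 = initial_rays(fan, a.width, intrinsics)
        depth = r0 * np.cos(ray_angle(fan.V, intrinsics.f))
        assert np.all(np.abs(depth - 400.0) < 0.5)


class TestInterRayAngles:
    def test_quarter_pi(self, unit_intrinsics):
        fan = RayFan(V=np.array([3.0, 0.0]), W=np.array([1.0, 1.0]),
                     flat_bottom=np.array([0]))
        theta = inter_ray_angles(fan, unit_intrinsics)
        assert np.allclose(theta, np.pi / 4)

    def test_non_monotone_rejected(self, unit_intrinsics):
        fan = RayFan(V=np.array([1.0, 1.0, 0.0]), W=np.ones(3),
                     flat_bottom=np.array([0]))
        with pytest.raises(ReconstructionError, match="decreasing"):
            inter_ray_angles(fan, unit_intrinsics)

    @given(st.lists(st.floats(-2, 2), min_size=4, max_size=12, unique=True))
    @settings(max_examples=30)
    def test_telescoping_sum(self, vs):
        k = CameraIntrinsics(f=4.0)
        V = np.sort(np.array(vs))[::-1]
        fan = RayFan(V=V, W=np.ones_like(V), flat_bottom=np.array([0]))
        theta = inter_ray_angles(fan, k)
        assert np.isclose(theta.sum(), np.arctan(V[0] / 4) - np.arctan(V[-1] / 4))


class TestObjective:
    def test_equilateral_triangle(self):
        assert objective_J(np.array([1.0, 1.0]), np.array([np.pi / 3]), 1.0) == \
            pytest.approx(0.0, abs=1e-15)

    def test_right_isoceles(self):
        j = objective_J(np.array([1.0, 1.0]), np.array([np.pi / 2]), 1.0)
        assert j == pytest.approx((np.sqrt(2) - 1) ** 2)

    def test_zero_when_chords_match(self):
        r = np.array([300.0, 310.0, 295.0])
        theta = np.array([0.03, 0.04])
        c_true = np.sqrt(
            r[:-1] ** 2 + r[1:] ** 2 - 2 * r[:-1] * r[1:] * np.cos(theta)
        )
        assert objective_J(r, theta, c_true) == pytest.approx(0.0, abs=1e-18)


class TestFlatBottomResiduals:
    def _fan(self, V, flat):
        return RayFan(V=np.asarray(V, float), W=np.ones(len(V)),
                      flat_bottom=np.asarray(flat))

    def test_symmetric_pair(self, unit_intrinsics):
        fan = self._fan([0.5, -0.5], [0, 1])
        res = flat_bottom_residuals(np.array([400.0, 400.0]), fan, unit_intrinsics)
        assert np.allclose(res, 0.0)

    def test_common_depth_zeroes_all(self, unit_intrinsics):
        V = np.array([0.6, 0.2, -0.1, -0.5])
        fan = self._fan(V, [0, 1, 2, 3])
        r = 300.0 / np.cos(ray_angle(V, unit_intrinsics.f))
        assert np.allclose(flat_bottom_residuals(r, fan, unit_intrinsics), 0.0)

    def test_perturbation_touches_two_residuals(self, unit_intrinsics):
        V = np.array([0.6, 0.2, -0.1, -0.5])
        fan = self._fan(V, [0, 1, 2, 3])
        r = 300.0 / np.cos(ray_angle(V, unit_intrinsics.f))
        base = flat_bottom_residuals(r, fan, unit_intrinsics)
        r2 = r.copy()
        r2[1] += 0.5
        changed = ~np.isclose(flat_bottom_residuals(r2, fan, unit_intrinsics), base)
        assert changed.sum() == 2

    def test_single_index_warns(self, unit_intrinsics):
        fan = self._fan([0.5, -0.5], [0])
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = flat_bottom_residuals(np.array([1.0, 1.0]), fan, unit_intrinsics)
        assert res.size == 0


class TestOptimizeRays:
    def test_noiseless_ray_recovery(self, noiseless_mid_sim):
        sim, cfg = noiseless_mid_sim
        a = sim.annotation
        fan = pair_and_measure(a, cfg.intrinsics, fit_borders(a, cfg.intrinsics))
        inter_ray_angles(fan, cfg.intrinsics)
        r0 = initial_rays(fan, a.width, cfg.intrinsics)
        r, diag = optimize_rays(fan, a.spacing_per_interval(), r0, cfg.intrinsics)
        assert np.max(np.abs(r - sim.r_true) / sim.r_true) <= 0.01
        assert diag.final_J <= diag.initial_J + 1e-12

    def test_fixed_point(self, noiseless_mid_sim):
        sim, cfg = noiseless_mid_sim
        a = sim.annotation
        fan = pair_and_measure(a, cfg.intrinsics, fit_borders(a, cfg.intrinsics))
        inter_ray_angles(fan, cfg.intrinsics)
        r0 = initial_rays(fan, a.width, cfg.intrinsics)
        C = a.spacing_per_interval()
        r1, d1 = optimize_rays(fan, C, r0, cfg.intrinsics)
        r2, d2 = optimize_rays(fan, C, r1, cfg.intrinsics)
        assert d2.final_J <= d1.final_J + 1e-10
        assert np.allclose(r2, r1, rtol=1e-4)

    def test_rejects_bad_init(self, unit_intrinsics):
        fan = RayFan(V=np.array([1.0, 0.0]), W=np.ones(2), flat_bottom=np.array([0, 1]))
        inter_ray_angles(fan, unit_intrinsics)
        with pytest.raises(ValueError):
            optimize_rays(fan, 12.7, np.array([-1.0, 1.0]), unit_intrinsics)


class TestCrossSection:
    def test_on_axis_landmark(self, unit_intrinsics):
        fan = RayFan(V=np.array([0.5, 0.0, -0.5]), W=np.ones(3),
                     flat_bottom=np.array([1]))
        r = np.array([400.0, 390.0, 400.0])
        cs = rays_to_cross_section(r, fan, unit_intrinsics)
        assert cs.u[1] == 0.0
        assert cs.w[1] == 390.0

    def test_flat_bottom_common_depth(self, noiseless_mid_sim):
        sim, cfg = noiseless_mid_sim
        res = reconstruct(sim.annotation, cfg.intrinsics, full_result=True)
        w_flat = res.cross_section.w[res.fan.flat_bottom]
        assert np.ptp(w_flat) < 1e-6 * np.max(w_flat)

    def test_consecutive_chords_match_spacing(self, noiseless_mid_sim):
        sim, cfg = noiseless_mid_sim
        res = reconstruct(sim.annotation, cfg.intrinsics, full_result=True)
        cs = res.cross_section
        d = np.hypot(np.diff(cs.u), np.diff(cs.w))
        C = sim.annotation.spacing_per_interval()
        rms_bound = np.sqrt(res.solver.final_J / len(d)) + 0.02 * np.mean(C)
        assert np.mean(np.abs(d - C)) <= max(rms_bound, 0.05)


class TestSymmetrize:
    def test_symmetric_vee_identity(self):
        u = np.array([-30.0, -15.0, 0.0, 15.0, 30.0])
        w = 400.0 - np.abs(u) * 0.5
        cs = CrossSection(u=u, w=w, flat_bottom=np.array([2]))
        prof = symmetrize(cs)
        assert prof.depth == pytest.approx(15.0, rel=1e-6)
        assert prof.radius_at(prof.depth) == pytest.approx(30.0, rel=1e-6)

    def test_mirror_invariance(self, noiseless_mid_sim):
        sim, cfg = noiseless_mid_sim
        res = reconstruct(sim.annotation, cfg.intrinsics, full_result=True)
        cs = res.cross_section
        mirrored = CrossSection(
            u=-cs.u[::-1], w=cs.w[::-1],
            flat_bottom=len(cs.u) - 1 - cs.flat_bottom[::-1],
        )
        p1 = symmetrize(cs)
        p2 = symmetrize(mirrored)
        assert np.allclose(p1.z, p2.z, atol=1e-9)
        assert np.allclose(p1.rho, p2.rho, atol=1e-6)

    def test_recovers_simulated_profile(self, noiseless_mid_sim, mid_bowl):
        sim, cfg = noiseless_mid_sim
        res = reconstruct(sim.annotation, cfg.intrinsics, full_result=True)
        prof = res.model.profile
        rho_true = np.interp(prof.z, sim.profile.z, sim.profile.rho)
        mask = prof.z > 0.05 * prof.depth  # spline toe near z=0 is extrapolated
        assert np.max(np.abs(prof.rho[mask] - rho_true[mask])) <= 0.015 * mid_bowl.rr

    def test_too_few_points(self):
        cs = CrossSection(u=np.array([-1.0, 0.0, 1.0]), w=np.array([4.0, 5.0, 4.0]),
                          flat_bottom=np.array([1]))
        with pytest.raises(ReconstructionError):
            symmetrize(cs)


class TestRevolve:
    def test_cylinder_closed_form(self):
        prof = HalfProfile(z=np.linspace(0, 100, 501), rho=np.full(501, 50.0))
        model = revolve(prof)
        assert model.capacity_ml == pytest.approx(np.pi * 50**2 * 100 / 1000, rel=1e-3)
        assert model.capacity_ml == pytest.approx(785.40, abs=0.8)

    def test_hemisphere_closed_form(self):
        R = 60.0
        z = np.linspace(0, R, 501)
        prof = HalfProfile(z=z, rho=np.sqrt(R**2 - (R - z) ** 2))
        model = revolve(prof)
        assert model.capacity_ml == pytest.approx(2 * np.pi * R**3 / 3 / 1000, rel=1e-3)
        assert model.capacity_ml == pytest.approx(452.39, abs=0.5)

    def test_cone_closed_form(self):
        R, H = 60.0, 90.0
        z = np.linspace(0, H, 501)
        model = revolve(HalfProfile(z=z, rho=z * R / H))
        assert model.capacity_ml == pytest.approx(np.pi * R**2 * H / 3 / 1000, rel=1e-3)
        assert model.capacity_ml == pytest.approx(339.29, abs=0.4)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            HalfProfile(z=np.linspace(0, 1, 10), rho=np.linspace(-0.1, 1, 10))

    def test_level_table_monotone(self, mid_bowl_model):
        v = mid_bowl_model.level_volumes_ml
        assert np.all(np.diff(v) > 0)
        assert v[-1] == pytest.approx(mid_bowl_model.capacity_ml)


class TestReconstructEndToEnd:
    def test_noiseless_capacity(self, noiseless_mid_sim, mid_bowl):
        sim, cfg = noiseless_mid_sim
        model = reconstruct(sim.annotation, cfg.intrinsics)
        truth = mid_bowl.capacity_ml()
        assert abs(model.capacity_ml - truth) / truth <= 0.02

    def test_flat_plate_degenerate(self, intrinsics):
        a = flat_plate_annotation(intrinsics, depth_mm=400.0, n=9)
        res = reconstruct(a, intrinsics, full_result=True)
        assert np.allclose(res.cross_section.w, 400.0, atol=0.5)
        assert res.model.depth < 0.1
        half_extent = 4 * 12.7  # 9 landmarks spaced 12.7 mm
        assert res.model.diameter == pytest.approx(2 * half_extent, rel=0.01)

    def test_scale_equivariance(self, noiseless_mid_sim):
        sim, cfg = noiseless_mid_sim
        a = sim.annotation
        c = 2.5
        scaled = RulerAnnotation(
            upper=a.upper, lower=a.lower,
            spacing=a.spacing_per_interval() * c, width=a.width * c,
            flat_bottom=a.flat_bottom,
            image_width=a.image_width, image_height=a.image_height,
        )
        m1 = reconstruct(a, cfg.intrinsics)
        m2 = reconstruct(scaled, cfg.intrinsics)
        assert m2.diameter == pytest.approx(c * m1.diameter, rel=1e-3)
        assert m2.depth == pytest.approx(c * m1.depth, rel=1e-3)
        assert m2.capacity_ml == pytest.approx(c**3 * m1.capacity_ml, rel=1e-3)

    def test_noisy_median_capacity(self, mid_bowl, sim_config):
        from bowlrecon.simulate import SimulationConfig, simulate_ruler_annotation

        truth = mid_bowl.capacity_ml()
        errs = []
        for seed in range(20):
            cfg = sim_config(noise_px=0.5, seed=seed)
            sim = simulate_ruler_annotation(mid_bowl, cfg)
            model = reconstruct(sim.annotation, cfg.intrinsics)
            errs.append(abs(model.capacity_ml - truth) / truth)
        assert np.median(errs) <= 0.05
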