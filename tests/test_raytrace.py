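"""Monte-Carlo ray tracer: sampling, Fresnel optics, intersections, ledger."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrsim.raytrace import (
    BIN_EDGES,
    DetectorPair,
    OpticalScene,
    Ray,
    TraceConfig,
    collection_within_NA,
    fresnel_split,
    intersect,
    run_simulation,
    sample_directions,
    sample_emitters,
    trace,
    trapped_fraction,
    trapped_fraction_quadrature,
)

TINY = TraceConfig(n_emitters=40, rays_per_emitter=400, rng_seed=0)


class TestSampling:
    def test_emitters_mean_radius(self, rng):
        pts = sample_emitters(100_000, 1.0, 0.0, rng)
        radii = np.linalg.norm(pts, axis=1)
        assert np.mean(radii) == pytest.approx(0.75, rel=0.01)
        assert radii.max() < 1.0

    def test_emitters_reproducible(self):
        a = sample_emitters(500, 1.0, 1.0, np.random.default_rng(7))
        b = sample_emitters(500, 1.0, 1.0, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_directions_isotropic(self, rng):
        d = sample_directions(100_000, rng)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        # CLT bound on the mean z-component (var of cos theta is 1/3)
        assert abs(d[:, 2].mean()) < 3.0 * math.sqrt(1.0 / 3.0 / len(d))

    def test_directions_cap_fraction(self, rng):
        d = sample_directions(1_000_000, rng)
        theta_c = math.radians(40.0)
        frac = np.mean(d[:, 2] > math.cos(theta_c))
        assert frac == pytest.approx((1 - math.cos(theta_c)) / 2, rel=0.01)


class TestFresnel:
    def test_normal_incidence_glass(self):
        r, t, ang = fresnel_split(1.0, 1.5, 0.0)
        assert r == pytest.approx(0.04, abs=1e-12)
        assert t == pytest.approx(0.96, abs=1e-12)
        assert ang == 0.0

    def test_total_internal_reflection(self):
        crit = math.degrees(math.asin(1.0 / 1.61))
        r, t, ang = fresnel_split(1.61, 1.0, crit + 0.01)
        assert r == 1.0 and t == 0.0 and math.isnan(ang)

    @given(
        st.floats(min_value=1.0, max_value=2.0),
        st.floats(min_value=1.0, max_value=2.0),
        st.floats(min_value=0.0, max_value=89.9),
    )
    def test_energy_conservation(self, n1, n2, angle):
        r, t, _ = fresnel_split(n1, n2, angle)
        assert abs(r + t - 1.0) < 1e-12
        assert 0.0 <= r <= 1.0

    def test_snell_angle(self):
        _, _, ang = fresnel_split(1.0, 1.5, 30.0)
        assert ang == pytest.approx(math.degrees(math.asin(math.sin(math.radians(30)) / 1.5)))


class TestIntersect:
    def test_axial_ray_through_sphere(self):
        # from one radius above the top pole: near pole at distance R, far
        # pole at 3R
        scene = OpticalScene.bare(bead_diameter=5e-6, substrate=False)
        R = scene.bead_radius
        origin = np.array([0.0, 0.0, 3 * R])
        down = np.array([0.0, 0.0, -1.0])
        hit, normal, name = intersect(Ray(origin=origin, direction=down), scene)
        assert name == "bead"
        assert np.linalg.norm(hit - origin) == pytest.approx(R, rel=1e-12)
        np.testing.assert_allclose(normal, [0, 0, 1], atol=1e-12)
        inside = origin + (R + 1e-9) * down
        hit2, _, _ = intersect(Ray(origin=inside, direction=down), scene)
        assert np.linalg.norm(hit2 - origin) == pytest.approx(3 * R, rel=1e-6)

    def test_escape_returns_none(self):
        scene = OpticalScene.bare(substrate=False)
        ray = Ray(origin=np.array([0.0, 0.0, 1e-5]), direction=np.array([0.0, 0.0, 1.0]))
        assert intersect(ray, scene) is None

    def test_spherical_cap_meniscus_matches_analytic_sphere(self):
        # generatrix sampled from a sphere: ray-frustum hits must agree with
        # the analytic ray-sphere solution to nanometer precision
        r_cap, height = 4e-6, 2.5e-6
        t_end = math.acos((r_cap - height) / r_cap)
        t = np.linspace(1e-6, t_end, 400)
        gen = np.column_stack((r_cap * np.sin(t), r_cap * np.cos(t) - (r_cap - height)))
        scene = OpticalScene(
            bead_diameter=1e-7, meniscus_generatrix=gen, contact_polar_angle=0.0,
            substrate=False,
        )
        z_c = -(r_cap - height)
        rng = np.random.default_rng(3)
        for _ in range(200):
            origin = np.array([0.0, 0.0, 1e-8])
            d = rng.normal(size=3)
            d[2] = abs(d[2])
            d /= np.linalg.norm(d)
            res = intersect(Ray(origin=origin, direction=d), scene)
            if res is None or res[2] != "meniscus":
                continue
            hit = res[0]
            assert abs(np.linalg.norm(hit - np.array([0, 0, z_c])) - r_cap) < 1e-9


class TestTraceLedger:
    def test_center_emitter_bare_sphere(self):
        # normal incidence everywhere: per-interface R = ((1.61-1)/2.61)^2
        scene = OpticalScene.bare(substrate=False)
        cfg = TraceConfig(n_emitters=1, rays_per_emitter=1, rng_seed=0)
        ray = Ray(origin=np.array([0.0, 0.0, scene.bead_center_z]),
                  direction=np.array([0.0, 0.0, 1.0]))
        det, ledger = trace(ray, scene, cfg)
        r1 = ((1.61 - 1.0) / 2.61) ** 2
        # escaping total = sum of the geometric series down to the cutoff
        assert ledger["trapped"] == 0.0
        assert det.upper_counts.sum() + det.lower_counts.sum() == pytest.approx(
            1.0 - ledger["truncated"], abs=1e-12
        )
        assert det.upper_counts.sum() >= (1 - r1) - 1e-12

    def test_ledger_conserves_intensity(self, family20):
        scene = OpticalScene.from_profile(family20.profiles[8])
        _, ledger = run_simulation(scene, TINY)
        assert ledger["total"] == pytest.approx(1.0, abs=1e-6)

    def test_bare_sphere_vacuum_mirror_symmetry(self):
        scene = OpticalScene.bare(substrate=False)
        cfg = TraceConfig(n_emitters=2000, rays_per_emitter=100, rng_seed=4)
        det, _ = run_simulation(scene, cfg)
        up, down = det.upper_counts.sum(), det.lower_counts.sum()
        assert abs(up - down) / (up + down) < 0.03

    def test_budget_scaling_reduces_scatter(self):
        # quadrupling the ray budget halves the seed-to-seed standard error
        scene = OpticalScene.bare()
        vals = {1: [], 4: []}
        for mult in (1, 4):
            for seed in range(8):
                cfg = TraceConfig(n_emitters=25 * mult, rays_per_emitter=100,
                                  rng_seed=100 + seed)
                det, _ = run_simulation(scene, cfg)
                vals[mult].append(det.lower_counts.sum())
        s1, s4 = np.std(vals[1], ddof=1), np.std(vals[4], ddof=1)
        assert s4 < s1  # noisy with 8 seeds; require the right direction

    def test_generatrix_refinement_is_converged(self, family20):
        # tracing the same meniscus with a 4x denser surface model moves the
        # detector totals by less than the Monte-Carlo scatter
        from scipy.interpolate import interp1d

        prof = family20.profiles[8]
        gen = prof.generatrix
        s = np.concatenate(([0.0], np.cumsum(np.hypot(*np.diff(gen, axis=0).T))))
        fine_s = np.linspace(0.0, s[-1], 4 * len(gen))
        fine = np.column_stack(
            (interp1d(s, gen[:, 0], kind="cubic")(fine_s), interp1d(s, gen[:, 1], kind="cubic")(fine_s))
        )
        scene_a = OpticalScene.from_profile(prof)
        scene_b = OpticalScene(
            bead_diameter=scene_a.bead_diameter, meniscus_generatrix=fine,
            contact_polar_angle=prof.contact_polar_angle_on_bead,
        )
        det_a, _ = run_simulation(scene_a, TINY)
        det_b, _ = run_simulation(scene_b, TINY)
        a, b = det_a.lower_counts.sum(), det_b.lower_counts.sum()
        assert abs(a - b) / a < 0.02


class TestTrappedFraction:
    def test_matches_quadrature(self):
        scene = OpticalScene.bare(substrate=False)
        mc = trapped_fraction(scene, TraceConfig.fast(rng_seed=0))
        quad = trapped_fraction_quadrature()
        assert mc == pytest.approx(quad, rel=0.01)

    def test_quadrature_matches_closed_form(self):
        # integral of 3 x^2 sqrt(1-(sc/x)^2) over [sc, 1] is (1-sc^2)^(3/2)
        for n in (1.33, 1.5, 1.61, 2.0):
            closed = (1.0 - 1.0 / n**2) ** 1.5
            assert trapped_fraction_quadrature(n) == pytest.approx(closed, rel=1e-10)

    def test_meniscus_scene_rejected(self, family20):
        scene = OpticalScene.from_profile(family20.profiles[0])
        with pytest.raises(ValueError, match="bare perfect sphere"):
            trapped_fraction(scene, TINY)


class TestCollectionWithinNA:
    def _uniform_detector(self):
        det = DetectorPair()
        det.upper_counts[:] = 1.0
        det.lower_counts[:] = 1.0
        return det

    def test_na_one_collects_everything(self):
        det = self._uniform_detector()
        assert collection_within_NA(det, 1.0, "lower") == pytest.approx(160.0)

    def test_boundary_bin_fractional_overlap(self):
        det = self._uniform_detector()
        theta = math.degrees(math.asin(0.13))  # 7.4684 deg
        expected = 2.0 * theta  # uniform bins of unit intensity per degree
        assert collection_within_NA(det, 0.13, "lower") == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_na(self, family20, enhancement_results):
        det = enhancement_results["det_bare"]
        vals = [collection_within_NA(det, na, "lower") for na in np.linspace(0.05, 1.0, 12)]
        assert np.all(np.diff(vals) >= 0)

    def test_bad_na_rejected(self):
        with pytest.raises(ValueError):
            collection_within_NA(DetectorPair(), 0.0)
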