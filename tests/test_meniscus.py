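"""Young-Laplace meniscus solver: constant-curvature oracles, matching, geometry."""

import math

import numpy as np
import pytest

from mrsim.constants import CODATA, PEGProperties
from mrsim.meniscus import (
    ContactGeometry,
    MeniscusNotFoundError,
    area_of_volume,
    build_family,
    integrate_generatrix,
    match_profile,
    profile_area,
    profile_volume,
    revolution_area,
    revolution_volume,
    solve_profile,
)

PEG = PEGProperties()
GAMMA = PEG.surface_tension


def cap_arrays(r_cap: float, height: float, n: int = 2001):
    """Generatrix of a spherical cap of sphere radius r_cap and cap height
    ``height`` resting on the plane h=0, sampled apex to contact circle."""
    t_end = math.acos((r_cap - height) / r_cap)
    t = np.linspace(1e-8, t_end, n)
    return r_cap * np.sin(t), r_cap * np.cos(t) - (r_cap - height)


class TestConstantCurvatureOracles:
    def test_spherical_cap_circle(self):
        # kappa = 2/R with liquid on the left reproduces the circle to 1e-6
        r_cap, h_c = 2.0, 1.0
        t0 = math.radians(60.0)  # contact point of the circle with h=0
        sol, _ = integrate_generatrix(
            r_cap * math.sin(t0), h_c - r_cap * math.cos(t0) + 1e-12, t0,
            kappa=2.0 / r_cap, bond=0.0, bead=False, s_max=r_cap * math.radians(110.0),
        )
        s = np.linspace(0.0, sol.t[-1], 400)
        r, h, _ = sol.sol(s)
        rel_err = np.abs(np.hypot(r, h - h_c) - r_cap) / r_cap
        assert rel_err.max() < 1e-6

    def test_catenoid_zero_mean_curvature(self):
        a, h0 = 0.7, -0.5
        u1 = 1.2
        phi1 = math.atan2(-1.0, -math.sinh(u1))
        sol, status = integrate_generatrix(
            a * math.cosh(u1), h0 + a * u1, phi1, kappa=0.0, bond=0.0, bead=False,
        )
        assert status == "ok"
        s = np.linspace(0.0, sol.t_events[0][0], 400)
        r, h, _ = sol.sol(s)
        rel_err = np.abs(r - a * np.cosh((h - h0) / a)) / r
        assert rel_err.max() < 1e-6

    def test_gravity_negligible_at_micron_scale(self):
        # Bond number rho g R^2 / gamma ~ 1e-5: gravity changes nothing
        geom = ContactGeometry(bead_diameter=10e-6)
        dp = 0.2 * GAMMA / (geom.bead_diameter / 2.0)
        with_g = match_profile(dp, geom, PEG, include_gravity=True)
        without = match_profile(dp, geom, PEG, include_gravity=False)
        scale = np.abs(with_g.generatrix[:, 1]).max()
        assert np.abs(with_g.generatrix - without.generatrix).max() / scale < 1e-4

    def test_bond_number_is_tiny(self):
        bond = PEG.liquid_density * CODATA.gravity_g * (5e-6) ** 2 / GAMMA
        assert bond < 1e-4


class TestSolveProfile:
    def test_failure_modes_are_classified(self):
        geom = ContactGeometry()
        r = geom.bead_diameter / 2.0
        reentry = solve_profile(4.0 * GAMMA / r, 65.0, geom, PEG)
        assert reentry.status == "bead_reentry"
        no_cross = solve_profile(0.0, 105.0, geom, PEG)
        assert no_cross.status == "no_substrate_crossing"

    def test_generatrix_endpoints(self):
        geom = ContactGeometry()
        prof = match_profile(0.0, geom, PEG)
        r = geom.bead_diameter / 2.0
        first, last = prof.generatrix[0], prof.generatrix[-1]
        # starts on the bead surface, ends exactly on the substrate
        assert math.hypot(first[0], first[1] - r) == pytest.approx(r, rel=1e-9)
        assert last[1] == 0.0

    def test_curvature_residual_along_matched_profile(self):
        # discrete Young-Laplace balance: (dp - rho g h)/gamma = 2 K_m
        geom = ContactGeometry()
        r_b = geom.bead_diameter / 2.0
        dp = 0.2 * GAMMA / r_b
        prof = match_profile(dp, geom, PEG)
        r, h = prof.generatrix[:, 0], prof.generatrix[:, 1]
        dr, dh = np.gradient(r), np.gradient(h)
        ds = np.hypot(dr, dh)
        phi = np.unwrap(np.arctan2(dh, dr))
        dphi_ds = np.gradient(phi) / ds
        # liquid on the right of travel: 2 K_m = -(dphi/ds + sin phi / r)
        two_km = -(dphi_ds + np.sin(phi) / r)
        lhs = (dp - PEG.liquid_density * CODATA.gravity_g * h) / GAMMA
        resid = np.abs(lhs - two_km)[5:-5]
        assert resid.max() < 1e-3 * abs(dp) / GAMMA


class TestMatchProfile:
    def test_substrate_angle_within_tolerance(self, default_geometry):
        prof = match_profile(0.0, default_geometry, PEG)
        assert abs(prof.achieved_theta_s - 30.0) <= 0.3

    def test_tighter_tolerance_barely_moves_volume(self, default_geometry):
        dp = 0.15 * GAMMA / 2.5e-6
        a = match_profile(dp, default_geometry, PEG, tolerance=0.3)
        b = match_profile(dp, default_geometry, PEG, tolerance=0.03)
        assert abs(a.liquid_volume - b.liquid_volume) / b.liquid_volume < 0.01

    def test_degenerate_tolerance_returns_first_crossing(self, default_geometry):
        prof = match_profile(0.0, default_geometry, PEG, tolerance=180.0)
        assert prof.ok

    def test_unsolvable_pressure_raises(self, default_geometry):
        with pytest.raises(MeniscusNotFoundError, match="no meniscus"):
            match_profile(4.0 * GAMMA / 2.5e-6, default_geometry, PEG)


class TestRevolutionGeometry:
    def test_cap_volume_formula(self):
        r_cap, height = 1.3, 0.8
        r, h = cap_arrays(r_cap, height)
        v_true = math.pi * height**2 * (3 * r_cap - height) / 3.0
        assert revolution_volume(r, h) == pytest.approx(v_true, rel=1e-8)

    def test_cap_area_formula(self):
        # dense sampling: arc length is estimated from chords, O(ds^2)
        r_cap, height = 1.3, 0.8
        r, h = cap_arrays(r_cap, height, n=8001)
        assert revolution_area(r, h) == pytest.approx(2 * math.pi * r_cap * height, rel=1e-8)

    def test_volume_additivity_at_a_split(self):
        r, h = cap_arrays(1.3, 0.8, n=2001)
        total = revolution_volume(r, h)
        k = 1000  # even split index keeps quadrature panels aligned
        v1 = revolution_volume(r[: k + 1], h[: k + 1])
        v2 = revolution_volume(r[k:], h[k:])
        assert abs((v1 + v2) - total) / total < 1e-10

    def test_degenerate_generatrix_has_zero_volume(self):
        r = np.full(5, 0.3)
        h = np.full(5, 0.0)
        assert revolution_volume(r, h) == 0.0

    def test_area_scaling_law(self):
        r, h = cap_arrays(1.3, 0.8, n=801)
        assert revolution_area(2 * r, 2 * h) == pytest.approx(4 * revolution_area(r, h), rel=1e-12)

    def test_catenoid_minimizes_area_among_perturbations(self, rng):
        a, h0 = 0.8, -0.3
        u = np.linspace(0.4, 1.4, 1001)
        h = h0 + a * u
        r = a * np.cosh(u)
        base = revolution_area(r, h)
        bump = np.sin(np.pi * (u - u[0]) / (u[-1] - u[0]))  # fixed endpoints
        for amp in (0.01, 0.03, -0.02):
            assert revolution_area(r + amp * bump, h) > base

    def test_profile_volume_matches_stored_value(self, small_family):
        for prof in small_family.profiles:
            v = profile_volume(prof)
            assert v == pytest.approx(prof.liquid_volume, rel=5e-4)
            assert profile_area(prof) == pytest.approx(prof.liquid_vapor_area, rel=5e-4)


class TestShapeFamily:
    def test_volumes_strictly_increasing(self, small_family):
        assert np.all(np.diff(small_family.volumes) > 0)

    def test_profiles_stay_outside_bead_and_above_substrate(self, small_family):
        r_b = small_family.geometry.bead_diameter / 2.0
        for prof in small_family.profiles:
            r, h = prof.generatrix[:, 0], prof.generatrix[:, 1]
            assert np.all(h >= -1e-15)
            dist = np.hypot(r, h - r_b)
            assert dist.min() >= r_b * (1.0 - 1e-6)

    def test_single_shape_family(self, default_geometry):
        fam = build_family(default_geometry, n_shapes=1, scan_points=12)
        assert len(fam) == 1
        assert fam.profiles[0].ok

    def test_partial_family_warns(self, default_geometry):
        with pytest.warns(UserWarning, match="partial family"):
            fam = build_family(
                default_geometry, n_shapes=10,
                delta_p_range=(0.1 * GAMMA / 2.5e-6, 0.25 * GAMMA / 2.5e-6),
                scan_points=4,
            )
        assert 0 < len(fam) < 10


class TestAreaOfVolume:
    def test_knots_reproduced_exactly(self, small_family):
        fn = area_of_volume(small_family)
        for v, a in zip(small_family.volumes, small_family.areas):
            assert fn(v) == pytest.approx(a, rel=1e-12)

    def test_midpoint_between_neighbors(self, small_family):
        fn = area_of_volume(small_family)
        v_mid = 0.5 * (small_family.volumes[2] + small_family.volumes[3])
        lo, hi = sorted((small_family.areas[2], small_family.areas[3]))
        assert lo <= fn(v_mid) <= hi

    def test_out_of_range_refused(self, small_family):
        fn = area_of_volume(small_family)
        with pytest.raises(ValueError, match="outside the family range"):
            fn(small_family.volumes[-1] * 10)

    def test_refinement_convergence(self, default_geometry, family70):
        # halving the family density changes interpolated areas by < 1%
        fam35 = build_family(default_geometry, n_shapes=35)
        f70 = area_of_volume(family70)
        f35 = area_of_volume(fam35)
        lo = max(f70.v_min, f35.v_min)
        hi = min(f70.v_max, f35.v_max)
        for v in np.geomspace(lo * 1.01, hi * 0.99, 25):
            assert f35(v) == pytest.approx(f70(v), rel=0.01)
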