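"""Axisymmetric Young-Laplace solver for the bead-substrate meniscus.

The liquid-air interface of the micro-reflector satisfies the
Young-Laplace balance  dp - rho g h = 2 gamma K_m, with K_m the local
mean curvature.  For an axisymmetric interface written as a generatrix
curve (r(s), h(s)) parameterized by arc length s with tangent
inclination phi, the balance becomes the first-order system

    dr/ds   = cos(phi)
    dh/ds   = sin(phi)
    dphi/ds = (dp - rho g h)/gamma - sin(phi)/r

The arc-length form handles vertical tangents that the graph form h(r)
cannot.  A profile is shot from a contact point on the bead (polar angle
``alpha`` from the bottom tangency point) with launch direction fixed by
the particle contact angle theta_p, integrated until it reaches the
substrate plane h = 0; the substrate contact angle it arrives with is
then matched to the target theta_s by a 1-D root search over alpha.

Internally the system is nondimensionalized by the bead radius R:
lengths in units of R, pressure as kappa = dp R / gamma, gravity as the
Bond number Bo = rho g R^2 / gamma (~3e-5 at 10 um: negligible but kept).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson, solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .constants import CODATA, PEGProperties, PhysicalConstants

__all__ = [
    "ContactGeometry",
    "MeniscusProfile",
    "ShapeFamily",
    "MeniscusNotFoundError",
    "integrate_generatrix",
    "solve_profile",
    "match_profile",
    "match_all_profiles",
    "build_family",
    "profile_volume",
    "profile_area",
    "revolution_volume",
    "revolution_area",
    "area_of_volume",
]

logger = logging.getLogger(__name__)

#: number of equal-arc-length samples stored per generatrix (stabilizes the
#: downstream ray-tracing surface model)
GENERATRIX_POINTS = 400
#: denser sampling used internally for volume / area quadrature
_QUAD_POINTS = 2001

STATUS_OK = "ok"
STATUS_BEAD_REENTRY = "bead_reentry"
STATUS_PINCH_OFF = "pinch_off"
STATUS_NO_CROSSING = "no_substrate_crossing"


class MeniscusNotFoundError(RuntimeError):
    """No meniscus satisfying the substrate contact angle exists at this dp."""


@dataclass(frozen=True)
class ContactGeometry:
    """Bead-on-substrate wetting geometry."""

    bead_diameter: float = 5e-6  # m
    particle_contact_angle: float = 60.0  # deg, through the liquid, vs the bead tangent
    substrate_contact_angle: float = 30.0  # deg, through the liquid, vs the substrate
    bead_substrate_gap: float = 0.0  # m (0 = bead tangent to the substrate)

    def __post_init__(self) -> None:
        if self.bead_diameter <= 0:
            raise ValueError("bead diameter must be positive")
        for name in ("particle_contact_angle", "substrate_contact_angle"):
            v = getattr(self, name)
            if not (0.0 < v < 180.0):
                raise ValueError(f"{name} must lie in (0, 180) degrees, got {v}")


@dataclass(frozen=True)
class MeniscusProfile:
    """One axisymmetric liquid-air interface.

    ``generatrix`` is an (N, 2) array of (r, h) points in meters running
    from the contact circle on the bead to the contact circle on the
    substrate (h = 0).
    """

    generatrix: np.ndarray
    delta_p: float  # Pa
    contact_polar_angle_on_bead: float  # deg from the bottom tangency point
    achieved_theta_s: float  # deg
    liquid_volume: float  # m^3
    liquid_vapor_area: float  # m^2
    status: str = STATUS_OK
    geometry: ContactGeometry | None = field(default=None, repr=False, compare=False)

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclass(frozen=True)
class ShapeFamily:
    """Volume-ordered family of meniscus shapes for one wetting geometry."""

    geometry: ContactGeometry
    profiles: tuple[MeniscusProfile, ...]
    volumes: np.ndarray  # m^3, strictly increasing
    areas: np.ndarray  # m^2

    def __post_init__(self) -> None:
        if np.any(np.diff(self.volumes) <= 0):
            raise ValueError("family volumes must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("family areas must be positive")

    def __len__(self) -> int:
        return len(self.profiles)


# ---------------------------------------------------------------------------
# core integrator (dimensionless)
# ---------------------------------------------------------------------------

def integrate_generatrix(
    r0: float,
    h0: float,
    phi0: float,
    kappa: float,
    bond: float = 0.0,
    *,
    bead: bool = True,
    s_max: float = 40.0,
    rtol: float = 1e-9,
    r_min: float = 1e-6,
    r_max: float = 30.0,
    h_max: float = 4.0,
):
    """Integrate the arc-length Young-Laplace system from (r0, h0, phi0).

    All quantities are dimensionless (lengths in bead radii, ``kappa`` =
    dp R / gamma, ``bond`` = rho g R^2 / gamma).  phi0 is the initial
    tangent inclination in radians.  Integration stops at the substrate
    crossing h = 0 (from above), at pinch-off r -> 0, on re-entry into the
    unit bead centered at (0, 1) when ``bead`` is true, or at ``s_max``.

    Orientation: the liquid lies on the LEFT of the direction of travel
    (outward normal (sin phi, -cos phi)); with that convention a spherical
    cap traversed from its contact circle toward the apex solves the system
    with kappa = +2/R_cap.  Callers whose traversal has the liquid on the
    right (e.g. bead-to-substrate meniscus shooting) must negate kappa and
    bond.

    Returns ``(sol, status)`` where ``sol`` is the scipy dense solution and
    ``status`` one of the STATUS_* strings.
    """

    def rhs(_s: float, y: np.ndarray):
        r, h, phi = y
        return (math.cos(phi), math.sin(phi), kappa - bond * h - math.sin(phi) / r)

    def hit_substrate(_s: float, y: np.ndarray) -> float:
        return y[1]
    hit_substrate.terminal = True  # type: ignore[attr-defined]
    hit_substrate.direction = -1  # type: ignore[attr-defined]

    def pinch(_s: float, y: np.ndarray) -> float:
        return y[0] - r_min
    pinch.terminal = True  # type: ignore[attr-defined]
    pinch.direction = -1  # type: ignore[attr-defined]

    def runaway(_s: float, y: np.ndarray) -> float:
        # escape far outside any plausible meniscus: abort early, counts as
        # "no substrate crossing"
        return max(y[0] - r_max, y[1] - h_max)
    runaway.terminal = True  # type: ignore[attr-defined]
    runaway.direction = 1  # type: ignore[attr-defined]

    events = [hit_substrate, pinch, runaway]
    if bead:
        def reenter(_s: float, y: np.ndarray) -> float:
            return y[0] ** 2 + (y[1] - 1.0) ** 2 - 1.0
        reenter.terminal = True  # type: ignore[attr-defined]
        reenter.direction = -1  # type: ignore[attr-defined]
        events.append(reenter)

    sol = solve_ivp(
        rhs, (0.0, s_max), [r0, h0, phi0], method="RK45",
        rtol=rtol, atol=1e-12, dense_output=True, events=events,
    )
    if len(sol.t_events[0]):
        status = STATUS_OK
    elif len(sol.t_events[1]):
        status = STATUS_PINCH_OFF
    elif bead and len(sol.t_events[3]):
        status = STATUS_BEAD_REENTRY
    else:
        status = STATUS_NO_CROSSING
    return sol, status


def _launch_state(alpha_deg: float, theta_p_deg: float) -> tuple[float, float, float]:
    """Initial (r0, h0, phi0) on the unit bead (dimensionless).

    The contact point sits at polar angle alpha from the bottom tangency
    point; the interface leaves it at the particle contact angle theta_p
    measured through the liquid relative to the local bead tangent, which
    gives the tangent inclination phi0 = alpha + theta_p - 180 deg.
    """
    a = math.radians(alpha_deg)
    phi0 = math.radians(alpha_deg + theta_p_deg - 180.0)
    r0 = math.sin(a)
    h0 = 1.0 - math.cos(a)
    return r0, h0, phi0


def solve_profile(
    delta_p: float,
    contact_polar_angle: float,
    geometry: ContactGeometry,
    materials: PEGProperties | None = None,
    include_gravity: bool = True,
    constants: PhysicalConstants = CODATA,
    rtol: float = 1e-9,
    light: bool = False,
) -> MeniscusProfile:
    """Shoot one interface from the bead at the given polar angle.

    Returns a MeniscusProfile candidate; ``status`` reports whether the
    curve reached the substrate (no theta_s guarantee) or how it failed.
    With ``light=True`` only the achieved substrate angle is computed
    (empty generatrix, NaN volume/area) -- used during root scans.
    """
    materials = materials or PEGProperties()
    radius = geometry.bead_diameter / 2.0
    gamma = materials.surface_tension
    kappa = delta_p * radius / gamma
    bond = (
        materials.liquid_density * constants.gravity_g * radius**2 / gamma
        if include_gravity else 0.0
    )
    r0, h0, phi0 = _launch_state(contact_polar_angle, geometry.particle_contact_angle)
    # nudge off the bead surface so the re-entry event does not fire at s=0;
    # bead-to-substrate traversal has the liquid on the right, hence -kappa
    ds0 = 1e-9
    sol, status = integrate_generatrix(
        r0 + ds0 * math.cos(phi0), h0 + ds0 * math.sin(phi0), phi0,
        -kappa, -bond, bead=True, rtol=rtol,
    )
    if status != STATUS_OK:
        return MeniscusProfile(
            generatrix=np.empty((0, 2)), delta_p=delta_p,
            contact_polar_angle_on_bead=contact_polar_angle,
            achieved_theta_s=math.nan, liquid_volume=math.nan,
            liquid_vapor_area=math.nan, status=status, geometry=geometry,
        )
    s_end = sol.t_events[0][0]
    phi_end = sol.y_events[0][0][2]
    achieved_theta_s = -math.degrees(phi_end)

    if light:
        return MeniscusProfile(
            generatrix=np.empty((0, 2)), delta_p=delta_p,
            contact_polar_angle_on_bead=contact_polar_angle,
            achieved_theta_s=achieved_theta_s, liquid_volume=math.nan,
            liquid_vapor_area=math.nan, status=STATUS_OK, geometry=geometry,
        )

    # dense quadrature samples for volume / area, then the stored generatrix
    s_quad = np.linspace(0.0, s_end, _QUAD_POINTS)
    rq, hq, _ = sol.sol(s_quad)
    rq = np.concatenate(([r0], rq[1:]))
    hq = np.concatenate(([h0], hq[1:-1], [0.0]))
    vol_dimless = revolution_volume(rq, hq, bead_contact_angle_deg=contact_polar_angle)
    area_dimless = 2.0 * math.pi * simpson(rq, x=s_quad)

    s_store = np.linspace(0.0, s_end, GENERATRIX_POINTS)
    rs, hs, _ = sol.sol(s_store)
    rs[0], hs[0] = r0, h0
    hs[-1] = 0.0
    generatrix = np.column_stack((rs, hs)) * radius

    return MeniscusProfile(
        generatrix=generatrix,
        delta_p=delta_p,
        contact_polar_angle_on_bead=contact_polar_angle,
        achieved_theta_s=achieved_theta_s,
        liquid_volume=vol_dimless * radius**3,
        liquid_vapor_area=area_dimless * radius**2,
        status=STATUS_OK,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# volume / area of revolution
# ---------------------------------------------------------------------------

def revolution_volume(
    r: np.ndarray,
    h: np.ndarray,
    bead_contact_angle_deg: float | None = None,
    bead_radius: float = 1.0,
) -> float:
    """Volume of revolution of the liquid region bounded by a generatrix.

    The generatrix runs from its upper end (on the bead, or on the axis for
    a free cap) down to the substrate plane h = 0.  By Green's theorem the
    enclosed volume is the boundary circulation of pi r^2 dh; the substrate
    segment contributes nothing and the bead arc term (subtracting the
    submerged spherical segment) is closed-form.
    """
    r = np.asarray(r, float)
    h = np.asarray(h, float)
    if r.ndim != 1 or r.shape != h.shape or len(r) < 3:
        raise ValueError("generatrix must be matching 1-D arrays of length >= 3")
    steps = np.hypot(np.diff(r), np.diff(h))
    if np.all(steps == 0):
        return 0.0  # zero-extent generatrix encloses nothing
    if np.any(steps == 0):
        raise ValueError("generatrix contains repeated points")
    v = -math.pi * simpson(r**2, x=h)
    if bead_contact_angle_deg is not None and bead_contact_angle_deg > 0:
        a = math.radians(bead_contact_angle_deg)
        # integral of sin^3 from 0 to alpha, times pi R^3, walked downward
        v -= math.pi * bead_radius**3 * (2.0 / 3.0 - math.cos(a) + math.cos(a) ** 3 / 3.0)
    if v < 0 and v > -1e-12 * max(abs(v), 1.0):
        v = 0.0
    return v


def revolution_area(r: np.ndarray, h: np.ndarray) -> float:
    """Lateral surface-of-revolution area 2 pi int r ds of a generatrix."""
    r = np.asarray(r, float)
    h = np.asarray(h, float)
    ds = np.hypot(np.diff(r), np.diff(h))
    s = np.concatenate(([0.0], np.cumsum(ds)))
    return 2.0 * math.pi * simpson(r, x=s)


def profile_volume(profile: MeniscusProfile, geometry: ContactGeometry | None = None) -> float:
    """Liquid volume of a profile from its stored generatrix."""
    geometry = geometry or profile.geometry
    alpha = profile.contact_polar_angle_on_bead
    bead_r = geometry.bead_diameter / 2.0 if geometry is not None else 1.0
    r, h = profile.generatrix[:, 0], profile.generatrix[:, 1]
    _check_no_self_intersection(r, h)
    return revolution_volume(r, h, bead_contact_angle_deg=alpha, bead_radius=bead_r)


def profile_area(profile: MeniscusProfile) -> float:
    """Liquid-vapor area of a profile from its stored generatrix."""
    return revolution_area(profile.generatrix[:, 0], profile.generatrix[:, 1])


def _check_no_self_intersection(r: np.ndarray, h: np.ndarray) -> None:
    # O(N^2) segment test is wasteful; a cheap necessary check suffices for
    # the smooth YL curves: reject if the polyline revisits a point.
    pts = np.column_stack((r, h))
    d = np.hypot(np.diff(r), np.diff(h))
    if np.any(d == 0):
        raise ValueError("generatrix is degenerate (repeated points)")
    # bounding check: curve turning more than 360 degrees implies a loop
    ang = np.arctan2(np.diff(h), np.diff(r))
    turn = np.abs(np.diff(np.unwrap(ang))).sum()
    if turn > 2.0 * math.pi:
        raise ValueError("generatrix self-intersects (total turning exceeds 360 degrees)")
    del pts


# ---------------------------------------------------------------------------
# matching and family construction
# ---------------------------------------------------------------------------

def match_all_profiles(
    delta_p: float,
    geometry: ContactGeometry,
    materials: PEGProperties | None = None,
    tolerance: float = 0.3,
    *,
    include_gravity: bool = True,
    alpha_range: tuple[float, float] = (0.5, 160.0),
    alpha_step: float = 2.0,
    rtol: float = 1e-9,
) -> list[MeniscusProfile]:
    """All bead contact points whose profiles meet the substrate at theta_s.

    At a fixed pressure difference the achieved substrate angle is generally
    non-monotone in the bead polar angle alpha, so up to two menisci (a
    small and a large branch) can satisfy the same contact-angle pair; both
    are returned, ordered by alpha.
    """
    materials = materials or PEGProperties()
    target = geometry.substrate_contact_angle

    cache: dict[float, MeniscusProfile] = {}
    scan_rtol = min(1e-6, rtol * 100)

    def candidate(alpha: float, light: bool = True) -> MeniscusProfile:
        key = alpha if light else -alpha - 1000.0
        if key not in cache:
            cache[key] = solve_profile(
                delta_p, alpha, geometry, materials,
                include_gravity=include_gravity,
                rtol=scan_rtol if light else rtol, light=light,
            )
        return cache[key]

    def mismatch(alpha: float) -> float:
        p = candidate(alpha)
        return p.achieved_theta_s - target if p.ok else math.nan

    alphas = np.arange(alpha_range[0], alpha_range[1] + 1e-9, alpha_step)
    vals = np.array([mismatch(a) for a in alphas])
    finite = np.isfinite(vals)

    if tolerance >= 180.0:
        # degenerate pass-through: first profile that reaches the substrate
        for a, good in zip(alphas, finite):
            if good:
                return [candidate(float(a), light=False)]
        raise MeniscusNotFoundError(
            f"no meniscus exists at dp={delta_p:.6g} Pa (no profile reaches the substrate)"
        )

    roots: list[MeniscusProfile] = []
    for i in range(len(alphas) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        if vals[i] == 0.0:
            roots.append(candidate(float(alphas[i]), light=False))
            continue
        if vals[i] * vals[i + 1] < 0:
            try:
                a_root = brentq(mismatch, alphas[i], alphas[i + 1], xtol=1e-4)
            except ValueError:
                continue
            prof = candidate(float(a_root), light=False)
            if prof.ok and abs(prof.achieved_theta_s - target) <= tolerance:
                roots.append(prof)
    if not roots:
        raise MeniscusNotFoundError(
            f"no meniscus exists at dp={delta_p:.6g} Pa for theta_s={target} deg "
            f"(no sign change over alpha in {alpha_range})"
        )
    return roots


def match_profile(
    delta_p: float,
    geometry: ContactGeometry,
    materials: PEGProperties | None = None,
    tolerance: float = 0.3,
    **kwargs,
) -> MeniscusProfile:
    """Matched meniscus at the given dp (the smallest-contact-circle branch).

    One-dimensional root search over the bead polar angle such that the
    achieved substrate contact angle is within ``tolerance`` degrees of the
    target; see :func:`match_all_profiles` for the multi-branch variant.
    """
    return match_all_profiles(delta_p, geometry, materials, tolerance, **kwargs)[0]


def build_family(
    geometry: ContactGeometry,
    materials: PEGProperties | None = None,
    n_shapes: int = 70,
    delta_p_range: tuple[float, float] | None = None,
    *,
    scan_points: int | None = None,
    include_gravity: bool = True,
) -> ShapeFamily:
    """Family of matched meniscus shapes ordered by strictly increasing volume.

    Scans a range of pressure differences (default: kappa = dp R / gamma in
    [-12, 1.6], which spans vanishing pendular rings to near-equator drops),
    matches each solvable dp, then selects ``n_shapes`` profiles spaced
    approximately uniformly in log-volume.  Unsolvable dp values are skipped
    with a log message; if fewer than ``n_shapes`` distinct volumes are
    solvable a partial family is returned with a warning.
    """
    materials = materials or PEGProperties()
    radius = geometry.bead_diameter / 2.0
    gamma = materials.surface_tension
    n_scan = scan_points or max(2 * n_shapes, 60)
    if delta_p_range is None:
        # Composite default grid in kappa = dp R / gamma.  Small pendular
        # rings live at strongly negative dp (capillary suction ~ -gamma /
        # ring size), large drop-like menisci in a narrow band of small
        # positive dp near the fold where the two solution branches merge,
        # so the negative side is sampled logarithmically and the positive
        # side finely.
        kneg = -np.geomspace(60.0, 0.005, n_scan // 2)
        kpos = np.linspace(0.005, 0.6, n_scan - n_scan // 2)
        dps = np.concatenate((kneg, kpos)) * gamma / radius
    else:
        dps = np.linspace(delta_p_range[0], delta_p_range[1], n_scan)

    solved: list[MeniscusProfile] = []
    for dp in dps:
        try:
            solved.extend(match_all_profiles(
                float(dp), geometry, materials, include_gravity=include_gravity,
            ))
        except MeniscusNotFoundError:
            logger.info("no meniscus at dp=%.6g Pa; skipped", dp)
    if not solved:
        raise MeniscusNotFoundError(
            f"no meniscus solvable anywhere in dp range {delta_p_range}"
        )

    solved.sort(key=lambda p: p.liquid_volume)
    vols = np.array([p.liquid_volume for p in solved])
    keep = np.concatenate(([True], np.diff(vols) > 1e-9 * vols[:-1]))
    solved = [p for p, k in zip(solved, keep) if k]
    vols = vols[keep]

    if len(solved) <= n_shapes:
        picked = solved
        if len(solved) < n_shapes:
            warnings.warn(
                f"only {len(solved)} of {n_shapes} requested shapes were solvable "
                f"in dp range {delta_p_range}; returning a partial family",
                stacklevel=2,
            )
    else:
        targets = np.geomspace(vols[0], vols[-1], n_shapes)
        idx: list[int] = []
        for tv in targets:
            i = int(np.argmin(np.abs(np.log(vols) - np.log(tv))))
            while i in idx and i + 1 < len(vols):
                i += 1
            if i not in idx:
                idx.append(i)
        # refill from unused scan profiles if collisions dropped some targets
        unused = [i for i in range(len(vols)) if i not in idx]
        while len(idx) < n_shapes and unused:
            idx.append(unused.pop(0))
        idx = sorted(set(idx))[:n_shapes]
        picked = [solved[i] for i in idx]

    picked.sort(key=lambda p: p.liquid_volume)
    volumes = np.array([p.liquid_volume for p in picked])
    areas = np.array([p.liquid_vapor_area for p in picked])
    return ShapeFamily(geometry=geometry, profiles=tuple(picked), volumes=volumes, areas=areas)


def area_of_volume(family: ShapeFamily):
    """Monotone interpolant V -> A_lv over the family's (V, A) knots.

    Queries outside [V_min, V_max] raise ValueError; the returned callable
    carries ``v_min`` / ``v_max`` attributes so the growth integrator can
    truncate at the domain edge.
    """
    if len(family) < 2:
        raise ValueError("area_of_volume needs a family with at least 2 members")
    interp = PchipInterpolator(family.volumes, family.areas, extrapolate=False)
    v_min, v_max = float(family.volumes[0]), float(family.volumes[-1])

    def area(v: float) -> float:
        if not (v_min <= v <= v_max):
            raise ValueError(
                f"volume {v:.6g} m^3 outside the family range [{v_min:.6g}, {v_max:.6g}]"
            )
        return float(interp(v))

    area.v_min = v_min  # type: ignore[attr-defined]
    area.v_max = v_max  # type: ignore[attr-defined]
    return area
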