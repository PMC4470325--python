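"""Non-sequential Monte-Carlo ray tracing with Fresnel intensity splitting.

The optical scene is the fluorescent polystyrene bead (n = 1.61) resting
on a transparent coverslip slab (n = 1.5, 180 um thick, laterally
infinite), optionally wrapped in the liquid meniscus (n = 1.46) described
by a surface of revolution from a :class:`~mrsim.meniscus.MeniscusProfile`.
Isotropic point emitters are placed uniformly inside the bead; every ray
is split at each interface into a reflected and a refracted child carrying
the unpolarized Fresnel power fractions, until it escapes to the far
field, drops below an intensity cutoff, or exceeds the maximum split
depth.  Escaping rays are binned by the polar angle of their final
direction into two hemispherical detectors (-80..80 deg, 1 deg bins);
an exact intensity ledger (detected up/down, outside aperture, cutoff,
trapped) is maintained and must conserve the emitted intensity.

The per-ray depth-first splitting walk is compiled with numba; the
public API works with plain numpy arrays and small dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import PEGProperties
from .meniscus import ContactGeometry, MeniscusProfile

__all__ = [
    "OpticalScene",
    "Ray",
    "DetectorPair",
    "TraceConfig",
    "sample_emitters",
    "sample_directions",
    "fresnel_split",
    "intersect",
    "trace",
    "run_simulation",
    "trapped_fraction",
    "trapped_fraction_quadrature",
    "collection_within_NA",
]

# medium codes used by the kernel
AIR, BEAD, LIQUID, SLAB = 0, 1, 2, 3

N_BINS = 160  # 1-degree bins from -80 to 80 per hemisphere
BIN_EDGES = np.arange(-80.0, 81.0, 1.0)

_EPS_T = 1e-12  # m, self-hit exclusion along the ray
LEDGER_TOL = 1e-6


@dataclass(frozen=True)
class Ray:
    """A single ray: origin (m), unit direction, relative intensity."""

    origin: np.ndarray
    direction: np.ndarray
    relative_intensity: float = 1.0
    current_medium: int = BEAD
    depth: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("ray direction must be normalized to 1e-12")
        if not (0.0 < self.relative_intensity <= 1.0):
            raise ValueError("relative intensity must lie in (0, 1]")


@dataclass(frozen=True)
class TraceConfig:
    """Monte-Carlo budget and termination policy."""

    n_emitters: int = 2000
    rays_per_emitter: int = 5000
    max_depth: int = 12
    intensity_cutoff: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_emitters < 1 or self.rays_per_emitter < 1:
            raise ValueError("ray budgets must be positive")
        if not (0.0 < self.intensity_cutoff <= 1e-2):
            raise ValueError("intensity cutoff must lie in (0, 1e-2]")

    @property
    def total_rays(self) -> int:
        return self.n_emitters * self.rays_per_emitter

    @classmethod
    def fast(cls, rng_seed: int = 0, **kwargs) -> "TraceConfig":
        """Reduced 200 x 2000 budget for desk-scale runs."""
        return cls(n_emitters=200, rays_per_emitter=2000, rng_seed=rng_seed, **kwargs)


@dataclass
class DetectorPair:
    """Far-field intensity binned by signed polar angle, both hemispheres.

    The signed angle is the polar angle from the optical axis with the sign
    of the ray's x-direction (the scene is axisymmetric); bins are 1 degree
    wide from -80 to 80 degrees.  ``distance`` is cosmetic: detection is by
    ray direction in the far field.
    """

    upper_counts: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS))
    lower_counts: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS))
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())
    distance: float = 0.1  # m

    def counts(self, side: str) -> np.ndarray:
        if side == "upper":
            return self.upper_counts
        if side == "lower":
            return self.lower_counts
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


@dataclass(frozen=True)
class OpticalScene:
    """Watertight optical geometry: bead + optional meniscus + coverslip."""

    bead_diameter: float = 5e-6
    n_bead: float = 1.61
    meniscus_generatrix: np.ndarray | None = None  # (N, 2) (r, z) in m
    n_liquid: float = 1.46
    contact_polar_angle: float = 0.0  # deg, wetted bead cap extent
    substrate: bool = True
    slab_thickness: float = 180e-6
    n_substrate: float = 1.5
    n_ambient: float = 1.0

    @property
    def bead_radius(self) -> float:
        return self.bead_diameter / 2.0

    @property
    def bead_center_z(self) -> float:
        return self.bead_radius  # tangent to the substrate plane z = 0

    @property
    def has_meniscus(self) -> bool:
        return self.meniscus_generatrix is not None and len(self.meniscus_generatrix) >= 2

    @property
    def substrate_contact_radius(self) -> float:
        return float(self.meniscus_generatrix[-1, 0]) if self.has_meniscus else 0.0

    def refractive_index(self, medium: int) -> float:
        return (self.n_ambient, self.n_bead, self.n_liquid, self.n_substrate)[medium]

    @classmethod
    def bare(cls, bead_diameter: float = 5e-6, substrate: bool = True, **kwargs) -> "OpticalScene":
        """Reference scene: the bead without any micro-reflector."""
        return cls(bead_diameter=bead_diameter, substrate=substrate, **kwargs)

    @classmethod
    def from_profile(
        cls,
        profile: MeniscusProfile,
        geometry: ContactGeometry | None = None,
        materials: PEGProperties | None = None,
        **kwargs,
    ) -> "OpticalScene":
        geometry = geometry or profile.geometry
        materials = materials or PEGProperties()
        return cls(
            bead_diameter=geometry.bead_diameter,
            meniscus_generatrix=np.asarray(profile.generatrix, float),
            n_liquid=materials.refractive_index,
            contact_polar_angle=profile.contact_polar_angle_on_bead,
            **kwargs,
        )

    def _kernel_args(self):
        if self.has_meniscus:
            gen = np.ascontiguousarray(self.meniscus_generatrix, dtype=np.float64)
            has_men = True
            cos_alpha = math.cos(math.radians(self.contact_polar_angle))
            r_sub = float(gen[-1, 0])
        else:
            gen = np.zeros((2, 2))
            has_men = False
            cos_alpha = 2.0  # nothing wetted
            r_sub = 0.0
        n_arr = np.array(
            [self.n_ambient, self.n_bead, self.n_liquid, self.n_substrate], float
        )
        return (
            self.bead_center_z, self.bead_radius, has_men,
            gen[:, 0].copy(), gen[:, 1].copy(), cos_alpha, r_sub,
            self.substrate, self.slab_thickness, n_arr,
        )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _lhs_uniform(n: int, rng: np.random.Generator) -> np.ndarray:
    """n jittered Latin-hypercube samples of Uniform(0,1): one per stratum,
    in random order.  Marginally uniform, far lower clustering variance."""
    return (rng.permutation(n) + rng.random(n)) / n


def sample_emitters(
    n: int, bead_radius: float, bead_center_z: float, rng: np.random.Generator
) -> np.ndarray:
    """n points uniform in the bead ball.

    Each of the three ball coordinates (radius^3, cos polar, azimuth) is
    Latin-hypercube stratified independently: every point is still
    marginally uniform in the ball, but the emitter-level clustering
    variance that dominates small-budget Monte-Carlo runs is strongly
    suppressed.
    """
    if n < 1:
        raise ValueError("need at least one emitter")
    radii = bead_radius * _lhs_uniform(n, rng) ** (1.0 / 3.0)
    cos_t = 2.0 * _lhs_uniform(n, rng) - 1.0
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * _lhs_uniform(n, rng)
    pts = np.column_stack((
        radii * sin_t * np.cos(phi),
        radii * sin_t * np.sin(phi),
        radii * cos_t + bead_center_z,
    ))
    return pts


def sample_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the sphere (full 4 pi solid angle), with
    cos(polar) and azimuth each Latin-hypercube stratified."""
    if n < 1:
        raise ValueError("need at least one direction")
    cos_t = 2.0 * _lhs_uniform(n, rng) - 1.0
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * _lhs_uniform(n, rng)
    return np.column_stack((sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t))


# ---------------------------------------------------------------------------
# Fresnel
# ---------------------------------------------------------------------------

def fresnel_split(n_in: float, n_out: float, incidence_angle_deg: float):
    """Unpolarized Fresnel power split (R, T, refraction angle in degrees).

    Beyond the critical angle (n_in > n_out) R = 1, T = 0 and the
    refraction angle is NaN (no transmitted ray).
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive")
    if not (0.0 <= incidence_angle_deg < 90.0):
        raise ValueError("incidence angle must lie in [0, 90) degrees")
    ci = math.cos(math.radians(incidence_angle_deg))
    si = math.sin(math.radians(incidence_angle_deg))
    sin2_t = (n_in / n_out) ** 2 * si * si
    if sin2_t >= 1.0:
        return 1.0, 0.0, math.nan
    ct = math.sqrt(1.0 - sin2_t)
    rs = (n_in * ci - n_out * ct) / (n_in * ci + n_out * ct)
    rp = (n_in * ct - n_out * ci) / (n_in * ct + n_out * ci)
    r = 0.5 * (rs * rs + rp * rp)
    return r, 1.0 - r, math.degrees(math.asin(math.sqrt(sin2_t)))


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hit_sphere(px, py, pz, dx, dy, dz, cz, R):
    ox, oy, oz = px, py, pz - cz
    b = ox * dx + oy * dy + oz * dz
    c = ox * ox + oy * oy + oz * oz - R * R
    disc = b * b - c
    if disc <= 0.0:
        return -1.0
    sq = math.sqrt(disc)
    t = -b - sq
    if t > _EPS_T:
        return t
    t = -b + sq
    if t > _EPS_T:
        return t
    return -1.0


@njit(cache=True, inline="always")
def _hit_plane(pz, dz, z_plane):
    if abs(dz) < 1e-300:
        return -1.0
    t = (z_plane - pz) / dz
    if t > _EPS_T:
        return t
    return -1.0


@njit(cache=True)
def _hit_meniscus(px, py, pz, dx, dy, dz, men_r, men_z, t_best):
    """Nearest intersection with the surface of revolution; (-1, -1) if none.

    Each generatrix segment is a conical frustum about the z axis; segments
    are pre-filtered by the z interval the ray can traverse within
    (eps, t_best).
    """
    nseg = men_r.shape[0] - 1
    # bounding-cylinder reject: line's closest approach to the z axis
    dxy2 = dx * dx + dy * dy
    r_max = men_r[0]
    for i in range(men_r.shape[0]):
        if men_r[i] > r_max:
            r_max = men_r[i]
    if dxy2 > 1e-300:
        perp = abs(px * dy - py * dx) / math.sqrt(dxy2)
        if perp >= r_max:
            return -1.0, -1
        # moving radially outward from outside the cylinder: cannot hit
        rho2 = px * px + py * py
        if rho2 >= r_max * r_max and (px * dx + py * dy) >= 0.0:
            return -1.0, -1
    else:
        if px * px + py * py >= r_max * r_max:
            return -1.0, -1
    # z window reachable by the ray
    if t_best > 1e30:
        t_hi = 1e30
    else:
        t_hi = t_best
    if dz >= 0.0:
        z_lo = pz
        z_hi = pz + t_hi * dz if t_hi < 1e30 else 1e30
    else:
        z_hi = pz
        z_lo = pz + t_hi * dz if t_hi < 1e30 else -1e30

    best_t = -1.0
    best_i = -1
    for i in range(nseg):
        r0 = men_r[i]
        z0 = men_z[i]
        r1 = men_r[i + 1]
        z1 = men_z[i + 1]
        if z0 < z1:
            s_lo, s_hi = z0, z1
        else:
            s_lo, s_hi = z1, z0
        if s_hi < z_lo or s_lo > z_hi:
            continue
        dzseg = z1 - z0
        seg_len = math.hypot(r1 - r0, dzseg)
        if abs(dzseg) < 1e-9 * seg_len:
            # near-horizontal segment: treat as a flat annulus at mid-height
            zm = 0.5 * (z0 + z1)
            if abs(dz) < 1e-300:
                continue
            t = (zm - pz) / dz
            if t <= _EPS_T or (best_t > 0.0 and t >= best_t) or t >= t_best:
                continue
            xh = px + t * dx
            yh = py + t * dy
            rho = math.sqrt(xh * xh + yh * yh)
            rlo = r0 if r0 < r1 else r1
            rhi = r1 if r1 > r0 else r0
            if rlo <= rho <= rhi:
                best_t = t
                best_i = i
            continue
        m = (r1 - r0) / dzseg
        q = r0 + m * (pz - z0)
        a = dx * dx + dy * dy - m * m * dz * dz
        b = px * dx + py * dy - m * dz * q
        c = px * px + py * py - q * q
        if abs(a) < 1e-300:
            if abs(b) < 1e-300:
                continue
            t = -c / (2.0 * b)
            if t > _EPS_T and t < t_best and (best_t < 0.0 or t < best_t):
                zh = pz + t * dz
                if s_lo - 1e-18 <= zh <= s_hi + 1e-18:
                    best_t = t
                    best_i = i
            continue
        disc = b * b - a * c
        if disc <= 0.0:
            continue
        sq = math.sqrt(disc)
        for sign in (-1.0, 1.0):
            t = (-b + sign * sq) / a
            if t <= _EPS_T or t >= t_best or (best_t > 0.0 and t >= best_t):
                continue
            zh = pz + t * dz
            if zh < s_lo - 1e-18 or zh > s_hi + 1e-18:
                continue
            # cone solutions with negative radius are spurious
            if r0 + m * (zh - z0) < 0.0:
                continue
            best_t = t
            best_i = i
    return best_t, best_i


@njit(cache=True)
def _trace_batch(
    origins, dirs, bead_cz, bead_R, has_men, men_r, men_z, cos_alpha, r_sub,
    has_sub, slab_T, n_arr, max_depth, cutoff,
):
    upper = np.zeros(N_BINS)
    lower = np.zeros(N_BINS)
    outside = 0.0
    truncated = 0.0
    trapped = 0.0

    nrays = origins.shape[0]
    stack_cap = max_depth + 4
    spx = np.empty(stack_cap)
    spy = np.empty(stack_cap)
    spz = np.empty(stack_cap)
    sdx = np.empty(stack_cap)
    sdy = np.empty(stack_cap)
    sdz = np.empty(stack_cap)
    sw = np.empty(stack_cap)
    smed = np.empty(stack_cap, np.int64)
    sdep = np.empty(stack_cap, np.int64)

    z_bot = -slab_T
    deg = 180.0 / math.pi

    for iray in range(nrays):
        sp = 0
        spx[0] = origins[iray, 0]
        spy[0] = origins[iray, 1]
        spz[0] = origins[iray, 2]
        sdx[0] = dirs[iray, 0]
        sdy[0] = dirs[iray, 1]
        sdz[0] = dirs[iray, 2]
        sw[0] = 1.0
        smed[0] = BEAD
        sdep[0] = 0
        sp = 1

        while sp > 0:
            sp -= 1
            px = spx[sp]
            py = spy[sp]
            pz = spz[sp]
            dx = sdx[sp]
            dy = sdy[sp]
            dz = sdz[sp]
            w = sw[sp]
            med = smed[sp]
            dep = sdep[sp]

            # nearest surface
            t_best = 1e300
            surf = -1
            t = _hit_sphere(px, py, pz, dx, dy, dz, bead_cz, bead_R)
            if t > 0.0 and t < t_best:
                t_best = t
                surf = 0
            if has_sub:
                t = _hit_plane(pz, dz, 0.0)
                if t > 0.0 and t < t_best:
                    t_best = t
                    surf = 2
                t = _hit_plane(pz, dz, z_bot)
                if t > 0.0 and t < t_best:
                    t_best = t
                    surf = 3
            if has_men:
                t, _seg = _hit_meniscus(px, py, pz, dx, dy, dz, men_r, men_z, t_best)
                if t > 0.0 and t < t_best:
                    t_best = t
                    surf = 1
                    men_seg = _seg
                else:
                    men_seg = -1
            else:
                men_seg = -1

            if surf < 0:
                # escaped to the far field
                if dz > 1e-12:
                    theta = math.acos(min(dz, 1.0)) * deg
                    if theta < 80.0:
                        sgn = 1.0 if dx >= 0.0 else -1.0
                        idx = int(sgn * theta + 80.0)
                        if idx >= N_BINS:
                            idx = N_BINS - 1
                        upper[idx] += w
                    else:
                        outside += w
                elif dz < -1e-12:
                    theta = math.acos(min(-dz, 1.0)) * deg
                    if theta < 80.0:
                        sgn = 1.0 if dx >= 0.0 else -1.0
                        idx = int(sgn * theta + 80.0)
                        if idx >= N_BINS:
                            idx = N_BINS - 1
                        lower[idx] += w
                    else:
                        outside += w
                else:
                    outside += w
                continue

            if dep >= max_depth:
                trapped += w
                continue

            # hit point
            hx = px + t_best * dx
            hy = py + t_best * dy
            hz = pz + t_best * dz

            # outward-vs-ray normal and new medium
            if surf == 0:
                nx = (hx) / bead_R
                ny = (hy) / bead_R
                nz = (hz - bead_cz) / bead_R
                if med == BEAD:
                    # leaving the bead: wetted below the contact circle?
                    if has_men and (bead_cz - hz) / bead_R > cos_alpha:
                        new_med = LIQUID
                    else:
                        new_med = AIR
                else:
                    new_med = BEAD
            elif surf == 1:
                i0 = men_seg
                trr = men_r[i0 + 1] - men_r[i0]
                tzz = men_z[i0 + 1] - men_z[i0]
                ln = math.hypot(trr, tzz)
                nr = tzz / ln
                nzc = -trr / ln
                rho = math.sqrt(hx * hx + hy * hy)
                if rho < 1e-300:
                    nx, ny, nz = 0.0, 0.0, 1.0
                else:
                    nx = nr * hx / rho
                    ny = nr * hy / rho
                    nz = nzc
                new_med = AIR if med == LIQUID else LIQUID
            elif surf == 2:
                nx, ny, nz = 0.0, 0.0, 1.0
                if dz < 0.0:
                    new_med = SLAB
                else:
                    rho = math.sqrt(hx * hx + hy * hy)
                    if has_men and rho < r_sub:
                        new_med = LIQUID
                    else:
                        new_med = AIR
            else:
                nx, ny, nz = 0.0, 0.0, 1.0
                new_med = AIR if dz < 0.0 else SLAB

            # orient normal against the incoming ray
            cosi = -(dx * nx + dy * ny + dz * nz)
            if cosi < 0.0:
                nx = -nx
                ny = -ny
                nz = -nz
                cosi = -cosi
            if cosi > 1.0:
                cosi = 1.0

            n1 = n_arr[med]
            n2 = n_arr[new_med]
            eta = n1 / n2
            sin2t = eta * eta * (1.0 - cosi * cosi)

            # reflected direction
            rdx = dx + 2.0 * cosi * nx
            rdy = dy + 2.0 * cosi * ny
            rdz = dz + 2.0 * cosi * nz

            if sin2t >= 1.0:
                # total internal reflection: single child, full intensity
                if sp < stack_cap:
                    spx[sp] = hx + 1e-12 * rdx
                    spy[sp] = hy + 1e-12 * rdy
                    spz[sp] = hz + 1e-12 * rdz
                    sdx[sp] = rdx
                    sdy[sp] = rdy
                    sdz[sp] = rdz
                    sw[sp] = w
                    smed[sp] = med
                    sdep[sp] = dep + 1
                    sp += 1
                continue

            cost = math.sqrt(1.0 - sin2t)
            rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
            rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
            refl = 0.5 * (rs * rs + rp * rp)
            wr = w * refl
            wt = w * (1.0 - refl)

            # refracted child
            tdx = eta * dx + (eta * cosi - cost) * nx
            tdy = eta * dy + (eta * cosi - cost) * ny
            tdz = eta * dz + (eta * cosi - cost) * nz

            if wt >= cutoff:
                spx[sp] = hx + 1e-12 * tdx
                spy[sp] = hy + 1e-12 * tdy
                spz[sp] = hz + 1e-12 * tdz
                sdx[sp] = tdx
                sdy[sp] = tdy
                sdz[sp] = tdz
                sw[sp] = wt
                smed[sp] = new_med
                sdep[sp] = dep + 1
                sp += 1
            else:
                truncated += wt
            if wr >= cutoff:
                spx[sp] = hx + 1e-12 * rdx
                spy[sp] = hy + 1e-12 * rdy
                spz[sp] = hz + 1e-12 * rdz
                sdx[sp] = rdx
                sdy[sp] = rdy
                sdz[sp] = rdz
                sw[sp] = wr
                smed[sp] = med
                sdep[sp] = dep + 1
                sp += 1
            else:
                truncated += wr

    return upper, lower, outside, truncated, trapped


# ---------------------------------------------------------------------------
# public tracing API
# ---------------------------------------------------------------------------

def intersect(ray: Ray, scene: OpticalScene):
    """Nearest surface hit of a single ray: (point, outward normal, surface id).

    Surface ids: 'bead', 'meniscus', 'substrate_top', 'substrate_bottom'.
    Returns None if the ray escapes the scene.
    """
    (cz, R, has_men, men_r, men_z, _ca, _rs, has_sub, slab_T, _n) = scene._kernel_args()
    p = np.asarray(ray.origin, float)
    d = np.asarray(ray.direction, float)
    t_best, surf = 1e300, -1
    t = _hit_sphere(p[0], p[1], p[2], d[0], d[1], d[2], cz, R)
    if 0.0 < t < t_best:
        t_best, surf = t, 0
    if has_sub:
        for z_plane, sid in ((0.0, 2), (-slab_T, 3)):
            t = _hit_plane(p[2], d[2], z_plane)
            if 0.0 < t < t_best:
                t_best, surf = t, sid
    seg = -1
    if has_men:
        t, seg_i = _hit_meniscus(p[0], p[1], p[2], d[0], d[1], d[2], men_r, men_z, t_best)
        if 0.0 < t < t_best:
            t_best, surf, seg = t, 1, seg_i
    if surf < 0:
        return None
    hit = p + t_best * d
    if surf == 0:
        normal = (hit - np.array([0.0, 0.0, cz])) / R
        name = "bead"
    elif surf == 1:
        tr = men_r[seg + 1] - men_r[seg]
        tz = men_z[seg + 1] - men_z[seg]
        ln = math.hypot(tr, tz)
        rho = math.hypot(hit[0], hit[1])
        nr, nz = tz / ln, -tr / ln
        normal = np.array([nr * hit[0] / rho, nr * hit[1] / rho, nz])
        name = "meniscus"
    else:
        normal = np.array([0.0, 0.0, 1.0])
        name = "substrate_top" if surf == 2 else "substrate_bottom"
    return hit, normal, name


def _ledger_from_raw(upper, lower, outside, truncated, trapped, n_rays):
    detected_up = float(upper.sum())
    detected_down = float(lower.sum())
    ledger = {
        "detected_up": detected_up / n_rays,
        "detected_down": detected_down / n_rays,
        "outside_aperture": float(outside) / n_rays,
        "truncated": float(truncated) / n_rays,
        "trapped": float(trapped) / n_rays,
    }
    total = sum(ledger.values())
    ledger["total"] = total
    if abs(total - 1.0) > LEDGER_TOL:
        raise RuntimeError(
            f"intensity ledger violates conservation: total {total:.9f} != 1 "
            f"(tolerance {LEDGER_TOL})"
        )
    return ledger


def trace(ray: Ray, scene: OpticalScene, config: TraceConfig):
    """Trace one ray through the scene; returns (DetectorPair, ledger)."""
    origins = np.asarray(ray.origin, float).reshape(1, 3)
    dirs = np.asarray(ray.direction, float).reshape(1, 3)
    args = scene._kernel_args()
    upper, lower, outside, truncated, trapped = _trace_batch(
        origins, dirs, args[0], args[1], args[2], args[3], args[4], args[5],
        args[6], args[7], args[8], args[9], config.max_depth, config.intensity_cutoff,
    )
    det = DetectorPair(upper_counts=upper, lower_counts=lower)
    ledger = _ledger_from_raw(upper, lower, outside, truncated, trapped, 1)
    return det, ledger


def run_simulation(
    scene: OpticalScene,
    config: TraceConfig,
    chunk_size: int = 2_000_000,
):
    """Full Monte-Carlo run: emitters x rays, reproducible by seed.

    Emitter positions are drawn first, then each emitter's block of ray
    directions in emitter order, from one seeded generator, so two scenes
    traced with the same config share identical rays (common random
    numbers).  Returns (DetectorPair, ledger) with all ledger entries as
    fractions of the emitted intensity.
    """
    rng = np.random.default_rng(config.rng_seed)
    emitters = sample_emitters(config.n_emitters, scene.bead_radius, scene.bead_center_z, rng)
    n_total = config.total_rays
    rpe = config.rays_per_emitter
    origins = np.repeat(emitters, rpe, axis=0)
    dirs = np.empty((n_total, 3))
    for i in range(config.n_emitters):
        dirs[i * rpe:(i + 1) * rpe] = sample_directions(rpe, rng)

    args = scene._kernel_args()
    upper = np.zeros(N_BINS)
    lower = np.zeros(N_BINS)
    outside = truncated = trapped = 0.0
    for lo in range(0, n_total, chunk_size):
        hi = min(lo + chunk_size, n_total)
        u, l, o, tr, tp = _trace_batch(
            np.ascontiguousarray(origins[lo:hi]), np.ascontiguousarray(dirs[lo:hi]),
            args[0], args[1], args[2], args[3], args[4], args[5], args[6],
            args[7], args[8], args[9], config.max_depth, config.intensity_cutoff,
        )
        upper += u
        lower += l
        outside += o
        truncated += tr
        trapped += tp

    ledger = _ledger_from_raw(upper, lower, outside, truncated, trapped, n_total)
    det = DetectorPair(upper_counts=upper / n_total, lower_counts=lower / n_total)
    return det, ledger


def trapped_fraction(scene: OpticalScene, config: TraceConfig) -> float:
    """Fraction of emitted intensity permanently trapped in a bare perfect sphere.

    In a perfect sphere the internal incidence angle repeats at every
    bounce, so a ray is trapped forever if and only if its first incidence
    angle exceeds the critical angle; each ray is classified once.
    """
    if scene.has_meniscus:
        raise ValueError("trapped_fraction is defined for the bare perfect sphere only")
    rng = np.random.default_rng(config.rng_seed)
    R = scene.bead_radius
    cz = scene.bead_center_z
    emitters = sample_emitters(config.n_emitters, R, cz, rng)
    n_total = config.total_rays
    rpe = config.rays_per_emitter
    origins = np.repeat(emitters, rpe, axis=0)
    dirs = np.empty((n_total, 3))
    for i in range(config.n_emitters):
        dirs[i * rpe:(i + 1) * rpe] = sample_directions(rpe, rng)

    # first sphere intersection from inside: |p + t d - c| = R, take t > 0
    rel = origins - np.array([0.0, 0.0, cz])
    b = np.einsum("ij,ij->i", rel, dirs)
    c = np.einsum("ij,ij->i", rel, rel) - R * R
    t = -b + np.sqrt(b * b - c)
    hit = rel + t[:, None] * dirs
    cos_inc = np.abs(np.einsum("ij,ij->i", hit, dirs)) / R
    sin_inc = np.sqrt(np.clip(1.0 - cos_inc**2, 0.0, 1.0))
    sin_crit = scene.n_ambient / scene.n_bead
    return float(np.mean(sin_inc >= sin_crit))


def trapped_fraction_quadrature(n_bead: float = 1.61, n_out: float = 1.0) -> float:
    """Independent 1-D quadrature for the trapped fraction of a perfect sphere.

    For an emitter at radius fraction x, sin(theta_i) = x sin(psi) for launch
    angle psi from the radial direction, so the trapped solid-angle fraction
    is sqrt(1 - (s_c/x)^2) for x > s_c (else 0), with s_c = n_out/n_bead.
    Volume-averaging over 3 x^2 dx gives the total.
    """
    from scipy.integrate import quad

    s_c = n_out / n_bead

    def f(x: float) -> float:
        return 3.0 * x * x * math.sqrt(max(0.0, 1.0 - (s_c / x) ** 2))

    val, _ = quad(f, s_c, 1.0, limit=200)
    return val


def collection_within_NA(detector: DetectorPair, na: float, side: str = "lower") -> float:
    """Total intensity inside the acceptance cone of numerical aperture ``na``.

    Sums detector bins whose |signed polar angle| lies within arcsin(NA)
    (in air); the boundary bin is weighted by its fractional angular
    overlap with the cone.
    """
    if not (0.0 < na <= 1.0):
        raise ValueError("NA must lie in (0, 1]")
    theta_max = math.degrees(math.asin(na))
    counts = detector.counts(side)
    edges = detector.bin_edges
    lo_e = edges[:-1]
    hi_e = edges[1:]
    overlap = np.clip(np.minimum(hi_e, theta_max) - np.maximum(lo_e, -theta_max), 0.0, None)
    frac = overlap / (hi_e - lo_e)
    return float(np.sum(counts * frac))
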