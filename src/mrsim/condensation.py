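"""Drop-wise condensation kinetics of PEG vapor around a microbead.

The micro-reflector grows by condensation of PEG vapor onto the
liquid-vapor interface of the meniscus pinned at the bead/substrate
triple junction.  Under the steady-state assumptions (constant vapor
density, unit sticking coefficient, transient heating neglected) the
volumetric growth rate is

    dV/dt = J * V1 * A_lv(V)

where ``J`` is the kinetic-theory impingement flux of vapor molecules,
``V1`` the liquid-phase volume of one molecule and ``A_lv(V)`` the
liquid-vapor surface area of the meniscus of volume ``V``.

The saturated vapor pressure of the oligomer is described by a
Clausius-Clapeyron correlation fitted to literature data for ethylene
glycol oligomers (see docs/methods.md); the saturation temperature is
obtained by inverting it through the ideal-gas closure P = n0 k T.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .constants import CODATA, PEGProperties, PhysicalConstants, molecule_mass, molecule_volume

__all__ = [
    "VaporState",
    "GrowthCurve",
    "vapor_pressure",
    "saturation_temperature",
    "molecular_flux",
    "nucleus_volume",
    "integrate_growth",
    "molecule_mass",
    "molecule_volume",
]

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314462618  # J/(mol K)
ATM_PRESSURE = 101325.0  # Pa

# Clausius-Clapeyron correlation for HO-(C2H4O)_M-H oligomers, fitted to
# literature boiling points and vaporization enthalpies of di-, tri- and
# tetraethylene glycol and extrapolated in M (docs/methods.md):
#   ln(P/P_atm) = -(dHvap(M)/R) (1/T - 1/Tb(M))
_DHVAP_J_PER_MOL = (23.5e3, 15.0e3)  # dHvap = a + b*M
_TBOIL_K = (450.0, 35.0)  # Tb = a + b*M

#: Celsius validity window of the correlation; values outside are
#: extrapolated with a logged warning.
VALID_RANGE_C = (20.0, 250.0)


def _dh_vap(n_monomers: int) -> float:
    return _DHVAP_J_PER_MOL[0] + _DHVAP_J_PER_MOL[1] * n_monomers


def _t_boil(n_monomers: int) -> float:
    return _TBOIL_K[0] + _TBOIL_K[1] * n_monomers


def vapor_pressure(temperature_k: float, n_monomers: int = 6) -> float:
    """Saturated vapor pressure (Pa) of the M-mer PEG at temperature T.

    The empirical correlation is expressed in Celsius; the kelvin input is
    converted at this boundary.  Strictly increasing in T and strictly
    decreasing in M at fixed T.
    """
    t_celsius = temperature_k - 273.15
    lo, hi = VALID_RANGE_C
    if not (lo <= t_celsius <= hi):
        logger.warning(
            "vapor_pressure evaluated at %.1f C, outside the fitted range "
            "[%.0f, %.0f] C; extrapolating", t_celsius, lo, hi,
        )
    t_k = t_celsius + 273.15
    dh = _dh_vap(n_monomers)
    tb = _t_boil(n_monomers)
    return ATM_PRESSURE * math.exp(-(dh / GAS_CONSTANT) * (1.0 / t_k - 1.0 / tb))


def saturation_temperature(
    number_density: float,
    n_monomers: int = 6,
    constants: PhysicalConstants = CODATA,
    bracket: tuple[float, float] = (150.0, 800.0),
) -> float:
    """Temperature (K) at which vapor of density n0 is exactly saturated.

    Solves P_vap(T) = n0 k T for T; the root is bracketed and converged
    to better than 0.01 K.
    """
    if number_density <= 0:
        raise ValueError("number density must be positive")
    k = constants.boltzmann_k

    def residual(t: float) -> float:
        return vapor_pressure(t, n_monomers) - number_density * k * t

    lo, hi = bracket
    # the bracket endpoints intentionally probe outside the fitted range;
    # only warn if the converged root itself lands out of range
    logger.disabled = True
    try:
        f_lo, f_hi = residual(lo), residual(hi)
        if f_lo * f_hi > 0:
            raise ValueError(
                f"no saturation-temperature root bracketed in [{lo}, {hi}] K "
                f"for n0={number_density:.3e} m^-3 (residuals {f_lo:.3e}, {f_hi:.3e})"
            )
        root = brentq(residual, lo, hi, xtol=1e-6)
    finally:
        logger.disabled = False
    vapor_pressure(root, n_monomers)  # re-warn if the root is out of range
    return root


def molecular_flux(
    number_density: float,
    t_sat: float,
    molecule_mass_kg: float,
    constants: PhysicalConstants = CODATA,
) -> float:
    """One-sided Maxwell-Boltzmann wall flux n0 sqrt(kT / 2 pi m1).

    Molecules per square meter per second impinging on (and, with unit
    sticking coefficient, condensing onto) the liquid surface.
    """
    if number_density < 0 or t_sat <= 0 or molecule_mass_kg <= 0:
        raise ValueError("number density must be >= 0; T and m1 must be positive")
    k = constants.boltzmann_k
    return number_density * math.sqrt(k * t_sat / (2.0 * math.pi * molecule_mass_kg))


def nucleus_volume(bead_diameter: float, molecule_volume_m3: float) -> float:
    """Initial condensate volume: a molecular monolayer ring at the triple junction.

    A ring of molecular thickness delta = V1^(1/3) and cross-section
    delta^2 along the contact circumference pi D gives V0 = pi D V1^(2/3).
    """
    if bead_diameter <= 0:
        raise ValueError("bead diameter must be positive")
    return math.pi * bead_diameter * molecule_volume_m3 ** (2.0 / 3.0)


@dataclass(frozen=True)
class VaporState:
    """Thermodynamic state of the PEG vapor near the sample."""

    number_density: float  # molecules / m^3
    saturation_temperature: float  # K
    partial_pressure: float  # Pa
    molecular_flux: float  # molecules / (m^2 s)

    def __post_init__(self) -> None:
        if min(self.number_density, self.saturation_temperature,
               self.partial_pressure, self.molecular_flux) < 0:
            raise ValueError("vapor-state fields must be non-negative")
        if (self.number_density == 0) != (self.molecular_flux == 0):
            raise ValueError("flux must vanish iff the number density vanishes")
        expected_p = self.number_density * CODATA.boltzmann_k * self.saturation_temperature
        if self.partial_pressure > 0 and abs(expected_p - self.partial_pressure) > 1e-6 * self.partial_pressure:
            raise ValueError("partial pressure violates the ideal-gas closure P = n0 k T")

    @classmethod
    def from_reservoir(
        cls,
        reservoir_temperature_k: float,
        peg: PEGProperties | None = None,
        constants: PhysicalConstants = CODATA,
    ) -> "VaporState":
        """Vapor state produced by a saturated reservoir at the given temperature."""
        peg = peg or PEGProperties()
        p = vapor_pressure(reservoir_temperature_k, peg.n_monomers)
        n0 = p / (constants.boltzmann_k * reservoir_temperature_k)
        t_sat = saturation_temperature(n0, peg.n_monomers, constants)
        j = molecular_flux(n0, t_sat, peg.molecule_mass_kg, constants)
        p_closed = n0 * constants.boltzmann_k * t_sat
        return cls(n0, t_sat, p_closed, j)


@dataclass(frozen=True)
class GrowthCurve:
    """Solution of the volumetric growth equation dV/dt = J V1 A_lv(V)."""

    times: np.ndarray  # s
    volumes: np.ndarray  # m^3
    flux_used: float  # molecules / (m^2 s)
    truncated: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.volumes, float)
        if t.shape != v.shape:
            raise ValueError("times and volumes must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(v) < -1e-12 * v[:-1]):
            raise ValueError("volumes must be non-decreasing")


def integrate_growth(
    flux: float,
    molecule_volume_m3: float,
    area_of_volume: Callable[[float], float],
    v0: float,
    t_end: float,
    n_steps: int = 200,
) -> GrowthCurve:
    """Integrate dV/dt = J V1 A_lv(V) from the nucleus volume v0 to t_end.

    ``area_of_volume`` maps volume (m^3) to liquid-vapor area (m^2); if it
    exposes a ``v_max`` attribute (as the meniscus shape-family interpolant
    does) the integration stops there and the curve is flagged truncated.
    Uses an adaptive explicit Runge-Kutta method, rtol 1e-8.
    """
    if flux < 0 or molecule_volume_m3 <= 0 or v0 <= 0 or t_end <= 0:
        raise ValueError("flux must be >= 0; V1, V0, t_end must be positive")

    v_min_dom = getattr(area_of_volume, "v_min", None)
    v_max_dom = getattr(area_of_volume, "v_max", None)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        v = float(y[0])
        # the adaptive stepper probes slightly past the terminal event; keep
        # the area callable inside its declared domain
        if v_min_dom is not None:
            v = max(v, v_min_dom)
        if v_max_dom is not None:
            v = min(v, v_max_dom)
        a = area_of_volume(v)
        if a < 0:
            raise ValueError(f"area_of_volume returned a negative area {a} at V={v:.3e}")
        return [flux * molecule_volume_m3 * a]

    events = []
    v_max = v_max_dom
    if v_max is not None:
        def hit_edge(_t: float, y: np.ndarray) -> float:
            return y[0] - v_max
        hit_edge.terminal = True  # type: ignore[attr-defined]
        hit_edge.direction = 1  # type: ignore[attr-defined]
        events.append(hit_edge)

    t_eval = np.linspace(0.0, t_end, n_steps)
    sol = solve_ivp(
        rhs, (0.0, t_end), [v0], t_eval=t_eval, rtol=1e-8, atol=v0 * 1e-12,
        events=events or None, dense_output=False, method="RK45",
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"growth ODE integration failed: {sol.message}")
    times = sol.t
    volumes = sol.y[0]
    truncated = sol.status == 1
    if truncated and sol.t_events and len(sol.t_events[0]):
        times = np.append(times, sol.t_events[0][0])
        volumes = np.append(volumes, sol.y_events[0][0][0])
    # adaptive stepping can leave ~1e-15 relative wiggle; clamp to monotone
    volumes = np.maximum.accumulate(volumes)
    return GrowthCurve(times=times, volumes=volumes, flux_used=flux, truncated=truncated)
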