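"""Fluorescence-collection enhancement analysis over a meniscus shape family.

The headline quantity is the collection enhancement: the intensity
collected within the acceptance cone of the imaging objective (numerical
aperture NA, on the coverslip side by default) with the micro-reflector
present, normalized by the same quantity for the bare bead traced with
the same rays (common random numbers).  Composing the enhancement-versus-
volume curve with the condensation growth law V(t) yields enhancement
versus time; by optical reciprocity the same reflector concentrates the
excitation light, so the predicted total signal enhancement is the square
of the collection enhancement, and conversely the square root of a
measured intensity curve isolates its collection component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .condensation import GrowthCurve
from .meniscus import ShapeFamily
from .raytrace import (
    DetectorPair,
    OpticalScene,
    TraceConfig,
    collection_within_NA,
    run_simulation,
)

__all__ = [
    "EnhancementCurve",
    "enhancement_vs_shape",
    "na_sweep",
    "na_sweep_from_detectors",
    "enhancement_vs_time",
    "total_signal_model",
    "experimental_adjustment",
]


@dataclass(frozen=True)
class EnhancementCurve:
    """Collection enhancement against shape volume, NA, or time.

    ``abscissa`` holds the running variable named by ``abscissa_name``
    ('volume' in m^3, 'NA' dimensionless, or 'time' in s); ``enhancement``
    is the ratio to the bare-sphere collection at the same NA (the bare
    sphere itself is exactly 1 by construction).
    """

    abscissa: np.ndarray
    enhancement: np.ndarray
    abscissa_name: str = "volume"
    na: float = 0.13
    mc_stderr: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.abscissa) != len(self.enhancement):
            raise ValueError("abscissa and enhancement must have equal length")
        if np.any(np.asarray(self.enhancement) <= 0):
            raise ValueError("enhancement values must be positive")

    @property
    def peak(self) -> float:
        return float(np.max(self.enhancement))

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.enhancement))


def _collect(det: DetectorPair, na: float, side: str) -> float:
    return collection_within_NA(det, na, side=side)


def enhancement_vs_shape(
    family: ShapeFamily,
    config: TraceConfig,
    na: float = 0.13,
    side: str = "lower",
    scene_kwargs: dict | None = None,
    return_detectors: bool = False,
):
    """Collection enhancement for every shape of the family at one NA.

    Runs the bare-bead reference and then each reflector shape with the
    identical emitters and ray directions (same seed: common random
    numbers, which largely cancels the Monte-Carlo noise in the ratio).
    """
    if len(family) == 0:
        raise ValueError("family is empty")
    scene_kwargs = scene_kwargs or {}
    bare = OpticalScene.bare(bead_diameter=family.geometry.bead_diameter, **scene_kwargs)
    det_bare, _ = run_simulation(bare, config)
    ref = _collect(det_bare, na, side)
    if ref <= 0:
        raise RuntimeError("bare-sphere reference collection is zero; increase the ray budget")

    n_rays = config.total_rays
    ratios = np.empty(len(family))
    stderr = np.empty(len(family))
    detectors: list[DetectorPair] = []
    for i, prof in enumerate(family.profiles):
        scene = OpticalScene.from_profile(prof, family.geometry, **scene_kwargs)
        det, _ = run_simulation(scene, config)
        val = _collect(det, na, side)
        ratios[i] = val / ref
        # binomial-style scale estimate; common random numbers make the true
        # ratio error smaller, so this is conservative
        stderr[i] = math.sqrt(max(val, 1.0 / n_rays) / n_rays) / ref
        if return_detectors:
            detectors.append(det)
    curve = EnhancementCurve(
        abscissa=family.volumes.copy(), enhancement=ratios,
        abscissa_name="volume", na=na, mc_stderr=stderr,
    )
    if return_detectors:
        return curve, detectors, det_bare
    return curve


def na_sweep_from_detectors(
    det_shape: DetectorPair,
    det_bare: DetectorPair,
    na_grid: np.ndarray,
    side: str = "lower",
) -> EnhancementCurve:
    """Re-bin one pair of runs into an enhancement-versus-NA curve."""
    na_grid = np.asarray(na_grid, float)
    if np.any(na_grid <= 0) or np.any(na_grid > 1):
        raise ValueError("NA grid must lie in (0, 1]")
    vals = np.array([
        _collect(det_shape, na, side) / _collect(det_bare, na, side) for na in na_grid
    ])
    return EnhancementCurve(abscissa=na_grid, enhancement=vals, abscissa_name="NA", na=math.nan)


def na_sweep(
    optimal_shape,
    config: TraceConfig,
    na_grid: np.ndarray,
    geometry=None,
    side: str = "lower",
    scene_kwargs: dict | None = None,
) -> EnhancementCurve:
    """Enhancement of one reflector shape as a function of detection NA.

    One pair of runs (bare + shape, common random numbers), re-binned per NA.
    """
    scene_kwargs = scene_kwargs or {}
    geometry = geometry or optimal_shape.geometry
    bare = OpticalScene.bare(bead_diameter=geometry.bead_diameter, **scene_kwargs)
    det_bare, _ = run_simulation(bare, config)
    scene = OpticalScene.from_profile(optimal_shape, geometry, **scene_kwargs)
    det_shape, _ = run_simulation(scene, config)
    return na_sweep_from_detectors(det_shape, det_bare, np.asarray(na_grid, float), side)


def enhancement_vs_time(curve: EnhancementCurve, growth: GrowthCurve) -> EnhancementCurve:
    """Compose enhancement(V) with the growth law V(t).

    Times whose volume falls outside the curve's volume range are dropped;
    an empty overlap is an error.
    """
    if curve.abscissa_name != "volume":
        raise ValueError("curve must be parameterized by volume")
    v = np.asarray(growth.volumes, float)
    t = np.asarray(growth.times, float)
    lo, hi = curve.abscissa[0], curve.abscissa[-1]
    keep = (v >= lo) & (v <= hi)
    if not keep.any():
        raise ValueError(
            f"growth volumes [{v[0]:.3g}, {v[-1]:.3g}] m^3 do not overlap the "
            f"enhancement curve range [{lo:.3g}, {hi:.3g}] m^3"
        )
    interp = PchipInterpolator(curve.abscissa, curve.enhancement, extrapolate=False)
    return EnhancementCurve(
        abscissa=t[keep], enhancement=interp(v[keep]),
        abscissa_name="time", na=curve.na,
    )


def total_signal_model(collection_enhancement):
    """Predicted total (excitation x emission) enhancement: the square.

    The objective both excites and collects through the same reflector, so
    by ray reversibility the excitation enhancement approximately equals
    the collection enhancement.
    """
    x = np.asarray(collection_enhancement, float)
    if np.any(x <= 0):
        raise ValueError("collection enhancement must be positive")
    out = x**2
    return float(out) if np.isscalar(collection_enhancement) or out.ndim == 0 else out


def experimental_adjustment(intensity_series):
    """Min-point renormalization followed by the square root.

    Rescales a measured intensity time series by its minimum (taking the
    smoothed, PEG-coated bead as the reference state) and takes the square
    root to separate the collection component from the reciprocal
    excitation enhancement.
    """
    s = np.asarray(intensity_series, float)
    if s.size == 0:
        raise ValueError("series is empty")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("intensity series must be strictly positive and finite")
    return np.sqrt(s / s.min())
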