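"""Pinhole-camera metric conversion between pixels and millimeters.

A weak-perspective model is used throughout: all berries of a bunch share a
single object--camera distance ``d``, so a berry of radius ``r_mm`` images at
``r_px = r_mm * f / d``.  Depth variation within a bunch is absorbed into the
distance uncertainty ``sigma_d`` (half the bunch thickness).  The conversion
factor from pixels to millimeters is

    C_px-mm = d / f          [mm/px]

with ``d`` in mm and the focal length ``f`` in px.  The camera calibration
that produces ``f`` (and its uncertainty) is consumed as an input, never
performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import Quantity


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera parameters with type-B standard uncertainties.

    Parameters
    ----------
    focal_px:
        Focal length f, px.  There is no sensible default: it must come from
        the user's own calibration.
    distance_mm:
        Object--camera distance d, mm (default 500 mm, the validation set-up).
    focal_sigma_px:
        Standard uncertainty of f, px (default 2 px).
    distance_sigma_mm:
        Standard uncertainty of d, mm (default 25 mm, half the vine thickness).
    """

    focal_px: float
    distance_mm: float = 500.0
    focal_sigma_px: float = 2.0
    distance_sigma_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise ValueError(f"focal length must be > 0 px, got {self.focal_px}")
        if self.distance_mm <= 0:
            raise ValueError(f"object distance must be > 0 mm, got {self.distance_mm}")
        if self.focal_sigma_px < 0 or self.distance_sigma_mm < 0:
            raise ValueError("standard uncertainties must be >= 0")


def px_to_mm_factor(camera: CameraModel) -> Quantity:
    """Pixel-to-millimeter conversion factor C = d/f with propagated uncertainty.

    First-order propagation for the ratio d/f gives the relative variance
    ``(sigma_d/d)**2 + (sigma_f/f)**2``.

    Returns
    -------
    Quantity
        C in mm/px with its standard uncertainty.
    """
    value = camera.distance_mm / camera.focal_px
    rel_var = (camera.distance_sigma_mm / camera.distance_mm) ** 2 + (
        camera.focal_sigma_px / camera.focal_px
    ) ** 2
    return Quantity(value=value, sigma=value * math.sqrt(rel_var), unit="mm/px")


def type_b_uniform_sigma(a: float, unit: str) -> Quantity:
    """Type-B standard uncertainty of a quantity known only to within +/- a.

    Under a uniform distribution over [-a, +a] the standard deviation is
    a/sqrt(3) (GUM type-B rule).  The returned quantity carries only the
    sigma; its nominal value is 0.

    Parameters
    ----------
    a:
        Half-width of the interval, >= 0, in ``unit``.
    """
    if a < 0:
        raise ValueError(f"half-width must be >= 0, got {a}")
    return Quantity(value=0.0, sigma=a / math.sqrt(3.0), unit=unit)


def mm_to_px_radius(r_mm: float, camera: CameraModel) -> float:
    """Project a metric radius to pixels: r_px = r_mm * f / d (weak perspective)."""
    if r_mm < 0:
        raise ValueError(f"radius must be >= 0, got {r_mm}")
    return r_mm * camera.focal_px / camera.distance_mm
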