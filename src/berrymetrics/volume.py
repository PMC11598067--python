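"""Spherical-berry volume estimators for grape bunches.

Berries of the validated variety are near-spherical, so every volume here is
a sum of sphere volumes (4/3) pi r^3.  Two routes exist for the visible part
of a bunch in an image:

* reference: per-berry annotated radii, V = sum_k (4/3) pi r_k^3;
* estimated: a count and a single mean radius, V = N * (4/3) pi r_mean^3.

The two coincide only when all radii equal the mean (Jensen: the mean-radius
form underestimates the per-berry sum for heterogeneous radii, since r^3 is
convex).  Results computed from a mean radius in place of per-berry values
carry an ``approximation="mean-radius"`` flag.

The whole-bunch metric volume is recovered from the visible pixel volume via
the cubed pixel-to-mm conversion factor and the total/visible volume ratio R:

    V_b,mm = V_I,px * C^3 * R
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .units import Quantity, UnitError


@dataclass(frozen=True)
class VolumeSet:
    """The volume quantities for one bunch/view, with provenance."""

    bunch_id: str
    view_index: int
    v_visible_px: Optional[float] = None  # px^3
    v_visible_mm: Optional[float] = None  # mm^3
    v_total_mm: Optional[float] = None  # mm^3
    provenance: str = "reference"  # or "estimated"
    approximation: Optional[str] = None  # e.g. "mean-radius"

    def __post_init__(self) -> None:
        for name in ("v_visible_px", "v_visible_mm", "v_total_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if (
            self.provenance == "reference"
            and self.v_total_mm is not None
            and self.v_visible_mm is not None
            and self.v_total_mm < self.v_visible_mm
        ):
            raise ValueError("reference total volume cannot be below the visible volume")


@dataclass(frozen=True)
class RatioEstimate:
    """Total/visible volume ratio R with its spread across images."""

    r_mean: float
    r_sigma: float
    n_images: int

    def __post_init__(self) -> None:
        if self.r_sigma < 0:
            raise ValueError("r_sigma must be >= 0")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


def sphere_volume(r: float) -> float:
    """(4/3) pi r^3; unit is the cube of the radius unit."""
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {r}")
    return (4.0 / 3.0) * math.pi * r**3


def visible_volume_estimated(n_est: int, r_mean_est_px: float) -> float:
    """Estimated visible volume in px^3 from a count and a mean radius.

    V = N * (4/3) pi r_mean^3 (mean-radius form, the detector's output shape).
    """
    if n_est < 0:
        raise ValueError(f"count must be >= 0, got {n_est}")
    if n_est > 0 and r_mean_est_px <= 0:
        raise ValueError(f"mean radius must be > 0 px, got {r_mean_est_px}")
    return n_est * sphere_volume(r_mean_est_px) if n_est else 0.0


def _sum_sphere_volumes(radii: Sequence[float], what: str) -> float:
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        warnings.warn(f"empty radius list: {what} volume is 0", stacklevel=3)
        return 0.0
    if np.any(radii <= 0):
        raise ValueError(f"all radii must be > 0 for a {what} volume")
    return float((4.0 / 3.0) * math.pi * np.sum(radii**3))


def visible_volume_reference(radii_px: Sequence[float]) -> float:
    """Reference visible volume in px^3: per-berry sum of sphere volumes."""
    return _sum_sphere_volumes(radii_px, "visible")


def bunch_volume_reference(radii_mm: Sequence[float]) -> float:
    """Reference whole-bunch volume in mm^3: per-berry sum of sphere volumes."""
    return _sum_sphere_volumes(radii_mm, "bunch")


def ratio_R(pairs: Sequence[tuple[float, float]]) -> RatioEstimate:
    """Total/visible ratio R from (v_total_mm, v_visible_mm) pairs.

    R is the mean of per-image ratios (not the ratio of means), and r_sigma
    is their sample standard deviation (0 for a single image).
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (total, visible) pair")
    totals = np.asarray([p[0] for p in pairs], dtype=float)
    visibles = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(visibles <= 0):
        raise ZeroDivisionError("visible volume must be > 0 to form a ratio")
    ratios = totals / visibles
    sigma = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return RatioEstimate(r_mean=float(np.mean(ratios)), r_sigma=sigma, n_images=int(ratios.size))


def total_volume_estimated(v_visible_px: float, c_px_mm: float | Quantity, r: RatioEstimate | float) -> float:
    """Whole-bunch metric volume: V_b,mm = V_I,px * C^3 * R.

    ``c_px_mm`` may be a bare factor or a mm/px :class:`Quantity` (unit checked).
    """
    if isinstance(c_px_mm, Quantity):
        c = c_px_mm.require_unit("mm/px").value
    else:
        c = float(c_px_mm)
    if c <= 0:
        raise UnitError(f"conversion factor must be > 0 mm/px, got {c}")
    if v_visible_px < 0:
        raise ValueError("visible volume must be >= 0")
    r_mean = r.r_mean if isinstance(r, RatioEstimate) else float(r)
    if r_mean <= 0:
        raise ValueError("ratio R must be > 0")
    return v_visible_px * c**3 * r_mean
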