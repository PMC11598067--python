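"""First-order (GUM) uncertainty propagation for the bunch-volume chain.

The measurand V_b,mm = V_I,px * (d/f)^3 * R is a product of powers of four
mutually independent sources, so the linear law of propagation gives

    (sigma_y / y)^2 = sum_i p_i^2 (sigma_i / x_i)^2

with powers p = (+1 on V_I,px, +3 on d, -3 on f, +1 on R).  Each source's
uncertainty percentage contribution (UPC) is its share of the combined
*variance* — the only definition under which the contributions sum to 100%.

A Monte Carlo sampler over the same sources acts as the independent oracle
for the linear budget: for small relative sigmas the two agree closely; at
large relative sigmas (the ratio R in practice) the linear budget is an
approximation and the MC result is the better estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .units import Quantity


@dataclass(frozen=True)
class UncertaintySource:
    """One input quantity of a power-product measurand y = prod x_i^{p_i}."""

    name: str
    quantity: Quantity
    exponent: int

    def __post_init__(self) -> None:
        if self.exponent == 0:
            raise ValueError(f"source {self.name!r}: exponent 0 contributes nothing")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Combined standard uncertainty plus per-source percentage contributions."""

    sources: tuple[UncertaintySource, ...]
    value: float
    combined_sigma: float
    relative_sigma: float
    upc: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.upc.values())
        # all-zero UPC is the degenerate no-uncertainty budget
        if self.upc and total != 0.0 and abs(total - 100.0) > 0.5:
            raise ValueError(f"UPC entries must sum to 100% (got {total:.3f}%)")


def propagate_power_product(sources: Sequence[UncertaintySource]) -> UncertaintyBudget:
    """Linear GUM budget of y = prod x_i^{p_i} for independent sources.

    Returns the nominal y, the combined standard uncertainty, and the UPC of
    each source: UPC_i = p_i^2 (sigma_i/x_i)^2 / sum_j p_j^2 (sigma_j/x_j)^2 * 100.
    """
    if not sources:
        raise ValueError("need at least one uncertainty source")
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError("source names must be unique")
    value = 1.0
    contribs = []
    for s in sources:
        x = s.quantity.value
        if x == 0:
            raise ZeroDivisionError(f"source {s.name!r} has zero nominal value")
        value *= x**s.exponent
        contribs.append((s.exponent * s.quantity.sigma / x) ** 2)
    total_var = float(sum(contribs))
    if total_var == 0:
        upc = {n: 0.0 for n in names}
        return UncertaintyBudget(tuple(sources), value, 0.0, 0.0, upc)
    upc = {n: 100.0 * c / total_var for n, c in zip(names, contribs)}
    rel = math.sqrt(total_var)
    return UncertaintyBudget(tuple(sources), value, abs(value) * rel, rel, upc)


def propagate_sphere_sum(radii: Sequence[float], sigma_r: float) -> Quantity:
    """Uncertainty of a sum of sphere volumes from per-radius uncertainty.

    For V = sum (4/3) pi r_k^3 with independent radius errors of standard
    uncertainty sigma_r, the first-order sensitivity of each term is
    4 pi r_k^2, so sigma_V^2 = sum (4 pi r_k^2)^2 sigma_r^2.  Unit tag is
    generic (px in, px^3 out is the caller's bookkeeping); returned in px3.
    """
    r = np.asarray(radii, dtype=float)
    if r.size == 0:
        raise ValueError("empty radius list")
    if np.any(r <= 0):
        raise ValueError("all radii must be > 0")
    if sigma_r < 0:
        raise ValueError("sigma_r must be >= 0")
    value = float((4.0 / 3.0) * math.pi * np.sum(r**3))
    sigma = float(math.sqrt(np.sum((4.0 * math.pi * r**2) ** 2)) * sigma_r)
    return Quantity(value=value, sigma=sigma, unit="px3")


def estimator_rmse_sigma(estimates: Sequence[float], references: Sequence[float], unit: str = "px3") -> Quantity:
    """Type-A style uncertainty of an estimator: RMSE against its references.

    The returned quantity's value is the mean estimate and its sigma the RMSE.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise ValueError("need equal-length, non-empty paired series")
    sigma = float(np.sqrt(np.mean((est - ref) ** 2)))
    return Quantity(value=float(np.mean(est)), sigma=sigma, unit=unit)


def monte_carlo_budget(
    sources: Sequence[UncertaintySource],
    n_samples: int = 1_000_000,
    seed: int = 12345,
) -> UncertaintyBudget:
    """Monte Carlo oracle for :func:`propagate_power_product`.

    Samples each source as an independent normal, evaluates the power
    product, and reports the empirical combined sigma.  UPC is estimated by
    one-at-a-time resampling: vary one source with the rest clamped at their
    nominal values, and take each resulting variance as that source's share.
    """
    if n_samples < 10_000:
        raise ValueError("need n_samples >= 10^4 for a stable Monte Carlo budget")
    if not sources:
        raise ValueError("need at least one uncertainty source")
    rng = np.random.default_rng(seed)
    nominal = np.array([s.quantity.value for s in sources])
    if np.any(nominal == 0):
        raise ZeroDivisionError("zero nominal value in a source")
    sigmas = np.array([s.quantity.sigma for s in sources])
    powers = np.array([s.exponent for s in sources], dtype=float)

    draws = rng.normal(nominal, sigmas, size=(n_samples, len(sources)))
    y = np.prod(draws**powers, axis=1)
    value = float(np.prod(nominal**powers))
    combined = float(np.std(y, ddof=1))

    variances = []
    for i in range(len(sources)):
        one = np.tile(nominal, (n_samples, 1))
        one[:, i] = rng.normal(nominal[i], sigmas[i], size=n_samples)
        yi = np.prod(one**powers, axis=1)
        variances.append(float(np.var(yi, ddof=1)))
    total = sum(variances)
    if total == 0:
        upc = {s.name: 0.0 for s in sources}
        return UncertaintyBudget(tuple(sources), value, 0.0, 0.0, upc)
    # normalized shares sum to 100 by construction (interaction terms excluded)
    upc = {s.name: 100.0 * v / total for s, v in zip(sources, variances)}
    return UncertaintyBudget(tuple(sources), value, combined, combined / abs(value), upc)


def compatibility_check(error: float, sigma: float, k: float = 2.0) -> bool:
    """Metrological compatibility: |error| <= k * sigma (default k=2, ~95%).

    A zero sigma is accepted only for an exactly zero error (the noiseless
    degenerate case); any other error with sigma <= 0 raises.
    """
    if k <= 0:
        raise ValueError("coverage factor must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return error == 0
    return abs(error) <= k * sigma
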