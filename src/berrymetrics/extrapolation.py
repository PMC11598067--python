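"""Extrapolation of the single-bunch counting-error law to B-bunch images.

The counting error of the detector on single-bunch images is modelled as
normal, E ~ N(ME, sigma_E^2).  For an image containing B bunches with
independent errors, the total error is the sum of B such variables:

    E_B ~ N(B * ME, B * sigma_E^2)

The expected metrics of the B-bunch error follow in closed form:

    ME^B   = mu_B                      (first moment)
    MAE^B  = E|E_B|                    (folded-normal mean)
    RMSE^B = sqrt(mu_B^2 + sigma_B^2)  (root of the second raw moment)

with mu_B = B*ME and sigma_B = sqrt(B)*sigma_E.  A quadrature evaluation of
the same three integrals serves as an independent oracle for the closed
forms.  Note the root in RMSE^B: the bare second raw moment is a mean
*square*; the root form is what is comparable to a finite-sample RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate
from scipy.special import ndtr  # standard normal CDF via erf


@dataclass(frozen=True)
class ErrorModel:
    """Single-bunch counting-error law N(me, sigma_e^2), in berries."""

    me: float
    sigma_e: float

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise ValueError(f"sigma_e must be >= 0, got {self.sigma_e}")


@dataclass(frozen=True)
class ExtrapolatedMetrics:
    """Expected error metrics for an image containing b bunches."""

    b: int
    me_b: float
    mae_b: float
    rmse_b: float

    def __post_init__(self) -> None:
        if not (self.rmse_b >= self.mae_b - 1e-12 and self.mae_b >= abs(self.me_b) - 1e-12):
            raise ValueError("expected RMSE^B >= MAE^B >= |ME^B|")


def _check_b(b: int) -> int:
    if int(b) != b or b < 1:
        raise ValueError(f"number of bunches must be an integer >= 1, got {b}")
    return int(b)


def extrapolate_error_pdf(model: ErrorModel, b: int) -> tuple[float, float]:
    """Parameters (mu_B, sigma_B) of the B-bunch error distribution.

    Independence of per-bunch errors gives mu_B = b*ME, sigma_B = sqrt(b)*sigma_E.
    """
    b = _check_b(b)
    return b * model.me, math.sqrt(b) * model.sigma_e


def folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ N(mu, sigma^2).

    Closed form: sigma*sqrt(2/pi)*exp(-mu^2/(2 sigma^2)) + mu*(1 - 2 Phi(-mu/sigma)).
    Degenerates to |mu| as sigma -> 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return abs(mu)
    z = mu / sigma
    return sigma * math.sqrt(2.0 / math.pi) * math.exp(-0.5 * z * z) + mu * (1.0 - 2.0 * ndtr(-z))


def extrapolated_metrics(model: ErrorModel, b: int) -> ExtrapolatedMetrics:
    """Closed-form ME^B, MAE^B, RMSE^B for an image with b bunches."""
    mu, sigma = extrapolate_error_pdf(model, b)
    return ExtrapolatedMetrics(
        b=_check_b(b),
        me_b=mu,
        mae_b=folded_normal_mean(mu, sigma),
        rmse_b=math.hypot(mu, sigma),
    )


def extrapolated_metrics_quadrature(
    model: ErrorModel, b: int, tol: float = 1e-10
) -> ExtrapolatedMetrics:
    """Quadrature oracle: direct adaptive integration of x*f, |x|*f and x^2*f.

    Integrates against the N(mu_B, sigma_B^2) density and applies the square
    root to the second raw moment.  The domain is truncated at mu +/- 12
    sigma (normal mass beyond is ~1e-32, far below the tolerance), with a
    breakpoint at x=0 for the |x| kink.  Raises if the quadrature error
    estimate exceeds the requested tolerance (scaled by the magnitude of the
    moment) rather than returning a silently truncated value.
    """
    mu, sigma = extrapolate_error_pdf(model, b)
    if sigma == 0:
        return extrapolated_metrics(model, b)

    def pdf(x: float) -> float:
        z = (x - mu) / sigma
        return math.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))

    lo, hi = mu - 12.0 * sigma, mu + 12.0 * sigma
    breaks = [x for x in (0.0, mu) if lo < x < hi]
    moments = []
    for weight in (lambda x: x, abs, lambda x: x * x):
        val, err = integrate.quad(
            lambda x: weight(x) * pdf(x),
            lo,
            hi,
            points=breaks or None,
            epsabs=tol,
            epsrel=tol,
            limit=200,
        )
        if err > max(tol, 1e-8 * (abs(val) + 1.0)):
            raise RuntimeError(f"quadrature did not converge (error estimate {err:g})")
        moments.append(val)
    return ExtrapolatedMetrics(
        b=_check_b(b), me_b=moments[0], mae_b=moments[1], rmse_b=math.sqrt(moments[2])
    )


def normalized_mae(metrics: ExtrapolatedMetrics, berries_per_cluster: float) -> float:
    """MAE^B as a percentage of the expected berry total b * berries_per_cluster."""
    if berries_per_cluster <= 0:
        raise ValueError("berries_per_cluster must be > 0")
    return 100.0 * metrics.mae_b / (metrics.b * berries_per_cluster)
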