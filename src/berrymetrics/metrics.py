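"""Validation metrics for paired estimate/reference series.

All metrics operate on K paired observations (estimate, reference) and follow
the metrological conventions: errors are estimate minus reference, standard
deviations use the K-1 (sample, GUM type-A) denominator, and percentages are
on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_errors(est, ref) -> np.ndarray:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"paired series length mismatch: {est.shape} vs {ref.shape}")
    if est.size == 0:
        raise ValueError("empty series")
    return est - ref


@dataclass(frozen=True)
class PairedSeries:
    """K paired (estimate, reference) values sharing a unit."""

    est: tuple[float, ...]
    ref: tuple[float, ...]

    def __post_init__(self) -> None:
        _as_errors(self.est, self.ref)

    @property
    def errors(self) -> np.ndarray:
        return _as_errors(self.est, self.ref)


def _split(s, ref=None):
    if ref is not None:
        return np.asarray(s, dtype=float), np.asarray(ref, dtype=float)
    return np.asarray(s.est, dtype=float), np.asarray(s.ref, dtype=float)


def mean_error(s, ref=None) -> float:
    """Mean error (1/K) sum(est_k - ref_k)."""
    est, refv = _split(s, ref)
    return float(np.mean(_as_errors(est, refv)))


def mean_percentage_error(s, ref=None) -> float:
    """Mean percentage error, 100 * (1/K) sum((est_k - ref_k)/ref_k)."""
    est, refv = _split(s, ref)
    e = _as_errors(est, refv)
    if np.any(refv == 0):
        raise ZeroDivisionError("MPE undefined with zero reference values")
    return float(100.0 * np.mean(e / refv))


def percentage_error_sd(s, ref=None) -> float:
    """Sample standard deviation of the per-pair percentage errors."""
    est, refv = _split(s, ref)
    e = _as_errors(est, refv)
    if e.size < 2:
        raise ValueError("need K >= 2 for a sample standard deviation")
    if np.any(refv == 0):
        raise ZeroDivisionError("percentage errors undefined with zero reference values")
    return float(np.std(100.0 * e / refv, ddof=1))


def mae(s, ref=None) -> float:
    """Mean absolute error (1/K) sum|est_k - ref_k|."""
    est, refv = _split(s, ref)
    return float(np.mean(np.abs(_as_errors(est, refv))))


def rmse(s, ref=None) -> float:
    """Root mean squared error sqrt((1/K) sum(est_k - ref_k)^2)."""
    est, refv = _split(s, ref)
    return float(np.sqrt(np.mean(_as_errors(est, refv) ** 2)))


def error_sd(s, ref=None) -> float:
    """Sample standard deviation (K-1 denominator) of the errors."""
    est, refv = _split(s, ref)
    e = _as_errors(est, refv)
    if e.size < 2:
        raise ValueError("need K >= 2 for a sample standard deviation")
    return float(np.std(e, ddof=1))


def coefficient_of_variability(values) -> float:
    """CoV: 100 * sample sd / mean of a series of repeated measures."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a CoV")
    m = float(np.mean(v))
    if m == 0:
        raise ZeroDivisionError("CoV undefined for zero mean")
    return float(100.0 * np.std(v, ddof=1) / m)


def summarize(est, ref) -> dict[str, float]:
    """All paired metrics in one pass: ME, sigma_E, MPE, MPE sd, MAE, RMSE."""
    return {
        "me": mean_error(est, ref),
        "sigma_e": error_sd(est, ref),
        "mpe_pct": mean_percentage_error(est, ref),
        "mpe_sd_pct": percentage_error_sd(est, ref),
        "mae": mae(est, ref),
        "rmse": rmse(est, ref),
    }
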