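"""Scalar quantities with a standard uncertainty and a unit tag.

Every value that flows through the uncertainty chain is a :class:`Quantity`:
a nominal value, its standard uncertainty (one sigma, same unit), and a unit
tag.  Mixing units without an explicit conversion is a hard error, never a
silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Unit tags accepted by the pipeline.
VALID_UNITS = frozenset({"px", "mm", "px3", "mm3", "dimensionless", "mm/px"})


class UnitError(ValueError):
    """Raised when an operation receives a quantity in the wrong unit."""


@dataclass(frozen=True)
class Quantity:
    """A value with a standard uncertainty and a unit tag.

    Parameters
    ----------
    value:
        Nominal value, in ``unit``.
    sigma:
        Standard uncertainty, same unit.  Must be non-negative.
    unit:
        One of ``px``, ``mm``, ``px3``, ``mm3``, ``dimensionless``, ``mm/px``.
    """

    value: float
    sigma: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {sorted(VALID_UNITS)}")
        if self.sigma < 0:
            raise ValueError(f"standard uncertainty must be >= 0, got {self.sigma}")

    @property
    def relative_sigma(self) -> float:
        """Relative standard uncertainty sigma/|value|."""
        if self.value == 0:
            raise ZeroDivisionError("relative uncertainty undefined for zero nominal value")
        return self.sigma / abs(self.value)

    def require_unit(self, unit: str) -> "Quantity":
        """Return self if tagged with ``unit``, else raise :class:`UnitError`."""
        if self.unit != unit:
            raise UnitError(f"expected a quantity in {unit!r}, got {self.unit!r}")
        return self
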