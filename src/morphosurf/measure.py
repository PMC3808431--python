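"""Reduction of measured shell radii to actual and lowest-integer proportions.

Maximum whorl radius ``R_max`` and maximum aperture radius ``r_max`` (cm)
are measured from specimens or pictures.  Size is removed by dividing both
through by the smaller of the two (the *actual proportion*, reported to 3
decimals); the members are then rounded to the nearest integers and reduced
by their greatest common divisor (the *integer proportion*).  Integer
proportions parameterize generalized "blank" models, while the raw actual
proportions remain available for refined, reverse-engineered models.

Rounding conventions: actual proportions round half away from zero at the
third decimal; integer rounding is half-up (1.5 -> 2).  Both choices follow
the published measurement table, which resolves its single printed tie
upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .surfaces import MorphosurfError

__all__ = [
    "MeasurementError",
    "DegenerateRatioError",
    "RadiiMeasurement",
    "Proportion",
    "actual_proportion",
    "integer_proportion",
    "reduce_measurement",
    "reduce_table",
    "REFERENCE_MEASUREMENTS",
]


class MeasurementError(MorphosurfError):
    """A non-positive measured radius."""


class DegenerateRatioError(MorphosurfError):
    """A proportion member rounded to zero, leaving no usable integer ratio."""


@dataclass(frozen=True)
class RadiiMeasurement:
    """Measured maximum whorl and aperture radii of one shell, in cm."""

    taxon: str
    R_max: float
    r_max: float

    def __post_init__(self) -> None:
        if not (self.R_max > 0 and self.r_max > 0):
            raise MeasurementError(
                f"radii must be strictly positive, got "
                f"R_max={self.R_max}, r_max={self.r_max} for {self.taxon!r}"
            )


@dataclass(frozen=True)
class Proportion:
    """Actual and reduced-integer proportions of a radii measurement.

    ``actual`` is the (whorl, aperture) pair divided by its smaller member
    and rounded to 3 decimals, so ``min(actual) == 1.0``; ``integer`` is the
    nearest-integer pair reduced by its gcd, hence coprime.
    """

    actual: tuple[float, float]
    integer: tuple[int, int]


def _round3(x: float) -> float:
    """Round half away from zero at the third decimal."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def actual_proportion(m: RadiiMeasurement) -> tuple[float, float]:
    """Divide (R_max, r_max) by the smaller member; report to 3 decimals.

    The smaller member becomes exactly 1; the proportion is invariant under
    uniform rescaling of both radii.
    """
    small = min(m.R_max, m.r_max)
    return (_round3(m.R_max / small), _round3(m.r_max / small))


def integer_proportion(actual: tuple[float, float]) -> tuple[int, int]:
    """Round each member half-up to the nearest integer, reduce by the gcd."""
    ints = tuple(int(math.floor(x + 0.5)) for x in actual)
    if min(ints) < 1:
        raise DegenerateRatioError(f"proportion member rounded to zero: {actual}")
    g = math.gcd(*ints)
    return (ints[0] // g, ints[1] // g)


def reduce_measurement(m: RadiiMeasurement) -> Proportion:
    """Full reduction: measurement -> actual proportion -> integer proportion."""
    actual = actual_proportion(m)
    return Proportion(actual=actual, integer=integer_proportion(actual))


def reduce_table(measurements: Iterable[RadiiMeasurement] | pd.DataFrame) -> pd.DataFrame:
    """Reduce many measurements to a measurement-table-shaped report.

    Accepts an iterable of :class:`RadiiMeasurement` or a DataFrame with
    columns ``taxon``, ``R_max``, ``r_max``; returns one row per shell with
    measured radii, actual proportions and integer proportions.
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = [
            RadiiMeasurement(str(row.taxon), float(row.R_max), float(row.r_max))
            for row in measurements.itertuples(index=False)
        ]
    rows = []
    for m in measurements:
        p = reduce_measurement(m)
        rows.append(
            {
                "taxon": m.taxon,
                "R_max_cm": m.R_max,
                "r_max_cm": m.r_max,
                "actual_R": p.actual[0],
                "actual_r": p.actual[1],
                "integer_R": p.integer[0],
                "integer_r": p.integer[1],
            }
        )
    return pd.DataFrame(rows)


#: the 14 published gastropod measurements (cm) used throughout the examples
REFERENCE_MEASUREMENTS: tuple[RadiiMeasurement, ...] = (
    RadiiMeasurement("Scaphander lignarius", 1.0, 1.5),
    RadiiMeasurement("Sinum perspectivum", 1.6, 1.6),
    RadiiMeasurement("Melampus coffeus", 0.7, 0.85),
    RadiiMeasurement("Oliva sayana", 0.8, 1.35),
    RadiiMeasurement("Longchaeus candidus", 0.55, 0.45),
    RadiiMeasurement("Lithopoma phoebium", 1.8, 0.75),
    RadiiMeasurement("Scalenostoma subulatum", 0.55, 0.4),
    RadiiMeasurement("Architectonica nobilis", 1.45, 0.4),
    RadiiMeasurement("Heliacus variegatus", 0.8, 0.3),
    RadiiMeasurement("Calliostoma bairdi", 1.2, 0.45),
    RadiiMeasurement("Janthina globosa", 1.35, 1.25),
    RadiiMeasurement("Vitrinella oldroydi", 0.7, 0.25),
    RadiiMeasurement("Scaphella junonia", 0.9, 1.55),
    RadiiMeasurement("Buccinum glaciale", 1.4, 1.05),
)
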