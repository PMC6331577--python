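"""Scale back-calculation and egg metrics.

Smolt length is back-calculated from adult scales with the classical
proportional (Lea-Dahl) body-scale relation: length at an annulus is the
annulus radius over the total scale radius times body length at capture.
Egg size per dam is derived from the count of eggs spanning 25 cm (sphere
model for per-egg volume) and egg number from the total spawned volume.
Only relative effects enter the downstream log-scale models, so the
constant factors in these conversions cancel there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import pandas as pd

__all__ = [
    "ScaleReading",
    "EggMeasurement",
    "back_calculate_length",
    "smolt_length",
    "egg_size_from_count",
    "reading_from_row",
    "add_back_calculated_smolt_length",
]


@dataclass(frozen=True)
class ScaleReading:
    """Annulus radii (consistent arbitrary units) plus capture measurements."""

    individual_id: str
    annulus_radii: tuple
    total_radius: float
    length_at_capture_mm: float
    smolt_annulus: int
    sea_age: int

    def __post_init__(self):
        radii = tuple(float(r) for r in self.annulus_radii)
        object.__setattr__(self, "annulus_radii", radii)
        if len(radii) == 0:
            raise ValueError("at least one annulus radius is required")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("annulus radii must be strictly increasing")
        if not 0 <= self.smolt_annulus < len(radii):
            raise ValueError("smolt_annulus index out of range")
        if radii[self.smolt_annulus] > self.total_radius:
            raise ValueError("smolt annulus radius exceeds total scale radius")
        if self.length_at_capture_mm <= 0:
            raise ValueError("body length at capture must be positive")


@dataclass(frozen=True)
class EggMeasurement:
    dam_id: str
    eggs_per_25cm: int
    total_volume_ml: float
    egg_diameter_mm: float
    egg_size_ml: float
    egg_number: int

    def __post_init__(self):
        if self.eggs_per_25cm <= 0 or self.total_volume_ml <= 0:
            raise ValueError("egg count and total volume must be positive")


def back_calculate_length(reading: ScaleReading, annulus_index: int) -> float:
    """Proportional back-calculated body length (mm) at an annulus:
    L_i = (S_i / S_total) * L_capture."""
    if not 0 <= annulus_index < len(reading.annulus_radii):
        raise ValueError(f"annulus_index {annulus_index} out of range")
    if reading.total_radius <= 0:
        raise ValueError("total scale radius must be positive")
    return reading.annulus_radii[annulus_index] / reading.total_radius * reading.length_at_capture_mm


def smolt_length(reading: ScaleReading) -> float:
    """Back-calculated body length at seaward migration."""
    return back_calculate_length(reading, reading.smolt_annulus)


def egg_size_from_count(
    eggs_per_25cm: int, total_volume_ml: float, dam_id: str = ""
) -> EggMeasurement:
    """Per-egg size and egg number from a 25-cm row count and total volume.

    Egg diameter is 250 mm / count; per-egg volume is the sphere volume
    (pi/6) d^3 in mm^3, converted to ml; egg number is total volume over
    per-egg volume, rounded to the nearest integer.
    """
    if eggs_per_25cm <= 0 or total_volume_ml <= 0:
        raise ValueError("eggs_per_25cm and total_volume_ml must be positive")
    diameter = 250.0 / eggs_per_25cm
    size_ml = math.pi / 6.0 * diameter**3 / 1000.0
    number = int(round(total_volume_ml / size_ml))
    return EggMeasurement(dam_id, int(eggs_per_25cm), float(total_volume_ml), diameter, size_ml, number)


def reading_from_row(row) -> ScaleReading:
    """Build a ScaleReading from a table row carrying an ``annulus_radii``
    field of ';'-joined radii (as written by the simulator and I/O layer)."""
    radii = [float(x) for x in str(row.annulus_radii).split(";")]
    return ScaleReading(
        individual_id=str(row.individual_id),
        annulus_radii=tuple(radii),
        total_radius=float(row.total_radius),
        length_at_capture_mm=float(row.capture_length_mm),
        smolt_annulus=int(row.smolt_annulus),
        sea_age=int(row.sea_age),
    )


def add_back_calculated_smolt_length(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``smolt_length_mm`` column of back-calculated lengths."""
    out = table.copy()
    out["smolt_length_mm"] = [
        smolt_length(reading_from_row(row)) for row in table.itertuples()
    ]
    return out
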