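"""Point-observation tables: loading, validation, splitting, summaries.

The canonical on-disk format is a CSV with one row per sampled corn field
point and exactly these columns, in order::

    point_no, dry_biomass, wet_biomass, soil_moisture,
    hh_backscatter, hv_backscatter, incidence_angle, ndvi

Biomass is in kg m^-2, soil moisture is volumetric (m^3 m^-3), backscatter
is the linear-power sigma-nought (NOT decibels) and the incidence angle is
in degrees.  A 66-point corn field dataset (RADARSAT-2 C-band HH/HV plus
RapidEye NDVI) ships with the package; its first 23 rows
are the model-calibration points and the remaining 43 the validation points.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "ObservationRecord",
    "ObservationTable",
    "SchemaError",
    "ValidationError",
    "load_table",
    "write_table",
    "load_corn_observations",
    "split",
    "summarize",
    "db_to_power",
    "power_to_db",
]

COLUMNS = (
    "point_no",
    "dry_biomass",
    "wet_biomass",
    "soil_moisture",
    "hh_backscatter",
    "hv_backscatter",
    "incidence_angle",
    "ndvi",
)

_NUMERIC_FIELDS = COLUMNS[1:]

DEFAULT_N_CALIBRATION = 23
_FIXTURE_NAME = "corn_observations.csv"


class SchemaError(ValueError):
    """The file does not have the expected column layout."""


class ValidationError(ValueError):
    """A record violates a physical-range invariant."""


@dataclass(frozen=True)
class ObservationRecord:
    """One ground/satellite sample point."""

    point_no: int
    dry_biomass: float
    wet_biomass: float
    soil_moisture: float
    hh_backscatter: float
    hv_backscatter: float
    incidence_angle: float
    ndvi: float

    def validate(self) -> None:
        pn = self.point_no
        if pn <= 0 or int(pn) != pn:
            raise ValidationError(f"point_no {pn!r} is not a positive integer")
        checks = [
            ("dry_biomass", self.dry_biomass >= 0.0),
            ("wet_biomass", self.wet_biomass >= self.dry_biomass),
            ("soil_moisture", 0.0 <= self.soil_moisture <= 1.0),
            ("hh_backscatter", self.hh_backscatter > 0.0),
            ("hv_backscatter", self.hv_backscatter > 0.0),
            ("incidence_angle", 0.0 < self.incidence_angle < 90.0),
            ("ndvi", -1.0 <= self.ndvi <= 1.0),
        ]
        for field, ok in checks:
            value = getattr(self, field)
            if not (ok and np.isfinite(value)):
                raise ValidationError(
                    f"point_no {self.point_no}: field {field}={value!r} "
                    "violates its physical range"
                )


@dataclass(frozen=True)
class ObservationTable:
    """An ordered set of records whose leading rows are calibration points."""

    records: tuple[ObservationRecord, ...]
    n_calibration: int = DEFAULT_N_CALIBRATION

    def __post_init__(self) -> None:
        if not 0 < self.n_calibration < len(self.records):
            raise ValidationError(
                f"n_calibration={self.n_calibration} must lie strictly between "
                f"0 and the number of records ({len(self.records)})"
            )
        nos = [r.point_no for r in self.records]
        if any(b <= a for a, b in zip(nos, nos[1:])):
            raise ValidationError("point_no values must be unique and ascending")
        for record in self.records:
            record.validate()

    def __len__(self) -> int:
        return len(self.records)

    @property
    def calibration(self) -> list[ObservationRecord]:
        return list(self.records[: self.n_calibration])

    @property
    def validation(self) -> list[ObservationRecord]:
        return list(self.records[self.n_calibration:])

    def split(self) -> tuple[list[ObservationRecord], list[ObservationRecord]]:
        return self.calibration, self.validation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_calibration: int) -> "ObservationTable":
        missing = [c for c in COLUMNS if c not in frame.columns]
        extra = [c for c in frame.columns if c not in COLUMNS]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        if extra:
            raise SchemaError(f"unexpected column(s): {', '.join(extra)}")
        if len(frame) == 0:
            raise SchemaError("table has no data rows")
        records = tuple(
            ObservationRecord(
                point_no=int(row.point_no),
                dry_biomass=float(row.dry_biomass),
                wet_biomass=float(row.wet_biomass),
                soil_moisture=float(row.soil_moisture),
                hh_backscatter=float(row.hh_backscatter),
                hv_backscatter=float(row.hv_backscatter),
                incidence_angle=float(row.incidence_angle),
                ndvi=float(row.ndvi),
            )
            for row in frame.itertuples(index=False)
        )
        return cls(records=records, n_calibration=n_calibration)


def load_table(path: str | Path, n_calibration: int = DEFAULT_N_CALIBRATION) -> ObservationTable:
    """Read and validate an observation CSV.

    Raises :class:`SchemaError` for a malformed file and
    :class:`ValidationError` for rows violating physical invariants.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    return ObservationTable.from_frame(frame, n_calibration=n_calibration)


def write_table(table: ObservationTable, path: str | Path) -> None:
    """Write a table in the canonical CSV layout (column order preserved).

    Floats use the shortest round-trippable representation so that
    load -> write -> load is lossless.
    """
    table.to_frame().to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def load_corn_observations(n_calibration: int = DEFAULT_N_CALIBRATION) -> ObservationTable:
    """Load the packaged 66-point corn dataset."""
    ref = resources.files("sarbiomass.data").joinpath(_FIXTURE_NAME)
    with resources.as_file(ref) as path:
        return load_table(path, n_calibration=n_calibration)


def split(table: ObservationTable) -> tuple[list[ObservationRecord], list[ObservationRecord]]:
    """Partition a table into (calibration, validation) record lists."""
    return table.split()


def summarize(records: Sequence[ObservationRecord] | Iterable[ObservationRecord]) -> pd.DataFrame:
    """Per-field min/max/count over a non-empty list of records.

    Returns a DataFrame indexed by field name with columns
    ``min``, ``max`` and ``count``.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty record list")
    frame = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
    numeric = frame[list(_NUMERIC_FIELDS)]
    return pd.DataFrame(
        {
            "min": numeric.min(),
            "max": numeric.max(),
            "count": len(records),
        }
    )


def db_to_power(value_db):
    """Convert backscatter from decibels to linear power."""
    return 10.0 ** (np.asarray(value_db, dtype=float) / 10.0)


def power_to_db(value_power):
    """Convert backscatter from linear power to decibels."""
    value_power = np.asarray(value_power, dtype=float)
    if np.any(value_power <= 0):
        raise ValueError("power must be strictly positive to convert to dB")
    return 10.0 * np.log10(value_power)
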