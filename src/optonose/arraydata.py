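"""Data model for multi-dye paper sensors and their RGB readings.

A sensor paper carries up to eight drop-casted dye spots. Each exposure of a
paper to a gas produces, per spot, a batch of raw RGB measurements from the
colour sensor; these are aggregated (channel-wise mean) and paired with the
aggregated reading of an unexposed control strip from the same batch. This
module defines the domain types (:class:`RGBReading`, :class:`DyeFormulation`,
:class:`SensorPanel`, :class:`ExposureRecord`), replicate aggregation, panel
validation, and reading/writing of the tabular interchange formats.

Readings-table schema (CSV, header row)::

    panel_id, spot_index, dye_id, gas, concentration_ppm, replicate,
    is_control, day, condition, r, g, b

``concentration_ppm``, ``day`` and ``condition`` may be empty (in vivo
exposures have unknown concentration). ``is_control`` is 0/1: control rows
come from paired unexposed strips, not time-zero readings of the same strip.

Panel-definition schema (CSV)::

    dye_id, base_dye, adjuvants, solvent, spot_index

with ``adjuvants`` semicolon-separated.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_SENSOR_MAX",
    "RGBReading",
    "DyeFormulation",
    "SensorPanel",
    "ExposureRecord",
    "aggregate_readings",
    "validate_panel",
    "read_exposures",
    "write_exposures",
    "read_panel",
    "write_panel",
]

#: Full-scale channel value of the RGB colour sensor (8-bit driver convention).
DEFAULT_SENSOR_MAX = 255.0

MAX_SPOTS = 8

READINGS_COLUMNS = [
    "panel_id",
    "spot_index",
    "dye_id",
    "gas",
    "concentration_ppm",
    "replicate",
    "is_control",
    "day",
    "condition",
    "r",
    "g",
    "b",
]

PANEL_COLUMNS = ["dye_id", "base_dye", "adjuvants", "solvent", "spot_index"]


@dataclass(frozen=True)
class RGBReading:
    """One (red, green, blue) measurement of a dye spot, in sensor counts."""

    red: float
    green: float
    blue: float

    def __post_init__(self) -> None:
        for name, value in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            if not math.isfinite(value):
                raise ValueError(f"RGB channel {name!r} is not finite: {value!r}")
            if value < 0:
                raise ValueError(f"RGB channel {name!r} is negative: {value!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.red, self.green, self.blue)

    def check_range(self, sensor_max: float = DEFAULT_SENSOR_MAX) -> None:
        """Raise ValueError if any channel exceeds the sensor full scale."""
        for name, value in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            if value > sensor_max:
                raise ValueError(
                    f"RGB channel {name!r} = {value} exceeds sensor maximum {sensor_max}"
                )


@dataclass(frozen=True)
class DyeFormulation:
    """A dye spot recipe: base dye plus selectivity-tuning adjuvants in a solvent."""

    dye_id: str
    base_dye: str = ""
    adjuvants: tuple[str, ...] = ()
    solvent: str = ""


@dataclass(frozen=True)
class SensorPanel:
    """An ordered layout of dye spots on one sensor paper (spot 0..n-1)."""

    panel_id: str
    spots: tuple[DyeFormulation, ...]

    @property
    def dye_ids(self) -> tuple[str, ...]:
        return tuple(s.dye_id for s in self.spots)

    @property
    def n_spots(self) -> int:
        return len(self.spots)


@dataclass
class ExposureRecord:
    """One exposure event: per-spot aggregated test and control readings.

    ``concentration`` is None for in vivo exposures where the headspace
    concentration is unknown; ``day``/``condition`` label time-course samples.
    """

    panel_id: str
    gas_id: str
    concentration: float | None
    replicate: int
    test: tuple[RGBReading, ...]
    control: tuple[RGBReading, ...]
    day: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if len(self.test) != len(self.control):
            raise ValueError(
                f"test ({len(self.test)} spots) and control ({len(self.control)} spots) "
                "aggregates have different lengths"
            )
        if self.concentration is not None and self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


def aggregate_readings(readings: Sequence[RGBReading]) -> RGBReading:
    """Channel-wise arithmetic mean of raw readings from one spot.

    Raises ValueError on an empty list (no data for the spot).
    """
    if len(readings) == 0:
        raise ValueError("cannot aggregate an empty list of readings: no data for spot")
    n = len(readings)
    return RGBReading(
        red=sum(r.red for r in readings) / n,
        green=sum(r.green for r in readings) / n,
        blue=sum(r.blue for r in readings) / n,
    )


def validate_panel(panel: SensorPanel) -> list[str]:
    """Report violations of the panel invariants; an empty list means valid."""
    violations: list[str] = []
    n = panel.n_spots
    if n < 1:
        violations.append("panel has no spots")
    if n > MAX_SPOTS:
        violations.append(f"spot count > {MAX_SPOTS} (got {n})")
    seen: set[str] = set()
    for spot in panel.spots:
        if spot.dye_id in seen:
            violations.append(f"duplicated dye_id: {spot.dye_id!r}")
        seen.add(spot.dye_id)
    return violations


def _parse_float(text: str, *, row: int, column: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"row {row}: malformed numeric value {text!r} in column {column!r}") from None
    if not math.isfinite(value):
        raise ValueError(f"row {row}: non-finite value {text!r} in column {column!r}")
    return value


def _parse_int(text: str, *, row: int, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"row {row}: malformed integer {text!r} in column {column!r}") from None


def read_exposures(
    path,
    panel: SensorPanel,
    sensor_max: float = DEFAULT_SENSOR_MAX,
) -> list[ExposureRecord]:
    """Parse a readings-table CSV into aggregated :class:`ExposureRecord` objects.

    Raw rows are grouped by (panel_id, gas, concentration, replicate, day,
    condition); within a group, rows are split by ``is_control`` and aggregated
    per spot with :func:`aggregate_readings`. Missing control rows, spot indices
    outside the panel, malformed numerics and saturated channels are rejected
    with errors naming the offending group or row.
    """
    groups: dict[tuple, dict[int, dict[int, list[RGBReading]]]] = {}
    order: list[tuple] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in READINGS_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"readings table is missing columns: {missing}")
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            if row["panel_id"] != panel.panel_id:
                continue
            spot = _parse_int(row["spot_index"], row=i, column="spot_index")
            if not 0 <= spot < panel.n_spots:
                raise ValueError(
                    f"row {i}: spot_index {spot} outside panel "
                    f"{panel.panel_id!r} (0..{panel.n_spots - 1})"
                )
            conc_text = (row["concentration_ppm"] or "").strip()
            conc = _parse_float(conc_text, row=i, column="concentration_ppm") if conc_text else None
            if conc is not None and conc < 0:
                raise ValueError(f"row {i}: negative concentration_ppm {conc}")
            replicate = _parse_int(row["replicate"], row=i, column="replicate")
            is_control = _parse_int(row["is_control"], row=i, column="is_control")
            if is_control not in (0, 1):
                raise ValueError(f"row {i}: is_control must be 0 or 1, got {is_control}")
            day_text = (row["day"] or "").strip()
            day = _parse_int(day_text, row=i, column="day") if day_text else None
            condition = (row["condition"] or "").strip() or None
            reading = RGBReading(
                red=_parse_float(row["r"], row=i, column="r"),
                green=_parse_float(row["g"], row=i, column="g"),
                blue=_parse_float(row["b"], row=i, column="b"),
            )
            try:
                reading.check_range(sensor_max)
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from None
            key = (row["gas"], conc, replicate, day, condition)
            if key not in groups:
                groups[key] = {0: {}, 1: {}}
                order.append(key)
            groups[key][is_control].setdefault(spot, []).append(reading)

    records: list[ExposureRecord] = []
    for key in order:
        gas, conc, replicate, day, condition = key
        label = f"(gas={gas!r}, concentration={conc}, replicate={replicate}, day={day}, condition={condition})"
        by_side = groups[key]
        if not by_side[1]:
            raise ValueError(f"no control rows for exposure group {label}")
        if not by_side[0]:
            raise ValueError(f"no test rows for exposure group {label}")
        aggregates: dict[int, list[RGBReading]] = {}
        for side in (0, 1):
            per_spot = by_side[side]
            missing_spots = sorted(set(range(panel.n_spots)) - set(per_spot))
            if missing_spots:
                side_name = "control" if side else "test"
                raise ValueError(
                    f"exposure group {label}: missing {side_name} rows for spots {missing_spots}"
                )
            aggregates[side] = [aggregate_readings(per_spot[s]) for s in range(panel.n_spots)]
        records.append(
            ExposureRecord(
                panel_id=panel.panel_id,
                gas_id=gas,
                concentration=conc,
                replicate=replicate,
                test=tuple(aggregates[0]),
                control=tuple(aggregates[1]),
                day=day,
                condition=condition,
            )
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(float(value))  # builtin repr survives numpy scalars
    return str(value)


def write_exposures(records: Iterable[ExposureRecord], panel: SensorPanel, path) -> None:
    """Write aggregated exposure records back to the readings-table schema.

    Each record becomes one test row and one control row per spot carrying the
    aggregated channel values at full float precision, so a write/read
    round-trip is lossless.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(READINGS_COLUMNS)
        for rec in records:
            for is_control, side in ((0, rec.test), (1, rec.control)):
                for spot, reading in enumerate(side):
                    writer.writerow(
                        [
                            rec.panel_id,
                            spot,
                            panel.spots[spot].dye_id,
                            rec.gas_id,
                            _fmt(rec.concentration),
                            rec.replicate,
                            is_control,
                            _fmt(rec.day),
                            rec.condition or "",
                            _fmt(reading.red),
                            _fmt(reading.green),
                            _fmt(reading.blue),
                        ]
                    )


def read_panel(path, panel_id: str = "panel") -> SensorPanel:
    """Read a panel-definition CSV into a :class:`SensorPanel` (spots by index)."""
    rows: list[tuple[int, DyeFormulation]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in PANEL_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"panel definition is missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            spot = _parse_int(row["spot_index"], row=i, column="spot_index")
            adjuvants = tuple(a for a in (row["adjuvants"] or "").split(";") if a)
            rows.append(
                (
                    spot,
                    DyeFormulation(
                        dye_id=row["dye_id"],
                        base_dye=row["base_dye"] or "",
                        adjuvants=adjuvants,
                        solvent=row["solvent"] or "",
                    ),
                )
            )
    rows.sort(key=lambda t: t[0])
    indices = [t[0] for t in rows]
    if indices != list(range(len(rows))):
        raise ValueError(f"spot indices must be contiguous 0..n-1, got {indices}")
    return SensorPanel(panel_id=panel_id, spots=tuple(t[1] for t in rows))


def write_panel(panel: SensorPanel, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PANEL_COLUMNS)
        for spot, dye in enumerate(panel.spots):
            writer.writerow([dye.dye_id, dye.base_dye, ";".join(dye.adjuvants), dye.solvent, spot])
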