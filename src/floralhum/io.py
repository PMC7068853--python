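"""Core records and file formats for floral-humidity transect surveys.

A survey run produces paired humidity time series from two DHT-22 style
probes: a *background* probe fixed away from the flower array, and a
*focal* probe moved by a robot arm through a horizontal (x) and a
vertical (z) transect above each flower. At every spatial offset the
probe dwells 230 s: a 30 s settling time followed by a 200 s measurement
period yielding roughly 100 readings per probe. Probe-control periods,
where the focal probe sits next to the background probe, anchor the
cross-calibration.

Probe logs are plain CSV with one row per reading; this module groups
them into :class:`MeasurementPeriod` records and validates the spatial
grid (x offsets -30..30 mm in 5 mm steps, z offsets 5..30 mm).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

X_OFFSETS = tuple(range(-30, 35, 5))  # 13 sampling points
Z_OFFSETS = tuple(range(5, 35, 5))  # 6 sampling points
REPLICATES = (1, 2, 3, 4)
SETTLING_S = 30.0
MEASUREMENT_S = 200.0

X_MODEL_IDS = tuple(f"m{i}" for i in range(11))
Z_MODEL_IDS = tuple(f"z{i}" for i in range(5))

PROBE_LOG_COLUMNS = [
    "day",
    "flower",
    "species",
    "replicate",
    "axis",
    "offset_mm",
    "probe_role",
    "timestamp_s",
    "rh_pct",
]


class ProbeLogError(ValueError):
    """Raised when a probe log violates the documented schema."""


@dataclass(frozen=True)
class ProbeReading:
    """One relative-humidity reading from one probe.

    timestamp: seconds since the start of the 230 s stop (settling time
    included), so readings with ``timestamp < settling_s`` belong to the
    non-sampled settling window.
    """

    timestamp: float
    rh: float
    probe_role: str  # "focal" | "background"

    def __post_init__(self) -> None:
        if not np.isfinite(self.rh) or not 0.0 <= self.rh <= 100.0:
            raise ValueError(f"relative humidity out of range: {self.rh!r}")
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp: {self.timestamp!r}")
        if self.probe_role not in ("focal", "background"):
            raise ValueError(f"unknown probe role: {self.probe_role!r}")


@dataclass
class MeasurementPeriod:
    """All paired readings taken while the focal probe dwelt at one offset.

    ``axis`` is ``"x"`` or ``"z"`` for transect stops and
    ``"probe_control"`` when the focal probe sat beside the background
    probe (``offset`` is then None). Settling-time readings are retained
    and flagged via timestamps so quality control can inspect the whole
    stop; downstream averaging uses only the measurement window.
    """

    day_id: str
    flower_id: str
    species_id: str
    replicate: int
    axis: str
    offset: float | None
    focal_readings: list[ProbeReading] = field(default_factory=list)
    background_readings: list[ProbeReading] = field(default_factory=list)
    settling_s: float = SETTLING_S

    def __post_init__(self) -> None:
        if self.replicate not in REPLICATES:
            raise ValueError(f"replicate must be 1-4, got {self.replicate}")
        if self.axis not in ("x", "z", "probe_control"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.axis == "x" and self.offset not in X_OFFSETS:
            raise ValueError(f"x offset {self.offset!r} not on the 5 mm grid")
        if self.axis == "z" and self.offset not in Z_OFFSETS:
            raise ValueError(f"z offset {self.offset!r} not on the 5 mm grid")
        if self.axis == "probe_control" and self.offset is not None:
            raise ValueError("probe-control periods carry no offset")

    @property
    def is_usable(self) -> bool:
        """At least two readings per probe inside the measurement window."""
        return (
            len(self.measurement_focal()) >= 2
            and len(self.measurement_background()) >= 2
        )

    def _in_window(self, readings: Sequence[ProbeReading]) -> list[ProbeReading]:
        hi = self.settling_s + MEASUREMENT_S
        return [r for r in readings if self.settling_s <= r.timestamp <= hi]

    def measurement_focal(self) -> list[ProbeReading]:
        return self._in_window(self.focal_readings)

    def measurement_background(self) -> list[ProbeReading]:
        return self._in_window(self.background_readings)

    def focal_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.measurement_focal()
        return (np.array([x.timestamp for x in r]), np.array([x.rh for x in r]))

    def background_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.measurement_background()
        return (np.array([x.timestamp for x in r]), np.array([x.rh for x in r]))

    @property
    def key(self) -> tuple:
        return (
            self.day_id,
            self.flower_id,
            self.species_id,
            self.replicate,
            self.axis,
            self.offset,
        )


@dataclass
class SpeciesSummaryRow:
    """One row of the survey summary table (species or control group)."""

    name: str
    is_control: bool
    best_x_model: str
    best_z_model: str
    x_max: float
    delta_rh_max: float
    rank: int | None = None
    floral_structure: str | None = None
    floral_type: str | None = None  # "flower" | "inflorescence"
    grown_outside: bool | None = None
    mean_span: float | None = None
    span_source: str | None = None
    stomata_pct: float | None = None
    stomata_n: int | None = None
    comparable_x_models: tuple[str, ...] = ()
    x_max_replicate: str | None = None  # "1".."4", "(Z)", or None

    def __post_init__(self) -> None:
        if self.best_x_model not in X_MODEL_IDS:
            raise ValueError(f"unknown x model id {self.best_x_model!r}")
        if self.best_z_model not in Z_MODEL_IDS:
            raise ValueError(f"unknown z model id {self.best_z_model!r}")
        if not -30.0 <= self.x_max <= 30.0:
            raise ValueError(f"x_max {self.x_max} outside the sampled range")
        if not self.comparable_x_models:
            self.comparable_x_models = (self.best_x_model,)


def _parse_offset(axis: str, raw: str, lineno: int) -> float | None:
    if axis == "probe_control":
        if raw not in ("", "NA"):
            raise ProbeLogError(
                f"line {lineno}: probe_control rows must leave offset_mm empty"
            )
        return None
    try:
        off = float(raw)
    except ValueError:
        raise ProbeLogError(f"line {lineno}: bad offset_mm {raw!r}") from None
    grid = X_OFFSETS if axis == "x" else Z_OFFSETS
    if off not in grid:
        raise ProbeLogError(
            f"line {lineno}: offset {off} mm is not on the legal {axis}-axis grid"
        )
    return off


def read_probe_log(path: str | Path, settling_s: float = SETTLING_S
                   ) -> list[MeasurementPeriod]:
    """Parse a probe-log CSV into measurement periods.

    Rejects malformed rows (naming the line), offsets off the 5 mm grid,
    and out-of-range humidity values. Periods with fewer than two
    readings per probe inside the measurement window are returned but
    flagged unusable (``is_usable``) so they can be excluded from fits.
    """
    path = Path(path)
    periods: dict[tuple, MeasurementPeriod] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(PROBE_LOG_COLUMNS) - set(
            reader.fieldnames
        ):
            raise ProbeLogError(
                f"{path}: header must contain columns {PROBE_LOG_COLUMNS}"
            )
        for row in reader:
            lineno = reader.line_num
            axis = row["axis"]
            if axis not in ("x", "z", "probe_control"):
                raise ProbeLogError(f"line {lineno}: unknown axis {axis!r}")
            try:
                replicate = int(row["replicate"])
                ts = float(row["timestamp_s"])
                rh = float(row["rh_pct"])
            except ValueError:
                raise ProbeLogError(
                    f"line {lineno}: malformed numeric field in {row!r}"
                ) from None
            offset = _parse_offset(axis, row["offset_mm"].strip(), lineno)
            key = (row["day"], row["flower"], row["species"], replicate, axis,
                   offset)
            if key not in periods:
                try:
                    periods[key] = MeasurementPeriod(
                        day_id=row["day"],
                        flower_id=row["flower"],
                        species_id=row["species"],
                        replicate=replicate,
                        axis=axis,
                        offset=offset,
                        settling_s=settling_s,
                    )
                except ValueError as exc:
                    raise ProbeLogError(f"line {lineno}: {exc}") from None
            try:
                reading = ProbeReading(ts, rh, row["probe_role"])
            except ValueError as exc:
                raise ProbeLogError(f"line {lineno}: {exc}") from None
            if reading.probe_role == "focal":
                periods[key].focal_readings.append(reading)
            else:
                periods[key].background_readings.append(reading)
    return list(periods.values())


def write_probe_log(periods: Iterable[MeasurementPeriod], path: str | Path) -> None:
    """Serialize periods back to the probe-log CSV schema (lossless)."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PROBE_LOG_COLUMNS)
        for p in periods:
            off = "" if p.offset is None else f"{p.offset:g}"
            for role, readings in (
                ("focal", p.focal_readings),
                ("background", p.background_readings),
            ):
                for r in readings:
                    writer.writerow(
                        [p.day_id, p.flower_id, p.species_id, p.replicate,
                         p.axis, off, role, repr(r.timestamp), repr(r.rh)]
                    )


_SUMMARY_COLUMNS = [
    "rank", "name", "is_control", "floral_structure", "floral_type",
    "grown_outside", "mean_span_mm", "span_source", "stomata_pct",
    "stomata_n", "best_x_model", "comparable_x_models", "best_z_model",
    "x_max_mm", "x_max_replicate", "delta_rh_max_pct",
]


def _row_from_record(rec: dict) -> SpeciesSummaryRow:
    def opt(v):
        return None if v in ("", None) or (isinstance(v, float) and np.isnan(v)) else v

    def opt_float(v):
        v = opt(v)
        return None if v is None else float(v)

    comp = opt(rec.get("comparable_x_models"))
    return SpeciesSummaryRow(
        name=str(rec["name"]),
        is_control=bool(int(rec["is_control"])),
        best_x_model=str(rec["best_x_model"]),
        best_z_model=str(rec["best_z_model"]),
        x_max=float(rec["x_max_mm"]),
        delta_rh_max=float(rec["delta_rh_max_pct"]),
        rank=None if opt(rec.get("rank")) is None else int(float(rec["rank"])),
        floral_structure=opt(rec.get("floral_structure")),
        floral_type=opt(rec.get("floral_type")),
        grown_outside=(
            None if opt(rec.get("grown_outside")) is None
            else bool(int(float(rec["grown_outside"])))
        ),
        mean_span=opt_float(rec.get("mean_span_mm")),
        span_source=None if opt(rec.get("span_source")) is None
        else str(rec["span_source"]),
        stomata_pct=opt_float(rec.get("stomata_pct")),
        stomata_n=(
            None if opt(rec.get("stomata_n")) is None
            else int(float(rec["stomata_n"]))
        ),
        comparable_x_models=(
            tuple(str(comp).split(";")) if comp is not None else ()
        ),
        x_max_replicate=None if opt(rec.get("x_max_replicate")) is None
        else str(rec["x_max_replicate"]),
    )


def read_summary_table(path: str | Path) -> list[SpeciesSummaryRow]:
    df = pd.read_csv(path, dtype={"span_source": str, "x_max_replicate": str})
    return [_row_from_record(rec) for rec in df.to_dict("records")]


def write_summary_table(rows: Iterable[SpeciesSummaryRow], path: str | Path) -> None:
    """Write the summary table CSV with a stable column order.

    An empty collection yields a header-only file; numeric cells keep
    full precision so a write/read round trip is lossless.
    """
    records = []
    for r in rows:
        records.append({
            "rank": "" if r.rank is None else r.rank,
            "name": r.name,
            "is_control": int(r.is_control),
            "floral_structure": r.floral_structure or "",
            "floral_type": r.floral_type or "",
            "grown_outside": "" if r.grown_outside is None else int(r.grown_outside),
            "mean_span_mm": "" if r.mean_span is None else repr(r.mean_span),
            "span_source": r.span_source or "",
            "stomata_pct": "" if r.stomata_pct is None else repr(r.stomata_pct),
            "stomata_n": "" if r.stomata_n is None else r.stomata_n,
            "best_x_model": r.best_x_model,
            "comparable_x_models": ";".join(r.comparable_x_models),
            "best_z_model": r.best_z_model,
            "x_max_mm": repr(r.x_max),
            "x_max_replicate": r.x_max_replicate or "",
            "delta_rh_max_pct": repr(r.delta_rh_max),
        })
    with open(Path(path), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_SUMMARY_COLUMNS)
        writer.writeheader()
        writer.writerows(records)


def load_species_summary() -> list[SpeciesSummaryRow]:
    """Load the packaged survey summary: 42 species rows + 6 control rows.

    Controls are water/lid/putty combinations of the horticultural tube
    (T, TL, TLP, TW, TWL, TWLP), each summarized once. The TWL control
    (0.46 %RH) is the benchmark for humidity extraneous to the flower;
    the TW control (1.17 %RH) is the strongest humidity any control
    produced.
    """
    ref = importlib.resources.files("floralhum") / "data" / "species_summary.csv"
    with importlib.resources.as_file(ref) as path:
        if not path.exists():  # pragma: no cover
            raise FileNotFoundError("packaged species summary fixture missing")
        return read_summary_table(path)
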