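"""Paired-probe cross-calibration and corrected humidity differences.

Two humidity probes never read identically (the DHT-22 is rated to
about +/-5 %RH between units), so each day x replicate includes
probe-control periods in which the focal probe sits next to the
background probe. Regressing the background readings on the paired
focal readings over those periods gives an affine correction

    f_corrected = W * f_uncorrected + M

which maps focal readings onto the background probe's scale. The
humidity elevation at a sampling point is then the per-period mean of

    dRH = f_corrected - f_background

over simultaneously paired readings.

Pairing is by nearest timestamp within a tolerance (default: half the
median sampling interval); the probes log on their own clocks and are
only nominally simultaneous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import MeasurementPeriod


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationFit:
    """Affine probe correction for one day x replicate."""

    W: float
    M: float
    day_id: str
    replicate: int
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise CalibrationError("calibration needs >= 3 paired readings")
        if not np.isfinite(self.W) or self.W == 0:
            raise CalibrationError(f"degenerate slope W={self.W!r}")

    def correct(self, focal_rh: np.ndarray | float) -> np.ndarray | float:
        return self.W * focal_rh + self.M


@dataclass(frozen=True)
class DeltaRHRecord:
    """Mean corrected focal-minus-background humidity for one period."""

    flower_id: str
    species_id: str
    replicate: int
    axis: str
    offset: float | None
    delta_rh: float
    within_period_sd: float
    n_readings: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_rh):
            raise ValueError("delta_rh must be finite")
        if self.within_period_sd < 0:
            raise ValueError("within_period_sd must be >= 0")


def pair_readings(
    focal_t: np.ndarray,
    focal_rh: np.ndarray,
    bg_t: np.ndarray,
    bg_rh: np.ndarray,
    tolerance: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Match focal readings to the nearest-in-time background reading.

    Returns (paired_focal, paired_background). Focal readings with no
    background reading within ``tolerance`` seconds are dropped. The
    default tolerance is half the median background sampling interval
    (or 1 s for degenerate series).
    """
    if len(focal_t) == 0 or len(bg_t) == 0:
        return np.empty(0), np.empty(0)
    order = np.argsort(bg_t)
    bg_t, bg_rh = bg_t[order], bg_rh[order]
    if tolerance is None:
        tolerance = (
            float(np.median(np.diff(bg_t))) / 2.0 if len(bg_t) > 1 else 1.0
        )
    idx = np.searchsorted(bg_t, focal_t)
    idx_lo = np.clip(idx - 1, 0, len(bg_t) - 1)
    idx_hi = np.clip(idx, 0, len(bg_t) - 1)
    pick = np.where(
        np.abs(bg_t[idx_hi] - focal_t) <= np.abs(bg_t[idx_lo] - focal_t),
        idx_hi,
        idx_lo,
    )
    ok = np.abs(bg_t[pick] - focal_t) <= tolerance
    return focal_rh[ok], bg_rh[pick[ok]]


def fit_probe_calibration(
    probe_control_periods: Sequence[MeasurementPeriod],
    pairing_tolerance: float | None = None,
    direction: str = "background_on_focal",
) -> CalibrationFit:
    """OLS fit of the probe correction from pooled probe-control periods.

    All periods must share one day and one replicate. The default
    regresses background readings on focal readings, so the corrected
    focal value is the predicted background-scale value and the
    self-calibrated probe-control dRH has mean ~0 by construction.
    ``direction="focal_on_background"`` fits the reverse regression and
    inverts it, for sensitivity checks.
    """
    if not probe_control_periods:
        raise CalibrationError("no probe-control periods supplied")
    days = {p.day_id for p in probe_control_periods}
    reps = {p.replicate for p in probe_control_periods}
    if len(days) != 1 or len(reps) != 1:
        raise CalibrationError(
            f"probe-control periods span days {days} and replicates {reps}; "
            "calibration is fitted per day x replicate"
        )
    if direction not in ("background_on_focal", "focal_on_background"):
        raise CalibrationError(f"unknown regression direction {direction!r}")
    xs, ys = [], []
    for p in probe_control_periods:
        if p.axis != "probe_control":
            raise CalibrationError(f"period {p.key} is not a probe control")
        ft, frh = p.focal_arrays()
        bt, brh = p.background_arrays()
        f, b = pair_readings(ft, frh, bt, brh, pairing_tolerance)
        xs.append(f)
        ys.append(b)
    focal = np.concatenate(xs)
    background = np.concatenate(ys)
    if len(focal) < 3:
        raise CalibrationError(
            f"only {len(focal)} paired readings; >= 3 required"
        )
    if np.ptp(focal) == 0 or np.ptp(background) == 0:
        which = "focal" if np.ptp(focal) == 0 else "background"
        raise CalibrationError(
            f"degenerate {which} readings (zero variance) in probe controls "
            f"for day {days.pop()!r}"
        )
    if direction == "background_on_focal":
        slope, intercept = np.polyfit(focal, background, 1)
        pred = slope * focal + intercept
        ss_res = float(np.sum((background - pred) ** 2))
        ss_tot = float(np.sum((background - background.mean()) ** 2))
    else:
        s, m = np.polyfit(background, focal, 1)
        slope, intercept = 1.0 / s, -m / s
        pred = s * background + m
        ss_res = float(np.sum((focal - pred) ** 2))
        ss_tot = float(np.sum((focal - focal.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    p0 = probe_control_periods[0]
    return CalibrationFit(
        W=float(slope),
        M=float(intercept),
        day_id=p0.day_id,
        replicate=p0.replicate,
        n_points=int(len(focal)),
        r_squared=r2,
    )


def apply_calibration(
    period: MeasurementPeriod, fit: CalibrationFit
) -> np.ndarray:
    """Return the period's measurement-window focal readings, corrected.

    Refuses day/replicate mismatches: a correction fitted on another
    day's probe controls must never be applied silently.
    """
    if (period.day_id, period.replicate) != (fit.day_id, fit.replicate):
        raise CalibrationError(
            f"calibration for day {fit.day_id!r} replicate {fit.replicate} "
            f"applied to period from day {period.day_id!r} replicate "
            f"{period.replicate}"
        )
    _, frh = period.focal_arrays()
    return fit.correct(frh)


def compute_delta_rh(
    period: MeasurementPeriod,
    fit: CalibrationFit,
    pairing_tolerance: float | None = None,
) -> DeltaRHRecord:
    """Per-period mean and SD of corrected focal minus paired background."""
    diffs = paired_differences(period, fit, pairing_tolerance)
    if len(diffs) == 0:
        raise CalibrationError(f"no paired readings in period {period.key}")
    return DeltaRHRecord(
        flower_id=period.flower_id,
        species_id=period.species_id,
        replicate=period.replicate,
        axis=period.axis,
        offset=period.offset,
        delta_rh=float(np.mean(diffs)),
        within_period_sd=float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0,
        n_readings=int(len(diffs)),
    )


def paired_differences(
    period: MeasurementPeriod,
    fit: CalibrationFit,
    pairing_tolerance: float | None = None,
) -> np.ndarray:
    """Individual corrected focal-minus-background differences (for QC)."""
    if (period.day_id, period.replicate) != (fit.day_id, fit.replicate):
        raise CalibrationError(
            f"calibration/period day-replicate mismatch for {period.key}"
        )
    ft, frh = period.focal_arrays()
    bt, brh = period.background_arrays()
    f, b = pair_readings(ft, frh, bt, brh, pairing_tolerance)
    return fit.correct(f) - b


def delta_rh_records(
    periods: Iterable[MeasurementPeriod],
    fits: dict[tuple[str, int], CalibrationFit],
    pairing_tolerance: float | None = None,
) -> list[DeltaRHRecord]:
    """Apply per-(day, replicate) calibrations across transect periods."""
    out = []
    for p in periods:
        if p.axis == "probe_control" or not p.is_usable:
            continue
        key = (p.day_id, p.replicate)
        if key not in fits:
            raise CalibrationError(f"no calibration for day x replicate {key}")
        out.append(compute_delta_rh(p, fits[key], pairing_tolerance))
    return out


def fit_all_calibrations(
    periods: Iterable[MeasurementPeriod],
    pairing_tolerance: float | None = None,
    direction: str = "background_on_focal",
) -> dict[tuple[str, int], CalibrationFit]:
    """Group probe-control periods by (day, replicate) and fit each."""
    groups: dict[tuple[str, int], list[MeasurementPeriod]] = {}
    for p in periods:
        if p.axis == "probe_control" and p.is_usable:
            groups.setdefault((p.day_id, p.replicate), []).append(p)
    return {
        key: fit_probe_calibration(ps, pairing_tolerance, direction)
        for key, ps in sorted(groups.items())
    }
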