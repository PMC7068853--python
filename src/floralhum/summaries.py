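"""Peak humidity summaries and control-threshold classification.

The intensity of a species' floral humidity is summarized by the peak
of the best-fitting x-axis model's mean curve. On replicate t the curve
is I + i_t + (A + a_t) X + (B + b_t) X^2 with the flower random
intercept set to zero, so the peak location is

    X_t_max = -(A + a_t) / (2 (B + b_t))

for quadratic fits with negative curvature, 0 for flat fits (any X
would do), and the sampled boundary +/-30 mm (sign of the slope) for
linear fits. The transect only covers +/-30 mm, so vertices outside
that range are clamped to the boundary and flagged: reporting an
extrapolated peak would overstate what was measured. The summary value
dRH_max is the curve evaluated at X_t_max, maximized over the four
replicate transects (ties resolve to the earliest replicate, closest to
the fresh-cut state).

Classification counts compare species peaks against the water-filled
tube controls: TWL (tube + water + lid, the humidity expected from the
horticultural tube itself) and TW (tube + water, the strongest control
signal), plus an absolute 3 %RH threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpeciesSummaryRow
from .models import FittedModel, SelectionResult

X_RANGE = (-30.0, 30.0)


class SummaryError(ValueError):
    pass


@dataclass(frozen=True)
class PeakEstimate:
    """Per-replicate peak locations and the maximized peak value."""

    x_max_per_replicate: dict[int, float]
    delta_rh_per_replicate: dict[int, float]
    x_max: float
    delta_rh_max: float
    argmax_replicate: int
    boundary_flag: bool


def _replicate_x_max(fit: FittedModel, t: int) -> tuple[float, bool]:
    """Peak location on replicate t; returns (x_max, at_boundary)."""
    icpt, slope, curv = fit.coef_at(t)
    lo, hi = X_RANGE
    spec = fit.spec
    if spec.is_flat:
        return 0.0, False
    if spec.is_linear or curv == 0.0:
        if slope == 0.0:
            return 0.0, False
        return (hi if slope > 0 else lo), False
    if curv < 0.0:
        vertex = -slope / (2.0 * curv)
        if vertex < lo:
            return lo, True
        if vertex > hi:
            return hi, True
        return vertex, False
    # upward-opening quadratic (not observed in practice): the maximum
    # sits at whichever sampled boundary predicts more humidity
    at_lo = icpt + slope * lo + curv * lo * lo
    at_hi = icpt + slope * hi + curv * hi * hi
    return (hi if at_hi >= at_lo else lo), True


def x_max(fit: FittedModel) -> dict[int, float]:
    """Peak x-offset of the fitted mean curve, per replicate transect."""
    if fit.spec.axis != "x":
        raise SummaryError("peak location is defined for x-axis fits only")
    return {t: _replicate_x_max(fit, t)[0] for t in (1, 2, 3, 4)}


def delta_rh_max(fit: FittedModel) -> PeakEstimate:
    """Peak humidity elevation, maximized over replicate transects.

    The per-flower random intercept is set to zero, so this is the
    population-mean peak for the species.
    """
    if fit.spec.axis != "x":
        raise SummaryError("peak value is defined for x-axis fits only")
    locs: dict[int, float] = {}
    vals: dict[int, float] = {}
    boundary = False
    for t in (1, 2, 3, 4):
        xm, at_bound = _replicate_x_max(fit, t)
        icpt, slope, curv = fit.coef_at(t)
        locs[t] = xm
        vals[t] = icpt + slope * xm + curv * xm * xm
        boundary = boundary or at_bound
    # earliest replicate wins ties
    best_t = min(vals, key=lambda t: (-vals[t], t))
    return PeakEstimate(
        x_max_per_replicate=locs,
        delta_rh_per_replicate=vals,
        x_max=locs[best_t],
        delta_rh_max=vals[best_t],
        argmax_replicate=best_t,
        boundary_flag=boundary,
    )


def assemble_species_summary(
    selection_x: SelectionResult,
    selection_z: SelectionResult,
    peak: PeakEstimate,
    metadata: dict,
) -> SpeciesSummaryRow:
    """Build one summary-table row from both axis selections and the peak.

    ``metadata`` supplies at least ``name``; optional keys mirror the
    summary-table columns (is_control, floral_structure, floral_type,
    grown_outside, mean_span, span_source, stomata_pct, stomata_n).
    """
    if selection_x.axis != "x" or selection_z.axis != "z":
        raise SummaryError("selections must cover the x and z axes")
    sx, sz = selection_x.species_id, selection_z.species_id
    if sx is not None and sz is not None and sx != sz:
        raise SummaryError(f"species mismatch between axes: {sx!r} vs {sz!r}")
    name = metadata.get("name") or sx
    if name is None:
        raise SummaryError("no species name available")
    rep = peak.argmax_replicate
    chosen_fit = selection_x.chosen_fit
    has_rep_terms = chosen_fit.spec.has_r or chosen_fit.spec.has_g
    return SpeciesSummaryRow(
        name=str(name),
        is_control=bool(metadata.get("is_control", False)),
        best_x_model=selection_x.chosen,
        best_z_model=selection_z.chosen,
        x_max=peak.x_max,
        delta_rh_max=peak.delta_rh_max,
        floral_structure=metadata.get("floral_structure"),
        floral_type=metadata.get("floral_type"),
        grown_outside=metadata.get("grown_outside"),
        mean_span=metadata.get("mean_span"),
        span_source=metadata.get("span_source"),
        stomata_pct=metadata.get("stomata_pct"),
        stomata_n=metadata.get("stomata_n"),
        comparable_x_models=tuple(selection_x.best_set),
        x_max_replicate=str(rep) if has_rep_terms else None,
    )


def assign_ranks(rows: list[SpeciesSummaryRow]) -> list[SpeciesSummaryRow]:
    """Rank species (controls excluded) by ascending peak humidity."""
    species = sorted(
        (r for r in rows if not r.is_control), key=lambda r: r.delta_rh_max
    )
    for i, row in enumerate(species, start=1):
        row.rank = i
    for row in rows:
        if row.is_control:
            row.rank = None
    return rows


NON_QUADRATIC_X = frozenset({"m0", "m1", "m4", "m5", "m8"})


@dataclass(frozen=True)
class ClassificationReport:
    """Counts of species against control thresholds and structure classes."""

    n_species: int
    twl_threshold: float
    tw_threshold: float
    above_twl: int
    above_tw: int
    above_3pct: int
    x_max_central: int
    x_max_offset_5mm: int
    non_quadratic_x: int

    def as_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "twl_threshold": self.twl_threshold,
            "tw_threshold": self.tw_threshold,
            "above_twl": self.above_twl,
            "above_tw": self.above_tw,
            "above_3pct": self.above_3pct,
            "x_max_central": self.x_max_central,
            "x_max_offset_5mm": self.x_max_offset_5mm,
            "non_quadratic_x": self.non_quadratic_x,
        }


def threshold_counts(rows: list[SpeciesSummaryRow]) -> ClassificationReport:
    """Classify species peaks against control benchmarks.

    Requires the TWL and TW control rows to be present among ``rows``;
    controls are excluded from every count.
    """
    controls = {r.name.split()[0].upper(): r for r in rows if r.is_control}
    twl = controls.get("TWL")
    tw = controls.get("TW")
    if twl is None or tw is None:
        raise SummaryError("classification requires the TWL and TW control rows")
    species = [r for r in rows if not r.is_control]
    return ClassificationReport(
        n_species=len(species),
        twl_threshold=twl.delta_rh_max,
        tw_threshold=tw.delta_rh_max,
        above_twl=sum(r.delta_rh_max > twl.delta_rh_max for r in species),
        above_tw=sum(r.delta_rh_max > tw.delta_rh_max for r in species),
        above_3pct=sum(r.delta_rh_max > 3.0 for r in species),
        x_max_central=sum(r.x_max == 0.0 for r in species),
        x_max_offset_5mm=sum(abs(r.x_max) >= 5.0 for r in species),
        non_quadratic_x=sum(r.best_x_model in NON_QUADRATIC_X for r in species),
    )
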