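"""The humidity-structure model family and AIC selection.

For each species the per-period mean humidity elevations along the
x-axis transect are described by nested linear mixed models built from
a quadratic in the offset X (mm),

    dRH = I + i_t + (A + a_t) X + (B + b_t) X^2 + nu_flower,

and along the z axis by a logarithmic decay in the offset Z (mm),

    dRH = I + i_t + (B + b_t) ln Z + nu_flower,

where t in {1..4} indexes the replicate transect and the replicate
modifiers i_t, a_t, b_t are indicator-coded shifts for t = 2, 3, 4
(replicate 1 is the reference level and its modifiers are identically
zero). nu_flower is a Gaussian random intercept. Eleven x-axis models
(m0-m10) and five z-axis models (z0-z4) arise by omitting terms:

    id    terms                 shape
    m0    I                     flat
    m1    I,A                   linear
    m2    I,B                   quadratic (centred)
    m3    I,A,B                 quadratic with offset
    m4    I,r                   flat + replicate intercepts
    m5    I,A,r                 linear + replicate intercepts
    m6    I,B,r                 quadratic + replicate intercepts
    m7    I,A,B,r               offset quadratic + replicate intercepts
    m8    I,A,r,g               linear, replicate-interacting slope
    m9    I,B,r,c               quadratic, replicate-interacting curvature
    m10   I,A,B,r,g,c           full model
    z0    I                     flat
    z1    I,B                   logarithmic
    z2    I,r                   flat + replicate intercepts
    z3    I,B,r                 logarithmic + replicate intercepts
    z4    I,B,r,c               logarithmic, replicate-interacting slope

(r = replicate intercept shifts r_t; g = replicate slope shifts g_t on
X; c = replicate curvature/log-slope shifts c_t.) All models are fit by
maximum likelihood so AIC, with k = free fixed effects + 2 variance
parameters, is comparable across the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .calibration import DeltaRHRecord
from .lmm import LMMError, LMMFit, fit_random_intercept


class ModelFamilyError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One member of the humidity-structure family."""

    axis: str  # "x" | "z"
    id: str
    has_A: bool  # linear offset term (x axis only)
    has_B: bool  # curvature (x) or log slope (z)
    has_r: bool  # replicate intercept shifts
    has_g: bool  # replicate slope shifts (x only)
    has_c: bool  # replicate curvature / log-slope shifts

    def __post_init__(self) -> None:
        if self.has_g and not self.has_A:
            raise ModelFamilyError(f"{self.id}: g_t requires A")
        if self.has_c and not self.has_B:
            raise ModelFamilyError(f"{self.id}: c_t requires B")
        if self.axis == "z" and (self.has_A or self.has_g):
            raise ModelFamilyError(f"{self.id}: z-axis models have no A term")

    @property
    def is_flat(self) -> bool:
        return not (self.has_A or self.has_B)

    @property
    def is_linear(self) -> bool:
        return self.has_A and not self.has_B

    @property
    def is_quadratic(self) -> bool:
        return self.axis == "x" and self.has_B

    @property
    def column_names(self) -> list[str]:
        names = ["I"]
        if self.has_A:
            names.append("A")
        if self.has_B:
            names.append("B")
        if self.has_r:
            names += ["r2", "r3", "r4"]
        if self.has_g:
            names += ["g2", "g3", "g4"]
        if self.has_c:
            names += ["c2", "c3", "c4"]
        return names


def _mk(axis, mid, terms):
    return ModelSpec(
        axis=axis,
        id=mid,
        has_A="A" in terms,
        has_B="B" in terms,
        has_r="r" in terms,
        has_g="g" in terms,
        has_c="c" in terms,
    )


X_SPECS: dict[str, ModelSpec] = {
    "m0": _mk("x", "m0", ""),
    "m1": _mk("x", "m1", "A"),
    "m2": _mk("x", "m2", "B"),
    "m3": _mk("x", "m3", "AB"),
    "m4": _mk("x", "m4", "r"),
    "m5": _mk("x", "m5", "Ar"),
    "m6": _mk("x", "m6", "Br"),
    "m7": _mk("x", "m7", "ABr"),
    "m8": _mk("x", "m8", "Arg"),
    "m9": _mk("x", "m9", "Brc"),
    "m10": _mk("x", "m10", "ABrgc"),
}

Z_SPECS: dict[str, ModelSpec] = {
    "z0": _mk("z", "z0", ""),
    "z1": _mk("z", "z1", "B"),
    "z2": _mk("z", "z2", "r"),
    "z3": _mk("z", "z3", "Br"),
    "z4": _mk("z", "z4", "Brc"),
}

ALL_SPECS = {**X_SPECS, **Z_SPECS}


def get_spec(model_id: str) -> ModelSpec:
    try:
        return ALL_SPECS[model_id]
    except KeyError:
        raise ModelFamilyError(f"unknown model id {model_id!r}") from None


def build_design(
    spec: ModelSpec,
    offsets: Sequence[float],
    replicates: Sequence[int],
) -> np.ndarray:
    """Fixed-effects design matrix for (offset, replicate) rows.

    x axis: columns I, X, X^2 and indicator interactions; z axis uses
    ln Z in place of X with no quadratic. Replicate 1 is the reference,
    so its indicator columns are all zero.
    """
    offsets = np.asarray(offsets, float)
    replicates = np.asarray(replicates, int)
    if offsets.shape != replicates.shape:
        raise ModelFamilyError("offsets and replicates must align")
    if np.any((replicates < 1) | (replicates > 4)):
        raise ModelFamilyError("replicates must lie in 1..4")
    if spec.axis == "z":
        if np.any(offsets <= 0):
            raise ModelFamilyError("z offsets must be positive for ln Z")
        base = np.log(offsets)
    else:
        base = offsets
    cols = [np.ones_like(base)]
    if spec.has_A:
        cols.append(base)
    if spec.has_B:
        cols.append(base**2 if spec.axis == "x" else base)
    ind = {t: (replicates == t).astype(float) for t in (2, 3, 4)}
    if spec.has_r:
        cols += [ind[2], ind[3], ind[4]]
    if spec.has_g:
        cols += [ind[2] * base, ind[3] * base, ind[4] * base]
    if spec.has_c:
        slope_term = base**2 if spec.axis == "x" else base
        cols += [ind[2] * slope_term, ind[3] * slope_term, ind[4] * slope_term]
    return np.column_stack(cols)


@dataclass
class FittedModel:
    """ML fit of one family member to one species' transect records."""

    spec: ModelSpec
    fixed_effects: dict[str, float]
    sigma2: float
    sigma2_flower: float
    log_likelihood: float
    aic: float
    n_observations: int
    n_flowers: int
    boundary: bool
    single_flower: bool
    lmm: LMMFit = field(repr=False, default=None)

    def effect(self, name: str) -> float:
        return self.fixed_effects.get(name, 0.0)

    def coef_at(self, t: int) -> tuple[float, float, float]:
        """(intercept, slope, curvature) of the mean curve on replicate t.

        For z-axis fits the "slope" multiplies ln Z and curvature is 0.
        """
        if t not in (1, 2, 3, 4):
            raise ModelFamilyError(f"replicate {t} out of range")
        suffix = str(t)
        icpt = self.effect("I") + (self.effect("r" + suffix) if t > 1 else 0.0)
        if self.spec.axis == "x":
            slope = self.effect("A") + (self.effect("g" + suffix) if t > 1 else 0.0)
            curv = self.effect("B") + (self.effect("c" + suffix) if t > 1 else 0.0)
        else:
            slope = self.effect("B") + (self.effect("c" + suffix) if t > 1 else 0.0)
            curv = 0.0
        return icpt, slope, curv

    def predict_mean(self, offsets, replicates) -> np.ndarray:
        """Population mean prediction (random intercept set to zero)."""
        X = build_design(self.spec, offsets, replicates)
        beta = np.array([self.fixed_effects[c] for c in self.spec.column_names])
        return X @ beta


def _records_to_arrays(records: Sequence[DeltaRHRecord], axis: str):
    recs = [r for r in records if r.axis == axis]
    if not recs:
        raise ModelFamilyError(f"no {axis}-axis records supplied")
    y = np.array([r.delta_rh for r in recs])
    off = np.array([r.offset for r in recs], float)
    rep = np.array([r.replicate for r in recs], int)
    flowers = np.array([r.flower_id for r in recs])
    return y, off, rep, flowers


def fit_model(
    spec: ModelSpec, records: Sequence[DeltaRHRecord]
) -> FittedModel:
    """ML fit of one spec to a species' per-period mean humidity records.

    Raises :class:`ModelFamilyError` naming missing replicate levels
    when the spec demands replicate terms the data cannot identify.
    """
    y, off, rep, flowers = _records_to_arrays(records, spec.axis)
    if spec.has_r or spec.has_g or spec.has_c:
        missing = sorted(set((2, 3, 4)) - set(rep.tolist()))
        if missing:
            raise ModelFamilyError(
                f"{spec.id} needs replicate levels {missing} absent from data"
            )
    X = build_design(spec, off, rep)
    try:
        fit = fit_random_intercept(y, X, flowers, spec.column_names)
    except LMMError as exc:
        raise ModelFamilyError(f"{spec.id}: {exc}") from exc
    effects = dict(zip(spec.column_names, fit.beta))
    return FittedModel(
        spec=spec,
        fixed_effects=effects,
        sigma2=fit.sigma2,
        sigma2_flower=fit.sigma2_group,
        log_likelihood=fit.log_likelihood,
        aic=fit.aic,
        n_observations=fit.n_obs,
        n_flowers=fit.n_groups,
        boundary=fit.boundary,
        single_flower=fit.single_group,
        lmm=fit,
    )


@dataclass
class SelectionResult:
    """AIC table over one axis' model family for one species."""

    axis: str
    table: list[dict]  # id, k, log_likelihood, aic, delta_aic, failed, error
    best_set: list[str]
    chosen: str
    fits: dict[str, FittedModel]
    comparability_threshold: float
    species_id: str | None = None

    @property
    def chosen_fit(self) -> FittedModel:
        return self.fits[self.chosen]


def select_best(
    records: Sequence[DeltaRHRecord],
    axis: str,
    comparability_threshold: float = 2.0,
) -> SelectionResult:
    """Fit every family member on one axis and select by AIC.

    The comparable best set contains every spec within
    ``comparability_threshold`` AIC units of the minimum; summary values
    downstream use the single lowest-AIC member. Exact AIC ties break
    toward fewer parameters. Specs that fail to fit stay in the table
    with a failure flag.
    """
    if axis not in ("x", "z"):
        raise ModelFamilyError(f"axis must be 'x' or 'z', got {axis!r}")
    species = sorted({r.species_id for r in records if r.axis == axis})
    if len(species) > 1:
        raise ModelFamilyError(
            f"records mix species {species}; fit one species at a time"
        )
    specs = X_SPECS if axis == "x" else Z_SPECS
    fits: dict[str, FittedModel] = {}
    rows: list[dict] = []
    for mid, spec in specs.items():
        row = {"id": mid, "k": len(spec.column_names) + 2,
               "log_likelihood": np.nan, "aic": np.nan, "delta_aic": np.nan,
               "failed": False, "error": ""}
        try:
            fit = fit_model(spec, records)
        except ModelFamilyError as exc:
            row["failed"] = True
            row["error"] = str(exc)
        else:
            fits[mid] = fit
            row["log_likelihood"] = fit.log_likelihood
            row["aic"] = fit.aic
        rows.append(row)
    if not fits:
        raise ModelFamilyError(f"every {axis}-axis model failed to fit")
    # ties break toward fewer parameters (k), then family order
    order = sorted(
        fits, key=lambda m: (round(fits[m].aic, 10), len(ALL_SPECS[m].column_names))
    )
    chosen = order[0]
    best_aic = fits[chosen].aic
    for row in rows:
        if not row["failed"]:
            row["delta_aic"] = row["aic"] - best_aic
    best_set = [m for m in fits if fits[m].aic - best_aic <= comparability_threshold]
    return SelectionResult(
        axis=axis,
        table=rows,
        best_set=best_set,
        chosen=chosen,
        fits=fits,
        comparability_threshold=comparability_threshold,
        species_id=species[0] if species else None,
    )


def aic_table_frame(result: SelectionResult):
    """Selection table as a DataFrame (CSV export mirrors it)."""
    import pandas as pd

    return pd.DataFrame(result.table)


def fit_both_axes(
    records: Iterable[DeltaRHRecord],
    comparability_threshold: float = 2.0,
) -> tuple[SelectionResult, SelectionResult]:
    records = list(records)
    return (
        select_best(records, "x", comparability_threshold),
        select_best(records, "z", comparability_threshold),
    )
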