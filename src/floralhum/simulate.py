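"""Synthetic survey data with known ground truth.

Two tiers of generator mirror the two scales of the pipeline:

* :func:`generate_transect_dataset` emits a full probe log — paired
  focal/background reading time series for every flower x replicate x
  offset stop plus per-replicate probe-control stops — so ingest,
  calibration, pairing and QC are all exercised. Background humidity is
  a level plus a slow sinusoidal drift plus white noise; the focal
  probe sees background plus the model-family mean curve plus a
  per-flower intercept; the *recorded* focal value is distorted by a
  known miscalibration (W, M) chosen so that the fitted correction
  recovers the truth.

* :func:`generate_delta_rh_records` emits per-period mean humidity
  records directly from the model-family mean structure, for cheap
  large-scale model-selection and recovery simulations.

:func:`generate_phylo_dataset` builds a random birth-death tree and
draws a multivariate-normal response with phylogenetic covariance for
the comparative stage.

Defaults emulate the survey conditions: background 49.1 %RH, four
replicate transects, 13 x-offsets and 6 z-offsets, ~100 readings per
200 s measurement period on a jittered 2 s cadence, reading noise
0.2 %RH, drift amplitude 0.5 %RH over a day.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .calibration import DeltaRHRecord
from .io import (
    MEASUREMENT_S,
    SETTLING_S,
    X_OFFSETS,
    Z_OFFSETS,
    MeasurementPeriod,
    ProbeReading,
)
from .models import build_design, get_spec


class SimulationError(ValueError):
    pass


def truth_mean(
    model_id: str, params: dict[str, float], offsets, replicates
) -> np.ndarray:
    """Mean humidity elevation of a family member at given design points."""
    spec = get_spec(model_id)
    names = spec.column_names
    unknown = set(params) - set(names)
    if unknown:
        raise SimulationError(
            f"parameters {sorted(unknown)} not in model {model_id} ({names})"
        )
    beta = np.array([params.get(n, 0.0) for n in names])
    return build_design(spec, offsets, replicates) @ beta


def analytic_peak(model_id: str, params: dict[str, float]) -> tuple[float, float]:
    """(x_max, dRH_max) implied by an x-axis truth, maximized over replicates."""
    spec = get_spec(model_id)
    if spec.axis != "x":
        raise SimulationError("analytic peak is defined for x-axis truths")
    best = (-np.inf, 0.0)
    for t in (1, 2, 3, 4):
        suf = str(t)
        icpt = params.get("I", 0.0) + (params.get("r" + suf, 0.0) if t > 1 else 0.0)
        slope = params.get("A", 0.0) + (params.get("g" + suf, 0.0) if t > 1 else 0.0)
        curv = params.get("B", 0.0) + (params.get("c" + suf, 0.0) if t > 1 else 0.0)
        if curv < 0:
            xm = float(np.clip(-slope / (2 * curv), -30.0, 30.0))
        elif slope != 0:
            xm = 30.0 if slope > 0 else -30.0
        else:
            xm = 0.0
        val = icpt + slope * xm + curv * xm * xm
        if val > best[0]:
            best = (val, xm)
    return best[1], best[0]


@dataclass
class GroundTruth:
    """Everything the transect generator needs, and tests recover."""

    x_model: str = "m2"
    x_params: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0, "B": -0.002}
    )
    z_model: str = "z1"
    z_params: dict[str, float] = field(
        default_factory=lambda: {"I": 1.2, "B": -0.35}
    )
    flower_sd: float = 0.1  # sd of the per-flower intercept, %RH
    # Per-reading instrument noise. The DHT-22's headline +/-5 %RH is
    # unit-to-unit bias (absorbed by the W, M correction); its
    # reading-to-reading repeatability sits on the 0.1 %RH resolution
    # scale, which is what white noise here represents.
    reading_sd: float = 0.1
    # Period-to-period variation of the floral humidity elevation itself
    # (airflow and biology differ between stops); this, not instrument
    # noise, dominates the residual scatter of per-period means.
    period_sd: float = 0.05
    background_level: float = 49.1
    # Slow background swing over a day. The surveyed room's background
    # humidity varied by several %RH around its mean across sampling;
    # this between-period variation also helps identify the pooled
    # per-replicate calibration regression.
    drift_amplitude: float = 2.0
    drift_period_s: float = 86400.0
    # Smooth room-air fluctuation (HVAC-like), common to both probes.
    # The shared variation within a 200 s stop identifies the probe
    # calibration slope even within single probe-control periods: with
    # a perfectly constant room the regression would be degenerate.
    fluctuation_amplitudes: tuple[float, ...] = (1.2, 0.9, 0.6)
    fluctuation_periods_s: tuple[float, ...] = (120.0, 300.0, 900.0)
    calibration_w: float = 0.95  # true probe slope (focal scale vs background)
    calibration_m: float = 2.0  # true probe offset, %RH

    def __post_init__(self) -> None:
        if self.flower_sd < 0 or self.reading_sd < 0:
            raise SimulationError("noise scales must be >= 0")
        get_spec(self.x_model)
        get_spec(self.z_model)
        if get_spec(self.x_model).axis != "x" or get_spec(self.z_model).axis != "z":
            raise SimulationError("truth model ids must match their axes")
        if self.calibration_w == 0:
            raise SimulationError("calibration slope must be nonzero")


def _timestamps(rng: np.random.Generator, cadence: float = 2.0,
                jitter: float = 0.2) -> np.ndarray:
    """Jittered sampling clock over one 230 s stop (settling included)."""
    base = np.arange(0.0, SETTLING_S + MEASUREMENT_S + 1e-9, cadence)
    t = base + rng.uniform(-jitter, jitter, len(base))
    return np.clip(t, 0.0, SETTLING_S + MEASUREMENT_S)


def _room_humidity(truth: GroundTruth, t_abs: np.ndarray,
                   phases: np.ndarray) -> np.ndarray:
    """Shared room humidity: level + daily drift + smooth fluctuation.

    Smoothness matters: both probes sample the same process at slightly
    different instants, so nearest-timestamp pairing must see nearly
    identical room values.
    """
    h = truth.background_level + truth.drift_amplitude * np.sin(
        2 * np.pi * t_abs / truth.drift_period_s
    )
    for a, p, phi in zip(truth.fluctuation_amplitudes,
                         truth.fluctuation_periods_s, phases):
        h = h + a * np.sin(2 * np.pi * t_abs / p + phi)
    return h


def generate_transect_dataset(
    truth: GroundTruth,
    n_flowers: int = 6,
    n_replicates: int = 4,
    seed: int | None = None,
    n_readings_cadence: float = 2.0,
    species_id: str = "synthetic",
    day_id: str = "day1",
) -> list[MeasurementPeriod]:
    """Simulate a full probe log for one species sampled on one day.

    Each flower x replicate visits all 13 x-offsets, all 6 z-offsets
    and ends with one probe-control stop per replicate. Readings are
    fully reproducible from ``seed``.
    """
    if not 1 <= n_replicates <= 4:
        raise SimulationError("n_replicates must be 1..4 for faithful emulation")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, len(truth.fluctuation_amplitudes))
    nu_x = rng.normal(0, truth.flower_sd, n_flowers)
    nu_z = rng.normal(0, truth.flower_sd, n_flowers)
    periods: list[MeasurementPeriod] = []
    clock = 0.0  # absolute seconds since the day's first stop
    stride = SETTLING_S + MEASUREMENT_S + 10.0  # travel time between stops

    pc_count = 0

    def emit(flower_i, rep, axis, offset, mean_elev):
        nonlocal clock, pc_count
        t = _timestamps(rng, n_readings_cadence)
        bg_rh = _room_humidity(truth, clock + t, phases) + rng.normal(
            0, truth.reading_sd, len(t)
        )
        t_f = _timestamps(rng, n_readings_cadence)
        elev = mean_elev
        if axis != "probe_control":
            elev = elev + rng.normal(0, truth.period_sd)
        focal_true = (
            _room_humidity(truth, clock + t_f, phases)
            + elev
            + rng.normal(0, truth.reading_sd, len(t_f))
        )
        focal_recorded = (focal_true - truth.calibration_m) / truth.calibration_w
        if flower_i is not None:
            flower = f"f{flower_i + 1}"
        else:
            pc_count += 1
            flower = f"pc{pc_count}"
        period = MeasurementPeriod(
            day_id=day_id,
            flower_id=flower,
            species_id=species_id if flower_i is not None else "probe_control",
            replicate=rep,
            axis=axis,
            offset=offset,
        )
        period.focal_readings = [
            ProbeReading(float(ts), float(np.clip(rh, 0, 100)), "focal")
            for ts, rh in zip(t_f, focal_recorded)
        ]
        period.background_readings = [
            ProbeReading(float(ts), float(np.clip(rh, 0, 100)), "background")
            for ts, rh in zip(t, bg_rh)
        ]
        periods.append(period)
        clock += stride

    # The robot visits each flower's x then z transect, then parks beside
    # the background probe for a probe-control stop, before the next
    # flower; the whole sequence repeats per replicate.
    for rep in range(1, n_replicates + 1):
        for fi in range(n_flowers):
            for off in X_OFFSETS:
                mean = float(
                    truth_mean(truth.x_model, truth.x_params, [off], [rep])[0]
                ) + nu_x[fi]
                emit(fi, rep, "x", float(off), mean)
            for off in Z_OFFSETS:
                mean = float(
                    truth_mean(truth.z_model, truth.z_params, [off], [rep])[0]
                ) + nu_z[fi]
                emit(fi, rep, "z", float(off), mean)
            emit(None, rep, "probe_control", None, 0.0)
    return periods


def generate_delta_rh_records(
    model_id: str,
    params: dict[str, float],
    n_flowers: int = 6,
    replicates: tuple[int, ...] = (1, 2, 3, 4),
    flower_sd: float = 0.1,
    resid_sd: float = 0.05,
    seed: int | None = None,
    species_id: str = "synthetic",
) -> list[DeltaRHRecord]:
    """Per-period mean humidity records straight from a family truth.

    The residual sd is the noise on period *means* (reading noise in a
    real run averages down by ~1/sqrt(100) within a period).
    """
    spec = get_spec(model_id)
    offsets = X_OFFSETS if spec.axis == "x" else Z_OFFSETS
    rng = np.random.default_rng(seed)
    nu = rng.normal(0, flower_sd, n_flowers)
    records = []
    for fi in range(n_flowers):
        for rep in replicates:
            means = truth_mean(model_id, params, offsets, [rep] * len(offsets))
            noise = rng.normal(0, resid_sd, len(offsets))
            for off, m, e in zip(offsets, means, noise):
                records.append(
                    DeltaRHRecord(
                        flower_id=f"f{fi + 1}",
                        species_id=species_id,
                        replicate=rep,
                        axis=spec.axis,
                        offset=float(off),
                        delta_rh=float(m + nu[fi] + e),
                        within_period_sd=resid_sd,
                        n_readings=100,
                    )
                )
    return records


def generate_phylo_dataset(
    n_species: int,
    beta: dict[str, float] | None = None,
    correlation_model: str = "BM",
    alpha: float | None = None,
    sigma2: float = 0.5,
    seed: int | None = None,
    birth_rate: float = 1.0,
    death_rate: float = 0.3,
) -> tuple[dendropy.Tree, pd.DataFrame, dict]:
    """Random tree plus a phylogenetically correlated trait table.

    ``beta`` maps {"intercept", "span", "floral_type", "grown_outside"}
    to true coefficients on the log-response scale. Span is log-normal
    (median ~35 mm), binaries Bernoulli(0.5). Returns (tree, prepared
    trait table with a ``response`` column, truth dict).
    """
    from dendropy.model import birthdeath

    from .phylo import PhyloError, build_correlation

    if n_species < 10:
        raise SimulationError("n_species must be >= 10")
    beta = dict(beta or {})
    defaults = {"intercept": 0.0, "span": 0.0, "floral_type": 0.0,
                "grown_outside": 0.0}
    unknown = set(beta) - set(defaults)
    if unknown:
        raise SimulationError(f"unknown coefficients {sorted(unknown)}")
    defaults.update(beta)
    rng = np.random.default_rng(seed)
    pyrng = random.Random(int(rng.integers(2**31)))
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_species,
        rng=pyrng,
    )
    # the birth-death process stops at the n-th speciation, which leaves
    # a zero-length cherry; extend every tip so extant species are
    # genuinely distinct (keeps the tree ultrametric)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(lf.root_distance for lf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.05 * height
    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = label
    try:
        corr, order = build_correlation(tree, correlation_model, alpha,
                                        taxa=labels)
    except PhyloError as exc:
        raise SimulationError(str(exc)) from exc
    span = rng.lognormal(mean=np.log(35.0), sigma=0.4, size=n_species)
    floral_type = rng.integers(0, 2, n_species)
    grown_outside = rng.integers(0, 2, n_species)
    X = np.column_stack([np.ones(n_species), span, floral_type, grown_outside])
    b = np.array([defaults["intercept"], defaults["span"],
                  defaults["floral_type"], defaults["grown_outside"]])
    try:
        L = np.linalg.cholesky(sigma2 * corr)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(sigma2 * corr + 1e-10 * np.eye(n_species))
    response = X @ b + L @ rng.standard_normal(n_species)
    table = pd.DataFrame({
        "species": order,
        "response": response,
        "span": span,
        "floral_type": floral_type,
        "grown_outside": grown_outside,
    })
    truth = {"beta": defaults, "sigma2": sigma2,
             "correlation_model": correlation_model, "alpha": alpha}
    return tree, table, truth
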