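import numpy as np
import pytest

from floralhum import calibration as cal
from floralhum import io as fio
from floralhum import simulate


@pytest.fixture(scope="session")
def species_rows():
    return fio.load_species_summary()


@pytest.fixture(scope="session")
def default_truth():
    return simulate.GroundTruth()


@pytest.fixture(scope="session")
def small_transect(default_truth):
    """One small simulated day: 2 flowers x 4 replicates."""
    return simulate.generate_transect_dataset(
        default_truth, n_flowers=2, n_replicates=4, seed=11
    )


def make_probe_control(
    focal_rh,
    background_rh,
    day="d1",
    replicate=1,
    t0=30.0,
    dt=2.0,
):
    """Build a probe-control period from paired reading values."""
    p = fio.MeasurementPeriod(
        day_id=day,
        flower_id="pc1",
        species_id="probe_control",
        replicate=replicate,
        axis="probe_control",
        offset=None,
    )
    for i, (f, b) in enumerate(zip(focal_rh, background_rh)):
        ts = t0 + i * dt
        p.focal_readings.append(fio.ProbeReading(ts, float(f), "focal"))
        p.background_readings.append(
            fio.ProbeReading(ts, float(b), "background")
        )
    return p


def make_transect_period(
    focal_rh,
    background_rh,
    offset=0.0,
    axis="x",
    day="d1",
    replicate=1,
    flower="f1",
    species="sp",
):
    p = fio.MeasurementPeriod(
        day_id=day,
        flower_id=flower,
        species_id=species,
        replicate=replicate,
        axis=axis,
        offset=offset,
    )
    for i, (f, b) in enumerate(zip(focal_rh, background_rh)):
        ts = 30.0 + i * 2.0
        p.focal_readings.append(fio.ProbeReading(ts, float(f), "focal"))
        p.background_readings.append(
            fio.ProbeReading(ts, float(b), "background")
        )
    return p


@pytest.fixture()
def identity_fit():
    return cal.CalibrationFit(
        W=1.0, M=0.0, day_id="d1", replicate=1, n_points=100, r_squared=1.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
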