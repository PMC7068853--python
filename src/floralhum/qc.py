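"""Measurement quality control: repeatability and turbulence checks.

Two diagnostics validate the robot transect protocol:

* **Repeatability** (intraclass correlation) of the ~100 humidity
  difference readings within each 200 s measurement period. R is the
  between-period share of total variance from a one-way Gaussian
  random-effects decomposition, with a parametric-bootstrap interval
  (default 100 refits). High R justifies collapsing each period to its
  mean before model fitting.

* **Turbulence**: probe motion may leave residual air disturbance after
  the 30 s settling time. The mean focal humidity over the first and
  last 20 s of each period is compared; the non-directional change
  f_change (default |f_first - f_last|; the squared difference is
  available by configuration) is regressed on the period mean focal
  humidity f_mean to test whether wetter air is more disturbed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .io import MeasurementPeriod
from .lmm import fit_random_intercept


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    se: float
    ci_low: float
    ci_high: float
    n_groups: int
    n_bootstrap: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"R out of [0, 1]: {self.R}")


def _icc_point(values: np.ndarray, codes: np.ndarray) -> tuple[float, float, float]:
    # zero within-group variance: all residual structure is between
    # groups and R = 1 exactly (the profile optimum sits at lam = inf)
    means = np.bincount(codes, weights=values) / np.bincount(codes)
    if np.allclose(values, means[codes], rtol=0, atol=0):
        return 1.0, float(np.var(means, ddof=1)), 0.0
    fit = fit_random_intercept(values, np.ones((len(values), 1)), codes)
    total = fit.sigma2 + fit.sigma2_group
    return fit.sigma2_group / total, fit.sigma2_group, fit.sigma2


def repeatability(
    values: Sequence[float],
    groups: Sequence,
    n_bootstrap: int = 100,
    seed: int | None = None,
) -> RepeatabilityResult:
    """Intraclass correlation of readings grouped by measurement period.

    ``values`` are individual humidity-difference readings and
    ``groups`` their period labels. Requires >= 2 groups with >= 2
    readings each and nonzero total variance. The CI is the 2.5/97.5
    percentile of ``n_bootstrap`` parametric-bootstrap refits (data
    simulated from the fitted variance components), the SE their
    standard deviation.
    """
    values = np.asarray(values, float)
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    sizes = np.bincount(codes)
    if len(sizes) < 2:
        raise QCError("repeatability needs >= 2 measurement periods")
    if sizes.min() < 2:
        raise QCError("every measurement period needs >= 2 readings")
    if np.var(values) == 0:
        raise QCError("zero total variance: repeatability undefined")
    r_hat, s2_g, s2 = _icc_point(values, codes)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    g = len(sizes)
    for b in range(n_bootstrap):
        u = rng.normal(0.0, np.sqrt(s2_g), g)
        sim = u[codes] + rng.normal(0.0, np.sqrt(s2), len(values))
        boots[b], _, _ = _icc_point(sim, codes)
    return RepeatabilityResult(
        R=float(r_hat),
        se=float(np.std(boots, ddof=1)) if n_bootstrap > 1 else float("nan"),
        ci_low=float(min(np.percentile(boots, 2.5), r_hat)),
        ci_high=float(max(np.percentile(boots, 97.5), r_hat)),
        n_groups=int(g),
        n_bootstrap=int(n_bootstrap),
    )


@dataclass(frozen=True)
class TurbulenceRecord:
    """Start-vs-end focal humidity change for one measurement period."""

    f_first: float
    f_last: float
    f_mean: float
    f_change: float
    flagged: bool = False


def turbulence_change(
    period: MeasurementPeriod,
    window_s: float = 20.0,
    convention: str = "absolute",
) -> TurbulenceRecord:
    """Non-directional focal humidity change over one measurement period.

    Uses uncorrected focal readings, comparing the mean over the first
    and last ``window_s`` seconds of the 200 s measurement window.
    ``convention`` is ``"absolute"`` (|f_first - f_last|, the default
    magnitude scale) or ``"squared"``. Periods with no readings in
    either window come back flagged rather than raising.
    """
    if convention not in ("absolute", "squared"):
        raise QCError(f"unknown turbulence convention {convention!r}")
    t, rh = period.focal_arrays()
    if len(t) == 0:
        raise QCError(f"period {period.key} has no focal readings")
    t0 = period.settling_s
    t1 = t.max()
    if t1 - t0 < 2 * window_s:
        raise QCError(
            f"period {period.key} spans {t1 - t0:.0f} s; "
            f">= {2 * window_s:.0f} s required"
        )
    first = rh[t <= t0 + window_s]
    last = rh[t >= t1 - window_s]
    flagged = len(first) < 2 or len(last) < 2
    f_first = float(first.mean()) if len(first) else float("nan")
    f_last = float(last.mean()) if len(last) else float("nan")
    diff = f_first - f_last
    f_change = abs(diff) if convention == "absolute" else diff**2
    return TurbulenceRecord(
        f_first=f_first,
        f_last=f_last,
        f_mean=float(rh.mean()),
        f_change=float(f_change),
        flagged=bool(flagged),
    )


@dataclass(frozen=True)
class TurbulenceRegression:
    """OLS of f_change on f_mean, reported per parameter."""

    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    df_resid: int
    n: int


def turbulence_regression(
    records: Sequence[TurbulenceRecord],
) -> TurbulenceRegression:
    """Fit and report the turbulence linear model over all periods."""
    usable = [r for r in records if not r.flagged]
    if len(usable) < 3:
        raise QCError(f"need >= 3 usable turbulence records, got {len(usable)}")
    f_mean = np.array([r.f_mean for r in usable])
    f_change = np.array([r.f_change for r in usable])
    if np.ptp(f_mean) == 0:
        raise QCError("zero variance in f_mean: slope unidentifiable")
    X = sm.add_constant(f_mean)
    res = sm.OLS(f_change, X).fit()
    names = ["intercept", "f_mean"]
    ci = res.conf_int()
    return TurbulenceRegression(
        params=dict(zip(names, res.params)),
        bse=dict(zip(names, res.bse)),
        tvalues=dict(zip(names, res.tvalues)),
        pvalues=dict(zip(names, res.pvalues)),
        conf_int={n: (float(ci[i][0]), float(ci[i][1])) for i, n in enumerate(names)},
        df_resid=int(res.df_resid),
        n=int(res.nobs),
    )
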