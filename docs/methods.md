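# Methods

`floralhum` analyses robot-arm humidity transects over cut flowers: a
focal probe is stepped along a horizontal (x) transect, −30 to +30 mm
in 5 mm steps through the point 5 mm above the flower's centre, then a
vertical (z) transect, 5 to 30 mm above it, while a background probe
logs the room. Each stop lasts 230 s — a 30 s settling time, then a
200 s measurement period of roughly 100 readings per probe. The whole
sequence repeats four times per flower (replicate transects t = 1..4),
and after each flower the focal probe parks next to the background
probe for a probe-control stop.

## Probe cross-calibration

Capacitive humidity probes disagree unit-to-unit by up to ±5 %RH, so
focal readings are mapped onto the background probe's scale with an
affine correction f_corrected = W·f_uncorrected + M. W and M come from
an OLS regression of background on focal readings, paired by nearest
timestamp, pooled over all probe-control periods of one day ×
replicate. Fitting background-on-focal (rather than the reverse) makes
the self-calibrated probe-control differences average exactly zero —
the residual-sum identity of OLS; the reverse direction is available
behind `direction="focal_on_background"` for sensitivity analysis.
Pairing tolerance defaults to half the median background sampling
interval. Note the estimator inherits OLS errors-in-variables
attenuation: W is biased toward zero by the ratio of instrument-noise
variance to genuine shared humidity variance during the probe-control
stops. With per-reading noise near 0.1 %RH and room variation of a few
%RH the bias is a fraction of a percent; it is visible in simulations
with noisy probes and a very still room.

The humidity elevation at a stop is ΔRH = f_corrected − f_background,
averaged over the paired readings of the measurement period; these
per-period means are the responses for all structure modelling.

## Quality control

* **Repeatability** R is the intraclass correlation of individual ΔRH
  readings grouped by measurement period, from a one-way Gaussian
  random-effects decomposition fit by ML: R = σ²_between/(σ²_between +
  σ²_within). The confidence interval is a parametric bootstrap
  (default 100 refits, seedable); data with exactly zero within-period
  variance return R = 1. R is invariant to shifting or rescaling all
  readings.
* **Turbulence**: for each period, f_first and f_last are the mean
  focal readings over the first and last 20 s of the measurement
  window; the non-directional change f_change = |f_first − f_last| by
  default (the squared form is one configuration flag away — the two
  agree as evidence, differing only in scale) is regressed on the
  period mean f_mean by OLS to check whether residual probe-motion
  turbulence scales with how humid the sampled air is.

## The humidity-structure model family

Per-period mean ΔRH for one species is modelled as a linear mixed
model with a Gaussian random intercept per flower. The x-axis family
is built from ΔRH = I + i_t + (A + a_t)X + (B + b_t)X², the z-axis
family from ΔRH = I + i_t + (B + b_t)·ln Z, with replicate modifiers
indicator-coded for t = 2, 3, 4 (replicate 1 is the reference, so its
modifiers are structurally zero). Omitting terms yields 11 x-axis
models (m0–m10) and 5 z-axis models (z0–z4); interactions never appear
without their main effect. ln Z uses Z in millimetres (Z ≥ 5, so no
offset constant is needed). The replicate intercept effect enters as
indicator-coded shifts, not a linear-in-t trend.

Fitting is maximum likelihood, not REML, because AIC comparisons span
models with different fixed effects. The fitter profiles the fixed
effects and residual variance analytically, leaving a one-dimensional
profile likelihood in the variance ratio λ = σ²_flower/σ², maximized
by a 57-point log-grid sweep with bounded refinement (xatol 1e−10);
blocks invert by Sherman–Morrison so a fit is O(n) per likelihood
evaluation. λ = 0 is a legal boundary optimum, reported with a flag;
single-flower data fall back to OLS with a warning flag. Tests verify
the optimized log-likelihood against a dense multivariate-normal
density and against an independent mixed-model implementation.

AIC uses k = (free fixed effects) + 2, counting both variance
components, so k is comparable across the family under one convention.
Model selection fits the whole family per axis; the *comparable best
set* holds every model within ΔAIC ≤ 2 of the minimum (configurable),
and summary values use the single lowest-AIC member, with exact ties
broken toward fewer parameters. AIC retains a finite overfitting
probability — an irrelevant extra parameter improves AIC with
probability P(χ²₁ > 2) ≈ 0.16 regardless of sample size — so null
truths are *retained in* the best set far more reliably than they are
*chosen outright*; the recovery simulations therefore score best-set
membership.

## Peak summaries

On replicate t the fitted mean curve is I + i_t + (A + a_t)X +
(B + b_t)X² with the flower intercept set to zero. The peak location
X_t^max is 0 for flat models (any X would serve), ±30 mm (the sign of
the slope) for linear models, and the vertex −(A + a_t)/(2(B + b_t))
for downward quadratics. Vertices outside the sampled ±30 mm are
clamped to the boundary and flagged: reporting an extrapolated vertex
would claim a peak the transect never measured. Upward-opening
quadratics (never favoured in practice) take the better sampled
boundary, flagged. ΔRH^max evaluates the curve at X_t^max and takes
the maximum over replicates; ties resolve to the earliest replicate,
the one closest to the fresh-cut state. Species are classified against
the water-filled-tube controls: above the TWL control (tube + water +
lid — humidity the horticultural tube itself could contribute), above
the TW control (tube + water, the strongest control signal), and above
an absolute 3 %RH.

## Phylogenetic comparative regression

log ΔRH^max (natural log; back-transformed effect sizes exponentiate)
is regressed on flower span (mm) and binary dummies for floral type
(flower = 0, inflorescence = 1) and outdoor growth, by GLS with a
phylogenetic residual correlation, fit by ML with σ² profiled out.
Under BM the tip correlation is the shared root-to-MRCA path length
over tree height. For OU we use the root-anchored process: covariance
∝ exp(−α·d_ij)·(1 − exp(−2α·t_ij)) with d_ij the patristic distance
and t_ij the MRCA depth on the height-normalized tree, scaled to unit
diagonal. This form converges entrywise to the BM matrix as α → 0 and
decays as exp(−α·d_ij) for large α; the common stationary
(Martins–Hansen) form exp(−α·d_ij) lacks the BM limit (it tends to
equicorrelation), which is why it is not the default here. α values
are therefore only comparable under this normalization — published α
estimates from other parameterizations will not match numerically.
When estimated, α maximizes the profile likelihood over a 61-point
log-spaced grid (1e−4..1e3) with bounded refinement. AIC counts
coefficients + residual variance (+ α when estimated). Full models are
compared to the grand-mean null, and OU to BM, by ΔAIC and
likelihood-ratio tests (χ² reference when nested). Coefficient
standard errors use the degrees-of-freedom-corrected residual
variance, t reference with n − p df.

## Synthetic data

The transect generator emulates the survey's statistical structure,
not flower physics. Shared room humidity is a level (49.1 %RH) plus a
slow daily sinusoid (amplitude 2 %RH) plus smooth HVAC-like
fluctuations (sinusoids of period 120/300/900 s, amplitudes
1.2/0.9/0.6 %RH, random phases). Both probes sample this common
process on their own jittered 2 s clocks (±0.2 s), each adding
0.1 %RH white instrument noise; the focal probe adds the
model-family mean elevation, a per-flower Gaussian intercept (sd
0.1 %RH) and a per-period elevation jitter (sd 0.05 %RH — residual
scatter in real transects is biological and aerodynamic, not just
instrumental). The recorded focal value is distorted by a known
miscalibration, recorded = (true − M)/W with defaults W = 0.95,
M = 2 %RH, so the fitted correction should recover (W, M). Probe
controls follow each flower, as in the robot's actual sequence.

Two deliberate smoothness/variation choices matter: the room
fluctuation must be *smooth* (nearest-timestamp pairing of two
asynchronous clocks only cancels a common signal that barely moves
within a second) and must be *present* (the calibration slope is
unidentifiable from a perfectly still room; too little shared
variation relative to instrument noise attenuates W and leaks spurious
replicate-interaction structure into ΔRH). Real rooms satisfy both.

A second-tier generator emits per-period mean ΔRH records directly
from a family truth (flower sd 0.1, period-mean residual sd 0.05 %RH
by default), for model-selection simulations where the reading-level
machinery is not under test. The comparative generator draws a
birth–death tree (birth 1.0, death 0.3), extends each terminal branch
by 5% of tree height (the process stops at a speciation event, which
would otherwise leave a zero-length cherry and a singular GLS),
samples span log-normally (median 35 mm, log-sd 0.4), binaries
Bernoulli(0.5), and the response multivariate-normal with covariance
σ²·(BM or OU correlation).

What the generator does not emulate: physical vapour diffusion and
boundary layers, temperature coupling, probe hysteresis and
quantization, inter-species heterogeneity of variance, and day/flower
scheduling constraints. Passing recovery tests therefore demonstrates
the *estimators* are correct under the stated statistical structure,
not that the structure exhausts real data.

## Problem sizes and numerical choices

Recovery simulations use the survey's own design (6 flowers × 4
replicate transects × 13 x-offsets / 6 z-offsets): model-selection
rates use 100 seeded period-level datasets per scenario, reading-level
end-to-end recovery 20 seeded full probe logs, comparative slope
recovery 200 seeded 40-tip trees; these sizes give Monte-Carlo error
comfortably below the thresholds being checked. Nearest-timestamp
pairing drops unmatched readings; calibration requires ≥ 3 paired
points and non-degenerate variance; correlation matrices are rejected
if their smallest eigenvalue is below −1e−8, and a 1e−10 diagonal
ridge handles semi-definite edge cases in factorization.

## Known limitations

Quantities that require the original raw probe logs — the per-species
ΔRH^max table, the survey-wide repeatability point estimate, and the
turbulence regression coefficients — or the external megaphylogeny
(the comparative effect-size table, OU-vs-BM statistics and the
published α) cannot be recomputed from this package alone; the
packaged summary table carries the published species-level values, and
the estimator implementations are validated by the oracle and recovery
suites instead. The published α in particular is tied to an
unspecified OU parameterization and is not numerically comparable to
this package's α under any setting.
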