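"""Synthetic targeted-temperature-management (TTM) cohort generator.

Real double-sensor validation data are recorded at the bedside and are not
publicly deposited, so the pipeline is exercised on simulated cohorts that
reproduce the statistical structure of a TTM study:

* a per-patient *true* core-temperature trajectory following the clinical
  protocol (induction to 33 °C, 24 h maintenance, rewarming at 0.25 °C/h to
  37 °C, 24 h post-hold), with optional slow AR(1) physiological jitter;
* a 1-Hz double-sensor stream derived from the true trajectory through the
  matched forward heat-flux model, carrying a per-patient systematic bias,
  a per-patient time lag, slow correlated sensor drift (vasomotion-like),
  sporadic large artifacts and optional logger dropouts;
* a 30-minute esophageal reference stream with small independent probe
  noise.

Every draw is governed by one seed per patient; a cohort derives patient
seeds deterministically from its master seed, so identical configuration
plus seed yields a bit-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .sensor_model import HeatFluxModel, forward_skin_temps
from .streams import DualSensorStream, ReferenceStream

__all__ = [
    "ProtocolConfig",
    "PatientParams",
    "CohortConfig",
    "TruthRecord",
    "PatientBundle",
    "generate_protocol_trajectory",
    "simulate_patient",
    "simulate_cohort",
    "patient_seed_for",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Piecewise-linear TTM core-temperature protocol.

    Phases: linear induction from ``start_temp`` down to ``target_temp`` at
    ``induction_rate``; maintenance plateau for ``maintenance_h``; linear
    rewarming at ``rewarm_rate`` up to ``post_target``; plateau for
    ``post_hold_h``. Temperatures in °C, rates in °C/h, durations in hours.
    """

    start_temp: float = 35.5
    induction_rate: float = 1.5
    target_temp: float = 33.0
    maintenance_h: float = 24.0
    rewarm_rate: float = 0.25
    post_target: float = 37.0
    post_hold_h: float = 24.0

    def __post_init__(self) -> None:
        if self.induction_rate <= 0 or self.rewarm_rate <= 0:
            raise ValueError("protocol rates must be > 0")
        if self.maintenance_h < 0 or self.post_hold_h < 0:
            raise ValueError("phase durations must be >= 0")
        if not self.target_temp < self.post_target:
            raise ValueError("target_temp must be below post_target")
        if self.start_temp < self.target_temp:
            raise ValueError("start_temp must be at or above target_temp")

    @property
    def induction_h(self) -> float:
        return (self.start_temp - self.target_temp) / self.induction_rate

    @property
    def rewarm_h(self) -> float:
        return (self.post_target - self.target_temp) / self.rewarm_rate

    @property
    def total_h(self) -> float:
        return self.induction_h + self.maintenance_h + self.rewarm_h + self.post_hold_h

    def core_temp(self, t_s) -> np.ndarray:
        """Noiseless protocol core temperature at time(s) ``t_s`` (seconds)."""
        knots_h = np.array(
            [
                0.0,
                self.induction_h,
                self.induction_h + self.maintenance_h,
                self.induction_h + self.maintenance_h + self.rewarm_h,
            ]
        )
        temps = np.array(
            [self.start_temp, self.target_temp, self.target_temp, self.post_target]
        )
        # np.interp holds the end values flat beyond the last knot (post-hold)
        return np.interp(np.asarray(t_s, dtype=float) / 3600.0, knots_h, temps)


@dataclass(frozen=True)
class PatientParams:
    """Per-patient stochastic structure of the simulated streams.

    ``sensor_bias_sd`` is the between-patient SD of the systematic
    double-sensor offset; ``ds_noise_sd`` the stationary SD of the slow
    correlated sensor drift (Ornstein-Uhlenbeck with correlation time
    ``ds_noise_tau_s``); ``oet_noise_sd`` the white reading noise of the
    esophageal probe. The defaults combine to a pooled paired-difference SD
    of sqrt(0.45² + 0.25² + 0.15²) ≈ 0.54 °C. Artifacts are injected per
    pairing epoch (one reference tick) as an additive Gaussian shock applied
    to all double-sensor samples in that epoch.
    """

    skin_offset_mean: float = 1.0
    sensor_bias_sd: float = 0.45
    lag_range_min: tuple[float, float] = (0.0, 10.0)
    ds_noise_sd: float = 0.25
    ds_noise_tau_s: float = 600.0
    oet_noise_sd: float = 0.15
    artifact_prob: float = 0.05
    artifact_magnitude_sd: float = 3.0
    dropout_segments: tuple[tuple[float, float], ...] = ()
    ambient_mean: float = 25.22
    ambient_sd: float = 1.48
    jitter_sd: float = 0.05
    jitter_rho: float = 0.99

    def __post_init__(self) -> None:
        for name in (
            "sensor_bias_sd",
            "ds_noise_sd",
            "oet_noise_sd",
            "artifact_magnitude_sd",
            "ambient_sd",
            "jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact_prob must lie in [0, 1]")
        lo, hi = self.lag_range_min
        if lo < 0 or hi < lo:
            raise ValueError("lag_range_min must satisfy 0 <= lo <= hi")
        if self.ds_noise_tau_s <= 0:
            raise ValueError("ds_noise_tau_s must be > 0")
        if not 0.0 <= self.jitter_rho < 1.0:
            raise ValueError("jitter_rho must lie in [0, 1)")
        if self.skin_offset_mean < 0:
            raise ValueError("skin_offset_mean must be >= 0")
        for seg in self.dropout_segments:
            if len(seg) != 2 or seg[1] <= seg[0] or seg[0] < 0:
                raise ValueError(f"invalid dropout segment {seg!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, recording span, sampling cadences and master seed."""

    n_patients: int
    duration_h: float = 48.0
    ds_rate_hz: float = 1.0
    oet_interval_min: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.ds_rate_hz <= 0:
            raise ValueError("ds_rate_hz must be > 0")
        if self.oet_interval_min <= 0:
            raise ValueError("oet_interval_min must be > 0")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")


@dataclass
class TruthRecord:
    """Ground truth retained for recovery testing."""

    t: np.ndarray
    true_core: np.ndarray
    sensor_bias: float
    lag_s: float
    artifact_times: np.ndarray
    artifact_shocks: np.ndarray
    dropout_segments: tuple[tuple[float, float], ...]
    patient_seed: int


@dataclass
class PatientBundle:
    ds: DualSensorStream
    ref: ReferenceStream
    truth: TruthRecord
    patient_id: int = 0


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series of length ``n`` with marginal SD ``sd``."""
    if sd == 0.0 or n == 0:
        # keep the draw count independent of sd so seeds stay comparable
        rng.normal(size=n)
        return np.zeros(n)
    eps = rng.normal(size=n)
    eps *= sd * math.sqrt(1.0 - rho * rho)
    eps[0] = eps[0] / math.sqrt(1.0 - rho * rho) if rho < 1.0 else eps[0]
    return lfilter([1.0], [1.0, -rho], eps)


def generate_protocol_trajectory(
    protocol: ProtocolConfig,
    duration_h: float,
    step_s: float,
    jitter_sd: float = 0.0,
    jitter_rho: float = 0.99,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the protocol trajectory on a regular grid.

    Returns ``(t, temp)`` with ``t`` in seconds from 0 to ``duration_h``
    inclusive. With ``jitter_sd`` > 0 a stationary AR(1) physiological
    jitter (autocorrelation ``jitter_rho`` per step) is added; the default
    is the exact noiseless piecewise-linear protocol.
    """
    if step_s <= 0:
        raise ValueError("step_s must be > 0")
    if duration_h < protocol.induction_h + protocol.maintenance_h:
        raise ValueError(
            "duration_h must cover at least induction + maintenance "
            f"({protocol.induction_h + protocol.maintenance_h:.2f} h)"
        )
    t = np.arange(0.0, duration_h * 3600.0 + 0.5 * step_s, step_s)
    temp = protocol.core_temp(t)
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        temp = temp + _ar1(rng, t.size, jitter_sd, jitter_rho)
    return t, temp


def simulate_patient(
    protocol: ProtocolConfig,
    params: PatientParams,
    cohort: CohortConfig,
    patient_seed: int,
    model: HeatFluxModel | None = None,
) -> PatientBundle:
    """Simulate one patient's double-sensor and reference streams.

    The double-sensor core-equivalent signal is the true trajectory read at
    ``t - lag`` plus the patient's systematic bias and the slow OU drift;
    it is converted to the (th1, th2) pair through the matched forward
    heat-flux model so that the analysis-side core computation inverts it
    exactly. Deterministic given ``patient_seed``.
    """
    if model is None:
        model = HeatFluxModel()
    rng = np.random.default_rng(patient_seed)
    duration_s = cohort.duration_h * 3600.0
    step = 1.0 / cohort.ds_rate_hz

    t_ds = np.arange(0.0, duration_s + 0.5 * step, step)
    n = t_ds.size
    jitter = _ar1(rng, n, params.jitter_sd, params.jitter_rho)
    true_core = protocol.core_temp(t_ds) + jitter

    sensor_bias = float(rng.normal(0.0, params.sensor_bias_sd))
    lag_s = float(rng.uniform(*params.lag_range_min) * 60.0)

    t_lagged = np.clip(t_ds - lag_s, 0.0, None)
    ds_core = (
        protocol.core_temp(t_lagged)
        + np.interp(t_lagged, t_ds, jitter)
        + sensor_bias
        + _ar1(rng, n, params.ds_noise_sd, math.exp(-step / params.ds_noise_tau_s))
    )

    # reference ticks and probe noise
    interval_s = cohort.oet_interval_min * 60.0
    t_ref = np.arange(0.0, duration_s + 1e-9, interval_s)
    ref_temp = (
        protocol.core_temp(t_ref)
        + np.interp(t_ref, t_ds, jitter)
        + rng.normal(0.0, params.oet_noise_sd, t_ref.size)
    )

    # epoch-level artifacts: one shock per affected reference tick, applied
    # to every DS sample in the half-interval around that tick
    hit = rng.random(t_ref.size) < params.artifact_prob
    shocks = rng.normal(0.0, params.artifact_magnitude_sd, t_ref.size)
    for tick, shock in zip(t_ref[hit], shocks[hit]):
        lo = np.searchsorted(t_ds, tick - interval_s / 2.0, side="left")
        hi = np.searchsorted(t_ds, tick + interval_s / 2.0, side="left")
        ds_core[lo:hi] += shock

    ambient = params.ambient_mean + _ar1(
        rng, n, params.ambient_sd, math.exp(-step / 3600.0)
    )

    keep = np.ones(n, dtype=bool)
    for seg_start, seg_end in params.dropout_segments:
        keep &= ~((t_ds >= seg_start) & (t_ds < seg_end))

    th1, th2 = forward_skin_temps(ds_core, params.skin_offset_mean, model)
    th1 = np.atleast_1d(th1)
    th2 = np.atleast_1d(th2)

    ds = DualSensorStream(t_ds[keep], th1[keep], th2[keep], ambient[keep])
    ref = ReferenceStream(t_ref, ref_temp)
    truth = TruthRecord(
        t=t_ds,
        true_core=true_core,
        sensor_bias=sensor_bias,
        lag_s=lag_s,
        artifact_times=t_ref[hit].copy(),
        artifact_shocks=shocks[hit].copy(),
        dropout_segments=params.dropout_segments,
        patient_seed=int(patient_seed),
    )
    return PatientBundle(ds=ds, ref=ref, truth=truth)


def patient_seed_for(master_seed: int, patient_index: int) -> int:
    """Deterministic per-patient seed: SeedSequence over (master, index)."""
    return int(
        np.random.SeedSequence([int(master_seed), int(patient_index)]).generate_state(
            1
        )[0]
    )


def simulate_cohort(
    cohort: CohortConfig,
    protocol: ProtocolConfig | None = None,
    params: PatientParams | None = None,
    model: HeatFluxModel | None = None,
) -> list[PatientBundle]:
    """Simulate ``cohort.n_patients`` independent patients.

    Per-patient seeds derive deterministically from the cohort master seed,
    so the same configuration and seed reproduce the cohort bit-identically.
    """
    if protocol is None:
        protocol = ProtocolConfig()
    if params is None:
        params = PatientParams()
    bundles = []
    for i in range(cohort.n_patients):
        bundle = simulate_patient(
            protocol, params, cohort, patient_seed_for(cohort.seed, i), model
        )
        bundle.patient_id = i
        bundles.append(bundle)
    return bundles
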