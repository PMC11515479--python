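"""Seeded synthetic ovine-trial data with the structure the analysis assumes.

Real recordings from the ventilated preterm-lamb trials are not publicly
available, so every pipeline stage is exercised on synthetic data instead.
The generator emulates the *statistical shape* of those trials, not lung
physiology: each monitored channel evolves as a bounded random walk
(reflected at its physiological bounds, so 20-s and 2-min windows are
locally smooth but non-trivial to average); intermittently active channels
(spontaneous breathing, leakage) switch between zero and active bursts;
blood gases arrive every 15-180 min and are documented at minute
resolution only; and the PaCO2 of each blood gas is linked to the
concurrent covariates through the published estimation equation plus
Gaussian noise and an optional fraction of gross outliers.

Because the documented minute is all a later analysis can see, the
generator defines "concurrent covariates" as the centred 2-min window
means around the documented minute - the same convention the
preprocessing stage uses - so that with zero noise the published model
reproduces every generated PaCO2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (CHANNEL_SPECS, ZERO_INFLATED_CHANNELS, ChannelSpec)
from .errors import DomainError, InvalidConfigError
from .estimator import predict, published_model
from .preprocess import CENTRED_POLICY, AveragedSample, centred_average
from .records import BloodGasRecord, TrialRecording
from .robust import FittedModel

#: Mean burst length for intermittently active channels, in samples at
#: 0.5 Hz (120 samples = 4 min).
_BURST_LEN_STEPS = 120


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of a synthetic trial population.

    Defaults follow the study conditions: recordings from the first day
    of life (a 4-h excerpt per animal at the native sampling rates),
    blood gases every 15-180 min, and a PaCO2 noise model (3 mmHg
    Gaussian, 5% outliers shifted by +-15 mmHg) strong enough that a
    robust fit and a least-squares fit differ visibly.
    """

    n_animals: int = 12
    duration: float = 14400.0
    bga_interval_range: tuple[float, float] = (900.0, 10800.0)
    noise_sd: float = 3.0
    outlier_fraction: float = 0.05
    outlier_shift: float = 15.0
    #: Stationary fraction of time that zero-inflated channels (%Spont,
    #: fSpont, Leak) spend in an active burst.
    burst_fraction: float = 0.2
    channel_specs: tuple[ChannelSpec, ...] = CHANNEL_SPECS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals <= 0:
            raise InvalidConfigError("n_animals must be positive")
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        lo, hi = self.bga_interval_range
        if not 0 < lo <= hi:
            raise InvalidConfigError("bga_interval_range must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if not 0 <= self.outlier_fraction < 1:
            raise InvalidConfigError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.burst_fraction < 1:
            raise InvalidConfigError("burst_fraction must be in [0, 1)")


def _reflect(x: np.ndarray, low: float, high: float) -> np.ndarray:
    """Fold values into [low, high] by reflection at both bounds."""
    span = high - low
    z = np.mod(x - low, 2.0 * span)
    return low + np.where(z > span, 2.0 * span - z, z)


def _bounded_walk(rng: np.random.Generator, spec: ChannelSpec,
                  n: int) -> np.ndarray:
    step_sd = (spec.high - spec.low) / 200.0
    start = rng.uniform(spec.low, spec.high)
    path = start + np.cumsum(rng.normal(0.0, step_sd, size=n))
    return _reflect(path, spec.low, spec.high)


def _burst_gate(rng: np.random.Generator, n: int,
                burst_fraction: float) -> np.ndarray:
    """Two-state on/off gate with ~`burst_fraction` stationary on-time."""
    if burst_fraction <= 0:
        return np.zeros(n, dtype=bool)
    p_off = 1.0 / _BURST_LEN_STEPS
    p_on = p_off * burst_fraction / (1.0 - burst_fraction)
    gate = np.empty(n, dtype=bool)
    state = rng.random() < burst_fraction
    for i in range(n):
        state = (rng.random() >= p_off) if state else (rng.random() < p_on)
        gate[i] = state
    return gate


def _channel_series(rng: np.random.Generator, spec: ChannelSpec,
                    duration: float,
                    burst_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / spec.sampling_rate
    times = np.arange(dt, duration + 1e-9, dt)
    values = _bounded_walk(rng, spec, len(times))
    if spec.name in ZERO_INFLATED_CHANNELS:
        gate = _burst_gate(rng, len(times), burst_fraction)
        values = np.where(gate, values, 0.0)
    return times, values


def structural_paco2(covariates: dict[str, float] | AveragedSample,
                     model: FittedModel | None = None,
                     rng: np.random.Generator | None = None,
                     noise_sd: float = 0.0,
                     outlier_fraction: float = 0.0,
                     outlier_shift: float = 15.0,
                     return_flag: bool = False):
    """Structural PaCO2 of a covariate vector under the estimation model.

    Returns the model prediction plus a ``Normal(0, noise_sd)`` draw,
    additionally shifted by ``+-outlier_shift`` with probability
    ``outlier_fraction``.  With ``return_flag=True`` the outlier indicator
    is returned alongside the value.
    """
    if model is None:
        model = published_model()
    if isinstance(covariates, AveragedSample):
        sample = covariates
    else:
        sample = AveragedSample(animal_id="", reference_time=0.0,
                                values=dict(covariates))
    vte = sample.values.get("Vte")
    if vte is not None and vte <= 0:
        raise DomainError("Vte must be positive (log transform undefined)")
    value = predict(model, sample)
    if value is None:
        raise DomainError("covariates required by the model are missing")
    is_outlier = False
    if noise_sd > 0 or outlier_fraction > 0:
        if rng is None:
            raise InvalidConfigError("rng required when noise or outliers are on")
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        if outlier_fraction > 0:
            is_outlier = bool(rng.random() < outlier_fraction)
            if is_outlier:
                value += outlier_shift * (1.0 if rng.random() < 0.5 else -1.0)
    if return_flag:
        return float(value), is_outlier
    return float(value)


def synthesize_capnogram(plateau: float, respiratory_rate: float,
                         duration: float, rate: float = 50.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Periodic breath-shaped CO2 waveform.

    Each breath cycle holds an inspiratory baseline of 0.5 mmHg for the
    first 30%, ramps up over the next 20%, and sits exactly at ``plateau``
    for the final 50% (the alveolar plateau), so the per-breath maximum
    equals ``plateau``.  No morphological realism beyond baseline and
    plateau is attempted.
    """
    if respiratory_rate <= 0:
        raise InvalidConfigError("respiratory_rate must be positive")
    if plateau <= 0:
        raise InvalidConfigError("plateau must be positive")
    if rate < 10:
        raise InvalidConfigError("sampling rate must be at least 10 Hz")
    baseline = 0.5
    period = 60.0 / respiratory_rate
    times = np.arange(0.0, duration, 1.0 / rate)
    phase = np.mod(times, period) / period
    values = np.full_like(times, baseline)
    upstroke = (phase >= 0.3) & (phase < 0.5)
    values[upstroke] = baseline + (plateau - baseline) * (phase[upstroke] - 0.3) / 0.2
    values[phase >= 0.5] = plateau
    return times, values


# ---------------------------------------------------------------------------
# design-phase samples (independent covariate draws)

#: Channels drawn uniformly over their full spec range for design samples.
_DESIGN_UNIFORM = {s.name: (s.low, s.high) for s in CHANNEL_SPECS}


def generate_design_samples(n: int,
                            rng: np.random.Generator | int,
                            model: FittedModel | None = None,
                            noise_sd: float = 0.0,
                            outlier_fraction: float = 0.0,
                            outlier_shift: float = 15.0,
                            burst_fraction: float = 0.2
                            ) -> tuple[list[AveragedSample], np.ndarray]:
    """Independent covariate vectors with structurally linked PaCO2.

    Emulates the averaged per-blood-gas samples of the design phase
    without simulating full recordings: every channel is drawn
    independently and uniformly over its physiological range
    (zero-inflated channels are zero with probability
    ``1 - burst_fraction``), and PaCO2 follows the estimation model plus
    noise/outliers.  Returns the samples and the outlier indicator array.
    """
    if n <= 0:
        raise InvalidConfigError("n must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if model is None:
        model = published_model()
    draws = {}
    for name, (lo, hi) in _DESIGN_UNIFORM.items():
        x = rng.uniform(lo, hi, size=n)
        if name in ZERO_INFLATED_CHANNELS:
            x = np.where(rng.random(n) < burst_fraction, x, 0.0)
        draws[name] = x
    samples: list[AveragedSample] = []
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        values = {name: float(draws[name][i]) for name in draws}
        sample = AveragedSample(animal_id=f"design{i:05d}",
                                reference_time=float(i),
                                values=values,
                                coverage={name: 1.0 for name in values},
                                complete=True)
        paco2, flag = structural_paco2(
            sample, model=model, rng=rng, noise_sd=noise_sd,
            outlier_fraction=outlier_fraction, outlier_shift=outlier_shift,
            return_flag=True)
        sample.paco2 = max(paco2, 0.1)
        flags[i] = flag
        samples.append(sample)
    return samples, flags


# ---------------------------------------------------------------------------
# full trial population

def generate_population(config: TrialConfig = TrialConfig(),
                        seed: int | None = None
                        ) -> list[tuple[TrialRecording, list[BloodGasRecord]]]:
    """Generate a seeded population of trial recordings with blood gases.

    Each animal gets a full multichannel recording (bounded random walks
    at the native sampling rates) and a blood-gas series spaced by
    uniform draws from ``bga_interval_range``.  Each blood gas' PaCO2 is
    the published equation's value for the centred 2-min window means of
    the concurrent channels, plus noise and optional outlier shifts; the
    exact draw instant and the outlier indicator are retained on the
    record as hidden ground truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    model = published_model()
    population: list[tuple[TrialRecording, list[BloodGasRecord]]] = []
    for i in range(config.n_animals):
        animal_id = f"sheep{i + 1:03d}"
        channels = {
            spec.name: _channel_series(rng, spec, config.duration,
                                       config.burst_fraction)
            for spec in config.channel_specs
        }
        trial = TrialRecording(animal_id=animal_id, channels=channels)

        # first blood gas after the minimum interval (stabilization),
        # subsequent ones spaced by uniform draws from the interval range
        lo, hi = config.bga_interval_range
        bgas: list[BloodGasRecord] = []
        t = lo
        while t <= config.duration - 60.0:
            minute = np.floor(t / 60.0) * 60.0
            if minute >= 60.0 and minute + 60.0 <= config.duration:
                sample = centred_average(
                    trial,
                    BloodGasRecord(animal_id, minute, paco2=1.0, ph=7.3,
                                   pao2=50.0),
                    CENTRED_POLICY)
                paco2, flag = structural_paco2(
                    sample, model=model, rng=rng, noise_sd=config.noise_sd,
                    outlier_fraction=config.outlier_fraction,
                    outlier_shift=config.outlier_shift, return_flag=True)
                bgas.append(BloodGasRecord(
                    animal_id=animal_id, documented_minute_s=minute,
                    paco2=max(paco2, 0.1),
                    ph=float(np.clip(rng.normal(7.30, 0.08), 6.6, 7.9)),
                    pao2=float(rng.uniform(20.0, 130.0)),
                    true_time_s=float(t), is_outlier=flag))
            t += rng.uniform(lo, hi)
        population.append((trial, bgas))
    return population
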