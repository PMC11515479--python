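"""Frozen published estimator, online estimation loop and baselines.

The published estimation equation maps five non-invasively available
covariates to PaCO2 (mmHg)::

    PaCO2 = 31.8164 + 0.8892*etCO2 - 0.0019*O2diff^2 - 0.0854*%spont
            + 0.002*Pmean^3 - 5.2879*log(Vte)

with O2diff = FiO2 - SpO2 and the natural logarithm of the expiratory
tidal volume.  Online estimation evaluates the model every 4 s on
trailing 20-s channel averages, strictly causally, and withholds an
estimate when the averaged Vte is below 12 mL (capnometry unreliable) or
any covariate is missing.  Two comparator baselines are provided: the
unaltered trailing-averaged etCO2, and etCO2 corrected by an offset that
is re-anchored to each blood-gas result as it becomes available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidConfigError
from .features import CandidateDescriptor
from .preprocess import AveragedSample, WindowPolicy, trailing_average
from .records import BloodGasRecord, TrialRecording
from .robust import FittedModel

#: Method labels used in estimate streams and reports.
METHOD_RLR = "rlr"
METHOD_ETCO2 = "etco2"
METHOD_OFFSET = "etco2_offset"


@dataclass(frozen=True)
class OnlineConfig:
    """Online estimation settings.

    window
        Trailing averaging window (s); 20 s trades outlier suppression
        against reaction delay.
    vte_min
        Minimum averaged expiratory tidal volume (mL) for a valid
        estimate.
    cadence
        Seconds between estimates; 4 s matches the 0.25 Hz etCO2 cadence.
    offset_initial
        Offset (mmHg) of the offset-corrected baseline before the first
        blood-gas result.
    result_delay
        Extra delay (s) between the end of a blood gas' documented minute
        and availability of its result to the offset baseline.
    min_coverage
        Coverage fraction a channel needs inside the trailing window.
    paco2_valid_max
        Estimates above this value (mmHg) are flagged as outside the
        validated range (they are still emitted).
    """

    window: float = 20.0
    vte_min: float = 12.0
    cadence: float = 4.0
    offset_initial: float = 0.0
    result_delay: float = 0.0
    min_coverage: float = 0.5
    paco2_valid_max: float = 75.0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.cadence <= 0:
            raise InvalidConfigError("window and cadence must be positive")

    @property
    def policy(self) -> WindowPolicy:
        return WindowPolicy("trailing", self.window, self.min_coverage)


@dataclass
class EstimateRecord:
    """One online estimate (or a withheld slot) at a cadence tick."""

    time: float
    method: str
    value: float | None
    withheld_reason: str = "none"       # none | low_vte | missing_parameters
    out_of_validated_range: bool = False

    @property
    def withheld(self) -> bool:
        return self.value is None


@dataclass
class OffsetState:
    """State of the offset-corrected baseline."""

    offset: float
    last_bga_time: float | None = None


def published_model() -> FittedModel:
    """The frozen published estimation equation as a fitted model."""
    return FittedModel(
        intercept=31.8164,
        coefficients={
            CandidateDescriptor("etCO2", "identity"): 0.8892,
            CandidateDescriptor("O2diff", "square"): -0.0019,
            CandidateDescriptor("%Spont", "identity"): -0.0854,
            CandidateDescriptor("Pmean", "cube"): 0.002,
            CandidateDescriptor("Vte", "log"): -5.2879,
        },
        scale=1.0, n_iter=0, converged=True,
    )


def required_channels(model: FittedModel,
                      include_vte: bool = True) -> set[str]:
    """Recorded channels a model evaluation needs (derived indices expand
    to FiO2 and SpO2)."""
    needed: set[str] = set()
    for term in model.coefficients:
        if term.base in ("O2diff", "O2quot"):
            needed.update(("FiO2", "SpO2"))
        else:
            needed.add(term.base)
    if include_vte:
        needed.add("Vte")
    return needed


def predict(model: FittedModel, sample: AveragedSample) -> float | None:
    """Evaluate a model on an averaged sample.

    Returns ``None`` (missing-parameters signal) when a required covariate
    is absent from the sample; raises :class:`~paco2est.errors.DomainError`
    for values outside a transform's domain (e.g. ``log`` of Vte <= 0).
    """
    from .features import derive_oxygen_indices

    value = model.intercept
    o2: tuple[float, float] | None = None
    for term, coef in model.coefficients.items():
        if term.base in sample.values:
            x = sample.values[term.base]
        elif term.base in ("O2diff", "O2quot"):
            if "FiO2" not in sample.values or "SpO2" not in sample.values:
                return None
            if o2 is None:
                o2 = derive_oxygen_indices(sample)
            x = o2[0] if term.base == "O2diff" else o2[1]
        else:
            return None
        value += coef * term.apply(x)
    return float(value)


def _ticks(trial: TrialRecording, cfg: OnlineConfig) -> np.ndarray:
    return np.arange(cfg.cadence, trial.duration + 1e-9, cfg.cadence)


def _stream(trial: TrialRecording, cfg: OnlineConfig, method: str,
            needed: set[str],
            value_fn: Callable[[float, AveragedSample], float | None]
            ) -> list[EstimateRecord]:
    """Shared causal loop: trailing-average at each tick, apply the
    withholding rules, then delegate to ``value_fn``."""
    policy = cfg.policy
    out: list[EstimateRecord] = []
    for t in _ticks(trial, cfg):
        t = float(t)
        sample = trailing_average(trial, t, policy)
        vte = sample.values.get("Vte")
        if vte is not None and vte < cfg.vte_min:
            out.append(EstimateRecord(t, method, None, "low_vte"))
            continue
        if any(name not in sample.values for name in needed):
            out.append(EstimateRecord(t, method, None, "missing_parameters"))
            continue
        value = value_fn(t, sample)
        if value is None:
            out.append(EstimateRecord(t, method, None, "missing_parameters"))
            continue
        out.append(EstimateRecord(t, method, value,
                                  out_of_validated_range=value > cfg.paco2_valid_max))
    return out


def run_online(trial: TrialRecording, model: FittedModel,
               cfg: OnlineConfig = OnlineConfig()) -> list[EstimateRecord]:
    """Causal online estimation with a fitted (or the published) model."""
    needed = required_channels(model)
    return _stream(trial, cfg, METHOD_RLR, needed,
                   lambda t, s: predict(model, s))


def etco2_baseline(trial: TrialRecording,
                   cfg: OnlineConfig = OnlineConfig()) -> list[EstimateRecord]:
    """Baseline: the unaltered trailing-averaged etCO2 as the estimate."""
    return _stream(trial, cfg, METHOD_ETCO2, {"etCO2", "Vte"},
                   lambda t, s: s.values["etCO2"])


def offset_baseline(trial: TrialRecording, bgas: Sequence[BloodGasRecord],
                    cfg: OnlineConfig = OnlineConfig()) -> list[EstimateRecord]:
    """Baseline: trailing-averaged etCO2 plus a blood-gas-anchored offset.

    At each blood gas the offset becomes that blood gas' PaCO2 minus the
    trailing-averaged etCO2 at its documented minute.  Because the true
    sampling instant lies inside the documented minute, the result cannot
    be available before that minute ends: the new offset takes effect at
    ``documented_minute + 60 s + result_delay``.  Estimates inside a blood
    gas' documented minute therefore still use the previous offset, so
    scoring against blood gas *k* only ever uses information from blood
    gases before *k*.
    """
    policy = cfg.policy
    updates: list[tuple[float, float]] = []   # (effect time, new offset)
    for bga in sorted(bgas, key=lambda b: b.documented_minute_s):
        m = bga.documented_minute_s
        sample = trailing_average(trial, m, policy)
        etco2 = sample.values.get("etCO2")
        if etco2 is None:
            continue                          # no anchor; keep prior offset
        updates.append((m + 60.0 + cfg.result_delay, bga.paco2 - etco2))

    state = OffsetState(offset=cfg.offset_initial)

    def value_fn(t: float, sample: AveragedSample) -> float:
        while updates and updates[0][0] <= t:
            effect_time, new_offset = updates.pop(0)
            state.offset = new_offset
            state.last_bga_time = effect_time
        return sample.values["etCO2"] + state.offset

    return _stream(trial, cfg, METHOD_OFFSET, {"etCO2", "Vte"}, value_fn)
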