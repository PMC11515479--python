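"""Windowed averaging, end-tidal CO2 extraction and exclusion filters.

Two window modes are used.  Model building averages every variable over a
centred 2-min window around the documented blood-gas minute, because only
the minute of the analysis is written down and the true instant lies
somewhere inside it.  Online estimation averages over a trailing 20-s
window so that no future samples are required and reaction delay stays
low.  Samples are then filtered with the study's exclusion rules: blood
gases with PaCO2 above 75 mmHg and averaged expiratory tidal volumes below
12 mL are removed (end-tidal CO2 becomes unreliable in both regimes), as
are samples with missing parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .channels import CHANNELS, CHANNEL_NAMES
from .errors import InvalidConfigError
from .records import BloodGasRecord, TrialRecording

DEFAULT_CENTRED_WIDTH = 120.0
DEFAULT_TRAILING_WIDTH = 20.0
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class WindowPolicy:
    """Averaging window definition.

    mode
        ``"centred"`` for design-phase averaging around the documented
        blood-gas minute, ``"trailing"`` for causal online averaging.
    width
        Window width in seconds (120 for centred, 20 for trailing).
    min_coverage
        Minimum fraction of the expected sample count a channel must
        provide inside the window to count as covered.
    """

    mode: Literal["centred", "trailing"]
    width: float
    min_coverage: float = DEFAULT_MIN_COVERAGE

    def __post_init__(self) -> None:
        if self.mode not in ("centred", "trailing"):
            raise InvalidConfigError(f"unknown window mode {self.mode!r}")
        if not self.width > 0:
            raise InvalidConfigError("window width must be positive")
        if not 0 < self.min_coverage <= 1:
            raise InvalidConfigError("min_coverage must be in (0, 1]")


CENTRED_POLICY = WindowPolicy("centred", DEFAULT_CENTRED_WIDTH)
TRAILING_POLICY = WindowPolicy("trailing", DEFAULT_TRAILING_WIDTH)


@dataclass
class AveragedSample:
    """Window means of all variables, optionally paired to one blood gas.

    ``values`` holds means only for channels whose coverage reached the
    policy's ``min_coverage``; ``complete`` is true iff every canonical
    channel is covered.
    """

    animal_id: str
    reference_time: float
    values: dict[str, float]
    coverage: dict[str, float] = field(default_factory=dict)
    complete: bool = True
    paco2: float | None = None


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion thresholds: keep PaCO2 <= paco2_max and Vte >= vte_min."""

    paco2_max: float = 75.0
    vte_min: float = 12.0

    def __post_init__(self) -> None:
        if self.paco2_max <= 0 or self.vte_min <= 0:
            raise InvalidConfigError("filter thresholds must be positive")


@dataclass
class FilterReport:
    """Accounting of the exclusion cascade (paco2 -> vte -> completeness)."""

    n_input: int
    n_kept: int
    n_excluded_paco2: int
    n_excluded_vte: int
    n_excluded_incomplete: int


def extract_etco2(times: np.ndarray, values: np.ndarray,
                  window: float = 4.0) -> float | None:
    """End-tidal CO2 from a capnogram window: the maximum CO2 partial
    pressure over the last ``window`` seconds of the waveform.

    Returns ``None`` for an empty window (missing-data signal).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return None
    times = np.asarray(times, dtype=float)
    mask = times > times[-1] - window
    return float(np.max(values[mask]))


def etco2_series_from_capnogram(times: np.ndarray, values: np.ndarray,
                                window: float = 4.0,
                                cadence: float = 4.0
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Apply :func:`extract_etco2` on a cadence over a capnogram stream.

    Emits one etCO2 value every ``cadence`` seconds (default 4 s, i.e.
    0.25 Hz), each the maximum of the waveform over the trailing
    ``window`` seconds.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        return np.array([]), np.array([])
    ticks, out = [], []
    t = np.ceil((times[0] + window) / cadence) * cadence
    while t <= times[-1]:
        mask = (times > t - window) & (times <= t)
        if mask.any():
            ticks.append(t)
            out.append(float(np.max(values[mask])))
        t += cadence
    return np.asarray(ticks), np.asarray(out)


def _expected_count(name: str, times: np.ndarray, width: float) -> float:
    spec = CHANNELS.get(name)
    if spec is not None:
        return width * spec.sampling_rate
    if len(times) > 1:          # unknown channel: infer rate from spacing
        dt = float(np.median(np.diff(times)))
        if dt > 0:
            return width / dt
    return 1.0


def _window_sample(trial: TrialRecording, animal_id: str, lo: float,
                   hi: float, closed: str, reference_time: float,
                   policy: WindowPolicy) -> AveragedSample:
    values: dict[str, float] = {}
    coverage: dict[str, float] = {}
    for name, (t, v) in trial.channels.items():
        if closed == "left":
            mask = (t >= lo) & (t < hi)
        else:
            mask = (t > lo) & (t <= hi)
        n = int(mask.sum())
        cov = min(1.0, n / _expected_count(name, t, policy.width))
        coverage[name] = cov
        if n and cov >= policy.min_coverage:
            values[name] = float(np.mean(v[mask]))
    complete = all(coverage.get(name, 0.0) >= policy.min_coverage
                   for name in CHANNEL_NAMES)
    return AveragedSample(animal_id=animal_id, reference_time=reference_time,
                          values=values, coverage=coverage, complete=complete)


def centred_average(trial: TrialRecording, bga: BloodGasRecord,
                    policy: WindowPolicy = CENTRED_POLICY) -> AveragedSample:
    """Average all channels over ``[m - w/2, m + w/2)`` around the
    documented blood-gas minute ``m``, and attach the reference PaCO2."""
    if policy.mode != "centred":
        raise InvalidConfigError("centred_average requires a centred policy")
    m = bga.documented_minute_s
    half = policy.width / 2.0
    sample = _window_sample(trial, bga.animal_id, m - half, m + half,
                            "left", m, policy)
    sample.paco2 = bga.paco2
    return sample


def trailing_average(trial: TrialRecording, t: float,
                     policy: WindowPolicy = TRAILING_POLICY) -> AveragedSample:
    """Average all channels over the causal window ``(t - w, t]``."""
    if policy.mode != "trailing":
        raise InvalidConfigError("trailing_average requires a trailing policy")
    return _window_sample(trial, trial.animal_id, t - policy.width, t,
                          "right", t, policy)


def apply_filters(samples: Sequence[AveragedSample],
                  cfg: FilterConfig = FilterConfig()
                  ) -> tuple[list[AveragedSample], FilterReport]:
    """Apply the study's exclusion rules to PaCO2-paired samples.

    A sample is kept iff PaCO2 <= ``paco2_max`` (75 mmHg), averaged Vte >=
    ``vte_min`` (12 mL) and the sample is complete.  Each excluded sample
    is counted once under the first failing rule, in the fixed order
    paco2 -> vte -> completeness, so that counts always sum to the input
    size.  Boundary values (PaCO2 exactly 75, Vte exactly 12) are kept.
    """
    kept: list[AveragedSample] = []
    n_paco2 = n_vte = n_incomplete = 0
    for s in samples:
        if s.paco2 is None:
            raise InvalidConfigError("apply_filters requires paco2-paired samples")
        vte = s.values.get("Vte")
        if s.paco2 > cfg.paco2_max:
            n_paco2 += 1
        elif vte is not None and vte < cfg.vte_min:
            n_vte += 1
        elif not s.complete or vte is None:
            n_incomplete += 1
        else:
            kept.append(s)
    report = FilterReport(
        n_input=len(samples), n_kept=len(kept), n_excluded_paco2=n_paco2,
        n_excluded_vte=n_vte, n_excluded_incomplete=n_incomplete,
    )
    return kept, report
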