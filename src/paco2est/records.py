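"""In-memory containers for trial recordings and blood-gas references.

All time coordinates are seconds from the start of the animal's recording.
Blood-gas analyses are documented by hand at minute resolution only, so a
:class:`BloodGasRecord` carries the documented minute (a multiple of 60 s);
the exact sampling instant, when known (synthetic data), is retained
separately as hidden ground truth and never used by the analysis itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

DEFAULT_START_TIME = "2024-01-01T00:00:00"


@dataclass
class TrialRecording:
    """One animal's multichannel recording.

    Attributes
    ----------
    animal_id : str
        Identifier of the animal.
    start_time : str
        ISO-8601 wall-clock time of recording start; channel times are
        seconds relative to this instant.
    channels : dict
        Map channel name -> ``(times, values)`` pair of 1-D float arrays
        with strictly increasing times.
    capnogram : tuple of arrays, optional
        Raw CO2 waveform ``(times, partial pressure in mmHg)`` when a
        capnogram is attached; end-tidal CO2 is otherwise provided directly
        as the ``etCO2`` channel.
    """

    animal_id: str
    channels: dict[str, tuple[np.ndarray, np.ndarray]]
    start_time: str = DEFAULT_START_TIME
    capnogram: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def duration(self) -> float:
        """Largest timestamp over all channels (s)."""
        return max(
            (float(t[-1]) for t, _ in self.channels.values() if len(t)),
            default=0.0,
        )


@dataclass
class BloodGasRecord:
    """One invasive blood-gas reference measurement.

    ``documented_minute_s`` is the hand-documented minute expressed as
    seconds from recording start and is always a multiple of 60.  The true
    sampling instant lies somewhere inside ``[documented_minute_s,
    documented_minute_s + 60)``.
    """

    animal_id: str
    documented_minute_s: float
    paco2: float
    ph: float
    pao2: float
    #: Hidden ground truth (synthetic data only): exact draw instant in s.
    true_time_s: float | None = field(default=None, repr=False)
    #: Hidden ground truth (synthetic data only): whether the PaCO2 value
    #: received an outlier shift.
    is_outlier: bool | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.paco2 <= 0:
            raise InvalidConfigError("paco2 must be positive")
        if self.documented_minute_s % 60 != 0:
            raise InvalidConfigError(
                "documented_minute_s must be minute-resolved (multiple of 60 s)"
            )
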