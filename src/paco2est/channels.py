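"""Canonical catalogue of monitored channels and derived base variables.

The estimation pipeline works on a fixed set of ventilator settings and
measurements plus vital parameters recorded during neonatal ventilation.
Fourteen ventilator/vital channels are sampled at 0.5 Hz; end-tidal CO2
(etCO2) is derived from the capnogram on a 4-s cadence, i.e. 0.25 Hz.
Two oxygenation indices, O2diff = FiO2 - SpO2 and O2quot = SpO2 / FiO2,
are derived per averaged sample rather than recorded, giving 17 base
variables in total for candidate-feature construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidConfigError

VENT_RATE_HZ = 0.5
ETCO2_RATE_HZ = 0.25


@dataclass(frozen=True)
class ChannelSpec:
    """Physical description of one recorded channel.

    Parameters
    ----------
    name : str
        Channel identifier (canonical spelling, e.g. ``"Pmean"``).
    unit : str
        Unit string, e.g. ``"mmHg"``.
    low, high : float
        Physiologically plausible bounds in the channel's unit; synthetic
        recordings are confined to ``[low, high]``.
    sampling_rate : float
        Sampling rate in Hz.
    """

    name: str
    unit: str
    low: float
    high: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidConfigError(
                f"channel {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )
        if not self.sampling_rate > 0:
            raise InvalidConfigError(
                f"channel {self.name!r}: sampling_rate must be positive"
            )


#: Canonical recorded channels.  Bounds for pressures, rates, volumes,
#: saturation and minute volume follow the observed ranges of the design
#: population; bounds for channels without a published range (Vti, Compl,
#: Leak, Resist, etCO2) are plausible values for ventilated preterm lambs.
CHANNEL_SPECS: tuple[ChannelSpec, ...] = (
    ChannelSpec("etCO2", "mmHg", 15.0, 70.0, ETCO2_RATE_HZ),
    ChannelSpec("FiO2", "%", 20.0, 100.0, VENT_RATE_HZ),
    ChannelSpec("PEEP", "mbar", 0.9, 9.715, VENT_RATE_HZ),
    ChannelSpec("Ppeak", "mbar", 9.0, 36.0, VENT_RATE_HZ),
    ChannelSpec("Pmean", "mbar", 4.8, 17.1, VENT_RATE_HZ),
    ChannelSpec("f", "b/min", 18.0, 101.0, VENT_RATE_HZ),
    ChannelSpec("fSpont", "b/min", 0.0, 101.0, VENT_RATE_HZ),
    ChannelSpec("%Spont", "%", 0.0, 100.0, VENT_RATE_HZ),
    ChannelSpec("MV", "mL/min", 254.0, 4758.0, VENT_RATE_HZ),
    ChannelSpec("SpO2", "%", 68.0, 100.0, VENT_RATE_HZ),
    ChannelSpec("Vti", "mL", 12.0, 85.0, VENT_RATE_HZ),
    ChannelSpec("Vte", "mL", 12.1, 84.9, VENT_RATE_HZ),
    ChannelSpec("Compl", "mL/mbar", 0.3, 5.0, VENT_RATE_HZ),
    ChannelSpec("Leak", "%", 0.0, 40.0, VENT_RATE_HZ),
    ChannelSpec("Resist", "mbar/L/s", 20.0, 400.0, VENT_RATE_HZ),
)

CHANNELS: dict[str, ChannelSpec] = {c.name: c for c in CHANNEL_SPECS}

CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in CHANNEL_SPECS)

#: Channels that are zero most of the time (no spontaneous breathing, no
#: leak) and only intermittently take positive values.
ZERO_INFLATED_CHANNELS: frozenset[str] = frozenset({"fSpont", "%Spont", "Leak"})

#: The 17 base variables considered for candidate features, in canonical
#: order: the 15 recorded channels followed by the two oxygenation indices.
BASE_VARIABLES: tuple[str, ...] = CHANNEL_NAMES + ("O2diff", "O2quot")

BASE_UNITS: dict[str, str] = {**{c.name: c.unit for c in CHANNEL_SPECS},
                              "O2diff": "%", "O2quot": "1"}
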