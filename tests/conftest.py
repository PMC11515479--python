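import numpy as np
import pytest

from paco2est import (AveragedSample, TrialConfig, TrialRecording,
                      generate_design_samples, generate_population)

#: Hand-evaluated value of the published equation on the worked covariate
#: vector (etCO2 40, FiO2 21, SpO2 91, %spont 0, Pmean 12, Vte 20).
WORKED_VALUE = (31.8164 + 0.8892 * 40 - 0.0019 * (21 - 91) ** 2
                - 0.0854 * 0 + 0.002 * 12 ** 3 - 5.2879 * np.log(20))


@pytest.fixture
def worked_sample() -> AveragedSample:
    return AveragedSample(
        animal_id="worked", reference_time=0.0,
        values={"etCO2": 40.0, "FiO2": 21.0, "SpO2": 91.0, "%Spont": 0.0,
                "Pmean": 12.0, "Vte": 20.0})


@pytest.fixture(scope="session")
def noisefree_design():
    """2000 averaged samples with PaCO2 exactly on the published equation."""
    samples, flags = generate_design_samples(2000, rng=7)
    assert not flags.any()
    return samples


@pytest.fixture(scope="session")
def small_population():
    """Two 1-h zero-noise recordings with frequent blood gases."""
    cfg = TrialConfig(n_animals=2, duration=3600.0,
                      bga_interval_range=(300.0, 600.0),
                      noise_sd=0.0, outlier_fraction=0.0, seed=11)
    return generate_population(cfg)


def constant_trial(duration: float = 600.0,
                   overrides: dict | None = None) -> TrialRecording:
    """A recording where every channel is constant (known window means)."""
    from paco2est import CHANNEL_SPECS

    defaults = {"etCO2": 44.0, "FiO2": 21.0, "PEEP": 7.0, "Ppeak": 20.0,
                "Pmean": 12.0, "f": 60.0, "fSpont": 0.0, "%Spont": 0.0,
                "MV": 1000.0, "SpO2": 91.0, "Vti": 21.0, "Vte": 20.0,
                "Compl": 1.5, "Leak": 0.0, "Resist": 100.0}
    if overrides:
        defaults.update(overrides)
    channels = {}
    for spec in CHANNEL_SPECS:
        dt = 1.0 / spec.sampling_rate
        t = np.arange(dt, duration + 1e-9, dt)
        channels[spec.name] = (t, np.full_like(t, defaults[spec.name]))
    return TrialRecording(animal_id="const", channels=channels)
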