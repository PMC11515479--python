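"""Evaluate the frozen published PaCO2 estimation equation.

Builds one covariate vector (a typical ventilated preterm lamb: etCO2
40 mmHg, FiO2 21%, SpO2 91%, no spontaneous breathing, mean airway
pressure 12 mbar, expiratory tidal volume 20 mL) and prints the model's
PaCO2 estimate term by term.
"""

import numpy as np

from paco2est import AveragedSample, predict, published_model

model = published_model()
sample = AveragedSample(
    animal_id="example", reference_time=0.0,
    values={"etCO2": 40.0, "FiO2": 21.0, "SpO2": 91.0, "%Spont": 0.0,
            "Pmean": 12.0, "Vte": 20.0})

print(f"intercept                {model.intercept:+9.4f} mmHg")
o2diff = 21.0 - 91.0
contributions = {
    "0.8892 * etCO2": 0.8892 * 40.0,
    "-0.0019 * O2diff^2": -0.0019 * o2diff ** 2,
    "-0.0854 * %spont": -0.0854 * 0.0,
    "0.002 * Pmean^3": 0.002 * 12.0 ** 3,
    "-5.2879 * log(Vte)": -5.2879 * np.log(20.0),
}
for label, value in contributions.items():
    print(f"{label:<24} {value:+9.4f} mmHg")

estimate = predict(model, sample)
print(f"{'estimated PaCO2':<24} {estimate:9.4f} mmHg")
print()
print("The estimate (45.689 mmHg) exceeds the measured etCO2 (40 mmHg):")
print("the model compensates the end-tidal underestimation caused by dead")
print("space and ventilation conditions, here mainly via the oxygenation")
print("difference and tidal-volume terms.")
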