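# paco2est

Non-invasive estimation of the arterial partial pressure of CO2 (PaCO2)
in mechanically ventilated neonates, from end-tidal CO2 (etCO2) and
routinely available ventilation and vital parameters.

In ventilated preterm patients, PaCO2 is the key indicator of whether
ventilation is adequate, but it is measured by intermittent, invasive
blood gas analyses (BGAs) that cost blood and cause stress. Capnometry
provides etCO2 continuously, but dead space and intrapulmonary shunt
make raw etCO2 a biased estimate of PaCO2, especially in neonates whose
apparatus dead space is large relative to tidal volume. This package
implements, end to end, a pipeline that corrects that mismatch with
non-invasive covariates, for researchers working on continuous CO2
monitoring and physiological closed-loop control of ventilation.

## The model

The frozen estimator is a robust linear regression of PaCO2 on etCO2 and
four non-invasive terms (natural logarithm; O2diff = FiO2 − SpO2):

```
PaCO2 ≈ 31.8164 + 0.8892·etCO2 − 0.0019·O2diff² − 0.0854·%spont
        + 0.002·Pmean³ − 5.2879·log(Vte)
```

with etCO2 in mmHg, O2diff in %, %spont the spontaneous-breathing
percentage, Pmean the mean airway pressure in mbar and Vte the expiratory
tidal volume in mL.

The model-building procedure that produced this equation is implemented
in full and can be re-run on data with the same structure:

* **Candidate catalogue** — 17 base variables (15 recorded channels plus
  the oxygenation indices O2diff and O2quot = SpO2/FiO2), each
  contributing identity, square and cube, and the natural log where the
  base is strictly positive.
* **Iterative selection** — starting from the raw deviation
  PaCO2 − etCO2, the candidate with the highest |Pearson r| against the
  current deviation is added, the model is refitted, and the deviation
  becomes the new residual; selection stops when no candidate correlates
  above 0.2.
* **Robust fit** — Huber M-estimation (k = 1.345, MAD scale) by
  iteratively reweighted least squares, so isolated gross BGA outliers do
  not drag the coefficients.
* **Study filters** — BGAs with PaCO2 > 75 mmHg or averaged Vte < 12 mL
  are excluded (etCO2 becomes unreliable in both regimes); covariates are
  averaged over a centred 2-min window around the documented BGA minute
  for model building, and over a causal trailing 20-s window for online
  estimation.
* **Evaluation** — MAE, SD of differences, SE = SD/√n, and Bland–Altman
  limits of agreement as empirical 2.5th/97.5th percentiles (the
  differences are not normal), against two baselines: unaltered etCO2
  and etCO2 plus a BGA-anchored offset.

Because the original ovine recordings are not openly available, the
package ships a seeded synthetic generator that emulates their
statistical shape (bounded random-walk channels at 0.5 Hz, etCO2 at
0.25 Hz, BGAs every 15–180 min documented at minute resolution, PaCO2
structurally linked to the covariates plus noise and outliers), so every
stage is testable without any download.

## Worked example

```
$ python examples/01_published_equation.py
intercept                 +31.8164 mmHg
0.8892 * etCO2            +35.5680 mmHg
-0.0019 * O2diff^2         -9.3100 mmHg
-0.0854 * %spont           -0.0000 mmHg
0.002 * Pmean^3            +3.4560 mmHg
-5.2879 * log(Vte)        -15.8411 mmHg
estimated PaCO2            45.6893 mmHg
```

For a ventilated lamb with etCO2 40 mmHg, FiO2 21%, SpO2 91%, no
spontaneous breathing, Pmean 12 mbar and Vte 20 mL, the model estimates
PaCO2 at 45.69 mmHg — above the raw etCO2 reading, compensating the
end-tidal underestimation. The other examples rebuild the equation from
synthetic data (`02_model_building.py`, exact recovery on noise-free
samples), run the causal online loop with withholding rules
(`03_online_estimation.py`), and produce a pooled method-comparison
table with quantile limits of agreement (`04_agreement_analysis.py`).

The same pipeline is scriptable from the shell:

```
paco2est simulate --seed 1 --out data/
paco2est preprocess --data data/ --out samples.csv
paco2est fit --samples samples.csv --out model.json
paco2est estimate --trial data/sheep001_trial.csv --bga data/bga.csv \
    --published --out est.csv
paco2est evaluate --estimates est.csv --bga data/bga.csv --out comp.json
```

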