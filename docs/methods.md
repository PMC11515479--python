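# Methods

## Problem and model

During mechanical ventilation of preterm patients, end-tidal CO2
(etCO2) from mainstream capnometry is the only continuous, non-invasive
signal related to the arterial CO2 partial pressure (PaCO2), but it is
biased low by anatomical and apparatus dead space and distorted by
shunt. The estimator implemented here models PaCO2 as a linear function
of etCO2 plus non-invasive correction terms:

PaCO2 ≈ 31.8164 + 0.8892·etCO2 − 0.0019·O2diff² − 0.0854·%spont
+ 0.002·Pmean³ − 5.2879·log(Vte),

where O2diff = FiO2 − SpO2 (%), %spont is the spontaneous-breathing
percentage (%), Pmean the mean airway pressure (mbar) and Vte the
expiratory tidal volume (mL); logarithms are natural throughout. The
package treats this equation in two roles: as the frozen published
estimator (`published_model()`), and as the structural ground truth of
the synthetic-data generator, so that the model-building pipeline can be
validated by exact recovery.

### Model building

The fit is a Huber M-estimate: coefficients minimise Σ ρ(rᵢ/σ) with ρ
quadratic for |u| ≤ k and linear beyond, k = 1.345 (95% Gaussian
efficiency). It is computed by iteratively reweighted least squares
(IRLS): ordinary least squares initialisation, weights w = 1 for
|r| ≤ kσ and kσ/|r| beyond, and the scale σ re-estimated each iteration
as 1.4826 × MAD of the current residuals. Iteration stops when the
maximum relative coefficient change falls below 1e-8 (default cap 50
iterations). If the residual MAD collapses to numerical noise — an
interpolating fit, as with noise-free synthetic data — the current
solution is accepted as converged and the reported scale is floored at a
tiny positive value.

Terms enter the model by iterative residual-correlation selection. The
candidate catalogue covers 17 base variables (15 recorded channels and
the derived O2diff/O2quot) with identity, square and cube transforms,
plus the natural log for bases strictly positive in every kept sample
("none or infrequent zero values" is operationalised as strictly
positive in 100% of kept samples, which avoids undefined logs without
imputation). The untransformed etCO2 term is forced into the model; its
square, cube and log remain ordinary candidates. The iteration-0
deviation is the raw difference PaCO2 − etCO2; each step adds the
unchosen candidate with the largest |Pearson r| against the current
deviation if it exceeds 0.2, refits robustly, and replaces the deviation
by the fit residual. The absolute correlation is used because the
equation contains negative coefficients; negatively correlated
candidates must be selectable. Ties break to the earlier catalogue
position; candidates with undefined correlations (constant columns, or
a numerically zero deviation after an exact fit) are skipped; a safety
cap of 10 terms guarantees termination. Selected candidates leave the
pool; sibling transforms of the same base remain selectable and are not
pruned. Regressors are never standardised: the published coefficients
are raw-scale.

### Windowing and filters

Model building averages every channel over a centred 2-min window
[m − 60 s, m + 60 s) around the documented BGA minute m — BGAs are
documented by hand at minute resolution, so the true draw instant lies
somewhere in that minute. (Whether the original window was instead
[m − 30, m + 90) cannot be decided from the available description; the
symmetric half-open reading is a convention of this package.) Online
estimation uses a causal trailing window (t − 20 s, t], never touching
samples after t, evaluated every 4 s to match the 0.25 Hz etCO2 cadence.
A channel counts as covered when it provides at least half of its
expected samples in the window (min_coverage 0.5); a sample is complete
when every channel is covered.

Exclusion filters keep a sample iff PaCO2 ≤ 75 mmHg, averaged
Vte ≥ 12 mL, and the sample is complete — both boundary values are kept.
The 12 mL rule is applied to the averaged Vte (the instantaneous-vs-
averaged choice is not decidable from the description; averaging is the
less noisy reading). Excluded samples are counted once under the first
failing rule in the fixed order PaCO2 → Vte → completeness so the counts
always add up to the input size.

### Online estimation and baselines

At each 4-s tick the model is evaluated on the trailing averages; the
estimate is withheld with reason `low_vte` when the averaged Vte is
below 12 mL and `missing_parameters` when any needed covariate is
uncovered. Estimates above 75 mmHg are still emitted but flagged
out-of-validated-range. Baselines: unaltered trailing-averaged etCO2,
and etCO2 plus an offset re-anchored at every BGA (offset = that BGA's
PaCO2 minus the concurrent trailing etCO2 mean). The offset starts at 0
before the first BGA, and a new offset takes effect only after the BGA's
documented minute has ended (m + 60 s, plus a configurable result
delay, default 0): the draw instant lies inside the documented minute,
so no result can causally exist before the minute ends. As a
consequence, scoring a BGA against the latest estimate inside its own
documented minute always uses the offset of the previous BGA.

### Agreement metrics

Differences are estimate − PaCO2. Reports carry n, mean difference,
MAE, the sample standard deviation of the differences about their own
mean (n − 1 denominator; with SE = SD/√n this reproduces every printed
SE from the printed SD and n), and limits of agreement as the empirical
2.5th/97.5th percentiles of the differences, computed by linear
interpolation between order statistics (h = (n − 1)q + 1) — quantiles
rather than mean ± 1.96 SD because the differences are heavy-tailed.
The Bland–Altman abscissa is the classical mean of the two methods.
Pairing of a continuous estimate stream with a minute-resolved BGA takes
the latest non-withheld estimate inside the documented minute
[m, m + 60); BGAs with no usable estimate are dropped and counted. In
method comparisons, a BGA enters the shared reference set only when
every method pairs it, so all reports are computed on the identical set.
Values are rounded to two decimals only at report serialisation.

## Synthetic data

The generator emulates the statistical shape of ventilated preterm-lamb
trials, not lung physiology (no gas-exchange compartments, no
shunt/dead-space mechanics, no capnogram morphology beyond baseline and
plateau):

* Each channel is a bounded random walk at its native rate (0.5 Hz; the
  etCO2 channel directly at 0.25 Hz), reflected at physiological bounds,
  with step SD 1/200 of the channel range, so 20-s and 2-min windows are
  locally smooth yet non-trivial to average. Pressure, rate, volume,
  saturation and minute-volume bounds follow the observed ranges of the
  design population; channels without a published range (Vti, Compl,
  Leak, Resist, etCO2) use plausible values for this setting.
* Intermittently active channels (%Spont, fSpont, Leak) switch between
  zero and active bursts via a two-state process with ~4-min mean burst
  length and a stationary active fraction of 0.2 — the population median
  stays 0, but the variables have enough variance that the %spont term
  is identifiable and selectable.
* BGAs are spaced by uniform draws from 15–180 min (defaults); the first
  comes after the minimum interval. The true draw instant is kept as
  hidden ground truth; the analysis sees only the floor-to-minute
  documented time.
* Each BGA's PaCO2 is the published equation's value for the centred
  2-min window means of the concurrent channels, plus Normal(0, 3 mmHg)
  noise and, with probability 0.05, a ±15 mmHg outlier shift (shift
  indicator retained as ground truth). Defining "concurrent covariates"
  as the centred-window means makes the zero-noise identity exact: with
  noise and outliers off, the published model reproduces every generated
  PaCO2 to machine precision through the real preprocessing code. The
  noise and outlier magnitudes are package choices — strong enough that
  Huber and least-squares fits differ visibly — not estimates of the
  original animal data.
* `generate_design_samples` additionally provides design-phase samples
  with independent uniform covariate draws over the full channel ranges,
  used for coefficient-recovery experiments at n = 2000.
* A synthetic capnogram (`synthesize_capnogram`) provides a periodic
  breath shape — 0.5 mmHg inspiratory baseline, expiratory upstroke,
  exact alveolar plateau over half the cycle — to exercise end-tidal
  extraction (maximum CO2 over the trailing 4 s, emitted at 0.25 Hz).

What passing tests on this data do and do not show: they verify the
pipeline's algebra, causality, determinism and robustness under the
assumed structure (linear link, independent or random-walk covariates,
symmetric contamination). They do not show that the published equation
is accurate on real animals or humans, nor that selection would recover
the same terms on physiological data, where covariates are mutually
dependent and autocorrelated.

## Problem sizes and numerical choices

Coefficient-recovery experiments use n = 2000 design samples: noise-free
recovery is then exact (coefficients to far better than 1e-4) and, under
contamination (3 mmHg noise, 5% outliers at ±15 mmHg, ten fixed seeds),
the Huber fit stays within 10% of every true coefficient and beats
ordinary least squares (by maximum relative coefficient error) on at
least 8 of 10 seeds. End-to-end recording simulations in the tests use
1–8 animals at 30 min–4 h with shortened BGA intervals, which keeps the
full pipeline exercised at second-scale runtimes.

A known, deliberate limitation of small recording-scale runs: with only
tens to a few hundred windowed samples, sibling transforms of one base
(e.g. Vte³ vs log(Vte)) are nearly collinear over the sampled range and
the selection may pick the sibling and stop early with a small residual
error. This mirrors the method's real data appetite — the original
equation was built from 863 samples over full-day recordings — and is
why exact-recovery checks run on design-scale samples while
recording-scale tests assert the ordering of methods rather than exact
coefficients.

Other numerical conventions: singular designs raise immediately (rank
checked via least-squares rank); fits require more rows than columns
plus intercept; Pearson correlations of (numerically) constant vectors
are undefined and skipped rather than raised during selection; the
synthetic PaCO2 is floored at 0.1 mmHg (records require positive
values; the floor is hit only in astronomically unlikely covariate
corners); all thresholds (75 mmHg, 12 mL, 0.2, 20 s, 120 s, 4 s,
k = 1.345) are configuration defaults, not hard-coded constants.
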