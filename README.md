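# cogniphys

Physiological sensing and cognitive-state estimation: feature extraction
from gaze, cardiac and respiratory time series; Sugeno-type neuro-fuzzy
inference of mental workload with first-order uncertainty propagation;
sensor characterisation statistics; and seeded synthetic-data generators
for every modality.

## What it does

Human-machine-interface studies estimate an operator's mental workload
(MWL) from unobtrusive physiological measurements. `cogniphys` implements
that sensing-to-state pipeline end to end:

- **Gaze** (`cogniphys.gaze`): blink detection from tracking loss,
  dispersion-threshold (I-DT) fixation identification, velocity-threshold
  saccade detection, region-of-interest dwells, one-way transition
  matrices, visual (gaze-transition) entropy, the nearest-neighbour index,
  explore/exploit ratio, pupil-dilation band power and blink statistics.
- **Cardiac** (`cogniphys.hrv`): RR-interval cleaning, time-domain metrics
  (SDRR, SDNN, RMSSD, pNN50), ULF/VLF/LF/HF band powers of the unevenly
  sampled tachogram (Lomb-Scargle, or cubic-spline resampling + Welch,
  selectable), and Poincaré SD1/SD2 with the fitted ellipse.
- **Respiration** (`cogniphys.respiration`): breathing rate, tidal volume
  and minute ventilation from volume traces.
- **Signal conditioning** (`cogniphys.filters`): zero-phase Butterworth
  low-/high-pass and notch chains with two-pass cutoff correction.
- **Fuzzy engine** (`cogniphys.fuzzy`): Sugeno models with trapezoid /
  Gaussian / sigmoid membership functions, product-AND firing,
  normalized-weight defuzzification, least-squares consequent calibration
  (optionally with premise refinement) returning a statsmodels-style
  results object, JSON serialisation, and delta-method uncertainty
  propagation from input sigmas to an output sigma.
- **Characterisation** (`cogniphys.characterise`): eye-tracker precision
  and accuracy from fixation clusters, lognormal two-sigma dynamic
  accuracy, field-of-view uncertainty, blink-rate error, and validity
  (RMS error + correlation) against a reference device.
- **Synthetic data** (`cogniphys.simulate`): seeded generators for gaze
  scan paths (with blinks and saccades), modulated RR series with known
  band powers, respiration traces, paired sensor recordings and labelled
  three-state workload sessions. Generator truth dictionaries make every
  detector round-trippable.

## Worked example

Simulate a labelled workload session, calibrate the three-rule MWL model
on it, and run uncertainty-aware inference:

```python
import numpy as np
from cogniphys.fuzzy import UncertainValue, propagate_uncertainty, workload_model
from cogniphys.simulate import WorkloadScenarioSpec, simulate_workload_session

df = simulate_workload_session(WorkloadScenarioSpec(seed=7))
model = workload_model(mf_family="gaussian", rule_alignment="clusters")
y = np.array([model({"HR": h, "BR": b}) for h, b in zip(df.HR, df.BR)])

res = model.fit(df[["HR", "BR"]], y)
print(res.summary())

est = propagate_uncertainty(
    res.model, [UncertainValue(66.0, 5.5), UncertainValue(13.5, 1.6)]
)
print(f"MWL = {est.value:.3f} +/- {est.sigma:.3f}")
```

Output:

```
                  Sugeno fuzzy calibration
============================================================
State:            MWL
No. observations: 600
No. rules:        3
Consequent order: 0
Premises refined: False
RMSE:             8.43916e-16
R-squared:        1
------------------------------------------------------------
          coef      std err
rule0:p0     1  5.96798e-17
rule1:p0   0.5  8.66007e-17
rule2:p0   0.1  5.52807e-17
============================================================

MWL = 0.347 +/- 1.923
```

The large sigma is real, not a bug: between the workload clusters the
normalized rule weights change steeply, so moderate input uncertainty
(5.5 beats/min, 1.6 breaths/min) makes the state estimate genuinely
ambiguous. See `docs/methods.md` for why the first-order sigma should be
read qualitatively in that regime.

The same flow is available from the command line:

```sh
cogniphys simulate session --seed 7 --out ./out
cogniphys simulate rr --seed 1 --out ./out && cogniphys hrv --input ./out/rr.csv
cogniphys characterise fov --object-size 0.5 --distance 1 --sigma-l 0.01 --sigma-d 0.02
```

## Layout

```
src/cogniphys/      library (gaze, hrv, respiration, filters, fuzzy/,
                    characterise, simulate, io, config, pipeline, cli)
tests/              pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py   acceptance-target computation
docs/methods.md     models, assumptions, parameter rationale, limitations
```
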