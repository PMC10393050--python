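# specklesense

Noninvasive blood-glucose classification from laser-speckle videos of skin
under an AC magnetic field.

## The problem and the method

When coherent light is reflected from skin, the self-interference of the
scattered wavefront forms a *secondary speckle pattern*; with a defocused
camera, tiny tilts of the surface appear as rigid translations of that
pattern. Glucose dissolved in blood plasma has an unusually large magnetic
rotatory power, so under a magnetic field **B** the polarization of light
traversing a path **L** through the tissue rotates by the Faraday angle

    φ = V·B·L,

with **V** the Verdet constant — and the rotation, hence the induced speckle
motion, is approximately linear in glucose concentration. Driving the field
with an AC current at a known frequency (140 Hz, 150 Gauss) turns the
glucose signal into a narrowband line that a digital lock-in can separate
from pulse, drift and sensor noise, which is what makes the measurement
selective.

The package implements that sensing pipeline end to end, exercised on
simulated recordings (the analysis assumes 128×128 px videos at 500 FPS,
2501 frames ≈ 5 s each):

1. **physics** — closed-form Faraday-rotation / Verdet / minimum
   decorrelation field / Beer–Lambert relations that parameterize the model;
2. **simulator** — synthetic speckle videos with glucose-proportional
   modulation at the drive frequency, blood-pulse motion, random-walk drift,
   speckle boiling and sensor noise, with ground-truth displacement stored
   per video;
3. **tracking** — per-frame-pair displacement by normalized FFT
   cross-correlation with 3-point parabolic sub-pixel refinement;
4. **lockin** — FFT band masking that keeps only the drive-frequency bins
   and returns a clean real time series, plus a band-energy diagnostic;
5. **models** / **nn** — an SVM on 500-column lock-in feature vectors with
   Gaussian-process Bayesian hyperparameter optimization and 5-fold
   stratified cross-validation, and a from-scratch numpy CNN→LSTM on stacks
   of normalized frame differences; both evaluated with confusion-matrix
   precision / recall / F1 (macro averaged);
6. **cli** — `specklesense simulate | analyze | report` for reproducible
   YAML-configured runs.

The 13 reference glucose levels (86–198 mg/dl) used as class labels ship
with the package (`specklesense.reference`).

## Worked example

```python
from specklesense import SimulationProtocol, run_simulated_experiment
from specklesense.reference import reference_levels

protocol = SimulationProtocol(frame_size=64, fps=500.0, duration=1.0)
result = run_simulated_experiment(
    reference_levels(), videos_per_level=10, protocol_template=protocol,
    seed=1, opt_budget=15,
)
print(result.summary())
```

prints

```
condition                     accuracy  macro-F1  mean 140Hz band
AC magnetic field (lock-in)     0.974     0.974          0.993
Normal condition                0.154     0.154          0.013
```

Reading: with the AC field on, 99.3% of the displacement-series AC energy
sits in the 140 Hz lock-in band and the SVM classifies 97.4% of held-out
videos into the correct one of 13 glucose levels; identically simulated
recordings without the field carry no drive line (1.3% band energy) and
classification collapses toward chance (1/13 ≈ 7.7%). The contrast is the
lock-in benefit the method is built on. `result.field_on.svm.summary()`
shows the chosen kernel/C/γ and the fold-wise CV accuracies.

The same analysis is available from the shell:

```bash
specklesense simulate --config run.yaml
specklesense analyze  --config run.yaml --backend svm
specklesense report   runs/
```

Every run directory contains the resolved config, seed and package version;
reports are written as JSON (confusion matrix, accuracy, per-class
precision/recall/F1, macro-F1, metadata) plus a per-class CSV table.

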