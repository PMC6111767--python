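# lmr — Low Movement Recumbency classification for dog collar accelerometers

`lmr` classifies tri-axial collar-accelerometer recordings of dogs into
three behavioural states — **Active**, **Rest with head up**, and **Rest
with head down** — on a one-second epoch grid.  Dogs, unlike humans, are
frequently recumbent yet alert (head raised, neck muscles engaged), so
neither a pure low-movement detector nor a pure posture detector captures
restfulness on its own.  The LMR method is a two-stage decision tree that
combines both, and is aimed at veterinary-behaviour and animal-welfare
researchers who need an objective, camera-free measure of resting
patterns in the home environment.

## The method

Acceleration is measured in g on the anatomical axes AP
(anterior-posterior), ML (medial-lateral) and DV (dorsal-ventral); a
rotation-correction step first re-orients the sensor frame so that the
z-axis reads DV, compensating collars that are not mounted precisely
ventrally.

**Stage 1 — low movement (rest vs active).**  The DV channel is low-pass
filtered (first-order Butterworth, f_c = 3 Hz) and split into
non-overlapping 1 s epochs.  Epoch *i* is flagged low-movement when its
population standard deviation is at or below a threshold δ:

    L_i = 1   iff   sqrt( (1/n) Σ (DV_k − DV̄)² ) ≤ δ        (δ = 0.014 g)

**Stage 2 — head posture (within rest).**  Pitch θ and roll φ are
estimated per sample from the gravity direction,

    θ = atan( −A_AP / √(A_ML² + A_DV²) )
    φ = atan(  A_ML / (sign(A_DV)·√(A_DV² + μ·A_AP²)) ),   μ = 0.1

where φ is the head-incline angle (positive = head away from the floor).
The mean incline over the 10 s window centred on each low-movement epoch
is thresholded at ω = 14°: at or above is *RestHeadUp*, below is
*RestHeadDown*.  Epochs with L = 0 are *Active* and never receive a head
state.

Both thresholds can be re-fitted to annotated data by a per-subject ROC
sweep whose operating point is the sensitivity/specificity crossing
(equal-error) point, followed by a group best-fit that minimises the mean
|SEN − SPC| across subjects.

Because no recordings are distributed with the package, a simulator
generates labelled synthetic recordings with the structure the method
assumes (1 g gravity orientation encoding posture, broadband movement
noise when active, slow head drift at rest, optional collar rotation and
out-of-view gaps), so every stage is testable end to end.

## Worked example

```sh
lmr simulate --seed 7 --duration 1800 --out-trace trace.csv --out-annotations annotations.csv
lmr classify --trace trace.csv --out states.csv
lmr evaluate --pred states.csv --annotations annotations.csv --out metrics.csv
```

prints

```text
simulated 1800 s at 100 Hz -> trace.csv, 11 annotation intervals -> annotations.csv
classified 1800 epochs -> states.csv ({'RestHeadDown': 1446, 'RestHeadUp': 233, 'Active': 121})
subject=subject, task=rest_vs_active, ppv=1.000, npv=0.942, spc=1.000, sen=0.996, acc=0.996
subject=subject, task=recumbent_alert_head_up, ppv=0.996, npv=0.997, spc=0.999, sen=0.983, acc=0.997
```

The simulated half-hour recording is mostly head-down rest with bouts of
head-up rest and activity; at the default thresholds the classifier
recovers the rest/active split with accuracy 0.996 and the head-up
("recumbent alert") state within rest with accuracy 0.997 against the
generative labels.  `lmr optimize --manifest cohort.csv --out thresholds.yaml`
refits δ and ω on a cohort of recordings, and

```sh
lmr report --out summary.csv
```

summarises the bundled 12-dog reference performance table:

```text
acc_rest_ess: mean 0.86 (SD = 0.08), n = 12
acc_rest_posture: mean 0.89 (SD = 0.06), n = 12
acc_recumbent_alert_lmr: mean 0.90 (SD = 0.08), n = 12
spc_recumbent_alert_lmr: mean 0.85 (SD = 0.16), n = 12
npv_recumbent_alert_lmr: mean 0.94 (SD = 0.04), n = 12
```

The same functionality is available as a library; the central estimator
follows scikit-learn conventions:

```python
from lmr import LMRClassifier, SimConfig, simulate_dog

trace, annotations = simulate_dog(SimConfig(seed=7))
states = LMRClassifier(delta_g=0.014, omega_deg=14.0).predict(trace)
```

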