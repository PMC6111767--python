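# Methods

This note documents the model behind `lmr`, the parameters that matter,
the numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Signal model and axis conventions

A collar-worn tri-axial accelerometer at 100 Hz (any uniform rate is
supported) measures specific force in g.  When the animal is still the
signal is a unit-magnitude gravity vector whose direction encodes
posture; movement adds broadband energy on top.  Axes are anatomical:
x = AP (cranial-caudal), y = ML, z = DV.  In the reference mounting
(sensor ventral, head level) the reading is (0, 0, +1).

Head-incline — the angle of the head away from the floor — moves the
gravity reading in the (ML, DV) plane and is recovered as the
μ-stabilised roll

φ = atan( A_ML / (sign(A_DV)·√(A_DV² + μ·A_AP²)) ),  μ = 0.1, sign(0) = +1.

The stabiliser keeps the denominator away from zero when the sensor is
near edge-on to gravity; μ = 0.1 is treated as a fixed constant of the
method.  Pitch (head-tilt, positive left) is
θ = atan(−A_AP / √(A_ML² + A_DV²)).  Exact zero vectors (no gravity, a
degenerate input) yield NaN angles that are excluded from window means
downstream; a window with no valid sample propagates NaN.

## Rotation correction

Collars rotate during wear, mixing ML and DV.  Gravity is the only
absolute reference an accelerometer offers, so the corrector isolates it
with a zero-phase second-order Butterworth low-pass at 0.5 Hz (zero-phase
so window angles are lag-free; this is pre-processing, not part of the
causal detection path) and measures, per non-overlapping 10 s window, the
angle of the mean gravity reading's (ML, DV) projection relative to the
reference orientation.  Windows whose gravity magnitude leaves
[0.5, 1.5] g for more than half their samples are flagged unreliable and
do not vote.

Collar roll and head-incline rotate gravity in the *same* plane, so they
cannot be separated window by window — a correction that tracked every
window would simply erase the posture signal.  They are separated
physically instead: during locomotion a loose collar settles toward the
bottom of the neck, so high-movement windows (raw |A| SD > 0.05 g) read
the mounting offset with head posture averaged out.  The correction
angle is the circular median over those locomotion windows; recordings
with fewer than six of them (under a minute of movement) fall back to
the circular median over all reliable windows, which is valid when
head-down recumbency dominates the recording.  The single angle is
applied to every sample as a rotation about the AP axis (norm-preserving
by construction).  A constant correction per recording was chosen over a
piecewise scheme deliberately: slow within-recording drift is possible
in principle but is not identifiable from gravity alone without
destroying the posture channel.  Positive angles mean rotation toward
the animal's left.

## Low-movement stage

The DV channel (AP and ML are discarded) passes a causal first-order
Butterworth low-pass with f_c = 3 Hz, then epoch SDs are taken over
non-overlapping 1 s windows (population form, divide-by-n; the epoch
sample count is round(f_s · 1 s), generalising 100).  Low movement is
declared when SD ≤ δ, with δ = 0.014 g as the published operating point.
The trailing partial epoch is dropped.  Two definitional wrinkles are
worth recording: the method's printed formulation elsewhere states the
inequality with the opposite sense, which contradicts its own prose and
its δ value (an upper bound on resting movement), so the prose semantics
are implemented; and the filter is sometimes described as first-order
*and* −60 dB at 11 Hz, which no first-order design can achieve (−11.6 dB
at 11 Hz for f_c = 3 Hz) — the literal first-order design is the
default and the order is configurable.  Filtering is causal
(single-pass); nothing indicates zero-phase filtering was intended in
the detection path.

Note on verifying the filter: the bilinear-transform digital realisation
matches the analog magnitude formula 1/√(1 + (f/f_c)²) closely only well
below Nyquist.  At f_s = 100 Hz the digital response at 30 Hz is ~31%
below the analog value — a property of any digital filter, not a defect
— so the filter oracle in the test suite evaluates at f_s = 1 kHz, where
the two agree to well under 1% across 1–30 Hz.

## Posture stage and the decision tree

Per-sample head-incline is averaged over 10 s windows (mitigating
head-shakes) and thresholded at ω = 14°: mean ≥ ω is head-up.  The
fired state is interpreted as head-*up* because positive incline is head
away from the floor; the incline (roll) channel is thresholded, as that
is the physically meaningful quantity for head position.

The two stages use different granularities (1 s vs 10 s).  They are
merged on the 1 s grid: each epoch takes L from its own epoch and the
head state of the 10 s incline window *centred* on it (clamped at trace
edges).  Centring halves the worst-case lag relative to leading or
trailing windows; with a 30°/0° posture contrast and ω = 14° the
misassigned zone around a posture change is ~0.3 s, i.e. at most the one
epoch containing the boundary.  Epochs with L = 0 are Active; head state
is computed everywhere but consumed only where L = 1, so the hierarchy
invariant (no head label on an active epoch) holds by construction.
Traces shorter than one posture window are rejected.

## Ground truth, epochs and scoring

Annotations follow a four-label ethogram: Rest (no movement, head not
supported by neck muscles), Resting-Head Up (no movement, head
supported), Not Resting, and Out of View.  Derivation rules: recumbent
head-down rest = Rest and not Resting-Head Up; alert/active = not
resting.  Epochs are half-open [t, t + Δ) to avoid double counting.  An
epoch takes its majority-duration label; exact ties break toward Not
Resting (conservative against over-calling rest — the annotation rules
themselves resolve sub-epoch mixtures in favour of movement).  Any
overlap with Out of View, however brief, excludes the whole epoch from
scoring, as does absence of any annotation: predictions are never scored
against unverifiable ground truth.

Confusion counts and PPV/NPV/SPC/SEN are standard; accuracy is
(TP + TN)/total (a printed variant of the accuracy formula elsewhere
reads (TP + FP)/total, which is the predicted-positive rate and
inconsistent with every reported value).  Zero-denominator metrics are
NaN, never silently zero.  Group summaries use the sample (n−1) SD and
round to two decimals; the bundled 12-dog table reproduces the published
group statistics under exactly these conventions (0.86/0.08 for the
low-movement stage, 0.89/0.06 for posture alone, 0.90/0.08 for the
recumbent-alert prediction).  The summarised specificity column rounds
to 0.85 where 0.84 was originally reported from unrounded inputs.
Inter-rater agreement is Cohen's kappa computed on the epoch grid over
jointly scored epochs (κ defined as 1 when both raters are constant and
identical); overlap-criterion event-matching schemes are out of scope.

Clap synchronisation finds the first n vector-magnitude peaks above 2 g
separated by ≥ 0.2 s; the original workflow identified claps by eye, so
a concrete detector needed a threshold and these defaults are
deliberately loose for 3 g claps on a 1 g baseline.

## Threshold fitting

For δ, the per-epoch statistic is the filtered-DV epoch SD with rest
(either rest state) positive and the decision rule "statistic ≤
threshold"; for ω, the statistic is the 10 s-window mean incline
restricted to windows whose ground truth is a rest state, with head-up
positive and the rule "statistic ≥ threshold".  Default grids:
δ ∈ {0.001, …, 0.100} g step 0.001, ω ∈ {1°, …, 45°} step 1°.  The
per-subject optimum is the grid point minimising |SEN − SPC| (nearest
grid point, no interpolation), ties broken by maximal SEN + SPC, then by
the median qualifying threshold.  The group threshold minimises the mean
|SEN − SPC| over subjects — the same objective lifted to the group, the
natural reading of a "best fit" across dogs — with ties broken by
maximal mean accuracy.  Subjects whose ground truth is single-class are
excluded with a warning.  Fitting is in-sample by design (no train/test
partition), and the CLI says so when reporting fitted values.

## Synthetic-data generator

The simulator emulates the recording conditions the method targets:
100 Hz sampling, recordings of 8640 s (the 144 min mean session length
of the validation study), a semi-Markov behaviour sequence with
exponential dwells (means: Active 60 s, RestHeadUp 120 s, RestHeadDown
300 s) and a 20 s dwell floor so posture windows are informative.
Per state: gravity is a unit vector at the state's head-incline (head-up
30°, head-down 0°), the incline wanders as a mean-reverting
(Ornstein-Uhlenbeck) walk reflected at ±90° — stationary SD 5° with a
30 s time constant at rest (heads drift slowly but do not random-walk
away), SD 10° with a 1 s time constant when active (gait-paced pendular
sway about the ventral hang) — movement noise is band-limited 1–10 Hz
Gaussian rescaled per segment (SD 0.2 g active, 0.008 g rest, matching
the premise that gait energy survives the 3 Hz low-pass while resting
movement stays an order of magnitude below δ), and white sensor noise
(SD 0.005 g) is added throughout.  Collar rotation (constant or linearly
drifting) is applied last; Out-of-View gaps are inserted as ~30 s
annotation intervals when requested.  Cohorts derive per-subject seeds
deterministically from a master seed and can jitter any configuration
field.

What the generator does *not* emulate: biomechanically realistic gait
(movement is coloured noise, not strides), head-tilt excursions
(pitch stays near zero), posture-dependent sensor pressure artefacts,
sub-second behavioural events, or annotation error — generative labels
are exact.  Passing tests on this data therefore demonstrate the
internal consistency of the pipeline (geometry inversion, threshold
recovery, hierarchy logic, robustness to collar rotation and noise at
realistic amplitudes), not field performance on real dogs, which the
bundled reference table summarises instead.

## Test and script problem sizes

The suite exercises short recordings (tens of seconds to 30 min) so the
full run stays fast; the acceptance script uses a full-length default
recording (8640 s) for end-to-end recovery and five 2400 s subjects for
threshold refitting.  Scored end-to-end accuracy excludes the one epoch
at each ground-truth state boundary (the epoch containing a behavioural
transition is ambiguous on any grid); steady-state cohort checks
likewise mask windows adjacent to a truth change.

## Known limitations

* Collar-roll correction is constant per recording and assumes either a
  minute of locomotion or head-down-dominated rest; recordings violating
  both (e.g. continuous head-up rest with a rotated collar) are
  uncorrectable from gravity alone, and drifting collars are corrected
  only in their median position.
* The head-incline geometry places posture and collar roll in the same
  rotation plane; AP misalignment of the sensor is not corrected.
* Fitted thresholds are in-sample equal-error points on a discrete grid;
  no interpolation, cross-validation or AUC summarisation is attempted.
* Rest is defined behaviourally (low movement, head position); no claim
  about physiological sleep is made or testable here.
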