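# Methods

## The problem and the pipeline

Myoelectric pattern recognition assigns a motion class to each short
window of multichannel surface EMG. `emgdyn` studies the *composition of
the training set* for this task when contractions contain both static
(isometric hold) and dynamic (ramping) portions. The pipeline is:
window segmentation → per-window features → Teager–Kaiser activity
gate → classifier → majority-vote fusion, evaluated by three-fold
leave-one-session-out cross-validation with the classifier trained on
one of five per-contraction sections (static 4 s; 6 s; 8 s; 10 s;
threshold-based).

## Synthetic data model

No public recordings exist for this protocol, so the package ships a
generator whose defaults *are* the study conditions: 8 subjects × 3
sessions, each session holding 2 contractions of each of 9 classes
(class 9 = rest) in random order, 10 s contractions (3 s ramp, 4 s hold,
3 s ramp) separated by 3 s rest, 6 channels at 1024 Hz.

The signal is an amplitude-modulated band-limited Gaussian carrier:

* **Carrier.** White Gaussian noise band-passed 47–440 Hz (zero-phase
  4th-order Butterworth, emulating the hardware filter), unit RMS per
  channel. The methods under study depend only on amplitude and spectral
  statistics, so no motor-unit physiology is modelled.
* **Class coding.** Each class has a per-channel activation pattern
  (max-normalized, pairwise distinct) and a peak activity level drawn
  from 56–92 % of full scale. Class amplitude on the strongest channel
  at hold is `10^(SNR/20)` times the rest level, with per-subject SNR
  drawn from 20–30 dB. The 56–92 % activity range anchors the observed
  between-class spread of normalized EMG activity; 20–30 dB corresponds
  to moderate-contraction sEMG over electrode/baseline noise (at 10 dB
  the weakest class would sit below twice the noise floor, which does
  not describe a usable recording).
* **Envelope.** The kinematic ramp is a raised cosine (linear
  optionally); EMG amplitude follows it through a sublinear mapping
  (exponent 0.35), because muscle activity during an unloaded reach
  rises well before the target posture is approached. A slow
  multiplicative jitter (CV 0.25, Gaussian-smoothed, shared across
  channels) emulates force-tracking variability — the protocol gives
  subjects no feedback to regulate contraction level, so within- and
  between-repetition amplitude variability is substantial.
* **Dynamic coordination.** Each class also has a movement-phase
  activation pattern; the instantaneous pattern blends from it into the
  hold pattern as the (kinematic) position approaches the target. Half
  of the movement pattern is a class-unspecific stabilizing synergy
  shared by all classes. This makes the ramps genuinely non-stationary
  and partially class-ambiguous — the property that makes training-set
  composition matter at all.
* **Rest class.** Realized both as inter-contraction gaps and as
  contraction-shaped rest segments (annotated with the same
  ramp/hold/ramp phase structure at rest amplitude), so training
  sections select rest-class windows exactly like any other class.

What the generator does **not** model: motor-unit recruitment and firing
statistics, electrode shift, fatigue, crosstalk structure, or real
kinematics. Passing tests on this cohort demonstrate that the pipeline's
*mechanics* behave as the study design predicts (section orderings, gate
behaviour, vote arithmetic); absolute error rates on real recordings
will differ.

## Features

* `td_ar`: mean absolute value, zero crossings, slope-sign changes,
  waveform length, plus order-6 AR coefficients by Burg's method, per
  channel (60 features). ZC/SSC use a deadzone of 0.01 × window RMS in
  pipeline runs (0 in unit tests). The AR order is not fixed by the
  study description; 6 is the convention of the real-time myoelectric
  literature and is a config knob. The bulk path uses a vectorized Burg
  recursion verified against `statsmodels` to machine precision.
* `wt`: 4-level DWT with Coiflet-4 and periodic extension; the marginal
  (L1 norm) of each detail band plus the final approximation (30
  features). Periodic extension keeps the transform orthogonal, so band
  energies satisfy Parseval exactly — used as an internal correctness
  oracle. Depth and norm are config knobs.

## Onset gate

Per-window, per-channel activity = mean |ψ[x]| with
ψ[x](n) = x(n)² − x(n−1)x(n+1) (aggregation statistic configurable:
mean/max/sum). A window is active when any channel strictly exceeds
`coefficient × rest reference` (rest reference = mean activity over the
learning data's rest windows). The coefficient is the largest value on a
log grid (10⁻¹–10³, 400 points) keeping >97 % of all active-class hold
windows and ≥85 % of each class's hold windows active, calibrated on the
static portions of the learning folds only. Feasibility is monotone in
the coefficient, so the grid maximizer is exact up to resolution; an
infeasible grid raises an error reporting the best achievable coverage.

## Classifiers and decision stream

Features are z-scored with training-fold statistics inside an sklearn
pipeline (no leakage by construction). LDA has no tunables. SVMs use the
Gaussian kernel; one-vs-one via `SVC` (pairwise votes, ties resolved by
aggregated decision values), one-vs-rest via `OneVsRestClassifier`
(argmax of discriminants). Default hyperparameters are C = 10,
γ = "scale"; `hyperparams="auto"` runs a 5-fold CV grid search
(C ∈ 10⁻¹–10³, γ ∈ 10⁻³–10¹) on the training fold — accurate but an
order of magnitude slower, so the shipped experiments use the fixed
default.

At test time a sub-threshold window is labelled rest outright; an active
window is classified. The fused label is the majority over the most
recent 6 raw labels (fewer during warm-up), ties going to the most
recent tied label. Fusion is causal.

## Evaluation

Per subject: 3 folds (leave one session out). The gate is calibrated and
the classifier trained on the 2 learning sessions (36 contractions, 4
per class — the rest class is a regular training class, so its
contraction-shaped segments enter the time-based sections like any
other; the threshold-based section rarely selects them). Training uses
every 4th overlapping window (non-overlapping 125 ms windows) since
75 %-overlapping neighbours are nearly duplicates; the evaluation stream
keeps every window of the held-out session, rest included. Error = the
fraction of windows whose fused label differs from the majority-sample
ground truth.

Time sections select windows fully inside the interval centered on the
contraction midpoint; named sections scale with the protocol (static =
hold; +1/3 and +2/3 of each ramp; whole contraction), giving exactly
4/6/8/10 s under the defaults. Window labels at annotation boundaries
take the majority annotation (ties to the later one); trailing samples
that do not fill a window are dropped.

The ability index Σᵢ of subject *i* is the arithmetic mean of the five
section errors; normalized errors η_x = e_x/Σᵢ make relative section
performance comparable across subjects and satisfy mean(η) = 1
identically (Σᵢ = 0 leaves η undefined and is reported as such).
Descriptive summaries (mean ± SD per section × classifier × feature set)
replace inferential statistics; raw per-subject tables are exported for
external analysis.

## Problem sizes

The headline study runs 8 subjects under the full default protocol with
the 15 design cells the conclusions rest on (TD+AR/LDA, WT/SVM-OVO and
TD+AR/SVM-OVR across all five sections), about 360 classifier fits and
~180 k evaluated windows; it completes in a few minutes on one CPU.
The full 2 × 3 × 5 factorial is available through `emgdyn run`.

## Known limitations

* The carrier is Gaussian; real sEMG is burst-like, so windowed activity
  statistics here are lighter-tailed than in recordings, and the
  calibrated gate coefficient sits closer to the hold-activity
  distribution than it may in practice.
* Spectral content is class-independent by construction; AR and
  wavelet-band *shape* features therefore carry less class information
  than channel-amplitude features, which favours neither feature set.
* One-vs-rest SVM behaviour under training-set growth is sensitive to
  implementation details (feature scaling, hyperparameter policy,
  solver); with z-scored features and either fixed or CV-selected
  hyperparameters, OVR error on this cohort *decreases* as dynamic data
  are added while remaining worse than OVO — the relative imbalance
  penalty is visible, a catastrophic collapse is not.
* Transitions between pairs of active classes, proportional/simultaneous
  control, and amputee data are out of scope.
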