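# emgdyn

Surface-EMG pattern recognition for myoelectric prosthesis control under
**dynamic contractions**: how much of each contraction should a classifier
be trained on?

Multifunction hand/wrist prostheses are commonly driven by classifying
windowed surface EMG (sEMG). Classifiers are usually trained and tested on
the *static* (isometric) part of a contraction, but real use is dominated
by *dynamic* phases — moving from rest to a posture and back — where the
signal is non-stationary and easily confused with rest. `emgdyn`
implements the full experimental pipeline needed to study this question
on a 9-class (8 motions + rest), 6-channel, 1024 Hz recording protocol:

* a **protocol-faithful synthetic sEMG generator** (8 subjects × 3
  sessions × 18 contractions; 3 s ramp up / 4 s hold / 3 s ramp down;
  47–440 Hz band-limited amplitude-modulated carrier with ground-truth
  class and phase annotations), so every stage is testable without any
  recordings — real data can be substituted via EDF + CSV sidecars;
* **windowing**: 128-sample (125 ms) windows with 96-sample overlap, one
  decision per 32-sample step;
* two **feature sets** per channel: Hudgins time-domain descriptors
  (MAV, ZC, SSC, WL) + order-6 Burg autoregressive coefficients
  (`td_ar`, 60 features), and L1 marginals of a 4-level Coiflet-4
  discrete wavelet decomposition (`wt`, 30 features);
* **onset gating** with the Teager–Kaiser energy operator
  ψ[x](n) = x(n)² − x(n−1)·x(n+1): a window is *active* when any channel
  exceeds `coefficient × rest activity`; the coefficient is maximized on
  the learning data subject to >97 % of all hold windows and ≥85 % of
  each class's hold windows being active;
* three **classifiers** on z-scored features: LDA, and Gaussian-kernel
  SVM in one-vs-one and one-vs-rest modes;
* five **training sections** per contraction: 4 s (static hold only),
  6 s, 8 s, 10 s (whole contraction), and threshold-based (windows whose
  activity crosses the gate);
* stream **fusion** by majority vote over the most recent 6 window
  decisions (281.25 ms of signal), and **evaluation** by three-fold
  leave-one-session-out cross-validation over all windows of the held-out
  session, rest included. Per-subject section errors e_x are normalized
  by the subject ability index Σᵢ = mean(e₄, e₆, e₈, e₁₀, e_T), so
  η_x = e_x / Σᵢ averages exactly 1 per subject.

## Worked example

```python
import emgdyn as eg

protocol = eg.ProtocolSpec()                      # 9 classes, 6 ch, 1024 Hz
subject = eg.make_subject(protocol, seed=7)
session = eg.generate_session(subject, protocol, session_index=1)
series = eg.segment(session, eg.WindowSpec())
print(len(series), eg.decision_span_ms(eg.WindowSpec(), 6))

features = eg.extract(series, "td_ar")
print(features.X.shape)
```

prints

```
7581 281.25
(7581, 60)
```

— one session is 237 s (18 contractions plus rest gaps) and yields 7581
overlapping windows; six decisions span 281.25 ms of signal; the TD+AR
feature set has 60 columns (6 channels × 10 features).

Running the study over a synthetic cohort:

```python
from emgdyn.study import run_headline_study, section_means

df = run_headline_study(master_seed=1, n_subjects=2)
print((100 * section_means(df, "td_ar", "lda")).round(1))
```

```
section
static_4s          23.3
dynamic1_6s        22.4
dynamic2_8s        19.6
all_10s            18.4
threshold_based    18.2
Name: error, dtype: float64
```

Mean window error (%) of the TD+AR/LDA pipeline per training section:
training only on the static hold is worst; every section that includes
dynamic portions — including the automatic threshold-based selection —
does better.

## Command line

```bash
emgdyn simulate --out data/           # write EDF + annotation sidecars
emgdyn run --out results/             # full 2×3×5 factorial experiment
emgdyn run --out results/ --only td_ar,lda,threshold_based
emgdyn report --results results/      # section × classifier summary table
```

A single YAML config (see `emgdyn.config.RunConfig`) controls protocol,
window geometry, features, classifiers, gate constraints and the master
seed; each run directory keeps a resolved snapshot.

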