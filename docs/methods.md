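# Methods

This note documents the modelling choices, defaults and limitations of
`psychstate` in the package's own terms: what is computed, under which
assumptions, and what the synthetic experiments do and do not show.

## State model

The patient's psychiatric state is modelled as a first-order Markov
chain over S = {N, A, E} (Normal, Atypical, Emergency), hidden behind
slot-level observations.  The first-order assumption — the next state
depends only on the current one — is the standard HMM simplification; it
ignores longer clinical history (medication cycles, circadian structure).
The model is λ = {π, T′, E′}: initial probabilities, a 3×3 transition
matrix, and an emission model.  The default emission model is a discrete
distribution over a K = 16-symbol k-means codebook of the reduced
feature vectors, because the single-pass counting trainer is defined
over countable emissions; per-state diagonal-Gaussian emissions over the
continuous features are available behind the same interface.

State order is fixed as N < A < E for indexing and decoder tie-breaks;
clinical severity E > A > N is used wherever a tie should fail safe
(candidate-frequency ties, 1-1-1 majority-vote splits), so an emergency
is never discarded by an arbitrary tie-break.

## Slot and window geometry

* τ = 15 s per observation slot.  This is the finest resolution at which
  signal features are stable (a slot must hold at least two heartbeats
  and, usually, at least one skin-conductance response at elevated
  arousal).
* w = 60 slots per prediction window, i.e. one 15-minute window,
  matching the cadence at which a clinician would annotate or want a
  prediction during a consultation.
* Default recording length is exactly one window (15 min) per subject,
  so the default 55-subject cohort yields 55 pooled window predictions —
  the same pooled-count geometry as a single-annotation-per-subject
  clinical evaluation.  Longer recordings produce multiple windows per
  subject; windows never overlap and a trailing partial window is
  dropped.

## Synthetic cohort generator

No public dataset pairs four-channel psychophysiology with psychiatric
state annotations at this cadence, so the generator is a first-class,
tested component rather than a fixture.  Per subject:

* **Trajectory.** A Markov chain with sticky default dynamics
  (self-transitions 0.86–0.92) biased toward the subject's assigned
  class; the chain is resampled (bounded retries, then deterministic
  repair) until at least 60% of slots carry the class label, so the
  window-dominant label equals the subject label while within-subject
  dynamics remain.
* **ECG** (250 Hz): a sum-of-five-Gaussians P-QRS-T template repeated at
  the slot state's heart rate (N/A/E = 65/76/90 bpm) with Gaussian R-R
  jitter standing in for HRV (sd 50/38/24 ms; variability falls with
  arousal).  Template wave offsets give an analytic QT of 0.255 s and
  R/S ratio of 4.
* **BVP** (64 Hz): two Gaussians per beat (systolic peak 0.15 s after
  the pulse foot, diastolic peak at 0.40 s), locked to the ECG beat
  times.  Systolic amplitude falls with arousal (vasoconstriction:
  1.00/0.88/0.72) as does the diastolic/systolic ratio (augmentation
  index 0.50/0.44/0.38).
* **EDA** (16 Hz): tonic level 2.0/3.0/4.5 µS plus a slow sinusoidal
  drift, with skin-conductance responses arriving as an inhomogeneous
  Poisson process (2/4/8 events·min⁻¹, sampled by thinning) shaped as a
  biexponential (rise 0.75 s, decay 3 s) of mean amplitude
  0.25/0.40/0.60 µS.
* **EMG** (1000 Hz): unit-RMS Gaussian noise band-limited to 20–450 Hz,
  multiplied by an envelope of state-dependent tone
  (0.050/0.080/0.125 mV) with rest gaps (~1 s at 5% of tone) arriving at
  6/3/1 gaps·min⁻¹ — sustained trapezius tension with few rest gaps is
  the stress signature.
* **Scores and history.** One draw per subject (questionnaires are
  answered at most weekly, far slower than slots): truncated rounded
  normals per instrument clamped to the published ranges; the HRSD
  suicide item is drawn from {0}, {1,2}, {3,4} for N/A/E respectively,
  which is also the label definition — for that reason HRSD scores are
  *excluded* from the feature vector to avoid label circularity.
  History flags are Bernoulli with state-dependent rates.

Channel noise defaults (ECG 20 µV, BVP 0.02 a.u., EDA 0.01 µS, EMG 2 µV)
are instrumentation-level; `noise_sd` scales them jointly and
`effect_scale` scales every state effect away from the Normal baseline
(0 removes all class signal; offsets are clamped non-negative).

**What the generator does not emulate:** motion and electrode-contact
artifacts, ectopic beats and arrhythmia, respiration coupling,
medication effects, missing channels, inter-subject physiological
baseline variation beyond the class effects, and item-level
questionnaire response behaviour.  Passing tests therefore demonstrate
correctness of the computational chain under idealized class structure,
not clinical accuracy; published clinical numbers from comparable
cohorts are *not* reproducible without the original data, and the
synthetic cross-validation target (pooled accuracy ≥ 0.80) is a
property of the generator's declared conditions.

## Feature extraction

Extraction is strictly slot-local (each slot is filtered and analysed in
isolation), which makes features reproducible under streaming and
testable sample-by-sample; the price is edge effects inside each slot,
handled by reflection padding.

* Band edges: ECG 0.5–40 Hz, BVP 0.5–8 Hz, EDA low-pass 1 Hz, EMG
  20–450 Hz (conventional clinical bands; configurable).  Filters are
  zero-phase order-8 Butterworth stages applied as a low-pass/high-pass
  cascade with even-reflection padding — a single high-order band-pass
  section and odd padding both produced multi-second edge transients
  through the 0.5 Hz edge.
* The 15-sample moving average (trailing, edge-truncated, hence causal)
  is applied to the EDA trace and to detector energy series; applying it
  to raw ECG/BVP would smear the very morphology being measured (60 ms
  at 250 Hz spans the QRS), so those channels are smoothed only at the
  detector stage.
* R peaks: squared-derivative energy, smoothed, thresholded at 20% of
  the slot maximum, refined to the local ECG maximum, 200 ms refractory.
* QTc uses Bazett's correction QT/√RR.  "First/second derivative"
  features are the means of successive first and second differences of
  the per-beat series.
* SCRs: excursions above a 4-s rolling-minimum baseline exceeding
  0.05 µS with ≥ 1 s separation; duration is the half-amplitude width.
* BVP: systolic peaks by prominence, diastolic peak as a genuine local
  maximum (3% prominence guard against filter ripple) 0.12–0.5 s after
  the systolic peak; the stiffness index divides a nominal height
  constant (1.75 m) by the systolic-to-diastolic interval, since subject
  height is not part of the data model — a documented proxy.
* EMG gaps: RMS envelope (50 ms) below 10% of slot RMS for ≥ 200 ms.
* Missing features (too few beats, absent channel, undefined ratio) are
  NaN and flagged, never silently zero; the pipeline imputes them with
  training-fold medians.

## Reduction pipeline

Min-max normalization to [0, 1] per feature (constant columns map to 0;
held-out values are clipped).  Mutual information uses 10 equal-width
bins on the normalized scale, in bits; features with zero MI against the
label are discarded outright, and greedy mRMR with the difference
(relevance − mean redundancy) criterion selects up to 30 features, ties
broken by name order for determinism.  PCA keeps components covering
95% of variance, with signs fixed by the largest-|loading|-positive
convention.  GDA is a kernel Fisher discriminant: samples are
represented by RBF-kernel similarities (bandwidth from the median
pairwise distance) to a basis of training points and the between- over
within-class scatter ratio is maximized by a generalized symmetric
eigenproblem with ridge ε = 1e-6.  Up to 512 basis points are used
(class-proportional deterministic subset beyond that — the standard
landmark approximation for kernel discriminants, keeping the
cross-validation fits quadratic rather than cubic in fold size); with
the full basis this is exactly the dual kernel discriminant, and with a
linear kernel it spans classical LDA.

## Training

* **VPC** counts initial states, transitions and emissions in one pass
  along labelled paths (supervised) or along single Viterbi decodes from
  a uniformly-jittered initialization (unsupervised), with a Laplace
  pseudo-count of 1.  Unsupervised training leaves state identities
  arbitrary; cross-validation aligns them to clinical labels by maximal
  overlap (Hungarian assignment) on the training decodes.
* **SVI** maintains Dirichlet posteriors over every probability row and
  blends natural parameters with step size ρ_i = 0.9·i^(−0.6)
  (initial rate 0.9, batch size 11 by default; the forgetting rate 0.6
  is a standard choice in (0.5, 1] guaranteeing convergence).  Expected
  sufficient statistics come from scaled (Rabiner-style) linear-domain
  forward–backward recursions under E[log θ]; per-iteration cost is
  independent of the dataset size, which is the point of the method.
* Decoding is exact Viterbi in log space (floor −1e9 stands in for
  log 0; fully-impossible observations are decoded through the floor and
  flagged).  A stepwise-argmax decoder is provided alongside for
  comparison: it is the literal one-pass reading of the per-slot argmax
  recursion, is myopic, and measurably diverges from the global optimum
  on adversarial models — the test suite asserts a nonzero discrepancy
  rate rather than hiding the difference.

## Window prediction

From the decoded window Q: LRL (longest run; ties go to the most recent
tied run, mirroring the recency logic of MRS), HFC (highest count; ties
go to the more severe state), MRS (last slot).  Majority vote over the
three candidates; a 1-1-1 split goes to the most severe candidate.  The
per-class score used for ROC curves is the candidate vote share scaled
by the per-slot geometric mean of the Viterbi path probability — the
method itself yields only a label, so a posterior proxy is needed for a
threshold-free curve and this one is deterministic and monotone in both
vote confidence and decode confidence.

## Evaluation

One-vs-rest confusion counts per class; Sen/Spe/FM/Acc and
FPR = FP/(FP+TN), FNR = FN/(FN+TP); undefined ratios are NaN, never 0 or
1.  DOR = (TP·TN)/(FP·FN) with Haldane 0.5 continuity correction
(flagged) when a cell is zero, and a log-normal 95% CI
exp(ln DOR ± 1.96·√(1/TP+1/FP+1/TN+1/FN)).  AUC is the Mann–Whitney rank
statistic.  Macro averages are arithmetic means over the three classes.
Cross-validation is stratified at the subject level by dominant label;
a subject's windows are never split across train and test, which is the
leakage mode that would otherwise dominate (scale scores are constant
within subject).

## Problem sizes used by the test suite

Unit and property tests run on reduced cohorts (6–15 subjects, 2–5
minutes per subject) chosen as the smallest sizes at which every stage
has non-degenerate inputs; the end-to-end evaluation runs the full
default cohort (55 subjects × 15 min, one window each).  Parameter
recovery uses 200 labelled length-100 sequences; the SVI/batch
comparison averages five seeds against a 30-iteration full-batch
variational fit; decoder correctness enumerates all 3⁶ paths on 100
random models.

## Known limitations

* The stiffness index uses a fixed height constant; between-subject
  pulse-transit scaling is not modelled.
* The MI estimator is binned, not adaptive; with very few rows per fold
  its zero-MI cut-off becomes conservative.
* Gaussian-emission decoding is implemented but the evaluation path
  exercises the discrete codebook route only.
* The cohort generator's "pulse interval" and "M-M interval" features
  are near-duplicates by construction (foot-to-foot vs peak-to-peak of
  the same template); both are kept because they differ under real pulse
  morphology, and mRMR is expected to drop one as redundant.
* Table-level clinical quantities that depend on the original
  (undeposited) patient cohort are reproduced only where they are pure
  functions of published counts; cohort-dependent rates are replaced by
  synthetic analogues and ordering properties.
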