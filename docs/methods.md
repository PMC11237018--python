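# Methods

This note documents the generative model behind the synthetic data, the
analysis conventions, the numerical choices, and what the passing recovery
tests do and do not establish.

## Task model

Two within-subject conditions are generated per participant, motor
inhibition (MI) first, interference suppression (IS) second (a simple
fixed order; full ABAB/BABA counterbalancing is not modelled).

* **MI**: 10 blocks × 80 trials. Congruent trials place the target on its
  home square. Between consecutive incongruent trials there are `g − 1`
  congruent trials with `g ~ Uniform{3,4,5}`; the first incongruent trial of
  a run is placed after an initial gap drawn the same way so the prepotent
  tendency is induced before it is violated. Block boundaries do not reset
  the gap counter, keeping the process stationary. Incongruent locations are
  uniform over the seven non-home squares. The long-run incongruent fraction
  is `1/mean{3,4,5} = 1/4`.
* **IS**: 6 blocks × 80 trials. Targets uniform over the eight shapes;
  locations uniform over the six squares excluding the target's and its
  mirror's home squares; the shape owning the chosen square is the
  distractor.
* Inter-trial intervals uniform over {550, 600, 650} ms; response deadline
  1000 ms; locations and keys are indexed 0–7 left to right, keys 0–3 are
  the left hand. All intervals are half-open and all indices 0-based.

## Behaviour generator

Each included trial draws a response category, an RT, and an 8-key force
trace.

**Categories.** Conditionally on not being excluded (no response 0.2 %,
too slow 2.5 %/4 % for MI/IS, "other error" — a press that is neither the
correct nor the location/distractor key — 2 %/28.4 %), an incongruent MI
trial is an MI error with probability 0.267 and an IS trial an IS error
with probability 0.181, so the *included-trial* response rates equal the
reference cell values by construction. Congruent MI trials are correct with
probability 0.912 (other error 6.1 %, too slow 2.5 %). The two other-error
rates are not free: they are pinned by the post-response accuracy levels of
the two conditions (≈ 94 % for MI, where the trial after any included trial
is congruent; ≈ 59 % for IS), which is why the IS condition carries a large
non-distractor error rate — an 8-choice task under a 1 s deadline produces
many presses that match neither target nor distractor.

**Response times.** Cell RTs are lognormal with log-sd σ = 0.2 and are drawn
*conditionally on beating the deadline*; the log-median is solved (fixed
point) so that the conditional median equals the stated cell median
(MI success 754.6, MI error 538.7, IS success 765.8, IS error 788.3,
congruent 680 ms — the last is a package choice, congruent responses being
location-guided and fast). The deadline conditioning matters: the reference
medians are themselves deadline-limited quantities, and calibrating the
unconditional median instead biases every recovered median downward by
1–3 %. Planted too-slow trials draw uniformly from 1060–1360 ms.

**Sequential structure.** The trial after a cell error gets `pes_shift_ms`
added (MI +11.5, IS +29.4), the trial before a cell error gets
`pre_error_drift_ms` (MI −18.0, IS −7.3); block boundaries break adjacency.
Because incongruent MI trials are at least three trials apart, both the
post-error and the post-success neighbour are congruent trials, so the
planted shift is exactly what the post-error-slowing contrast estimates.

**Force traces.** A gamma-density pulse (shape 3, 150 ms onset-to-peak)
on the pressed key is positioned so it crosses the 40 cN registration
threshold exactly at the drawn RT and peaks at the cell's force level
(means 164.9/111.9/189.8/159.2 cN, trial sd 25 cN, floor 45 cN). Multiple
responses add a second supra-threshold pulse ~180 ms later on another key;
on error trials that second key is the *correct* key with the cell's
correction probability (corrections are a subset of multiple responses).
Per-trial multiple/correction probabilities are the reference cell
percentages divided by the cell's response rate, because the cell
percentages are expressed relative to all included trials of the condition
(under that convention the two cells of a condition sum to the
condition-level percentage — e.g. 3.9 % + 5.0 % = 8.9 % multiple responses
in IS — which is the only reading consistent with both the cell and the
condition values).

## EEG generator

500 Hz, reduced montage by default (FCz, Cz, Pz, PO7/8, PO9/10, P1/2,
C3′/C4′ + 2 mastoids + 4 EOG); the full 63-channel montage is available.
C3′/C4′ are dedicated abstract motor channels (placed 1.5 cm anterior to
C3/C4 so spline operations stay well defined); ERP templates put no weight
on them and the motor ramp is injected only there.

* **Background**: independent 1/f noise per channel, 4 µV RMS (a clean
  active-electrode recording); 3 µV 50 Hz line noise; blinks at 8/min,
  120 µV in the upper vertical EOG with a fixed frontal-gradient scalp map —
  exactly the rank-one linear propagation the regression corrector assumes.
* **ERP components**: half-period cosine bumps (120–200 ms wide) at
  component-specific latencies with 10 ms jitter, Gaussian scalp maps
  (σ = 4 cm) centred on the measurement electrodes, amplitudes per
  condition × accuracy cell. Components quantified on the current source
  density state their amplitudes in µV/cm²; the µV source amplitude is
  obtained by pushing the template's unit map through the pipeline's own
  spline Laplacian **on the full montage** and inverting the gain at the
  measurement electrodes. (Calibrating on a sparse montage is ill-posed —
  the Laplacian gain of a lateral-occipital bump collapses on 11 electrodes
  and the implied sources become unphysically large.)
* **Motor ramp**: the contralateral primed channel (left hand → C4′) ramps
  to −4 µV with a 150 ms half-cosine rise whose *half-amplitude time* is the
  cell's response-locked onset parameter (−140.2 / −223.8 / −114.3 /
  −139.3 ms), holds until 50 ms after the response, then decays. Because the
  50 % fractional-peak criterion estimates precisely the half-amplitude
  time, the quantification returns the generating parameter with zero noise
  — the round-trip identity the recovery tests rely on. Stimulus-locked LRP
  onsets are emergent (≈ RT + response-locked onset), not separately
  planted: the response time links the two locks, so only one can be a free
  parameter per trial.
* **Instability scenario** (off by default): MI-error trials receive three
  brief (120 ms) low-amplitude (0.8–1.6 µV) contralateral impulses scattered
  within −180…+40 ms of the response instead of one sustained ramp —
  response preparation repeatedly interrupted by inhibition attempts. The
  averaged waveform is then shallow and late; the onset estimator either
  returns a late onset or none, and the jackknife flags incomplete cells.

## Analysis conventions

* Preprocessing order: notch → mastoid re-reference → EOG regression
  (propagation factors by least squares on the continuous record, blink
  segments included) → epoching → baseline → ±100 µV rejection (scalp
  channels, post-correction, pre-CSD) → optional CSD (spline stiffness 4,
  λ = 1e−5 — standard published defaults).
* Epochs: stimulus-locked [−100, 700) ms, response-locked [−100, 500) ms,
  baseline [−100, 0). Response-locked **LRP** epochs use [−500, 200) ms and
  are baselined on [−500, −400): the motor ramp is already active in the
  100 ms before the response, so the conventional pre-event baseline would
  subtract signal.
* ERP amplitude: extremum of the stated polarity in the closed window, mean
  of the five samples centred on it, clamped at epoch edges; the parietal
  P3's peak latency is the P3 latency measure; an optional 40-sample wide
  mode exists for the slow components. Minimum trial counts: 20 (N2), 14
  (P3), 6 per cell (Ne/c, Pe/c); LRP additionally needs 6 trials *per hand*,
  and for error cells the executed hand defines laterality.
* Sequential effects: PES = mean RT after included errors − mean RT after
  included successes (per condition); pre-error speeding analogously for
  preceding trials. The adjacent trial contributes its RT whenever a
  response was registered — exclusion criteria apply to the analysed trial,
  not its neighbours; in particular the congruent trial that always follows
  an MI error is used. Without this rule the deadline would clip the
  shifted post-error RT distribution asymmetrically and bias PES toward
  zero by ~25 %.
* Statistics: explicit sums-of-squares 2×2 within-subject ANOVA (each
  effect tested against its own effect × subject term; df1 = 1 throughout,
  so no sphericity correction can apply), partial η² =
  SS_eff/(SS_eff+SS_err); within-subject Tukey contrasts via the
  studentized range with k = 4 on paired t statistics; complete-case
  handling per analysis; no alpha adjustment across the battery
  (exploratory reporting).

## Problem sizes

The recovery studies use 30 simulated participants for behaviour-only
analyses and 12 participants on the reduced montage for the EEG analyses
(6 for the instability scenario) — sizes at which every recovered group
mean sits well inside two reference standard errors of its generating value
while a full study run stays comfortably desk-scale.

## Limitations

* All simulated participants share the same generating parameters: the
  generator models within-participant trial noise only. Passing recovery
  therefore demonstrates that the pipeline's estimators are unbiased and
  correctly wired, not that they are robust to between-participant
  heterogeneity, non-stationarity, drifting electrodes, or real ocular/EMG
  artifact structure.
* No biophysical forward model: scalp maps are Gaussian bumps, the CSD unit
  mapping is calibrated empirically, and C3′/C4′ are abstractions rather
  than interpolated electrode sites.
* Condition order is fixed (MI then IS); practice blocks are generated only
  on request and never analysed; the occipital sustained positivity seen in
  real recordings of this paradigm is not modelled.
* Detection timing is limited by the 2 ms sample grid of the simulated
  force traces (the reference apparatus sampled force at 1024 Hz).
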