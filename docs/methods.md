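# Methods

This note documents the models, conventions and numerical choices behind
`microsleep`, in the package's own terms: what is computed, under what
assumptions, and what the synthetic validation does and does not show.

## Problem setting

Microsleep episodes (MSEs) are brief sleep fragments — 1 to 15 s — whose
EEG signature is a slowing from the occipital alpha rhythm (8–12 Hz,
prominent in relaxed wakefulness) to theta dominance (4–7 Hz), typically
heralded by slow eye movements in the EOG.  Clinical maintenance-of-
wakefulness tests (MWT, 40 min) are conventionally scored in 30 s epochs,
which cannot resolve such episodes; this package scores **every sample**
of the recording (200 Hz) as one of four classes: wake (W), microsleep
episode (MSE), microsleep-episode candidate (MSEc) and episode of
drowsiness (ED).  The borderline classes MSEc/ED exist because human
scorers cannot always commit: they are intermediate by definition.

## Per-sample classification with sliding-window CNNs

A window of raw signal (one occipital EEG derivation plus two EOG
derivations, or EEG alone) is classified by a 1-D CNN, and the predicted
label is assigned to the window's **central sample**, which keeps the
information content symmetric around the decision point.  Sliding the
window at stride 1 yields a label per sample; larger strides trade
resolution for speed, with skipped samples inheriting the nearest
computed center.

### Architecture

Each convolutional block is: convolution (N filters of length 3, stride
1, no padding) → batch normalization → ReLU → max-pooling (size 2); a
block therefore maps a temporal length L to ⌊(L−2)/2⌋.  The closing head
is flatten → dropout (p = 0.5) → dense (64, ReLU) → dense softmax over
the classes.  Weights are Glorot-normal; Gaussian noise (SD 5 × 10⁻⁴) is
added to the scaled input during training.  Inputs are scaled from μV by
x/100 clipped to [−1, 1] (CNN) or (x+100)/200 clipped to [0, 1]
(CNN-LSTM).

Depth is tied to the window length: the final block is repeated once more
for each doubling of the window — 3 repetitions for 2 s up to 7 for 32 s
— on top of **four fixed leading blocks** with the filter ladder
8 → 16 → 32 → 64 (repetitions stay at the 64 cap).  The fixed-block count
is the package's completion of the sizing rule: with unpadded kernel-3
convolutions and pool-2, four fixed blocks plus the window-dependent
repetitions reduce *every* supported window to a temporal extent of
exactly 1 (e.g. 400 → 199 → 98 → 48 → 23 → 10 → 4 → 1 for 2 s), i.e. the
last layer's receptive field covers the whole window and the flattened
feature is exactly 64-dimensional.  This shape law is asserted by
symbolic propagation at build time and cross-checked against real forward
passes in the tests.

Windows are restricted to {2, 4, 8, 16, 32} s deliberately: the network
must learn EEG patterns, not episode-duration statistics; the 1–15 s
duration criteria are applied post hoc to detected runs (shorter MSE runs
are dropped, longer ones relabeled as consolidated sleep).

### CNN-LSTM variant

A 1 s CNN (six blocks, 200 → 99 → 48 → 23 → 10 → 4 → 1) is applied to
overlapping windows strided by 50 samples (0.25 s); the 64-d feature
sequence feeds an LSTM (128 hidden units) that emits one label per
window, assigned to the window's center, giving 0.25 s output resolution.
The default is two classes (MSE vs everything else).  Training is
end-to-end with the CNN trunk shared across the sequence (sequences of 32
windows by default); gradient norms are clipped at 1.  The LSTM uses
Glorot-normal input weights, orthogonal recurrent weights, and
forget-gate bias 1.

### Training protocol

Nadam (Adam with Nesterov momentum; β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷) at
learning rate 0.002; batch size 200 (CNN) or 128 (CNN-LSTM); 3 training
iterations for CNNs and 8 for the CNN-LSTM, where one *iteration* is one
pass over the frame set ("epoch" is reserved for scoring epochs).
Consecutive frames differ in two samples only, so the frame set is highly
redundant and performance typically saturates within one iteration; a
configurable frame stride (default 1) thins it for desk-scale runs.
Frames are drawn without repetition in a seeded permutation.  Class
imbalance (wake ≈ 89 % of MWT time) is countered with weights inversely
proportional to class frequency, normalized to mean 1 over the classes
present (absent classes get weight 0 and a warning); uniform weighting is
available as an ablation.  Each training frame draws its EEG channel at
random from the two occipital derivations (O1M2/O2M1) — cheap
augmentation that roughly doubles the training set; evaluation uses O1M2.

The neural-network layer stack, backpropagation (including BPTT for the
LSTM) and the Nadam optimizer are implemented in numpy inside
`microsleep.nn`, with float64 arithmetic throughout; every backward pass
is verified against central finite differences in the test suite.  Batch
normalization keeps running statistics with momentum 0.9 (chosen so the
inference statistics converge within the ~100 batches of a desk-scale
iteration) and uses them at inference.

## Preprocessing

Signal conditioning is a zero-phase Fourier filter: FFT over the whole
recording, zero all bins strictly below 0.5 Hz or strictly above 45 Hz
(bins at exactly 0.5/45 Hz are retained), inverse FFT.  It is applied to
all channels identically, before windowing, making the pipeline
device-agnostic; it is idempotent and leaves passband content untouched
to ~1e−9.  No artifact rejection or notch filtering is performed.

Interval scorings convert to per-sample tracks on a half-open grid:
seconds map to samples as ⌊t·fs⌋ inclusive start, exclusive end (with a
10⁻⁶-sample guard against binary-float droop, e.g. 36.66 × 200 evaluating
to 7331.999…); unscored samples are wake.  Run extraction is the exact
inverse on the grid.  Consolidated-sleep events (SLEEP, > 15 s) rasterize
to MSE for training targets by default.  Even-length windows take their
center at offset ⌊L/2⌋ from the window start.

## Evaluation protocol

Agreement is Cohen's kappa, computed **one-vs-rest per class**: class k
maps to 1, everything else to 0, and κ = (p_o − p_e)/(1 − p_e) from the
binary contingency table.  Because some recordings lack entire classes,
recordings are concatenated (sorted by id) before computing kappa — a
single pooled value per class, with no per-recording error bars by
construction.  When p_e = 1 (both tracks constant and identical, e.g. an
all-wake recording scored perfectly) kappa is returned as 0 with a
degenerate flag: correct but carrying no evidence of skill.  Argmax
tie-breaks take the lowest class index.  Predictions at coarser strides
(including the CNN-LSTM's 0.25 s grid) are expanded to per-sample tracks
by nearest-center assignment before evaluation, which is done at full
per-sample resolution by default.  For display, tracks may be coarsened
to 0.5 s by per-interval majority vote (ties inherit the previous
interval's label, or wake at the start; the operation is idempotent).

## Feature visualization

The best CNN can be built with one extra 64-filter convolutional layer
(kernel 3, zero-padded — the temporal extent is already 1 at that depth)
whose output is a 64-d feature vector per window; the layer is trained
jointly.  Features are extracted at every 100th window center by default
and embedded in 2-D with t-SNE (perplexity 30, PCA initialization, fixed
seed).  The embedding reflects the network's internal representation, not
ground truth; hyperparameters are documented defaults, and the associated
test asserts cluster preservation on synthetic Gaussians rather than any
particular layout.

## Synthetic data: what it emulates, and what it does not

The generator produces 40-min, 200 Hz, four-channel recordings (O1M2,
O2M1, E1M1, E2M1) with scored events, at the class composition of
clinical MWT data: 8 % MSE, 1 % MSEc, 2 % ED, remainder wake.  MSE
durations are uniform on 1–15 s; event budgets are realized to within a
fraction of one event and laid out with ≥ 3 s wake gaps.

* **Rhythms.** Alpha and theta are amplitude-modulated sinusoids (carrier
  drawn per recording from the band interior, envelope varying ≤ 1 Hz
  within [0.5, 1.5]) switched by per-class envelopes: wake has alpha on /
  theta off, MSE the reverse (alpha residual 0.05).  A sustained rhythm
  whose *presence* is the class signature is the modeling intent; a
  band-filtered-noise alternative was rejected because its envelope fades
  make stretches of wake spectrally indistinguishable from the borderline
  classes.  Broadband 0.5–45 Hz background noise (σ = 8 μV) overlays
  everything; the two EEG channels share the rhythm components (bilateral
  episodes) with independent background.
* **EOG.** Both derivations reference the left mastoid.  Blinks during
  wake are biphasic 0.3 s transients (~150 μV) with equal polarity on
  both channels; each MSE is preceded by a 3 s slow-eye-movement epoch
  (0.2–0.6 Hz, σ = 100 μV) with *opposite* polarity on E1M1/E2M1
  (horizontal roll), continuing at half amplitude into the episode.
* **Borderline classes.** MSEc and ED are intermediate mixtures: each
  event draws independent alpha and theta envelope levels from
  U(0.35, 0.75), with identical distributions for the two classes, so
  nothing in the signal separates MSEc from ED.
* **Determinism.** One integer seed fixes everything bit-for-bit; cohorts
  derive per-recording seeds from a master seed via a seed sequence and
  can be split train/val/test 70/15/15 by largest-remainder apportionment
  (remainder ties resolved in train/val/test order).

`validate_simulation` self-checks each recording: theta/alpha band-power
ordering between MSE and wake, realized class budgets within ±20 %
relative (enforced from 10 min duration upward — shorter recordings
cannot realize a 1 % class), MSE durations within 1–15 s, and EOG
anti-correlation < −0.5 in slow-eye-movement epochs.

**Limitations.**  The synthetic signal has crisp state boundaries, exact
band structure, and no artifacts, ECG crosstalk, electrode drift or
inter-subject variability; passing the end-to-end test demonstrates that
the pipeline recovers the generative parameters under its own
assumptions, not clinical-grade performance.  Two consequences deserve
emphasis.  First, held-out per-class kappas for wake and MSE on synthetic
cohorts (≈ 0.9) exceed what the same protocol achieves on patient data
(≈ 0.6–0.7), where boundary ambiguity is real rather than simulated.
Second, because simulated borderline events have a *consistent*
intermediate signature, a 4-class network can partially detect their
union and the larger borderline class inherits moderate one-vs-rest
kappa; in real recordings borderline-ness itself is rater-dependent and
agreement on MSEc/ED is near zero.  The evaluation therefore gates only
wake and MSE recovery, and demonstrates the near-zero borderline
convention with a detector that does not emit borderline labels (whose
MSEc/ED kappa is exactly 0 by the one-vs-rest convention).

## Numerical and interface conventions

* EDF I/O: 16-bit encoding over a declared physical range (default
  ±3276.8 μV → 0.1 μV per digit); 1 s data records, so recordings must be
  whole seconds; fixed header timestamps make equal data byte-identical
  files.  Reading goes through MNE and fails (never resamples) on
  mixed or unexpected sampling rates; a write→read round trip crosses two
  independent codecs and agrees within one quantization step.
* Scoring CSV: `label,start_s,end_s`, UTF-8, `.` decimal point,
  case-insensitive labels in {W, MSE, MSEc, ED, SLEEP}; intervals are
  half-open, validated non-overlapping (adjacent events may touch);
  floats are written as their shortest exact representation so round
  trips are equal, not merely close.  Foreign layouts plug in via
  `read_events(parser=...)`.
* Checkpoints: weights in a `.npz` plus a JSON sidecar of the model
  specification; the CLI writes a `manifest.json` (command, config,
  seeds, package version) next to every output set.
* Desk-scale problem sizes used in tests: 2-min recordings for I/O and
  windowing; one 40-min recording for generator statistics; a 20 × 5 min
  cohort (14 train / 6 held-out), frame stride 50, one training
  iteration, evaluation stride 25 for the end-to-end recovery check.
  These sizes are the package's own test-design choices; all are
  configurable.
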