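# microsleep

Per-sample detection of microsleep episodes in raw EEG/EOG with
sliding-window convolutional networks.

Microsleep episodes (MSEs) are sleep fragments of 1–15 s — an occipital
EEG slowing from the waking alpha rhythm (8–12 Hz) to theta dominance
(4–7 Hz), usually preceded by slow eye movements in the EOG.  Standard
30 s-epoch scoring of the maintenance-of-wakefulness test (MWT) cannot
resolve them, and manual sub-epoch scoring is laborious.  This package is
for sleep researchers and clinicians' analysts who want automatic,
sample-resolution (200 Hz) segmentation of MWT-style recordings into
wake (W), MSE, MSE candidate (MSEc) and episode of drowsiness (ED),
together with the evaluation and visualization protocol that goes with
it — plus a synthetic EEG/EOG generator so the entire pipeline runs and
is tested without any patient data.

## Method in brief

A 1-D CNN classifies a window of raw signal (one occipital derivation
O1M2 or O2M1 plus two EOG derivations E1M1/E2M1, bandpass 0.5–45 Hz,
scaled to [−1, 1]) and assigns the label to the window's **central
sample**; sliding at stride 1 labels every sample.  The network is a
stack of blocks `conv(N filters, length 3) → batch-norm → ReLU →
max-pool(2)`; the final block is repeated once more per doubling of the
window length (3× at 2 s … 7× at 32 s) on top of four fixed blocks with
filter ladder 8→16→32→64, so every supported window collapses to
temporal extent 1 and the last receptive field spans the whole window.
Training uses Nadam (lr 0.002), batch 200, weighted cross-entropy with
weights ∝ 1/class-frequency, and random choice between the two occipital
derivations per frame as augmentation.  A CNN-LSTM variant applies a 1 s
CNN at 0.25 s stride and labels each window with an LSTM (2 classes,
gradient clipping at norm 1).  Detected runs get the duration criteria
post hoc: MSE < 1 s dropped, > 15 s relabeled consolidated sleep.

Agreement is evaluated with one-vs-rest Cohen's kappa per class,
κ = (p_o − p_e)/(1 − p_e), on recordings concatenated across subjects;
an all-wake recording scored perfectly yields κ = 0 with a degenerate
flag (correct, but no evidence of skill).  Internal 64-d features from
an appended convolutional layer can be embedded in 2-D with t-SNE.

Everything runs on plain numpy — the layer stack, backpropagation, the
LSTM and the Nadam optimizer live in `microsleep.nn` and are verified
against finite differences in the test suite.  See `docs/methods.md`
for modeling details and limitations.

## Worked example

`examples/02_train_and_detect.py` simulates ten 5-min recordings, trains
a 2 s-window CNN (two training iterations, frame stride 50) and scores a
held-out recording:

```
inverse-frequency class weights (W, MSE, MSEc, ED): [0.027 0.306 2.445 1.222]
trained on 7 recordings, loss 1.928 → 0.592
detected MSE     74.50–  89.00 s (14.50 s)
detected MSE    192.50– 204.00 s (11.50 s)
reference MSEs: ['75.30–88.46', '192.93–203.76']
per-class kappa on the held-out recording: {'W': 0.885, 'MSE': 0.954, 'MSEC': 0.399, 'ED': 0.767}
```

The weights show the class imbalance (wake is ~89 % of MWT time, so it
gets weight 0.027 while the rare candidate class gets 2.445); the two
detected episodes bracket the scored ones to within about a second; and
per-class kappa is high for wake and MSE.  The borderline classes are
intermediate alpha/theta mixtures with no signal distinguishing MSEc
from ED, so their single-recording kappas are erratic by design.

Other examples: `01_simulate_cohort.py` (generator + self-validation),
`03_agreement_evaluation.py` (kappa conventions), `04_feature_embedding.py`
(t-SNE of internal features).  The same pipeline is available as a CLI:

```sh
microsleep simulate --n 10 --seed 1 --duration-s 300 --out data
microsleep train --data data --out ckpt/cnn16.npz --window 16 --stride 50
microsleep predict --model ckpt/cnn16.npz --edf data/sim008.edf --out preds
microsleep evaluate --pred preds --ref data --out report.json
```

Real EDF exports are read with `read_recording(path, channel_map=...)`,
where the map builds derivations such as `O1M2 = O1 − M2`; scorings use
a `label,start_s,end_s` CSV (foreign layouts plug in via
`read_events(parser=...)`).

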