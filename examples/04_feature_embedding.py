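"""Visualize the network's internal representation with t-SNE.

Trains a small CNN carrying the extra 64-filter convolutional layer whose
output serves as a 64-d feature vector per window, extracts features at
every 25th window center of a held-out recording, and projects them to
2-D with seeded t-SNE.  In a well-trained detector, wake and microsleep
form two clusters; borderline episodes fall between them.
"""

import numpy as np

from microsleep import (
    ModelSpec,
    SamplerConfig,
    SimConfig,
    TrainConfig,
    build_cnn,
    class_weights,
    extract_features,
    filter_recording,
    generate_cohort,
    plot_embedding,
    rasterize_events,
    sample_batches,
    train,
    tsne_embed,
)

cohort = generate_cohort(6, SimConfig(duration_s=300.0), seed=21, split=True)
prepared = [
    (filter_recording(c.recording),
     rasterize_events(c.events, c.recording.n_samples, c.recording.fs),
     c.split)
    for c in cohort
]
train_pairs = [(r, t) for r, t, s in prepared if s == "train"]
held_rec, held_track, _ = next(p for p in prepared if p[2] != "train")

model = build_cnn(ModelSpec(kind="cnn", window_s=2, feature_layer=True), seed=3)
weights = class_weights(np.concatenate([t.labels for _, t in train_pairs]))
train(
    model,
    lambda it: sample_batches(
        train_pairs, SamplerConfig(window_s=2, stride=50, seed=3),
        np.random.default_rng(it),
    ),
    TrainConfig(iterations=1, class_weights=weights),
)

feats = extract_features(model, held_rec, held_track, subsample=25,
                         channels=["O1M2", "E1M1", "E2M1"])
print(f"extracted {feats.vectors.shape[0]} feature vectors of length "
      f"{feats.vectors.shape[1]}")

coords = tsne_embed(feats, seed=0)
plot_embedding(coords, feats.labels, "scratch_example_tsne.png")
print("wrote scratch_example_tsne.png — wake (blue) and MSE (red) should "
      "separate into two clusters; borderline classes sit at the interface")
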