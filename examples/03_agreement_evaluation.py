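"""Per-class Cohen's kappa and its conventions on small worked cases.

The evaluation protocol binarizes each class one-vs-rest and computes
kappa on recordings concatenated across subjects.  Two conventions
matter in practice and are shown here: the degenerate all-one-class case
(kappa 0 with a flag, not 1), and the insensitivity of pooled kappa to
recording order.
"""

import numpy as np

from microsleep import Label, cohen_kappa, per_class_kappa, pooled_evaluation

rng = np.random.default_rng(0)

# perfect agreement on a mixed sequence → kappa 1
a = np.array([0, 0, 1, 1, 0, 1])
print("identical mixed sequences:", cohen_kappa(a, a))

# agreement no better than chance → kappa 0
print("chance-level agreement:  ",
      cohen_kappa(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])))

# a recording that is entirely wake, scored entirely wake: the observed
# agreement is perfect but so is chance agreement → kappa 0, flagged
all_wake = np.zeros(1000, dtype=int)
print("all-wake vs all-wake:    ", cohen_kappa(all_wake, all_wake))

# per-class kappa over a 4-class pair with one absent class
ref = rng.integers(0, 3, 2000)          # MSEc (class 2) never occurs
pred = np.where(rng.random(2000) < 0.9, ref, rng.integers(0, 3, 2000))
for cls, res in per_class_kappa(ref, pred).items():
    print(f"  kappa({cls.name:4s}) = {res.value:6.3f}  degenerate={res.degenerate}")

# pooling recordings: kappa of the concatenation, order-invariant
tracks_ref = {"a": ref[:1000], "b": ref[1000:]}
tracks_pred = {"a": pred[:1000], "b": pred[1000:]}
rep = pooled_evaluation(tracks_pred, tracks_ref)
print("pooled:", {k: round(v, 3) for k, v in rep.per_class_kappa.items()})
print(rep.note)
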