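"""The ordinal evaluation metrics on hand-constructed predictions.

macro-AUC averages one-vs-rest AUCs so minority classes count equally; the
ranked probability score (RPS) compares *cumulative* predicted and observed
class distributions, so probability mass placed on a class near the truth is
penalized less than mass far away — the property that makes it the natural
score for ordered categories.
"""

import numpy as np

from osnn.metrics import accuracy, macro_auc, rps

y = np.array([1, 2, 3])

sharp_correct = np.eye(3)[[0, 1, 2]]
uniform = np.full((3, 3), 1 / 3)
near_miss = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25], [0.0, 0.5, 0.5]])
far_miss = np.array([[0.5, 0.0, 0.5], [0.25, 0.5, 0.25], [0.5, 0.0, 0.5]])

for name, probs in [("sharp correct", sharp_correct), ("uniform", uniform),
                    ("near miss", near_miss), ("far miss", far_miss)]:
    labels = 1 + probs.argmax(axis=1)
    print(f"{name:14s} macro-AUC={macro_auc(probs, y):.3f} "
          f"RPS={rps(probs, y):.3f} accuracy={accuracy(labels, y):.3f}")
# Note the RPS ordering: sharp correct (0) < near miss < far miss, while plain
# accuracy cannot distinguish near from far misses.
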