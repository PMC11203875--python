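"""Train the moth/noise SVM and look at its two trajectory features.

Real flight covers ground with consistent heading (high positional SD,
low turning-angle SD over the last 10 frames); transient stereo noise
jitters in place with near-reversing direction.  A linear SVM on the
two standardised features separates the regimes.
"""

import numpy as np

from mothflight import extract_features, train_classifier
from mothflight.simulate import make_training_paths

train_paths, train_labels = make_training_paths(200, seed=0)
feats = [extract_features(p, 10) for p in train_paths]
model = train_classifier(feats, train_labels, seed=0)

for label in ("moth", "noise"):
    sel = [f for f, l in zip(feats, train_labels) if l == label]
    sd_pos = np.mean([f.sd_position_m for f in sel])
    sd_turn = np.mean([f.sd_turning_deg for f in sel])
    print(f"{label:5s}: mean sd_position {sd_pos * 100:.2f} cm, mean sd_turning {sd_turn:.1f} deg")

test_paths, test_labels = make_training_paths(200, seed=1)
preds = [model.predict(extract_features(p, 10)) for p in test_paths]
acc = np.mean([p == t for p, t in zip(preds, test_labels)])
print(f"held-out accuracy: {acc:.1%} on {len(test_paths)} trajectories")
print(f"model: w={model.weights.round(3)}, b={model.bias:.3f}")
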