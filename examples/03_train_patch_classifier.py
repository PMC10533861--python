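"""Train the residual patch classifier on separable synthetic patches.

Builds the full-census network (39 convolutional layers, 1 average
pooling, 1 fully connected; 5x24x24 input) and trains it with the
Nesterov-Adam optimizer (learning rate 0.002, beta_1 0.9, beta_2 0.999,
epsilon 1e-8, schedule decay 0.004) on blob-like (aneurysm) versus
tube-like (vessel) patches.  With clean, separable classes the held-out
AUC approaches 1 after a few epochs; the per-epoch losses show the
optimization converging.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from aneucad.nnet import ArchitectureSpec, TrainingConfig, build_model, train

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))
from conftest import make_patch_dataset  # programmatic blob/tube patches

x, y = make_patch_dataset(300, seed=0)
x_train, y_train, x_test, y_test = x[:240], y[:240], x[240:], y[240:]

model = build_model(ArchitectureSpec(), seed=0)
print("layer census:", model.layer_census())

train(model, x_train, y_train, TrainingConfig(epochs=5, seed=0))
print("train loss per epoch:", [round(l, 4) for l in model.history["train_loss"]])

auc = roc_auc_score(y_test, model.score_patches(x_test))
print(f"held-out AUC on {len(y_test)} patches: {auc:.3f}")
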