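"""Train the dual-sequence lesion classifier with the multi-reader loss on
a small planted-lesion corpus and evaluate held-out per-lesion AUC against
inter-consensus labels.

Reduced budget (30 patients, 150 steps, ~1 min); the acceptance benchmark
uses 100 patients and 400 steps.
"""

import numpy as np

from sijkit.classify import (
    ClassifierConfig,
    crossval_split,
    evaluate_by_lesion,
    predictions_frame,
    train_classifier,
)
from sijkit.synth import make_lesion_dataset

rng = np.random.default_rng(0)
dataset, label_table, truth = make_lesion_dataset(30, rng=rng)
subjects = sorted({sid.split("_")[0] for sid, _ in dataset})
held_out = set(crossval_split(subjects, 5, seed=0).subjects_in_fold(0))
train_ds = [(s, p) for s, p in dataset if s.split("_")[0] not in held_out]
test_ds = [(s, p) for s, p in dataset if s.split("_")[0] in held_out]
print(f"{len(train_ds)} training SIJs, {len(test_ds)} held-out SIJs "
      f"({len(label_table.df)} reader labels)")

config = ClassifierConfig(steps=150, batch_size=16, seed=0)
model, history = train_classifier(train_ds, config, label_table)
print(f"training loss: {history['train'][0]:.2f} -> {history['train'][-1]:.2f}")

preds = predictions_frame(model, test_ds)
print()
print("held-out metrics against inter-consensus labels:")
for lesion, rep in sorted(evaluate_by_lesion(preds, label_table).items()):
    auc = "undefined" if rep.auc is None else f"{rep.auc:.3f}"
    print(f"  {lesion:10s} AUC {auc}  BA {rep.balanced_accuracy:.3f}  n={rep.n}")
print()
print("AUC is the rank statistic of root-node positive probabilities;")
print("samples whose readers never reached consensus are excluded.")
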