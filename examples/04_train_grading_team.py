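"""Train a small multi-diagnosis team on strong-signal synthetic grades.

Trains one cross-entropy base sub-model and one focal (gamma = 1)
sub-model on clearly separable synthetic grading patches, fuses their
frozen features with a two-layer head, and compares test accuracies.
Takes a couple of minutes on one CPU.
"""

import numpy as np

import avgrade as ag
from avgrade.models import MDTNetConfig, PatchDataset, SubModelSpec, train_mdtnet

spec = ag.SceneSpec(
    image_size=(300, 300),
    n_crossings=1,
    noise_level=0.0,
    z_order_artery_over_prob=1.0,
    grade_distribution=(0.25, 0.25, 0.25, 0.25),
    narrowing_profile={
        "none": (1.0, 1.0), "mild": (0.75, 0.75),
        "moderate": (0.5, 1.0), "severe": (0.5, 0.5),
    },
    seed=42,
)
ds = ag.generate_dataset(spec, n_scenes=400, subjects=40)
patches = PatchDataset.from_patches(ds.patches, "grade")
assignment = ag.group_split(ds.manifest, seed=0)
splits = ds.manifest["subject_id"].map(assignment.subject_to_split).to_numpy()
train, val, test = (
    patches.subset(np.where(splits == name)[0]) for name in ("train", "val", "test")
)
print(f"patches: {len(train)} train / {len(val)} val / {len(test)} test")

weights = ag.compute_class_weights(train.class_counts(4)).weights
config = MDTNetConfig(base_specs=[SubModelSpec("tiny")], n_focal=1, n_classes=4, fusion_hidden=64)
ensemble = train_mdtnet(config, train, val, epochs=12, lr=3e-3, seed=1, class_weights=weights)

for m in ensemble.submodels:
    acc = float((m.predict_batches(test) == test.labels).mean())
    print(f"sub-model (gamma={m.spec.loss.gamma:.0f}) test accuracy: {acc:.3f}")
pred = ensemble.predict_batches(test)
acc = float((pred == test.labels).mean())
kappa = ag.cohen_kappa(ag.confusion_matrix(test.labels, pred, 4))
print(f"fused team test accuracy: {acc:.3f}, kappa: {kappa:.3f}")
print("the fused decision should match or beat the best single sub-model")
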