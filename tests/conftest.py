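"""Shared fixtures: strong-signal synthetic data and small trained models.

Model training is expensive relative to the rest of the suite, so trained
models are session-scoped and reused by the model, pipeline and acceptance
tests.  Everything is seeded; fixtures are deterministic across runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import avgrade as ag
from avgrade.models import MDTNetConfig, PatchDataset, SubModelSpec, train_mdtnet, train_submodel

#: narrowing factors far apart: the easy, clearly-separable grading regime
STRONG_NARROWING = {
    "none": (1.0, 1.0),
    "mild": (0.75, 0.75),
    "moderate": (0.5, 1.0),
    "severe": (0.5, 0.5),
}


def strong_grading_spec(seed: int = 42, image_size: int = 300) -> ag.SceneSpec:
    """Noise-free scenes, one valid crossing each, balanced grades."""
    return ag.SceneSpec(
        image_size=(image_size, image_size),
        n_crossings=1,
        noise_level=0.0,
        z_order_artery_over_prob=1.0,
        grade_distribution=(0.25, 0.25, 0.25, 0.25),
        narrowing_profile=dict(STRONG_NARROWING),
        seed=seed,
    )


def strong_validity_spec(seed: int = 7, image_size: int = 300) -> ag.SceneSpec:
    """Noise-free scenes with a mix of valid and invalid crossings."""
    return ag.SceneSpec(
        image_size=(image_size, image_size),
        n_crossings=1,
        noise_level=0.0,
        z_order_artery_over_prob=0.55,
        seed=seed,
    )


def split_dataset(ds: ag.SyntheticDataset, task: str, seed: int = 0):
    """Subject-grouped 8:1:1 split of a synthetic dataset into PatchDatasets."""
    patches = PatchDataset.from_patches(ds.patches, task)
    if task == "grade":
        keep = ds.manifest["grade"].ne("")
    else:
        keep = ds.manifest["is_valid"].notna()
    assignment = ag.group_split(ds.manifest, seed=seed)
    splits = ds.manifest.loc[keep, "subject_id"].map(assignment.subject_to_split).to_numpy()
    return tuple(
        patches.subset(np.where(splits == name)[0]) for name in ("train", "val", "test")
    )


@pytest.fixture(scope="session")
def grading_data():
    """~160 strong-signal graded patches split 8:1:1 by subject."""
    ds = ag.generate_dataset(strong_grading_spec(seed=42), n_scenes=160, subjects=40)
    return split_dataset(ds, "grade", seed=0)


@pytest.fixture(scope="session")
def validity_data():
    """~400 strong-signal validity patches split 8:1:1 by subject."""
    ds = ag.generate_dataset(strong_validity_spec(seed=7), n_scenes=400, subjects=40)
    return split_dataset(ds, "validity", seed=0)


@pytest.fixture(scope="session")
def validity_model(validity_data):
    """A single tiny sub-model trained well on the validity task."""
    train, val, _ = validity_data
    return train_submodel(SubModelSpec("tiny"), train, val, epochs=16, lr=3e-3, seed=3)


@pytest.fixture(scope="session")
def grading_ensemble(grading_data):
    """A small but functional grading team (one base + one focal sub-model)."""
    train, val, _ = grading_data
    config = MDTNetConfig(
        base_specs=[SubModelSpec("tiny")], n_focal=1, n_classes=4, fusion_hidden=64
    )
    weights = ag.compute_class_weights(train.class_counts(4)).weights
    return train_mdtnet(config, train, val, epochs=8, lr=3e-3, seed=11, class_weights=weights)


@pytest.fixture(scope="session")
def model_dir(tmp_path_factory, validity_model, grading_ensemble):
    """Checkpoint directory holding the validity model and grading ensemble."""
    from avgrade.models import save_ensemble, save_submodel

    path = tmp_path_factory.mktemp("models")
    save_submodel(validity_model, path / "validity")
    save_ensemble(grading_ensemble, path / "grading")
    return path
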