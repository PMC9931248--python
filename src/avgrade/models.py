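"""Crossing validity and severity-grading models, and the MDTNet ensemble.

The grading model is a *multi-diagnosis team*: several convolutional
sub-models are trained independently on the same patches — a *base module*
of distinct architectures trained with cross-entropy, and a *focal module*
of sub-models sharing one architecture but trained with focal losses of
increasing focusing strength (gamma = 1..n).  Their penultimate-layer
features are then concatenated and a small two-layer fusion head (ReLU
between the layers, softmax on top) is trained on the frozen features to
produce the final decision.  Ensembling over gammas sidesteps tuning the
focal loss's hyperparameter: sub-models with different gammas attend to
different cues and the fusion head arbitrates.

The validity classifier (true vs false crossing) is a single sub-model
trained with cross-entropy — a plain classifier suffices for that easier,
better-balanced task.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .detect import LabeledPatch
from .losses import LossSpec
from .metrics import cohen_kappa, confusion_matrix
from .scene import GRADE_TO_INDEX

# ---------------------------------------------------------------------------
# architecture registry


def _build_tiny(rng: np.random.Generator, n_classes: int) -> nn.Sequential:
    return nn.Sequential(
        nn.AvgPool2d(4),
        nn.Conv2d(3, 8, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(8, 16, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(16, 32, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Flatten(),
        nn.Linear(32 * 4 * 4, 64, rng), nn.ReLU(),
        nn.Linear(64, n_classes, rng),
    )


def _build_wide(rng: np.random.Generator, n_classes: int) -> nn.Sequential:
    return nn.Sequential(
        nn.AvgPool2d(4),
        nn.Conv2d(3, 16, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(16, 32, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(32, 64, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Flatten(),
        nn.Linear(64 * 4 * 4, 96, rng), nn.ReLU(),
        nn.Linear(96, n_classes, rng),
    )


def _build_deep(rng: np.random.Generator, n_classes: int) -> nn.Sequential:
    return nn.Sequential(
        nn.AvgPool2d(2),
        nn.Conv2d(3, 8, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(8, 16, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(16, 32, rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(32, 48, rng), nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Linear(48, 80, rng), nn.ReLU(),
        nn.Linear(80, n_classes, rng),
    )


def _build_smooth(rng: np.random.Generator, n_classes: int) -> nn.Sequential:
    return nn.Sequential(
        nn.AvgPool2d(4),
        nn.Conv2d(3, 12, rng), nn.ReLU(), nn.AvgPool2d(2),
        nn.Conv2d(12, 24, rng), nn.ReLU(), nn.AvgPool2d(2),
        nn.Conv2d(24, 48, rng), nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Linear(48, 72, rng), nn.ReLU(),
        nn.Linear(72, n_classes, rng),
    )


#: architecture_id -> (builder, feature_dim)
ARCHITECTURES: dict[str, tuple] = {
    "tiny": (_build_tiny, 64),
    "compact-wide": (_build_wide, 96),
    "compact-deep": (_build_deep, 80),
    "compact-smooth": (_build_smooth, 72),
}


@dataclasses.dataclass
class SubModelSpec:
    """One team member: an architecture paired with a loss."""

    architecture_id: str = "tiny"
    loss: LossSpec = dataclasses.field(default_factory=LossSpec)
    pretrained: bool = False
    feature_dim: int = 0

    def __post_init__(self) -> None:
        if self.architecture_id not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture_id!r}; "
                f"registered: {sorted(ARCHITECTURES)}"
            )
        registry_dim = ARCHITECTURES[self.architecture_id][1]
        if self.feature_dim == 0:
            self.feature_dim = registry_dim
        elif self.feature_dim != registry_dim:
            raise ValueError(
                f"feature_dim {self.feature_dim} does not match "
                f"{self.architecture_id!r}'s penultimate width {registry_dim}"
            )
        if self.pretrained:
            raise ValueError(
                "no pretrained weights ship with this package; "
                "set pretrained=False and train from scratch"
            )


@dataclasses.dataclass
class MDTNetConfig:
    """Ensemble layout: base sub-models, focal-module size and fusion head."""

    base_specs: list[SubModelSpec] = dataclasses.field(
        default_factory=lambda: [SubModelSpec("tiny")]
    )
    n_focal: int = 3
    focal_architecture_id: str | None = None  # default: first base architecture
    fusion_hidden: int = 256
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.n_focal not in (0, 1, 2, 3):
            raise ValueError("n_focal must be in {0, 1, 2, 3}")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 (validity) or 4 (grades)")
        if not self.base_specs:
            raise ValueError("at least one base sub-model is required")

    def focal_specs(self, class_weights: np.ndarray | None = None) -> list[SubModelSpec]:
        arch = self.focal_architecture_id or self.base_specs[0].architecture_id
        return [
            SubModelSpec(arch, loss=LossSpec(gamma=float(g), class_weights=class_weights))
            for g in range(1, self.n_focal + 1)
        ]

    @property
    def fused_width_of(self) -> int:
        """Fusion input width = sum of sub-model feature dims."""
        arch = self.focal_architecture_id or self.base_specs[0].architecture_id
        return sum(s.feature_dim for s in self.base_specs) + self.n_focal * ARCHITECTURES[arch][1]


# ---------------------------------------------------------------------------
# datasets


class PatchDataset:
    """Labelled patches as a training-ready array pair.

    ``task='validity'`` labels every patch 0 (false crossing) / 1 (true);
    ``task='grade'`` keeps only valid patches and labels them 0..3 by grade.
    """

    def __init__(self, images: np.ndarray, labels: np.ndarray):
        if len(images) != len(labels):
            raise ValueError("images and labels disagree in length")
        if len(images) == 0:
            raise ValueError("dataset is empty")
        self.images = np.asarray(images, dtype=np.uint8)
        self.labels = np.asarray(labels, dtype=np.int64)

    @classmethod
    def from_patches(cls, patches: list[LabeledPatch], task: str) -> "PatchDataset":
        if task == "validity":
            keep = [p for p in patches if p.is_valid is not None]
            labels = [int(p.is_valid) for p in keep]
        elif task == "grade":
            keep = [p for p in patches if p.grade is not None]
            labels = [GRADE_TO_INDEX[p.grade] for p in keep]
        else:
            raise ValueError("task must be 'validity' or 'grade'")
        if not keep:
            raise ValueError(f"no patches usable for task {task!r}")
        return cls(np.stack([p.pixels for p in keep]), np.array(labels))

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "PatchDataset":
        return PatchDataset(self.images[idx], self.labels[idx])

    def tensor(self, idx=None) -> np.ndarray:
        imgs = self.images if idx is None else self.images[idx]
        return _to_tensor(imgs)

    def class_counts(self, n_classes: int) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)


def _to_tensor(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> centered float32 (N, 3, H, W)."""
    x = images.astype(np.float32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# sub-models


class SubModel:
    """A single CNN classifier whose penultimate activations act as features."""

    def __init__(self, spec: SubModelSpec, n_classes: int, seed: int = 0,
                 network: nn.Sequential | None = None, feature_dim: int | None = None):
        self.spec = spec
        self.n_classes = n_classes
        self.seed = seed
        rng = np.random.default_rng(seed)
        if network is None:
            builder, feature_dim = ARCHITECTURES[spec.architecture_id]
            network = builder(rng, n_classes)
        self.network = network
        self.feature_dim = feature_dim if feature_dim is not None else spec.feature_dim
        self.trained = False
        self.best_val: dict = {}
        self.history: list[dict] = []

    # -- forward helpers ----------------------------------------------------

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.network.forward(x)

    def features(self, x: np.ndarray) -> np.ndarray:
        out = x
        for layer in self.network.layers[:-1]:
            out = layer.forward(out)
        return out

    def last_spatial_index(self) -> int:
        """Index of the last layer with a spatial (4-D) output."""
        idx = None
        for i, layer in enumerate(self.network.layers):
            if isinstance(layer, (nn.GlobalAvgPool, nn.Flatten)):
                idx = i - 1
        if idx is None or idx < 0:
            raise ValueError("model has no spatial feature maps")
        return idx

    def predict_batches(self, ds: PatchDataset, batch_size: int = 64) -> np.ndarray:
        preds = []
        for i in range(0, len(ds), batch_size):
            z = self.logits(ds.tensor(slice(i, i + batch_size)))
            preds.append(z.argmax(axis=1))
        return np.concatenate(preds)


def train_submodel(
    spec: SubModelSpec,
    train: PatchDataset,
    val: PatchDataset,
    epochs: int = 20,
    lr: float = 0.0001,
    batch_size: int = 32,
    seed: int = 0,
    augment_config=None,
) -> SubModel:
    """Train one sub-model with its own loss, keeping the best-on-validation weights.

    After every epoch the validation accuracy (and, for the 4-class grading
    task, Cohen's kappa) is computed; the checkpoint with the highest
    validation accuracy is restored at the end.  Fully deterministic for a
    fixed seed, data and configuration.
    """
    n_classes = int(max(train.labels.max(), val.labels.max())) + 1
    if spec.loss.class_weights is not None and len(spec.loss.class_weights) != n_classes:
        raise ValueError("class_weights length does not match the number of classes")
    if (train.labels < 0).any() or (val.labels >= n_classes).any():
        raise ValueError("labels out of range")
    model = SubModel(spec, n_classes, seed=seed)
    opt = nn.Adam(model.network, lr=lr)
    rng = np.random.default_rng(seed + 1)
    aug_rng = np.random.default_rng(seed + 2)
    if augment_config is not None:
        from .augment import augment as _augment

    best_acc = -1.0
    best_state = model.network.state_dict()
    for epoch in range(epochs):
        order = rng.permutation(len(train))
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            imgs = train.images[idx]
            if augment_config is not None:
                imgs = np.stack(
                    [
                        _augment(LabeledPatch(img, (0, 0)), augment_config, aug_rng).pixels
                        for img in imgs
                    ]
                )
            x = _to_tensor(imgs)
            z = model.network.forward(x)
            loss, dz = nn.focal_loss_grad(
                z,
                train.labels[idx],
                gamma=spec.loss.gamma,
                class_weights=spec.loss.class_weights,
                floor=spec.loss.probability_floor,
            )
            model.network.backward(dz)
            opt.step()
        val_pred = model.predict_batches(val)
        acc = float((val_pred == val.labels).mean())
        entry = {"epoch": epoch, "val_accuracy": acc, "train_loss": loss}
        if n_classes == 4:
            entry["val_kappa"] = cohen_kappa(confusion_matrix(val.labels, val_pred, 4))
        model.history.append(entry)
        if acc > best_acc:
            best_acc = acc
            best_state = model.network.state_dict()
            model.best_val = dict(entry)
    model.network.load_state_dict(best_state)
    model.trained = True
    return model


def extract_features(model: SubModel, patch: LabeledPatch | np.ndarray) -> np.ndarray:
    """Penultimate-layer activation vector for one patch (inference mode)."""
    if not model.trained:
        raise ValueError("model is not trained")
    pixels = patch.pixels if isinstance(patch, LabeledPatch) else patch
    x = _to_tensor(pixels[None])
    return model.features(x)[0]


def _features_matrix(submodels: list[SubModel], ds: PatchDataset, batch_size: int = 64) -> np.ndarray:
    cols = []
    for m in submodels:
        feats = []
        for i in range(0, len(ds), batch_size):
            feats.append(m.features(ds.tensor(slice(i, i + batch_size))))
        cols.append(np.concatenate(feats))
    return np.concatenate(cols, axis=1).astype(np.float32)


# ---------------------------------------------------------------------------
# ensemble


class EnsembleModel:
    """Frozen sub-models plus a trained two-layer fusion head."""

    def __init__(self, config: MDTNetConfig, submodels: list[SubModel], fusion: nn.Sequential):
        self.config = config
        self.submodels = submodels
        self.fusion = fusion
        self.trained = False

    @property
    def fused_width(self) -> int:
        return sum(m.feature_dim for m in self.submodels)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        ds = PatchDataset(patches, np.zeros(len(patches), dtype=np.int64))
        feats = _features_matrix(self.submodels, ds)
        return nn.softmax(self.fusion.forward(feats))

    def predict_batches(self, ds: PatchDataset) -> np.ndarray:
        feats = _features_matrix(self.submodels, ds)
        return self.fusion.forward(feats).argmax(axis=1)


def build_and_train_fusion(
    config: MDTNetConfig,
    submodels: list[SubModel],
    train: PatchDataset,
    val: PatchDataset,
    seed: int = 0,
    epochs: int = 40,
    lr: float = 0.001,
    batch_size: int = 32,
) -> EnsembleModel:
    """Concatenate frozen sub-model features and train the two-layer head.

    Sub-model parameters are never touched: features are precomputed once
    and only the head's weights are optimized (cross-entropy, best-on-
    validation selection).
    """
    expected = len(config.base_specs) + config.n_focal
    if len(submodels) != expected:
        raise ValueError(f"config expects {expected} sub-models, got {len(submodels)}")
    for m in submodels:
        if not m.trained:
            raise ValueError("all sub-models must be pretrained before fusion")
    width = sum(m.feature_dim for m in submodels)
    rng = np.random.default_rng(seed)
    fusion = nn.Sequential(
        nn.Linear(width, config.fusion_hidden, rng),
        nn.ReLU(),
        nn.Linear(config.fusion_hidden, config.n_classes, rng),
    )
    f_train = _features_matrix(submodels, train)
    f_val = _features_matrix(submodels, val)
    opt = nn.Adam(fusion, lr=lr)
    shuffle_rng = np.random.default_rng(seed + 1)
    best_acc, best_state = -1.0, fusion.state_dict()
    for _ in range(epochs):
        order = shuffle_rng.permutation(len(train))
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            z = fusion.forward(f_train[idx])
            _, dz = nn.focal_loss_grad(z, train.labels[idx], gamma=0.0)
            fusion.backward(dz)
            opt.step()
        acc = float((fusion.forward(f_val).argmax(axis=1) == val.labels).mean())
        if acc > best_acc:
            best_acc, best_state = acc, fusion.state_dict()
    fusion.load_state_dict(best_state)
    ensemble = EnsembleModel(config, submodels, fusion)
    ensemble.trained = True
    return ensemble


def predict(model: EnsembleModel | SubModel, patch: LabeledPatch | np.ndarray) -> tuple[int, np.ndarray]:
    """Class label and softmax probability vector for one patch.

    Ties in the probability vector resolve to the lowest class index.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    pixels = patch.pixels if isinstance(patch, LabeledPatch) else patch
    if isinstance(model, EnsembleModel):
        probs = model.predict_proba(pixels[None])[0]
    else:
        probs = nn.softmax(model.logits(_to_tensor(pixels[None])))[0]
    return int(np.argmax(probs)), probs


def explain_prediction(
    model: EnsembleModel | SubModel,
    patch: LabeledPatch | np.ndarray,
    target_class: int,
    out_size: int | None = None,
) -> np.ndarray:
    """Gradient-weighted class-activation map for one patch.

    The map is computed on the designated sub-model's last spatial layer
    (for an ensemble: the first base sub-model, with gradients flowing
    through the fusion head).  Channel weights are the spatial means of the
    gradients; the weighted activation sum is rectified, normalized to
    [0, 1] and upsampled to the patch size.
    """
    pixels = patch.pixels if isinstance(patch, LabeledPatch) else patch
    out_size = out_size or pixels.shape[0]
    x = _to_tensor(pixels[None])
    sub = model.submodels[0] if isinstance(model, EnsembleModel) else model
    spatial_idx = sub.last_spatial_index()
    if isinstance(model, EnsembleModel):
        if not 0 <= target_class < model.config.n_classes:
            raise ValueError(f"target_class {target_class} out of range")
        # forward every sub-model (caching activations in the designated one)
        feats = [m.features(x) for m in model.submodels]
        fused = np.concatenate(feats, axis=1)
        logits = model.fusion.forward(fused)
        dy = np.zeros_like(logits)
        dy[0, target_class] = 1.0
        dfused = model.fusion.backward(dy)
        dfeat = dfused[:, : sub.feature_dim]
        # backprop the feature gradient through the sub-model's top layers
        layers = sub.network.layers
        d = dfeat
        for i in range(len(layers) - 2, spatial_idx, -1):
            d = layers[i].backward(d)
        grad = d
        acts = _recover_activation(sub, x, spatial_idx)
    else:
        if not 0 <= target_class < model.n_classes:
            raise ValueError(f"target_class {target_class} out of range")
        outs = sub.network.forward_collect(x)
        logits = outs[-1]
        dy = np.zeros_like(logits)
        dy[0, target_class] = 1.0
        grad = sub.network.backward_to(dy, spatial_idx)
        acts = outs[spatial_idx]
    weights = grad.mean(axis=(2, 3))  # (1, C)
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1)[0], 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    cam = _sk_resize(cam, (out_size, out_size), order=1, preserve_range=True, anti_aliasing=False)
    return np.clip(cam, 0.0, 1.0)


def _recover_activation(sub: SubModel, x: np.ndarray, spatial_idx: int) -> np.ndarray:
    out = x
    for layer in sub.network.layers[: spatial_idx + 1]:
        out = layer.forward(out)
    return out


# ---------------------------------------------------------------------------
# high-level training and checkpointing


def train_mdtnet(
    config: MDTNetConfig,
    train: PatchDataset,
    val: PatchDataset,
    epochs: int = 20,
    lr: float = 0.0001,
    batch_size: int = 32,
    seed: int = 0,
    class_weights: np.ndarray | None = None,
    augment_config=None,
) -> EnsembleModel:
    """Train the full team: base sub-models, focal sub-models, fusion head.

    Base sub-models use cross-entropy; focal sub-models share the
    architecture of the best-performing base sub-model (on validation
    accuracy) and use gamma = 1..n_focal.  Class weights, when given, are
    applied to every sub-model's loss.
    """
    submodels: list[SubModel] = []
    for k, spec in enumerate(config.base_specs):
        spec = dataclasses.replace(
            spec, loss=LossSpec(gamma=0.0, class_weights=class_weights)
        )
        submodels.append(
            train_submodel(
                spec, train, val, epochs=epochs, lr=lr, batch_size=batch_size,
                seed=seed + 101 * k, augment_config=augment_config,
            )
        )
    if config.focal_architecture_id is None and len(submodels) > 1:
        best = max(submodels, key=lambda m: m.best_val.get("val_accuracy", 0.0))
        config = dataclasses.replace(config, focal_architecture_id=best.spec.architecture_id)
    for k, spec in enumerate(config.focal_specs(class_weights)):
        submodels.append(
            train_submodel(
                spec, train, val, epochs=epochs, lr=lr, batch_size=batch_size,
                seed=seed + 1009 + 101 * k, augment_config=augment_config,
            )
        )
    return build_and_train_fusion(config, submodels, train, val, seed=seed + 5001)


def save_submodel(model: SubModel, path: str | Path) -> None:
    """Write weights (.npz) plus a JSON sidecar describing the run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.network.state_dict())
    sidecar = {
        "architecture_id": model.spec.architecture_id,
        "gamma": model.spec.loss.gamma,
        "class_weights": (
            None if model.spec.loss.class_weights is None
            else [float(w) for w in model.spec.loss.class_weights]
        ),
        "n_classes": model.n_classes,
        "seed": model.seed,
        "feature_dim": model.feature_dim,
        "best_val": model.best_val,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_submodel(path: str | Path) -> SubModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    weights = (
        None if meta["class_weights"] is None else np.asarray(meta["class_weights"])
    )
    spec = SubModelSpec(
        meta["architecture_id"], loss=LossSpec(gamma=meta["gamma"], class_weights=weights)
    )
    model = SubModel(spec, meta["n_classes"], seed=meta["seed"])
    state = dict(np.load(path.with_suffix(".npz")))
    model.network.load_state_dict(state)
    model.best_val = meta["best_val"]
    model.trained = True
    return model


def save_ensemble(model: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sub in enumerate(model.submodels):
        save_submodel(sub, directory / f"submodel_{i}")
    np.savez(directory / "fusion.npz", **model.fusion.state_dict())
    cfg = {
        "base_architectures": [s.architecture_id for s in model.config.base_specs],
        "n_focal": model.config.n_focal,
        "focal_architecture_id": model.config.focal_architecture_id,
        "fusion_hidden": model.config.fusion_hidden,
        "n_classes": model.config.n_classes,
        "n_submodels": len(model.submodels),
    }
    (directory / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    submodels = [
        load_submodel(directory / f"submodel_{i}") for i in range(cfg["n_submodels"])
    ]
    config = MDTNetConfig(
        base_specs=[SubModelSpec(a) for a in cfg["base_architectures"]],
        n_focal=cfg["n_focal"],
        focal_architecture_id=cfg["focal_architecture_id"],
        fusion_hidden=cfg["fusion_hidden"],
        n_classes=cfg["n_classes"],
    )
    width = sum(m.feature_dim for m in submodels)
    rng = np.random.default_rng(0)
    fusion = nn.Sequential(
        nn.Linear(width, config.fusion_hidden, rng),
        nn.ReLU(),
        nn.Linear(config.fusion_hidden, config.n_classes, rng),
    )
    fusion.load_state_dict(dict(np.load(directory / "fusion.npz")))
    model = EnsembleModel(config, submodels, fusion)
    model.trained = True
    return model
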