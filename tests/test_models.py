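"""Sub-model training, feature fusion, prediction and Grad-CAM contracts."""

import numpy as np
import pytest

import avgrade as ag
from avgrade import nn
from avgrade.losses import LossSpec
from avgrade.models import (
    ARCHITECTURES,
    EnsembleModel,
    MDTNetConfig,
    PatchDataset,
    SubModel,
    SubModelSpec,
    build_and_train_fusion,
    explain_prediction,
    extract_features,
    load_ensemble,
    load_submodel,
    predict,
    save_ensemble,
    save_submodel,
    train_submodel,
)


def tiny_run(train, val, epochs=2, seed=0, gamma=0.0):
    spec = SubModelSpec("tiny", loss=LossSpec(gamma=gamma))
    return train_submodel(spec, train, val, epochs=epochs, lr=3e-3, seed=seed)


@pytest.fixture(scope="module")
def quick_models(grading_data):
    """Two cheaply trained sub-models used for structural checks."""
    train, val, _ = grading_data
    return [tiny_run(train, val, seed=0), tiny_run(train, val, seed=1, gamma=1.0)]


class TestTrainSubmodel:
    def test_best_checkpoint_beats_first_epoch(self, grading_data):
        train, val, _ = grading_data
        model = tiny_run(train, val, epochs=4, seed=5)
        assert model.best_val["val_accuracy"] >= model.history[0]["val_accuracy"]

    def test_same_seed_reproduces_metrics_and_weights(self, grading_data):
        train, val, _ = grading_data
        a = tiny_run(train, val, seed=9)
        b = tiny_run(train, val, seed=9)
        assert a.history == b.history
        for key, value in a.network.state_dict().items():
            assert np.array_equal(value, b.network.state_dict()[key])

    def test_rejects_mismatched_class_weights(self, grading_data):
        train, val, _ = grading_data
        spec = SubModelSpec("tiny", loss=LossSpec(class_weights=np.array([0.5, 0.5])))
        with pytest.raises(ValueError):
            train_submodel(spec, train, val, epochs=1)

    def test_learns_strong_signal_grades(self, grading_data):
        """On clearly separable synthetic grades the tiny backbone reaches
        >= 0.80 validation accuracy within a short training run."""
        train, val, _ = grading_data
        model = tiny_run(train, val, epochs=14, seed=2)
        assert model.best_val["val_accuracy"] >= 0.80


class TestFeatures:
    def test_feature_vector_length_matches_spec(self, quick_models, grading_data):
        _, _, test = grading_data
        patch = ag.LabeledPatch(test.images[0], (75, 75))
        for model in quick_models:
            feats = extract_features(model, patch)
            assert feats.shape == (model.spec.feature_dim,)

    def test_inference_is_deterministic(self, quick_models, grading_data):
        _, _, test = grading_data
        patch = ag.LabeledPatch(test.images[0], (75, 75))
        f1 = extract_features(quick_models[0], patch)
        f2 = extract_features(quick_models[0], patch)
        assert np.array_equal(f1, f2)

    def test_distinct_patches_give_distinct_features(self, quick_models, grading_data):
        train, _, _ = grading_data
        i, j = int(np.argmax(train.labels == 0)), int(np.argmax(train.labels == 3))
        fi = extract_features(quick_models[0], ag.LabeledPatch(train.images[i], (75, 75)))
        fj = extract_features(quick_models[0], ag.LabeledPatch(train.images[j], (75, 75)))
        assert not np.array_equal(fi, fj)

    def test_untrained_model_refuses_feature_extraction(self):
        model = SubModel(SubModelSpec("tiny"), n_classes=4)
        with pytest.raises(ValueError, match="trained"):
            extract_features(model, np.zeros((150, 150, 3), dtype=np.uint8))


class TestFusion:
    def test_fused_width_is_sum_of_feature_dims(self):
        dims = {arch: ARCHITECTURES[arch][1] for arch in ARCHITECTURES}
        config = MDTNetConfig(
            base_specs=[SubModelSpec("tiny"), SubModelSpec("compact-wide")],
            n_focal=3,
            focal_architecture_id="compact-deep",
        )
        expected = dims["tiny"] + dims["compact-wide"] + 3 * dims["compact-deep"]
        assert config.fused_width_of == expected

    @pytest.mark.parametrize("n_focal", [0, 1])
    def test_fusion_freezes_submodels_bit_exact(self, grading_data, n_focal):
        train, val, _ = grading_data
        subs = [tiny_run(train, val, seed=10)]
        subs += [tiny_run(train, val, seed=11 + g, gamma=float(g + 1)) for g in range(n_focal)]
        before = [s.network.state_dict() for s in subs]
        config = MDTNetConfig(
            base_specs=[SubModelSpec("tiny")], n_focal=n_focal, n_classes=4, fusion_hidden=32
        )
        ensemble = build_and_train_fusion(config, subs, train, val, seed=0, epochs=3)
        for snap, model in zip(before, subs):
            after = model.network.state_dict()
            for key in snap:
                assert np.abs(snap[key] - after[key]).max() == 0
        assert ensemble.fused_width == (1 + n_focal) * 64

    def test_fusion_rejects_wrong_submodel_count(self, quick_models, grading_data):
        train, val, _ = grading_data
        config = MDTNetConfig(base_specs=[SubModelSpec("tiny")], n_focal=3, n_classes=4)
        with pytest.raises(ValueError, match="sub-models"):
            build_and_train_fusion(config, quick_models, train, val)


class TestPredict:
    def test_probabilities_sum_to_one(self, grading_ensemble, grading_data):
        _, _, test = grading_data
        label, probs = predict(grading_ensemble, ag.LabeledPatch(test.images[0], (75, 75)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert 0 <= label < 4

    def test_exact_tie_breaks_to_lower_index(self):
        assert int(np.argmax(np.array([0.4, 0.4, 0.2]))) == 0


class TestGradCam:
    def test_heatmap_shape_and_range(self, grading_ensemble, grading_data):
        _, _, test = grading_data
        heat = explain_prediction(grading_ensemble, test.images[0], target_class=2)
        assert heat.shape == (150, 150)
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_constant_output_model_gives_zero_map(self, grading_data):
        _, _, test = grading_data
        rng = np.random.default_rng(0)
        network = nn.Sequential(
            nn.Conv2d(3, 4, rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Linear(4, 2, rng),
        )
        network.layers[-1].params["W"][:] = 0.0  # constant logits -> zero gradients
        model = SubModel(SubModelSpec("tiny"), 2, network=network, feature_dim=4)
        model.trained = True
        heat = explain_prediction(model, test.images[0][:32, :32], target_class=0, out_size=32)
        assert heat.max() == 0.0

    def test_single_conv_oracle_peaks_at_bright_spot(self):
        """With one averaging conv filter and an identity head, the heatmap
        must peak where the input is brightest (analytic single-layer case)."""
        rng = np.random.default_rng(1)
        network = nn.Sequential(
            nn.Conv2d(3, 1, rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Linear(1, 2, rng),
        )
        network.layers[0].params["W"][:] = 1.0 / 27.0
        network.layers[0].params["b"][:] = 0.0
        network.layers[-1].params["W"][:] = np.array([[1.0, -1.0]])
        network.layers[-1].params["b"][:] = 0.0
        # mid-gray background normalizes to ~0 so the bright spot dominates
        img = np.full((40, 40, 3), 128, dtype=np.uint8)
        img[30, 12] = 255
        model = SubModel(SubModelSpec("tiny"), 2, network=network, feature_dim=1)
        model.trained = True
        heat = explain_prediction(model, img, target_class=0, out_size=40)
        peak = np.unravel_index(np.argmax(heat), heat.shape)
        assert abs(peak[0] - 30) <= 2 and abs(peak[1] - 12) <= 2


class TestCheckpointRoundTrip:
    def test_submodel_save_load_preserves_predictions(self, tmp_path, quick_models, grading_data):
        _, _, test = grading_data
        model = quick_models[0]
        save_submodel(model, tmp_path / "sub")
        loaded = load_submodel(tmp_path / "sub")
        assert np.array_equal(model.predict_batches(test), loaded.predict_batches(test))

    def test_ensemble_save_load_preserves_predictions(self, tmp_path, grading_ensemble, grading_data):
        _, _, test = grading_data
        save_ensemble(grading_ensemble, tmp_path / "ens")
        loaded = load_ensemble(tmp_path / "ens")
        assert np.array_equal(
            grading_ensemble.predict_batches(test), loaded.predict_batches(test)
        )


class TestSpecValidation:
    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="architecture"):
            SubModelSpec("resnet-50")

    def test_pretrained_flag_rejected(self):
        with pytest.raises(ValueError, match="pretrained"):
            SubModelSpec("tiny", pretrained=True)

    def test_feature_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature_dim"):
            SubModelSpec("tiny", feature_dim=128)

    def test_invalid_ensemble_configs_rejected(self):
        with pytest.raises(ValueError):
            MDTNetConfig(n_focal=5)
        with pytest.raises(ValueError):
            MDTNetConfig(n_classes=3)
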