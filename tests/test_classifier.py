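"""Patch classifiers: backbone structure, demo training, fusion."""

import numpy as np
import pytest
from sklearn.base import clone

from lungrpn.classifier import (
    Backbone,
    BackboneConfig,
    FusionRule,
    PatchClassifier,
    TrainConfig,
    _ResidualStage,
    build_backbone,
    classify_patches,
    fuse_multibackbone,
    load_checkpoint,
    save_checkpoint,
    separable_conv_params,
    standard_conv_params,
    train_demo,
)

FAMILIES = ["resnet", "densenet", "mobilenet", "mixnet"]


def separable_patches(rng, n=60, size=24):
    """Bright-blob vs background patches: linearly separable by pooled features."""
    X = rng.rand(n, size, size) * 10
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    X[: n // 2, 8:16, 8:16] += 120
    return X, y


class TestBackboneStructure:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_final_layer_width_is_two(self, family, rng):
        model = build_backbone(BackboneConfig(family=family))
        assert model.head_w.shape[0] == 2
        assert model.forward(rng.rand(3, 24, 24)).shape == (3, 2)

    def test_residual_stage_is_transform_plus_shortcut(self, rng):
        stage = _ResidualStage(channels=6, rng=rng)
        x = rng.randn(2, 6, 8, 8)
        np.testing.assert_allclose(stage(x), stage.transform(x) + stage.shortcut(x))
        stage.zero_transform()
        np.testing.assert_allclose(stage(x), x)  # identity once the transform is off

    def test_dense_stage_channel_growth_is_linear(self):
        model = build_backbone(BackboneConfig(family="densenet", depth_scale=2.0))
        for stage in model.stages:
            increments = np.diff(stage.layer_in_channels)
            assert len(set(increments)) <= 1  # constant growth rate
            assert stage.out_channels == stage.layer_in_channels[-1] + increments[-1]

    def test_separable_convolution_is_cheaper_than_standard(self):
        # closed form: depthwise+pointwise < dense conv for k>1 and out_c>1
        for in_c, out_c, k in [(8, 16, 3), (16, 32, 3), (4, 8, 5)]:
            assert separable_conv_params(in_c, out_c, k) < standard_conv_params(in_c, out_c, k)
        model = build_backbone(BackboneConfig(family="mobilenet"))
        for stage in model.stages:
            dense_twin = standard_conv_params(stage.dw.shape[0], stage.out_channels, 3)
            assert stage.num_params < dense_twin

    @pytest.mark.parametrize("attention", ["none", "se", "ca1", "ca2"])
    def test_attention_insertion_keeps_output_contract(self, attention, rng):
        model = build_backbone(BackboneConfig(family="resnet", attention=attention))
        out = model.forward(rng.rand(2, 24, 24))
        assert out.shape == (2, 2) and np.all(np.isfinite(out))

    def test_3d_patches_enter_as_depth_channels(self, rng):
        model = build_backbone(BackboneConfig(family="resnet", input_size=(8, 16, 16)))
        out = model.forward(rng.rand(4, 8, 16, 16))
        assert out.shape == (4, 2)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(family="vgg")


class TestClassifyPatches:
    def test_duplicated_sample_scores_identically(self, rng):
        model = build_backbone(BackboneConfig())
        X = rng.rand(3, 24, 24)
        X[2] = X[0]
        scores = classify_patches(model, X)
        assert scores[0] == scores[2]

    def test_scores_in_unit_interval(self, rng):
        model = build_backbone(BackboneConfig(family="mixnet"))
        scores = classify_patches(model, rng.rand(10, 24, 24) * 200)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_training_separates_blob_patches(self, rng):
        X, y = separable_patches(rng)
        model, _ = train_demo((X, y), BackboneConfig(family="resnet", attention="ca1"), seed=0)
        acc = ((classify_patches(model, X) > 0.5) == y).mean()
        assert acc > 0.9


class TestTrainDemo:
    def test_zero_learning_rate_freezes_loss(self, rng):
        X, y = separable_patches(rng, n=20)
        _, trace = train_demo((X, y), seed=0, train_config=TrainConfig(epochs=5, lr=0.0))
        assert np.ptp(trace["train_loss"]) == 0.0

    def test_same_seed_reproduces_trace(self, rng):
        X, y = separable_patches(rng, n=30)
        _, t1 = train_demo((X, y), seed=3, train_config=TrainConfig(epochs=8))
        _, t2 = train_demo((X, y), seed=3, train_config=TrainConfig(epochs=8))
        np.testing.assert_array_equal(t1["train_loss"], t2["train_loss"])
        np.testing.assert_array_equal(t1["val_loss"], t2["val_loss"])

    def test_loss_decreases_on_separable_set(self, rng):
        X, y = separable_patches(rng)
        _, trace = train_demo((X, y), seed=0)
        assert trace["train_loss"][-1] < trace["train_loss"][0]
        assert len(trace["val_loss"]) == len(trace["train_loss"])


class TestCheckpoint:
    def test_roundtrip_reproduces_scores_exactly(self, rng, tmp_path):
        X, y = separable_patches(rng, n=30)
        model, _ = train_demo(
            (X, y), BackboneConfig(family="resnet", attention="ca1"),
            seed=0, train_config=TrainConfig(epochs=10),
        )
        restored = load_checkpoint(save_checkpoint(model, tmp_path / "model.json"))
        np.testing.assert_array_equal(
            classify_patches(restored, X), classify_patches(model, X)
        )


class TestFusion:
    def test_agreement_is_preserved(self):
        labels, _ = fuse_multibackbone([0.9, 0.1], [0.8, 0.2], FusionRule("union_positive"))
        np.testing.assert_array_equal(labels, [True, False])

    def test_union_positive_takes_either_branch(self):
        labels, fused = fuse_multibackbone([0.9], [0.1], FusionRule("union_positive", 0.5))
        assert labels[0] and fused[0] == 0.9

    def test_mean_score_tie_is_not_positive_under_strict_threshold(self):
        labels, fused = fuse_multibackbone([0.9], [0.1], FusionRule("mean_score", 0.5))
        assert fused[0] == pytest.approx(0.5) and not labels[0]

    def test_union_sensitivity_dominates_branches(self, rng):
        truth = rng.rand(200) > 0.5
        a, b = rng.rand(200), rng.rand(200)
        rule = FusionRule("union_positive", 0.5)
        union, _ = fuse_multibackbone(a, b, rule)

        def sens(pred):
            return (pred & truth).sum() / truth.sum()

        assert sens(union) >= sens(a > 0.5)
        assert sens(union) >= sens(b > 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_multibackbone([0.5], [0.5, 0.6], FusionRule())


class TestPatchClassifierEstimator:
    def test_sklearn_fit_predict_cycle(self, rng):
        X, y = separable_patches(rng, n=40)
        est = PatchClassifier(family="densenet", epochs=20, seed=0).fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (40, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (est.predict(X) == y).mean() > 0.9

    def test_clone_preserves_params(self):
        est = PatchClassifier(family="mixnet", attention="ca2", epochs=7)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
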