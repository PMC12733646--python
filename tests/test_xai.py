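"""Grad-CAM, SE attention, and Integrated Gradients contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpsenet import ArchitectureConfig, build_model
from dpsenet.xai import (
    explain, explain_batch, grad_cam, integrated_gradients, render_overlay,
    render_composite, se_attention, se_spatial_heatmap, signed_view,
)


def _head_passthrough(model, channel=0, sign=1.0):
    """Wire the classifier head so logit 0 = sign * mean of one fused channel.

    dense1 copies the chosen GAP component (ReLU is inert on nonnegative
    trunk features), dense2 routes it to class 0.
    """
    model.params["dense1/W"][:] = 0
    model.params["dense1/b"][:] = 0
    model.params["dense1/W"][channel, 0] = 1.0
    model.params["dense2/W"][:] = 0
    model.params["dense2/b"][:] = 0
    model.params["dense2/W"][0, 0] = sign


class _LinearStub:
    """F(x) = w.x on logit 0 — exact closed form for Integrated Gradients."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=np.float32)

    def forward_batch(self, x, cache=False):
        logits = np.stack([(x * self.w).sum(axis=(1, 2, 3)),
                           np.zeros(len(x), dtype=np.float32)], axis=1)
        return logits, None, None

    def input_gradient(self, x, target_class):
        if target_class != 0:
            return np.zeros_like(x)
        return np.broadcast_to(self.w, x.shape).copy()


@pytest.fixture(scope="module")
def small_model():
    cfg = ArchitectureConfig(input_height=16, input_width=16, block_filters=(4, 8),
                             se_reduction=4, dense_units=12, n_classes=5,
                             variant="dual_se")
    return build_model(cfg, seed=4)


class TestGradCAM:
    def test_mean_of_single_map_closed_form(self, small_model, rng):
        # logit = mean(A_0): alpha_0 = 1/Z, map = ReLU(A_0/Z) proportional to A_0
        model = build_model(small_model.config, seed=4)
        _head_passthrough(model, channel=0)
        x = rng.random((16, 16, 3), dtype=np.float32)
        g = grad_cam(model, x, 0)
        _, _, cc = model.forward_batch(x[None], cache=True)
        A0 = cc["feat"][0, :, :, 0]
        assert g.alpha[0] == pytest.approx(1.0 / g.z, rel=1e-4)
        assert np.allclose(np.abs(g.alpha[1:]), 0, atol=1e-9)
        assert np.allclose(g.raw, np.maximum(A0 / g.z, 0), atol=1e-8)
        if A0.max() > 0:
            assert g.upsampled.max() == pytest.approx(1.0)

    def test_constant_score_yields_zero_map(self, small_model, rng):
        model = build_model(small_model.config, seed=4)
        model.params["dense1/W"][:] = 0  # logits independent of features
        model.params["dense2/W"][:] = 0
        x = rng.random((16, 16, 3), dtype=np.float32)
        g = grad_cam(model, x, 2)
        assert not g.raw.any()
        assert not g.upsampled.any()

    def test_negative_influence_clipped_to_zero(self, small_model, rng):
        model = build_model(small_model.config, seed=4)
        _head_passthrough(model, channel=0, sign=-1.0)
        x = rng.random((16, 16, 3), dtype=np.float32) + 0.2
        g = grad_cam(model, x, 0)
        assert not g.raw.any()

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_maps_nonnegative_under_fuzzed_weights_and_inputs(self, seed):
        rng = np.random.default_rng(seed)
        cfg = ArchitectureConfig(input_height=8, input_width=8, block_filters=(3, 5),
                                 se_reduction=1, dense_units=6, n_classes=3,
                                 variant="dual_se")
        model = build_model(cfg, seed=seed % 1000)
        for k, v in model.params.items():
            model.params[k] = (v + rng.normal(0, 0.1, v.shape)).astype(np.float32)
        x = rng.random((8, 8, 3)).astype(np.float32)
        g = grad_cam(model, x, int(rng.integers(0, 3)))
        assert np.all(g.raw >= 0)
        assert np.all(g.upsampled >= 0) and np.all(g.upsampled <= 1.0 + 1e-6)

    def test_non_spatial_layer_rejected(self, small_model, rng):
        with pytest.raises(ValueError, match="spatial"):
            grad_cam(small_model, rng.random((16, 16, 3), dtype=np.float32),
                     0, layer="gap")


class TestSEAttention:
    def test_gates_strictly_in_unit_interval(self, small_model, rng):
        res = se_attention(small_model, rng.random((16, 16, 3), dtype=np.float32))
        assert np.all(res.gates > 0) and np.all(res.gates < 1)

    def test_variant_without_se_rejected(self, rng):
        cfg = ArchitectureConfig(input_height=16, input_width=16,
                                 block_filters=(4, 8), dense_units=12,
                                 n_classes=5, variant="dual")
        model = build_model(cfg, seed=0)
        with pytest.raises(ValueError, match="no SE block"):
            se_attention(model, rng.random((16, 16, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="no SE block"):
            se_spatial_heatmap(model, rng.random((16, 16, 3), dtype=np.float32))

    def test_tied_gates_pick_lowest_channel_indices(self, small_model, rng):
        model = build_model(small_model.config, seed=4)
        model.params["se/W1"][:] = 0
        model.params["se/b1"][:] = 0
        model.params["se/W2"][:] = 0
        model.params["se/b2"][:] = 0  # all gates exactly 0.5
        res = se_attention(model, rng.random((16, 16, 3), dtype=np.float32), top_k=4)
        assert res.top_channels.tolist() == [0, 1, 2, 3]
        assert np.allclose(res.normalized, 0)

    def test_gates_depend_on_input_after_training(self, tiny_trained):
        model, images, labels, _ = tiny_trained
        a = se_attention(model, images[0]).gates
        idx_other = int(np.flatnonzero(labels != labels[0])[0])
        b = se_attention(model, images[idx_other]).gates
        assert not np.allclose(a, b)


class TestIntegratedGradients:
    def test_exact_on_linear_model_any_steps(self, rng):
        w = rng.normal(0, 1, (4, 4, 3)).astype(np.float32)
        stub = _LinearStub(w)
        x = rng.random((4, 4, 3)).astype(np.float32)
        baseline = rng.random((4, 4, 3)).astype(np.float32) * 0.1
        for m in (1, 7, 32):
            attr = integrated_gradients(stub, x, baseline, steps=m, target_class=0)
            assert np.allclose(attr.values, (x - baseline) * w, atol=1e-6)
            assert attr.completeness_gap < 1e-4

    def test_zero_path_gives_zero_attributions(self, small_model, rng):
        x = rng.random((16, 16, 3)).astype(np.float32)
        attr = integrated_gradients(small_model, x, baseline=x.copy(), steps=8)
        assert not attr.values.any()

    def test_shape_mismatch_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            integrated_gradients(small_model, rng.random((16, 16, 3)),
                                 baseline=np.zeros((8, 8, 3)), steps=4)

    def test_completeness_gap_small_and_shrinking(self, tiny_trained):
        model, images, _, _ = tiny_trained
        x = images[0]
        pred = int(model.predict_proba(x[None])[0].argmax())
        gaps = {}
        for m in (16, 64, 256):
            attr = integrated_gradients(model, x, steps=m, target_class=pred)
            gaps[m] = attr.completeness_gap
            delta = abs(attr.score_delta)
        assert gaps[256] <= 1e-3 * delta + 1e-6
        # convergence up to quadrature noise: coarse grids no better than fine
        assert gaps[256] <= gaps[16] + 1e-6


class TestExplainPipeline:
    def test_bundle_members_share_target_and_are_deterministic(self, tiny_trained):
        model, images, _, _ = tiny_trained
        b1 = explain(model, images[3], ig_steps=8)
        b2 = explain(model, images[3], ig_steps=8)
        assert b1.grad_cam.target_class == b1.predicted_class
        assert b1.se_attention is not None
        assert np.array_equal(b1.grad_cam.upsampled, b2.grad_cam.upsampled)
        assert np.array_equal(b1.integrated_gradients.values,
                              b2.integrated_gradients.values)
        assert b1.class_score == b2.class_score

    def test_batch_of_inputs_yields_ordered_bundles(self, tiny_trained):
        model, images, _, _ = tiny_trained
        bundles = explain_batch(model, images[:3], ig_steps=4)
        assert len(bundles) == 3
        singles = [explain(model, img, ig_steps=4) for img in images[:3]]
        for b, s in zip(bundles, singles):
            assert b.predicted_class == s.predicted_class
            assert np.array_equal(b.grad_cam.upsampled, s.grad_cam.upsampled)

    def test_se_free_variant_downgrades_with_warning(self, rng):
        cfg = ArchitectureConfig(input_height=16, input_width=16,
                                 block_filters=(4, 8), dense_units=12,
                                 n_classes=5, variant="dual")
        model = build_model(cfg, seed=0)
        with pytest.warns(UserWarning, match="no SE block"):
            bundle = explain(model, rng.random((16, 16, 3)).astype(np.float32),
                             ig_steps=4)
        assert bundle.se_attention is None
        assert bundle.grad_cam is not None


class TestRendering:
    def test_zero_alpha_overlay_is_identity(self, rng):
        x = rng.random((16, 16, 3))
        heat = rng.random((16, 16))
        assert np.allclose(render_overlay(x, heat, alpha=0.0), x)

    def test_zero_map_blends_constant_zero_color(self, rng):
        x = rng.random((16, 16, 3))
        out = render_overlay(x, np.zeros((16, 16)), alpha=0.3)
        import matplotlib
        zero_color = matplotlib.colormaps["jet"](0.0)[:3]
        assert np.allclose(out, 0.7 * x + 0.3 * np.asarray(zero_color))

    def test_alpha_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            render_overlay(rng.random((8, 8, 3)), np.zeros((8, 8)), alpha=1.5)

    def test_signed_view_maps_zero_to_half(self):
        attr = np.array([[-2.0, 0.0], [0.0, 2.0]])
        v = signed_view(attr)
        assert v[0, 1] == pytest.approx(0.5)
        assert v.min() >= 0 and v.max() <= 1

    def test_composites_written_for_each_class_sample(self, tiny_trained, tmp_path):
        model, images, labels, _ = tiny_trained
        n = 0
        for c in range(5):
            i = int(np.flatnonzero(labels == c)[0])
            render_composite(model, images[i], tmp_path / f"c{c}.png", ig_steps=4)
            n += 1
        files = sorted(tmp_path.glob("*.png"))
        assert len(files) == n
        from PIL import Image
        w, h = Image.open(files[0]).size
        assert (w, h) == (4 * 32, 32)  # four panels side by side
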