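"""Explainability bundle: Grad-CAM, SE attention, Integrated Gradients.

All gradients are taken with respect to the pre-softmax class logit: softmax
gradients saturate on confident predictions, which would both flatten
Grad-CAM maps and break the completeness interpretation of Integrated
Gradients.

Grad-CAM: channel weights are the spatial means of the logit's gradient on a
chosen feature layer (default: the recalibrated fused map, the network's last
spatial representation); the map is the ReLU of the weighted channel sum,
bilinearly upsampled to input resolution and max-normalized.

Integrated Gradients uses a midpoint Riemann sum along the straight path
from a baseline (default: black image); the completeness gap
|Σ IG − (F(x) − F(x'))| is recorded on every call.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _resize

from .model import Model

DEFAULT_LAYER = "feat"  # recalibrated fused feature map (post-SE when present)


@dataclass
class GradCAMMap:
    raw: np.ndarray        # (H', W') nonnegative, on the layer grid
    upsampled: np.ndarray  # (H, W) in [0, 1]
    target_class: int
    layer: str
    alpha: np.ndarray      # per-channel importance weights
    z: int                 # number of spatial positions of the layer


@dataclass
class SEAttentionResult:
    gates: np.ndarray       # strictly in (0, 1)
    normalized: np.ndarray  # min-max view in [0, 1]
    top_channels: np.ndarray


@dataclass
class AttributionMap:
    values: np.ndarray       # per-pixel, per-channel attributions, input shape
    spatial: np.ndarray      # channel-summed 2-D view
    baseline: np.ndarray
    steps: int
    completeness_gap: float
    score_delta: float       # F(x) − F(x′)


@dataclass
class XAIBundle:
    grad_cam: GradCAMMap
    se_attention: SEAttentionResult | None
    integrated_gradients: AttributionMap
    predicted_class: int
    class_score: float


# -------------------------------------------------------------------- Grad-CAM

def grad_cam(model: Model, x: np.ndarray, target_class: int,
             layer: str = DEFAULT_LAYER) -> GradCAMMap:
    """Class-discriminative saliency on a spatial feature layer.

    alpha_k = (1/Z)·Σ_ij ∂logit_c/∂A_k(i,j); map = ReLU(Σ_k alpha_k·A_k).
    """
    c = model.config
    if target_class >= c.n_classes or target_class < 0:
        raise ValueError(f"target class {target_class} out of range")
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 3
    logits, _, cc = model.forward_batch(x[None] if single else x, cache=True)
    if layer not in cc or np.asarray(cc[layer]).ndim != 4:
        raise ValueError(f"layer {layer!r} does not expose a spatial feature map")
    A = cc[layer]
    dlogits = np.zeros_like(logits)
    dlogits[:, target_class] = 1.0
    _, captured = model.backward(cc, dlogits, want_param_grads=False, capture=(layer,))
    grad = captured[layer]
    z = A.shape[1] * A.shape[2]
    alpha = grad.mean(axis=(1, 2))                          # (N, C)
    raw = np.maximum((A * alpha[:, None, None, :]).sum(-1), 0.0)  # (N, H', W')
    ups = np.stack([
        _resize(m, (c.input_height, c.input_width), order=1,
                mode="edge", anti_aliasing=False, preserve_range=True)
        for m in raw
    ])
    peak = ups.max(axis=(1, 2), keepdims=True)
    ups = np.where(peak > 0, ups / np.maximum(peak, 1e-30), 0.0)
    if single:
        return GradCAMMap(raw=raw[0], upsampled=ups[0], target_class=target_class,
                          layer=layer, alpha=alpha[0], z=z)
    return [GradCAMMap(raw=raw[i], upsampled=ups[i], target_class=target_class,
                       layer=layer, alpha=alpha[i], z=z) for i in range(len(raw))]


# -------------------------------------------------------------- SE attention

def se_attention(model: Model, x: np.ndarray, top_k: int = 10) -> SEAttentionResult:
    """The SE gate vector observed during the forward pass on one input."""
    if not model.config.has_se:
        raise ValueError(f"variant {model.config.variant!r} has no SE block")
    x = np.asarray(x, dtype=np.float32)
    _, _, cc = model.forward_batch(x[None] if x.ndim == 3 else x, cache=True)
    gates = cc["se/gates"][0]
    lo, hi = gates.min(), gates.max()
    normalized = (gates - lo) / (hi - lo) if hi > lo else np.zeros_like(gates)
    # stable sort so ties resolve to the lowest channel index
    order = np.argsort(-gates, kind="stable")
    return SEAttentionResult(gates=gates, normalized=normalized,
                             top_channels=order[:top_k])


def se_spatial_heatmap(model: Model, x: np.ndarray) -> np.ndarray:
    """Gate-weighted channel sum of the fused feature map, as a [0,1] image.

    The per-channel gate vector has no intrinsic spatial layout; this view
    projects it back onto the fused map so it can be drawn next to Grad-CAM.
    """
    if not model.config.has_se:
        raise ValueError(f"variant {model.config.variant!r} has no SE block")
    x = np.asarray(x, dtype=np.float32)
    _, _, cc = model.forward_batch(x[None] if x.ndim == 3 else x, cache=True)
    m = (cc["fused"][0] * cc["se/gates"][0]).sum(-1)
    c = model.config
    m = _resize(m, (c.input_height, c.input_width), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    lo, hi = m.min(), m.max()
    return (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)


# ------------------------------------------------------- Integrated Gradients

def integrated_gradients(model, x: np.ndarray, baseline: np.ndarray | None = None,
                         steps: int = 64, target_class: int = 0,
                         batch_size: int = 32) -> AttributionMap:
    """Midpoint-rule path integral of logit gradients from baseline to input.

    ``model`` needs ``input_gradient(batch, class)`` and a logit-producing
    ``forward_batch``; any object with that surface works.
    """
    x = np.asarray(x, dtype=np.float32)
    if baseline is None:
        baseline = np.zeros_like(x)
    baseline = np.asarray(baseline, dtype=np.float32)
    if baseline.shape != x.shape:
        raise ValueError(f"baseline shape {baseline.shape} != input shape {x.shape}")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    diff = x - baseline
    total_grad = np.zeros_like(x, dtype=np.float64)
    ts = (np.arange(1, steps + 1) - 0.5) / steps
    for i in range(0, steps, batch_size):
        chunk = ts[i:i + batch_size]
        pts = baseline[None] + chunk[:, None, None, None] * diff[None]
        total_grad += model.input_gradient(pts, target_class).sum(axis=0)
    ig = diff * (total_grad / steps)
    f_x = float(model.forward_batch(x[None])[0][0, target_class])
    f_b = float(model.forward_batch(baseline[None])[0][0, target_class])
    delta = f_x - f_b
    gap = abs(float(ig.sum()) - delta)
    spatial = ig.sum(axis=-1)
    return AttributionMap(values=ig.astype(np.float32), spatial=spatial,
                          baseline=baseline, steps=steps,
                          completeness_gap=gap, score_delta=delta)


def signed_view(attr: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Symmetric percentile clipping, then [−1, 1] → [0, 1] for display."""
    scale = np.percentile(np.abs(attr), percentile)
    if scale <= 0:
        return np.full(attr.shape, 0.5)
    return (np.clip(attr / scale, -1.0, 1.0) + 1.0) / 2.0


# ------------------------------------------------------------------- pipeline

def explain(model: Model, x: np.ndarray, target_class: int | None = None,
            ig_steps: int = 64, layer: str = DEFAULT_LAYER) -> XAIBundle:
    """Full bundle for one input: forward pass, Grad-CAM, SE gates, IG."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("explain takes a single HxWx3 image")
    logits, probs, _ = model.forward_batch(x[None])
    pred = int(probs[0].argmax())
    target = pred if target_class is None else int(target_class)
    gc = grad_cam(model, x, target, layer=layer)
    if model.config.has_se:
        se = se_attention(model, x)
    else:
        se = None
        warnings.warn(f"variant {model.config.variant!r} has no SE block; "
                      "bundle downgraded to Grad-CAM + Integrated Gradients")
    ig = integrated_gradients(model, x, steps=ig_steps, target_class=target)
    return XAIBundle(grad_cam=gc, se_attention=se, integrated_gradients=ig,
                     predicted_class=pred, class_score=float(logits[0, target]))


def explain_batch(model: Model, images: np.ndarray, **kwargs) -> list[XAIBundle]:
    return [explain(model, img, **kwargs) for img in images]


# ------------------------------------------------------------------ rendering

def render_overlay(x: np.ndarray, heat: np.ndarray, colormap: str = "jet",
                   alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a [0,1] heat map over the image; returns a [0,1] RGB array."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if heat.shape != x.shape[:2]:
        raise ValueError(f"map shape {heat.shape} must match image grid {x.shape[:2]}")
    import matplotlib
    cmap = matplotlib.colormaps[colormap]
    heat_rgb = cmap(np.clip(heat, 0, 1))[..., :3]
    return (1 - alpha) * x + alpha * heat_rgb


def render_composite(model: Model, x: np.ndarray, out_path, alpha: float = 0.4,
                     ig_steps: int = 64, colormap: str = "jet") -> XAIBundle:
    """Write a 4-panel composite: original | Grad-CAM | SE heatmap | IG view."""
    bundle = explain(model, x, ig_steps=ig_steps)
    panels = [x, render_overlay(x, bundle.grad_cam.upsampled, colormap, alpha)]
    if bundle.se_attention is not None:
        panels.append(render_overlay(x, se_spatial_heatmap(model, x), colormap, alpha))
    else:
        panels.append(np.zeros_like(x))
    ig_img = np.repeat(signed_view(bundle.integrated_gradients.spatial)[..., None], 3, axis=-1)
    panels.append(ig_img)
    strip = np.concatenate(panels, axis=1)
    Image.fromarray((np.clip(strip, 0, 1) * 255 + 0.5).astype(np.uint8)).save(out_path)
    return bundle


def bundle_record(bundle: XAIBundle) -> dict:
    """JSON-serialisable summary of one explanation bundle."""
    return {
        "predicted_class": bundle.predicted_class,
        "class_score": bundle.class_score,
        "grad_cam_layer": bundle.grad_cam.layer,
        "ig_steps": bundle.integrated_gradients.steps,
        "ig_completeness_gap": bundle.integrated_gradients.completeness_gap,
        "top_se_channels": (bundle.se_attention.top_channels.tolist()
                            if bundle.se_attention is not None else None),
    }
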