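"""Dual-path convolutional classifier with squeeze-and-excitation recalibration.

The network processes an H×W×3 patch through one or two parallel stacks of
[conv → ReLU → 2×2 max-pool] blocks. A 3×3-kernel path captures fine cellular
texture while a 5×5-kernel path captures broader glandular context; their
outputs are concatenated on the channel axis. A squeeze-and-excitation (SE)
block then recalibrates the fused channels: global average pooling squeezes
each channel to a scalar, a two-layer bottleneck (C → C/r → C) with ReLU and
sigmoid produces per-channel gates in (0, 1), and the feature map is scaled
channel-wise by those gates. Global average pooling, a 128-unit ReLU dense
layer and a softmax output head complete the classifier.

Six ablation variants are supported: each single path with and without SE,
the dual-path fusion without SE, and the full dual-path + SE model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from ._layers import (
    DTYPE, glorot_uniform, conv2d, conv2d_backward, maxpool2d, maxpool2d_backward,
    dense, dense_backward, relu, sigmoid, softmax,
)

VARIANTS = ("single_a", "single_b", "single_a_se", "single_b_se", "dual", "dual_se")

#: Table-style display names, in canonical ablation order.
VARIANT_LABELS = {
    "single_a": "Single Path A (No SE)",
    "single_b": "Single Path B (No SE)",
    "single_a_se": "Single Path A + SE",
    "single_b_se": "Single Path B + SE",
    "dual": "Simple Dual-Path (No SE)",
    "dual_se": "Dual-Path + SE (Full)",
}


class ConfigurationError(ValueError):
    """Raised when an architecture configuration violates its invariants."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Every free hyperparameter of the network.

    Defaults give the canonical dual-path + SE model for 128×128×3 input:
    3×3 and 5×5 kernel paths with 32/64/128 filters, SE reduction 16,
    128-unit dense layer and 5 output classes.
    """

    input_height: int = 128
    input_width: int = 128
    input_channels: int = 3
    path_a_kernel: int = 3
    path_b_kernel: int = 5
    block_filters: tuple[int, ...] = (32, 64, 128)
    pool_size: int = 2
    se_reduction: int = 16
    dense_units: int = 128
    n_classes: int = 5
    variant: str = "dual_se"

    def __post_init__(self):
        object.__setattr__(self, "block_filters", tuple(int(f) for f in self.block_filters))
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if not self.block_filters or any(f < 1 for f in self.block_filters):
            raise ConfigurationError("block_filters must be nonempty with all counts >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.pool_size < 1:
            raise ConfigurationError("pool_size must be >= 1")
        stride = self.pool_size ** len(self.block_filters)
        for name, dim in (("input_height", self.input_height), ("input_width", self.input_width)):
            if dim % stride != 0:
                raise ConfigurationError(
                    f"{name}={dim} is not divisible by pool_size^depth = {stride}"
                )
        if self.has_se and self.se_channels // self.se_reduction < 1:
            raise ConfigurationError(
                f"se_reduction={self.se_reduction} leaves no bottleneck units for "
                f"{self.se_channels} channels at the SE insertion point"
            )

    # -- derived structure -------------------------------------------------
    @property
    def paths(self) -> tuple[str, ...]:
        if self.variant in ("single_a", "single_a_se"):
            return ("a",)
        if self.variant in ("single_b", "single_b_se"):
            return ("b",)
        return ("a", "b")

    @property
    def has_se(self) -> bool:
        return self.variant.endswith("_se")

    @property
    def fused_channels(self) -> int:
        return self.block_filters[-1] * len(self.paths)

    @property
    def se_channels(self) -> int:
        return self.fused_channels

    @property
    def fused_spatial(self) -> tuple[int, int]:
        d = self.pool_size ** len(self.block_filters)
        return self.input_height // d, self.input_width // d

    def kernel_for(self, path: str) -> int:
        return self.path_a_kernel if path == "a" else self.path_b_kernel

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_filters"] = list(self.block_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        d["block_filters"] = tuple(d.get("block_filters", (32, 64, 128)))
        return cls(**d)

    def with_variant(self, variant: str) -> "ArchitectureConfig":
        return replace(self, variant=variant)


# --------------------------------------------------------------- SE primitives

def se_squeeze(x: np.ndarray) -> np.ndarray:
    """Global average pooling: z_c = mean over spatial positions of channel c."""
    x = np.asarray(x)
    if x.ndim != 3 or x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError(f"expected a nonempty HxWxC feature map, got shape {x.shape}")
    return x.mean(axis=(0, 1))


def se_excite(z: np.ndarray, W1: np.ndarray, W2: np.ndarray,
              b1: np.ndarray | None = None, b2: np.ndarray | None = None) -> np.ndarray:
    """Gates s = sigmoid(W2 · ReLU(W1 · z)); W1 is (C/r, C), W2 is (C, C/r)."""
    z = np.asarray(z)
    if W1.shape[1] != z.shape[-1] or W2.shape[1] != W1.shape[0] or W2.shape[0] != z.shape[-1]:
        raise ValueError(
            f"excitation shapes do not conform: z {z.shape}, W1 {W1.shape}, W2 {W2.shape}"
        )
    h = W1 @ z
    if b1 is not None:
        h = h + b1
    h = relu(h)
    a = W2 @ h
    if b2 is not None:
        a = a + b2
    return sigmoid(a)


def se_recalibrate(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling: output channel c is s_c · X_c everywhere."""
    x, s = np.asarray(x), np.asarray(s)
    if x.shape[-1] != s.shape[-1]:
        raise ValueError(f"channel mismatch: feature map has {x.shape[-1]}, gates {s.shape[-1]}")
    return x * s


# ----------------------------------------------------------------------- model

class Model:
    """A built network: parameter store plus forward/backward machinery.

    Parameters live in ``params`` keyed by hierarchical names
    (``path_a/block1/W`` …). ``forward_batch(x, cache=True)`` records every
    intermediate tensor so ``backward`` can produce parameter gradients and,
    on request, gradients with respect to named intermediates (used for
    Grad-CAM) or the input (used for Integrated Gradients).
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        c = config
        for path in c.paths:
            k = c.kernel_for(path)
            c_in = c.input_channels
            for i, f in enumerate(c.block_filters, start=1):
                fan_in, fan_out = k * k * c_in, k * k * f
                self.params[f"path_{path}/block{i}/W"] = glorot_uniform(
                    rng, (k, k, c_in, f), fan_in, fan_out)
                self.params[f"path_{path}/block{i}/b"] = np.zeros(f, dtype=DTYPE)
                c_in = f
        if c.has_se:
            C = c.se_channels
            Cr = C // c.se_reduction
            self.params["se/W1"] = glorot_uniform(rng, (Cr, C), C, Cr)
            self.params["se/b1"] = np.zeros(Cr, dtype=DTYPE)
            self.params["se/W2"] = glorot_uniform(rng, (C, Cr), Cr, C)
            self.params["se/b2"] = np.zeros(C, dtype=DTYPE)
        self.params["dense1/W"] = glorot_uniform(
            rng, (c.fused_channels, c.dense_units), c.fused_channels, c.dense_units)
        self.params["dense1/b"] = np.zeros(c.dense_units, dtype=DTYPE)
        self.params["dense2/W"] = glorot_uniform(
            rng, (c.dense_units, c.n_classes), c.dense_units, c.n_classes)
        self.params["dense2/b"] = np.zeros(c.n_classes, dtype=DTYPE)

    # -- forward ------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        c = self.config
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != (c.input_height, c.input_width, c.input_channels):
            raise ValueError(
                f"input shape {x.shape} does not match configured "
                f"{(c.input_height, c.input_width, c.input_channels)}"
            )
        return x

    def forward_batch(self, x: np.ndarray, cache: bool = False):
        """Return (logits, probs, cache_dict). Cache is None unless requested."""
        c = self.config
        x = self._check_input(x)
        cc: dict = {"input": x} if cache else None
        path_out = {}
        for path in c.paths:
            a = x
            for i in range(1, len(c.block_filters) + 1):
                z, xpad = conv2d(a, self.params[f"path_{path}/block{i}/W"],
                                 self.params[f"path_{path}/block{i}/b"])
                r = relu(z)
                p, idx = maxpool2d(r, c.pool_size)
                if cache:
                    cc[f"path_{path}/block{i}"] = (xpad, z, r.shape, idx)
                    cc[f"path_{path}/pool{i}"] = p
                a = p
            path_out[path] = a
        if len(path_out) == 2:
            ha, wa = path_out["a"].shape[1:3]
            hb, wb = path_out["b"].shape[1:3]
            if (ha, wa) != (hb, wb):
                raise ConfigurationError(
                    f"spatial mismatch at concatenation: path A {(ha, wa)} vs path B {(hb, wb)}"
                )
            fused = np.concatenate([path_out["a"], path_out["b"]], axis=-1)
        else:
            fused = next(iter(path_out.values()))
        if cache:
            cc["fused"] = fused
        if c.has_se:
            z = fused.mean(axis=(1, 2))  # (N, C)
            h_pre = z @ self.params["se/W1"].T + self.params["se/b1"]
            h = relu(h_pre)
            gates = sigmoid(h @ self.params["se/W2"].T + self.params["se/b2"])
            feat = fused * gates[:, None, None, :]
            if cache:
                cc["se/z"] = z
                cc["se/h_pre"] = h_pre
                cc["se/h"] = h
                cc["se/gates"] = gates
        else:
            gates = None
            feat = fused
        if cache:
            cc["feat"] = feat
        gap = feat.mean(axis=(1, 2))
        d1_pre = dense(gap, self.params["dense1/W"], self.params["dense1/b"])
        d1 = relu(d1_pre)
        logits = dense(d1, self.params["dense2/W"], self.params["dense2/b"])
        if cache:
            cc["gap"] = gap
            cc["d1_pre"] = d1_pre
            cc["d1"] = d1
            cc["logits"] = logits
        return logits, softmax(logits), cc

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        images = np.asarray(images, dtype=DTYPE)
        if images.ndim == 3:
            images = images[None]
        out = [self.forward_batch(images[i:i + batch_size])[1]
               for i in range(0, len(images), batch_size)]
        return np.concatenate(out, axis=0)

    # -- backward -----------------------------------------------------------
    def backward(self, cc: dict, dlogits: np.ndarray, want_param_grads: bool = True,
                 capture: tuple[str, ...] = (), need_dx: bool = False):
        """Backpropagate dlogits through a cached forward pass.

        Returns (param_grads, tensor_grads) where tensor_grads holds the
        gradients at the intermediates named in ``capture`` (valid names:
        "fused", "feat", "path_?/pool?", "input").
        """
        c = self.config
        grads: dict[str, np.ndarray] = {}
        captured: dict[str, np.ndarray] = {}
        need_dx = need_dx or ("input" in capture)

        dd1, dW, db = dense_backward(dlogits, cc["d1"], self.params["dense2/W"])
        if want_param_grads:
            grads["dense2/W"], grads["dense2/b"] = dW, db
        dd1_pre = dd1 * (cc["d1_pre"] > 0)
        dgap, dW, db = dense_backward(dd1_pre, cc["gap"], self.params["dense1/W"])
        if want_param_grads:
            grads["dense1/W"], grads["dense1/b"] = dW, db
        h, w = c.fused_spatial
        dfeat = np.broadcast_to(dgap[:, None, None, :] / (h * w),
                                cc["feat"].shape).astype(DTYPE)
        if "feat" in capture:
            captured["feat"] = dfeat
        if c.has_se:
            fused, gates = cc["fused"], cc["se/gates"]
            dgates = (dfeat * fused).sum(axis=(1, 2))
            dfused = dfeat * gates[:, None, None, :]
            da = dgates * gates * (1 - gates)
            if want_param_grads:
                grads["se/W2"] = da.T @ cc["se/h"]
                grads["se/b2"] = da.sum(axis=0)
            dh = (da @ self.params["se/W2"]) * (cc["se/h_pre"] > 0)
            if want_param_grads:
                grads["se/W1"] = dh.T @ cc["se/z"]
                grads["se/b1"] = dh.sum(axis=0)
            dz = dh @ self.params["se/W1"]
            dfused = dfused + dz[:, None, None, :] / (h * w)
        else:
            dfused = dfeat
        if "fused" in capture:
            captured["fused"] = dfused
        # split across paths
        if len(c.paths) == 2:
            f = c.block_filters[-1]
            dpath = {"a": dfused[..., :f], "b": dfused[..., f:]}
        else:
            dpath = {c.paths[0]: dfused}
        dx_total = None
        for path in c.paths:
            d = dpath[path]
            for i in range(len(c.block_filters), 0, -1):
                key = f"path_{path}/pool{i}"
                if key in capture:
                    captured[key] = d
                xpad, z_pre, r_shape, idx = cc[f"path_{path}/block{i}"]
                dr = maxpool2d_backward(np.ascontiguousarray(d), idx, c.pool_size, r_shape)
                dz = dr * (z_pre > 0)
                need_lower = need_dx or i > 1
                dx, dW, db = conv2d_backward(
                    dz, xpad, self.params[f"path_{path}/block{i}/W"], need_dx=need_lower)
                if want_param_grads:
                    gW, gb = f"path_{path}/block{i}/W", f"path_{path}/block{i}/b"
                    grads[gW], grads[gb] = dW, db
                d = dx
            if need_dx:
                dx_total = d if dx_total is None else dx_total + d
        if need_dx and "input" in capture:
            captured["input"] = dx_total
        return grads, captured

    def input_gradient(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """d logit_c / d input for a batch, one shared target class."""
        logits, _, cc = self.forward_batch(x, cache=True)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        _, captured = self.backward(cc, dlogits, want_param_grads=False,
                                    capture=("input",))
        return captured["input"]

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Write weights to an HDF5 container plus a JSON config sidecar."""
        import h5py

        path = str(path)
        with h5py.File(path, "w") as f:
            for name, arr in self.params.items():
                f.create_dataset(name, data=arr)
        with open(path + ".json", "w") as f:
            json.dump(self.config.to_dict(), f, indent=2)

    @classmethod
    def load(cls, path) -> "Model":
        import h5py

        path = str(path)
        with open(path + ".json") as f:
            config = ArchitectureConfig.from_dict(json.load(f))
        model = cls(config, seed=0)
        with h5py.File(path, "r") as f:
            stored = {}
            f.visititems(lambda n, obj: stored.update({n: obj[()]})
                         if isinstance(obj, h5py.Dataset) else None)
        if set(stored) != set(model.params):
            raise ValueError(
                "weights file inconsistent with config: "
                f"missing {sorted(set(model.params) - set(stored))}, "
                f"unexpected {sorted(set(stored) - set(model.params))}"
            )
        for name, arr in stored.items():
            if arr.shape != model.params[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: file {arr.shape}, config {model.params[name].shape}")
            model.params[name] = arr.astype(DTYPE)
        return model

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()

    # -- structure summary (used by the complexity profiler) ------------------
    def layer_summary(self) -> list[dict]:
        """Ordered layer descriptors: kind, block, and shape information."""
        c = self.config
        layers = []
        h, w = c.input_height, c.input_width
        for path in c.paths:
            hh, ww, c_in = h, w, c.input_channels
            k = c.kernel_for(path)
            for i, f in enumerate(c.block_filters, start=1):
                layers.append(dict(kind="conv", block=f"Path {path.upper()}",
                                   name=f"path_{path}/block{i}", kernel=k,
                                   c_in=c_in, c_out=f, h_out=hh, w_out=ww))
                hh //= c.pool_size
                ww //= c.pool_size
                c_in = f
        fh, fw = c.fused_spatial
        if c.has_se:
            C = c.se_channels
            layers.append(dict(kind="se", block="Squeeze-and-Excitation", name="se",
                               channels=C, bottleneck=C // c.se_reduction, h=fh, w=fw))
        layers.append(dict(kind="dense", block="Classifier", name="dense1",
                           n_in=c.fused_channels, n_out=c.dense_units))
        layers.append(dict(kind="dense", block="Classifier", name="dense2",
                           n_in=c.dense_units, n_out=c.n_classes))
        return layers


def build_model(config: ArchitectureConfig | None = None, seed: int = 0) -> Model:
    """Construct a network with freshly initialised (Glorot-uniform) weights."""
    return Model(config or ArchitectureConfig(), seed=seed)


def forward(model: Model, image: np.ndarray) -> np.ndarray:
    """Class probabilities for a single H×W×3 image in [0, 1]."""
    image = np.asarray(image, dtype=DTYPE)
    if image.ndim != 3:
        raise ValueError(f"expected a single HxWx3 image, got shape {image.shape}")
    return model.predict_proba(image[None])[0]
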