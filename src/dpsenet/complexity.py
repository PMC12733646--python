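"""Parameter, size, and FLOP accounting for the built network.

Counting conventions
--------------------
* Parameters: convolution ``(k·k·C_in + 1)·C_out`` (bias included), dense
  ``(n_in + 1)·n_out``, SE block ``C·⌊C/r⌋ + ⌊C/r⌋ + ⌊C/r⌋·C + C``
  (both excitation layers carry biases). All parameters are trainable.
* FLOPs (single-image inference): one multiply-accumulate counts as 2 FLOPs
  and bias adds count 1 each, so a convolution costs
  ``2·H_out·W_out·C_out·(k²·C_in) + H_out·W_out·C_out`` and a dense layer
  ``2·n_in·n_out + n_out``. Pooling (including the SE squeeze and the
  classifier's global average pooling), activations and softmax are
  excluded. The SE block additionally pays ``C·H·W`` recalibration
  multiplies. Functional blocks reported: Path A, Path B,
  Squeeze-and-Excitation, Classifier.
* Model size: mebibytes at 4 bytes per float32 parameter.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .model import Model

BYTES_PER_PARAM = 4


@dataclass
class ComplexityReport:
    total_params: int
    trainable_params: int
    model_size_mb: float
    total_gflops: float
    blocks: list[tuple[str, float, float]]  # (block_name, gflops, percent_of_total)
    per_layer_params: dict[str, int] = field(default_factory=dict)
    variant: str = ""
    input_shape: tuple[int, int, int] = (128, 128, 3)


# -------------------------------------------------------------- closed forms

def conv_params(kernel: int, c_in: int, c_out: int) -> int:
    return (kernel * kernel * c_in + 1) * c_out


def dense_params(n_in: int, n_out: int) -> int:
    return (n_in + 1) * n_out


def se_params(channels: int, reduction: int) -> int:
    cr = channels // reduction
    return channels * cr + cr + cr * channels + channels


def conv_flops(kernel: int, c_in: int, c_out: int, h_out: int, w_out: int) -> int:
    return 2 * h_out * w_out * c_out * (kernel * kernel * c_in) + h_out * w_out * c_out


def dense_flops(n_in: int, n_out: int) -> int:
    return 2 * n_in * n_out + n_out


def se_flops(channels: int, bottleneck: int, h: int, w: int) -> int:
    return (dense_flops(channels, bottleneck) + dense_flops(bottleneck, channels)
            + channels * h * w)


# ----------------------------------------------------------------- profiling

def count_parameters(model: Model) -> tuple[dict[str, int], int]:
    """Per-layer parameter counts from the closed-form formulas, plus total."""
    per_layer: dict[str, int] = {}
    for layer in model.layer_summary():
        if layer["kind"] == "conv":
            n = conv_params(layer["kernel"], layer["c_in"], layer["c_out"])
        elif layer["kind"] == "dense":
            n = dense_params(layer["n_in"], layer["n_out"])
        else:
            n = se_params(layer["channels"], model.config.se_reduction)
        per_layer[layer["name"]] = n
    return per_layer, sum(per_layer.values())


def enumerate_parameters(model: Model) -> int:
    """Brute-force total: sum of the sizes of every weight array in the model."""
    return int(sum(arr.size for arr in model.params.values()))


def count_flops(model: Model, input_shape: tuple[int, int, int] | None = None
                ) -> list[tuple[str, float, float]]:
    """Per-functional-block FLOP breakdown as (block, gflops, percent)."""
    c = model.config
    if input_shape is None:
        input_shape = (c.input_height, c.input_width, c.input_channels)
    h0, w0, _ = input_shape
    if h0 % c.pool_size ** len(c.block_filters) or w0 % c.pool_size ** len(c.block_filters):
        raise ValueError(f"input {h0}x{w0} not divisible by the pooling pyramid")
    block_flops: dict[str, int] = {}
    for path in c.paths:
        name = f"Path {path.upper()}"
        k = c.kernel_for(path)
        hh, ww, c_in = h0, w0, input_shape[2]
        total = 0
        for f in c.block_filters:
            total += conv_flops(k, c_in, f, hh, ww)
            hh //= c.pool_size
            ww //= c.pool_size
            c_in = f
        block_flops[name] = total
    fh = h0 // c.pool_size ** len(c.block_filters)
    fw = w0 // c.pool_size ** len(c.block_filters)
    if c.has_se:
        C = c.se_channels
        block_flops["Squeeze-and-Excitation"] = se_flops(C, C // c.se_reduction, fh, fw)
    block_flops["Classifier"] = (dense_flops(c.fused_channels, c.dense_units)
                                 + dense_flops(c.dense_units, c.n_classes))
    grand = sum(block_flops.values())
    return [(name, flops / 1e9, 100.0 * flops / grand)
            for name, flops in block_flops.items()]


def profile(model: Model, input_shape: tuple[int, int, int] | None = None) -> ComplexityReport:
    """Full complexity report for a built model."""
    c = model.config
    if input_shape is None:
        input_shape = (c.input_height, c.input_width, c.input_channels)
    per_layer, total = count_parameters(model)
    blocks = count_flops(model, input_shape)
    return ComplexityReport(
        total_params=total,
        trainable_params=total,
        model_size_mb=total * BYTES_PER_PARAM / 2 ** 20,
        total_gflops=sum(g for _, g, _ in blocks),
        blocks=blocks,
        per_layer_params=per_layer,
        variant=c.variant,
        input_shape=tuple(input_shape),
    )


# ------------------------------------------------------------------ rendering

def render_report(report: ComplexityReport, format: str = "text") -> str:
    """Render the report in the two-table layout (characteristics + breakdown)."""
    if not report.blocks:
        raise ValueError("report has an empty block list")
    if format == "json":
        return json.dumps({
            "metrics": {
                "total_params": report.total_params,
                "trainable_params": report.trainable_params,
                "model_size_mb": round(report.model_size_mb, 2),
                "total_gflops": round(report.total_gflops, 6),
            },
            "blocks": [{"block": n, "gflops": g, "percent": p}
                       for n, g, p in report.blocks],
        }, indent=2)
    rows_m = [
        ("Total parameters", f"{report.total_params:,}", "Trainable only"),
        ("Model size", f"{report.model_size_mb:.2f} MB", "Float32 representation"),
        ("FLOPs per inference", f"{report.total_gflops:.3f} GFLOPs",
         "{} x {} x {} input".format(*report.input_shape)),
    ]
    rows_b = [(n, f"{g:.6f}", f"{p:.2f}%") for n, g, p in report.blocks]
    rows_b.append(("Total", f"{report.total_gflops:.6f}", "100.00%"))
    if format == "csv":
        buf = io.StringIO()
        buf.write("Metric,Value,Description\n")
        for r in rows_m:
            buf.write(",".join(f'"{x}"' for x in r) + "\n")
        buf.write("\nFunctional Block,GFLOPs,Percentage\n")
        for r in rows_b:
            buf.write(",".join(f'"{x}"' for x in r) + "\n")
        return buf.getvalue()
    if format == "text":
        lines = [f"{'Metric':<22}{'Value':<18}Description"]
        lines += [f"{a:<22}{b:<18}{c}" for a, b, c in rows_m]
        lines.append("")
        lines.append(f"{'Functional Block':<26}{'GFLOPs':<12}Percentage")
        lines += [f"{a:<26}{b:<12}{c}" for a, b, c in rows_b]
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}; choose text, csv or json")
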