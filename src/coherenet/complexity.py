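"""Analytic cost accounting and wall-clock timing for the SLSC variants.

FLOP counts follow the convention that a dense layer mapping N_i inputs to
N_{i+1} outputs costs 2*N_i*N_{i+1} + N_{i+1} FLOPs (multiply-adds plus
bias adds), ReLU costs 2 FLOPs per value, tanh 8, and the average pool 7
per output value. One forward pass through the coherence network applied
to a k-row kernel therefore costs

    O = k * [ sum_{hidden} (2 N_i N_{i+1} + N_{i+1} + 2 N_{i+1})
              + 2 N_{L-1} N_L + N_L + 8 N_L + 7 N_L ]

and one image costs O times the number of pixels. Wall-clock timings are
informational only: they depend on the host and are reported, never
asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import NetworkSpec


@dataclass
class FlopReport:
    """Per-layer and total FLOP counts for one forward pass / one image."""

    per_layer: list[tuple[str, int, int]]
    forward_total: int
    image_total: Optional[int] = None


def param_count(spec: NetworkSpec) -> int:
    """Total trainable scalars: sum over layers of N_i*N_{i+1} + N_{i+1}."""
    return spec.param_count()


def flops_forward(
    spec: NetworkSpec, kernel_len: Optional[int] = None, n_pixels: Optional[int] = None
) -> FlopReport:
    """Exact FLOP count of one forward pass (see module docstring).

    ``kernel_len`` defaults to the spec's input kernel length; supply
    ``n_pixels`` (axial pixels x scanlines) to also get the per-image total.
    """
    k = spec.input_shape[0] if kernel_len is None else int(kernel_len)
    widths = spec.widths
    n_layers = len(spec.layer_sizes)
    per_layer = []
    inner = 0
    for i in range(n_layers):
        fc = 2 * widths[i] * widths[i + 1] + widths[i + 1]
        act = (8 if i == n_layers - 1 else 2) * widths[i + 1]
        per_layer.append((f"fc{i + 1}", fc, act))
        inner += fc + act
    pool = 7 * widths[-1]
    per_layer.append(("avg_pool", 0, pool))
    inner += pool
    total = k * inner
    report = FlopReport(per_layer=per_layer, forward_total=total)
    if n_pixels is not None:
        report.image_total = total * int(n_pixels)
    return report


def memory_footprint(spec: NetworkSpec, bytes_per_param: int = 4) -> int:
    """Weight storage in kilobytes (decimal: 1000 B/kB), rounded to nearest."""
    return int(round(spec.param_count() * bytes_per_param / 1000.0))


def timing_sweep(
    data,
    variants: dict,
    factors: Sequence[float] = (0.125, 0.25, 0.5, 1.0, 2.0),
    iterations: int = 10,
) -> pd.DataFrame:
    """Wall-clock sweep over resampling factors for each image variant.

    ``variants`` maps a variant name to a callable ``f(channel_data) ->
    SLSCImage-or-array``; a ``"cpu"`` entry, if present, serves as the
    correlation baseline at each factor. Returns one row per (variant,
    factor) with mean and standard deviation of the per-iteration times and
    the image-to-image correlation against the CPU baseline.
    """
    from .beamform import resample_channel_data
    from .metrics import image_correlation

    rows = []
    for factor in factors:
        scaled = resample_channel_data(data, factor)
        baseline = None
        if "cpu" in variants:
            baseline = _pixels(variants["cpu"](scaled))
        for name, fn in variants.items():
            times = []
            img = None
            for _ in range(max(1, iterations)):
                t0 = time.perf_counter()
                img = fn(scaled)
                times.append(time.perf_counter() - t0)
            corr = None
            if baseline is not None:
                corr = image_correlation(_pixels(img), baseline)
            rows.append(
                {
                    "variant": name,
                    "factor": factor,
                    "n_samples": int(np.prod(_pixels(img).shape)),
                    "mean_s": float(np.mean(times)),
                    "std_s": float(np.std(times)),
                    "correlation_vs_cpu": corr,
                }
            )
    return pd.DataFrame(rows)


def _pixels(img):
    return img.pixels if hasattr(img, "pixels") else np.asarray(img)
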