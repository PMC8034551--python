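"""Short-lag spatial coherence (SLSC) beamforming.

An SLSC image displays, per pixel, the spatial coherence of the received
wavefield rather than its amplitude. For a pixel centered at axial sample
``n``, a kernel of ``k`` consecutive time samples is taken on each of the
``N`` receive channels; the normalized correlation between channels ``i``
and ``i + m`` is averaged over all element pairs at lag ``m``:

    R(m) = 1/(N-m) * sum_{i=1}^{N-m}
           sum_k s_i s_{i+m} / sqrt(sum_k s_i^2 * sum_k s_{i+m}^2)

with each channel's kernel zero-meaned first. The pixel value is the sum
of R(m) over the short-lag region m = 1..M.

Three image-formation variants are provided:

* ``slsc_image_cpu`` — the double-precision reference above;
* ``slsc_image_gpu_style`` — the single-sample-ensemble simplification used
  by parallel implementations: per-time-sample correlations with a per-lag
  aggregate normalization, kernel averaging applied only afterwards;
* ``slsc_image_dnn`` (in :mod:`coherenet.network`) — the reference
  estimator replaced by the learned CohereNet estimator.

A minimal delay-and-sum (DAS) baseline and an axial/lateral resampling
utility for speed/quality sweeps round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import scipy.signal

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ChannelData


@dataclass
class KernelBlock:
    """One k x N axial kernel of channel data centered at depth ``center_depth``."""

    samples: np.ndarray
    center_depth: Optional[int] = None
    zero_meaned: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("KernelBlock samples must be rank-2 [k, N]")
        k, n = self.samples.shape
        if k < 1:
            raise ValueError("kernel length must be >= 1")
        if n < 2:
            raise ValueError("need at least 2 channels")


@dataclass
class CoherenceFunction:
    """Coherence R(m) for lags m = 1..n_lags (stored at index m-1).

    By convention ``n_lags`` equals the channel count N; the lag-N entry is
    an empty pair sum and is fixed at 0.
    """

    values: np.ndarray
    n_lags: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.n_lags,):
            raise ValueError("values length must equal n_lags")


@dataclass(frozen=True)
class SLSCParams:
    """SLSC formation parameters.

    kernel_len
        Axial kernel length k (odd; default 7, about one wavelength).
    short_lag
        Upper lag M of the pixel sum (default 25).
    edge_skip
        Axial pixels dropped at each image edge; defaults to
        ``(kernel_len - 1) // 2``, i.e. exactly the pixels whose kernel
        would be incomplete.
    """

    kernel_len: int = 7
    short_lag: int = 25
    edge_skip: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kernel_len < 1 or self.kernel_len % 2 == 0:
            raise ValueError("kernel_len must be odd and >= 1")
        if self.short_lag < 1:
            raise ValueError("short_lag must be >= 1")
        if self.edge_skip is None:
            object.__setattr__(self, "edge_skip", (self.kernel_len - 1) // 2)
        elif self.edge_skip < 0:
            raise ValueError("edge_skip must be >= 0")

    @property
    def half_kernel(self) -> int:
        return (self.kernel_len - 1) // 2


@dataclass
class SLSCImage:
    """Grid of short-lag coherence sums with its formation parameters.

    ``axial_offset`` maps image row r back to channel-data axial sample
    ``r + axial_offset``.
    """

    pixels: np.ndarray
    params: SLSCParams
    variant: str
    axial_offset: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SLSC image contains non-finite pixels")


def zero_mean_kernel(block: KernelBlock) -> KernelBlock:
    """Subtract each channel's mean over the k axial samples."""
    z = block.samples - block.samples.mean(axis=0, keepdims=True)
    return KernelBlock(samples=z, center_depth=block.center_depth, zero_meaned=True)


def coherence_batch(kernels: np.ndarray, n_lags: Optional[int] = None) -> np.ndarray:
    """Reference coherence for a batch of kernels.

    Parameters
    ----------
    kernels : array [B, k, N]
        Raw kernel blocks; zero-meaning per channel is applied internally.
    n_lags : int, optional
        Highest lag to evaluate (default N-1). The returned array always
        has N columns (lag m at column m-1); unevaluated lags are 0.

    Element pairs with a zero-energy channel contribute 0 to the lag
    average while the 1/(N-m) normalization keeps the full pair count; a
    lag where every pair is degenerate therefore yields 0.
    """
    kernels = np.asarray(kernels, dtype=np.float64)
    if kernels.ndim != 3:
        raise ValueError("kernels must be rank-3 [B, k, N]")
    b, k, n = kernels.shape
    if k < 1:
        raise ValueError("kernel length must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 channels")
    z = kernels - kernels.mean(axis=1, keepdims=True)
    energy = np.einsum("bki,bki->bi", z, z)
    max_lag = n - 1 if n_lags is None else min(int(n_lags), n - 1)
    out = np.zeros((b, n))
    for m in range(1, max_lag + 1):
        num = np.einsum("bki,bki->bi", z[:, :, : n - m], z[:, :, m:])
        den = energy[:, : n - m] * energy[:, m:]
        r = np.zeros_like(num)
        np.divide(num, np.sqrt(den), out=r, where=den > 0)
        out[:, m - 1] = r.sum(axis=1) / (n - m)
    return out


def coherence_cpu(block: KernelBlock | np.ndarray) -> CoherenceFunction:
    """Reference normalized spatial correlation of one kernel block."""
    samples = block.samples if isinstance(block, KernelBlock) else np.asarray(block)
    if samples.ndim != 2:
        raise ValueError("expected a rank-2 [k, N] kernel")
    values = coherence_batch(samples[None])[0]
    return CoherenceFunction(values=values, n_lags=samples.shape[1])


def slsc_value(coh: CoherenceFunction | np.ndarray, short_lag: int) -> float:
    """Sum of the coherence function over lags 1..M (one SLSC pixel)."""
    values = coh.values if isinstance(coh, CoherenceFunction) else np.asarray(coh)
    if not (1 <= short_lag <= values.shape[-1]):
        raise ValueError(f"short_lag must lie in [1, {values.shape[-1]}]")
    return float(np.sum(values[:short_lag]))


def _edge_trim(params: SLSCParams, n_axial: int) -> tuple[int, int]:
    """Rows kept after edge handling: (offset, count)."""
    h = params.half_kernel
    skip = max(params.edge_skip, h)
    count = n_axial - 2 * skip
    if count < 1:
        raise ValueError(
            f"{n_axial} axial samples leave no valid pixels for kernel_len="
            f"{params.kernel_len} with edge_skip={params.edge_skip}"
        )
    return skip, count


def slsc_image_cpu(data: "ChannelData", params: SLSCParams = SLSCParams()) -> SLSCImage:
    """Reference SLSC image: per-pixel kernel coherence summed over short lags."""
    from .simulate import _frame_kernels

    a, n, lines = data.shape
    if params.short_lag > n - 1:
        raise ValueError(f"short_lag must be <= N-1 = {n - 1}")
    skip, count = _edge_trim(params, a)
    kernels = _frame_kernels(data, params.kernel_len).reshape(-1, params.kernel_len, n)
    coh = coherence_batch(kernels, n_lags=params.short_lag)
    pixels = coh[:, : params.short_lag].sum(axis=1).reshape(a - params.kernel_len + 1, lines)
    extra = skip - params.half_kernel
    if extra > 0:
        pixels = pixels[extra : pixels.shape[0] - extra]
    return SLSCImage(pixels=pixels, params=params, variant="cpu", axial_offset=skip)


def slsc_image_gpu_style(
    data: "ChannelData", params: SLSCParams = SLSCParams()
) -> SLSCImage:
    """Single-sample-ensemble SLSC approximation.

    Correlations are computed per time sample (no kernel, no zero-meaning)
    with one aggregate normalization per lag:

        r(m, n') = sum_i s_i(n') s_{i+m}(n')
                   / sqrt(sum_i s_i(n')^2) / sqrt(sum_i s_{i+m}(n')^2)

    The kernel dependence is reintroduced afterwards by averaging
    r(m, .) over the k samples centered at each pixel; the pixel is the
    short-lag sum of those averages. Edge handling matches the reference.
    """
    s = data.samples
    a, n, lines = s.shape
    if params.short_lag > n - 1:
        raise ValueError(f"short_lag must be <= N-1 = {n - 1}")
    skip, count = _edge_trim(params, a)
    sq_cum = np.concatenate(
        [np.zeros((a, 1, lines)), np.cumsum(s**2, axis=1)], axis=1
    )
    r_sum = np.zeros((a, lines))
    for m in range(1, params.short_lag + 1):
        num = np.einsum("ail,ail->al", s[:, : n - m, :], s[:, m:, :])
        e_lo = sq_cum[:, n - m, :] - sq_cum[:, 0, :]
        e_hi = sq_cum[:, n, :] - sq_cum[:, m, :]
        den = e_lo * e_hi
        r = np.zeros_like(num)
        np.divide(num, np.sqrt(den), out=r, where=den > 0)
        r_sum += r
    k = params.kernel_len
    windows = np.lib.stride_tricks.sliding_window_view(r_sum, k, axis=0)
    pixels = windows.mean(axis=-1)
    extra = skip - params.half_kernel
    if extra > 0:
        pixels = pixels[extra : pixels.shape[0] - extra]
    return SLSCImage(
        pixels=pixels, params=params, variant="gpu_style", axial_offset=skip
    )


def das_image(data: "ChannelData") -> np.ndarray:
    """Minimal delay-and-sum baseline.

    Channels are summed per pixel, the envelope is taken as the magnitude
    of the axial analytic signal, and the image is normalized to its
    maximum (left untouched if identically zero).
    """
    summed = data.samples.sum(axis=1)
    env = np.abs(scipy.signal.hilbert(summed, axis=0))
    peak = env.max()
    if peak > 0:
        env = env / peak
    return env


def resample_channel_data(data: "ChannelData", factor: float) -> "ChannelData":
    """Rescale axial sample count and scanline count by ``factor``.

    Axial resampling uses linear interpolation; lateral resampling
    decimates (factor < 1) or replicates (factor > 1) scanlines. The
    metadata sampling frequency is rescaled accordingly. Intended factors
    are 2, 1, 1/2, 1/4 and 1/8.
    """
    from .simulate import ChannelData, FrameMeta

    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1:
        return ChannelData(
            samples=data.samples.copy(),
            meta=data.meta,
            provenance=data.provenance + "|resample:1",
        )
    s = data.samples
    a, n, lines = s.shape
    new_a = int(round(a * factor))
    if new_a < 1:
        raise ValueError("resampling leaves no axial samples")
    pos = np.arange(new_a) / factor
    i0 = np.clip(np.floor(pos).astype(int), 0, a - 1)
    i1 = np.clip(i0 + 1, 0, a - 1)
    frac = (pos - i0).reshape(-1, 1, 1)
    axial = s[i0] * (1.0 - frac) + s[i1] * frac
    if factor > 1:
        rep = int(round(factor))
        lateral = np.repeat(axial, rep, axis=2)
    else:
        step = int(round(1.0 / factor))
        lateral = axial[:, :, ::step]
    meta = FrameMeta(
        n_channels=data.meta.n_channels,
        center_freq_hz=data.meta.center_freq_hz,
        sampling_freq_hz=data.meta.sampling_freq_hz * factor,
        seed=getattr(data.meta, "seed", None),
    )
    return ChannelData(
        samples=np.ascontiguousarray(lateral),
        meta=meta,
        provenance=data.provenance + f"|resample:{factor}",
    )
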