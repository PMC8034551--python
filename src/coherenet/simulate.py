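"""Synthetic focus-aligned RF channel data with controlled spatial coherence.

For diffuse scattering and a focused transmit, the van Cittert–Zernike
theorem predicts that the spatial covariance of the backscattered wavefield
across the receive aperture falls off as a triangle in element spacing
(lag) ``m``: roughly ``1 - m/N`` for an ``N``-element aperture. Rather than
simulating acoustic propagation from point scatterers, this module draws
band-limited Gaussian channel signals and *colors* them across the channel
axis with a matrix square root of the desired triangular covariance, which
gives exact control over the coherence ground truth while remaining fast
enough to regenerate whole datasets on demand.

Hypoechoic or anechoic lesions are carved into the field as circular
regions whose signal amplitude is scaled by their echogenicity; a fixed
channel-uncorrelated noise floor then dominates the attenuated signal
inside the lesion, reproducing the low-coherence lesion appearance that
short-lag spatial coherence imaging exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class Lesion:
    """Circular lesion in (axial sample, scanline) index coordinates."""

    center_axial: float
    center_lateral: float
    radius: float
    echogenicity_db: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"lesion radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and scene parameters for one synthetic frame.

    Defaults mirror a 64-element high-frequency linear-array acquisition:
    a 12.5 MHz broadband pulse sampled at 40 MHz. The wide fractional
    bandwidth keeps axial samples within the short correlation kernel
    weakly correlated, which keeps the finite-kernel bias of the
    normalized-correlation estimator small against the triangular
    coherence prediction.
    ``coherence_scale`` is the fraction of coherent signal power: the
    across-channel covariance of the speckle is
    ``coherence_scale * (1 - m/N)`` at lag ``m >= 1`` (unit variance at lag
    0). ``noise_db`` sets the channel-uncorrelated noise power relative to
    the mean speckle power; use ``-inf`` for a noiseless frame.
    """

    n_channels: int = 64
    n_axial: int = 400
    n_lines: int = 64
    center_freq_hz: float = 12.5e6
    sampling_freq_hz: float = 40.0e6
    fractional_bandwidth: float = 1.0
    coherence_scale: float = 1.0
    noise_db: float = -40.0
    lesions: tuple[Lesion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_axial < 1 or self.n_lines < 1:
            raise ValueError("n_axial and n_lines must be >= 1")
        if self.sampling_freq_hz <= 2.0 * self.center_freq_hz:
            raise ValueError(
                "sampling_freq_hz must exceed twice center_freq_hz "
                f"(got fs={self.sampling_freq_hz}, fc={self.center_freq_hz})"
            )
        if not (0.0 < self.fractional_bandwidth <= 1.0):
            raise ValueError("fractional_bandwidth must lie in (0, 1]")
        if not (0.0 <= self.coherence_scale <= 1.0):
            raise ValueError(
                f"coherence_scale must lie in [0, 1], got {self.coherence_scale}"
            )
        lesions = tuple(
            l if isinstance(l, Lesion) else Lesion(*l) for l in self.lesions
        )
        object.__setattr__(self, "lesions", lesions)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class FrameMeta:
    """Minimal acquisition metadata for frames not produced by the simulator.

    Unlike :class:`SimConfig` this carries no scene description and no
    Nyquist constraint, so it can describe deliberately sub-Nyquist
    resampled data and frames loaded from disk.
    """

    n_channels: int
    center_freq_hz: float
    sampling_freq_hz: float
    seed: Optional[int] = None


@dataclass
class ChannelData:
    """Time-delayed (focus-aligned) RF channel data.

    ``samples`` is a rank-3 float array indexed [axial sample, receive
    channel, scanline]. All beamformers in this package consume this
    container; receive delays are assumed already applied. ``meta`` is a
    :class:`SimConfig` for simulated frames or a :class:`FrameMeta` for
    loaded/derived ones.
    """

    samples: np.ndarray
    meta: "SimConfig | FrameMeta"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3:
            raise ValueError("samples must be rank-3 [axial, channel, line]")
        if self.samples.shape[1] != self.meta.n_channels:
            raise ValueError(
                f"channel axis length {self.samples.shape[1]} does not match "
                f"metadata n_channels {self.meta.n_channels}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("channel data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.samples.shape


def triangle_coherence(m, n_channels: int):
    """Predicted coherence ``1 - m/N`` at lag ``m`` for an ``N``-element aperture.

    Closed-form van Cittert–Zernike triangle used as the simulator oracle.
    Accepts scalar or array lags; raises for lags outside ``[0, N]``.
    """
    m_arr = np.asarray(m, dtype=np.float64)
    if np.any(m_arr < 0) or np.any(m_arr > n_channels):
        raise ValueError(f"lag must lie in [0, {n_channels}]")
    out = 1.0 - m_arr / float(n_channels)
    return out if out.ndim else float(out)


def channel_covariance(n_channels: int, coherence_scale: float) -> np.ndarray:
    """Target across-channel covariance: scaled triangle off-diagonal, unit diagonal."""
    m = np.abs(np.subtract.outer(np.arange(n_channels), np.arange(n_channels)))
    cov = coherence_scale * (1.0 - m / float(n_channels))
    np.fill_diagonal(cov, 1.0)
    return cov


def _covariance_sqrt(cov: np.ndarray, coherence_scale: float) -> np.ndarray:
    """Symmetric matrix square root via eigendecomposition.

    The triangular kernel is positive semidefinite for any
    ``coherence_scale`` in [0, 1]; eigenvalues below a small negative
    tolerance indicate a genuinely invalid configuration.
    """
    w, v = np.linalg.eigh(cov)
    tol = -1e-10 * max(w[-1], 1.0)
    if w[0] < tol:
        raise ValueError(
            "across-channel covariance is not positive semidefinite "
            f"(min eigenvalue {w[0]:.3e}); offending parameter: "
            f"coherence_scale={coherence_scale}"
        )
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _bandpass_noise(rng: np.random.Generator, shape, config: SimConfig) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited around the center frequency.

    A Gaussian-shaped passband is applied along the axial (fast-time) axis;
    its standard deviation is set so the fractional bandwidth is the full
    width at half maximum of the amplitude spectrum.
    """
    n_axial = shape[0]
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n_axial, d=1.0 / config.sampling_freq_hz)
    sigma_f = (
        config.fractional_bandwidth
        * config.center_freq_hz
        / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    )
    h = np.exp(-0.5 * ((freqs - config.center_freq_hz) / sigma_f) ** 2)
    spec = np.fft.rfft(white, axis=0) * h.reshape((-1,) + (1,) * (white.ndim - 1))
    x = np.fft.irfft(spec, n=n_axial, axis=0)
    rms = math.sqrt(float(np.mean(x**2)))
    if rms > 0:
        x /= rms
    return x


def lesion_amplitude_map(config: SimConfig) -> np.ndarray:
    """Per-(axial, line) linear amplitude scaling implied by the lesion list."""
    amp = np.ones((config.n_axial, config.n_lines))
    if not config.lesions:
        return amp
    ax = np.arange(config.n_axial)[:, None]
    lat = np.arange(config.n_lines)[None, :]
    for les in config.lesions:
        mask = (ax - les.center_axial) ** 2 + (lat - les.center_lateral) ** 2 <= (
            les.radius**2
        )
        amp[mask] = 10.0 ** (les.echogenicity_db / 20.0)
    return amp


def generate_speckle_frame(config: SimConfig) -> ChannelData:
    """Draw one seeded frame of diffuse speckle channel data.

    The across-channel field at each axial position is a zero-mean Gaussian
    process, band-limited axially around the center frequency, whose
    across-channel covariance is ``coherence_scale * tri(m/N)`` with unit
    variance. Lesions scale the signal amplitude by
    ``10**(echogenicity_db/20)``; channel-uncorrelated band-limited noise is
    added at ``noise_db`` relative to the mean speckle power. Identical
    configs (including seed) yield bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_axial, config.n_channels, config.n_lines)

    x = _bandpass_noise(rng, shape, config)
    cov = channel_covariance(config.n_channels, config.coherence_scale)
    sqrt_cov = _covariance_sqrt(cov, config.coherence_scale)
    # Color the channel axis at every (axial, line) position.
    s = np.einsum("ij,ajl->ail", sqrt_cov, x)

    amp = lesion_amplitude_map(config)
    s *= amp[:, None, :]

    if np.isfinite(config.noise_db):
        sigma_n = 10.0 ** (config.noise_db / 20.0)
        s += sigma_n * _bandpass_noise(rng, shape, config)

    return ChannelData(samples=s, meta=config, provenance=f"sim:seed={config.seed}")


@dataclass
class ExampleSet:
    """Paired kernels and reference coherence functions for one data split.

    ``inputs`` has shape [n_examples, kernel_len, n_channels]; ``targets``
    has shape [n_examples, n_channels] (lags 1..N, last entry fixed at 0).
    Every target is the reference normalized-correlation computation applied
    to its paired input.
    """

    inputs: np.ndarray
    targets: np.ndarray
    split_tag: str = "train"

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must have equal lengths")
        if self.split_tag not in {"train", "val", "test"}:
            raise ValueError(f"unknown split_tag {self.split_tag!r}")

    def __len__(self) -> int:
        return len(self.inputs)


def _check_frames(frames: Sequence[ChannelData], kernel_len: int) -> int:
    if kernel_len < 1 or kernel_len % 2 == 0:
        raise ValueError("kernel_len must be odd and >= 1")
    n_set = {f.meta.n_channels for f in frames}
    if len(n_set) > 1:
        raise ValueError(f"frames have mismatched channel counts: {sorted(n_set)}")
    n = n_set.pop() if n_set else 0
    if frames and n < 2:
        raise ValueError("frames must have at least 2 receive channels")
    return n


def _frame_kernels(frame: ChannelData, kernel_len: int) -> np.ndarray:
    """All complete kernels of a frame as [center*line, kernel_len, n_channels].

    Kernels overlapping the first/last (kernel_len-1)/2 axial samples are
    excluded; scanlines with fewer receive channels than the frame metadata
    promises never occur by construction of :class:`ChannelData`.
    """
    s = frame.samples
    windows = np.lib.stride_tricks.sliding_window_view(s, kernel_len, axis=0)
    # windows: [n_centers, channel, line, k] -> [n_centers, line, k, channel]
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1))


def build_example_set(frames, params, split_tag: str = "train") -> ExampleSet:
    """One example per (axial center, scanline) admitting a complete kernel.

    Targets are computed by the reference coherence estimator
    (:func:`coherenet.beamform.coherence_batch`), so recomputing it on any
    stored input reproduces the stored target exactly.
    """
    from .beamform import coherence_batch

    k = params.kernel_len
    n = _check_frames(frames, k)
    if not frames:
        return ExampleSet(
            inputs=np.zeros((0, k, 0)), targets=np.zeros((0, 0)), split_tag=split_tag
        )
    blocks = []
    for frame in frames:
        if frame.shape[0] < k:
            raise ValueError(
                f"frame has {frame.shape[0]} axial samples; kernel needs {k}"
            )
        kern = _frame_kernels(frame, k)
        blocks.append(kern.reshape(-1, k, n))
    inputs = np.concatenate(blocks, axis=0)
    targets = coherence_batch(inputs)
    return ExampleSet(inputs=inputs, targets=targets, split_tag=split_tag)


def sample_example_set(
    frames, params, n_examples: int, rng: np.random.Generator, split_tag: str = "train"
) -> ExampleSet:
    """Uniformly subsample ``n_examples`` valid kernel positions across frames.

    Used to build desk-scale training sets without materializing every
    kernel of every frame. Sampling is without replacement within the pooled
    position set.
    """
    from .beamform import coherence_batch

    k = params.kernel_len
    n = _check_frames(frames, k)
    if not frames:
        raise ValueError("cannot sample from an empty frame list")
    counts = []
    for frame in frames:
        n_centers = frame.shape[0] - k + 1
        if n_centers < 1:
            raise ValueError("frame too short for the kernel length")
        counts.append(n_centers * frame.shape[2])
    total = int(np.sum(counts))
    if n_examples > total:
        raise ValueError(f"requested {n_examples} examples but only {total} exist")
    chosen = np.sort(rng.choice(total, size=n_examples, replace=False))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    inputs = np.empty((n_examples, k, n))
    pos = 0
    for fi, frame in enumerate(frames):
        local = chosen[(chosen >= offsets[fi]) & (chosen < offsets[fi + 1])] - offsets[fi]
        if local.size == 0:
            continue
        kern = _frame_kernels(frame, k).reshape(-1, k, n)
        inputs[pos : pos + local.size] = kern[local]
        pos += local.size
    targets = coherence_batch(inputs)
    return ExampleSet(inputs=inputs, targets=targets, split_tag=split_tag)
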