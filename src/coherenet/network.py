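"""CohereNet: a fully connected estimator of spatial coherence functions.

The network maps one k x N kernel of zero-meaned, amplitude-normalized
channel data to the N-point coherence function that the reference
normalized-correlation estimator would compute from it. Four dense layers
act along the channel axis with weights shared across the k kernel rows
(ReLU, ReLU, ReLU, tanh); an average pool over the kernel axis then
collapses the k rows into the final 1 x N output. The tanh output layer
bounds every estimate inside (-1, 1), mirroring the range of a normalized
correlation. With the default sizes 64 -> 64 -> 128 -> 128 -> 64 the model
has exactly 37248 trainable parameters.

Training minimizes a Gaussian-weighted mean squared error over lags,
weighting the short-lag region (the part summed into SLSC pixels) most
heavily. Everything is plain NumPy in double precision: forward pass,
analytic backpropagation, and an Adam optimizer, which keeps training
deterministic for fixed seeds on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .beamform import KernelBlock, SLSCImage, SLSCParams, _edge_trim

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ChannelData, ExampleSet

_ACTIVATIONS = {"relu", "tanh"}


@dataclass(frozen=True)
class NetworkSpec:
    """Layer shapes and activations.

    ``input_shape`` is (kernel_len, n_channels); each entry of
    ``layer_sizes`` is the output width of one dense layer applied along
    the channel axis. The final activation must be tanh so the pooled
    output stays inside (-1, 1).
    """

    input_shape: tuple[int, int] = (7, 64)
    layer_sizes: tuple[int, ...] = (64, 128, 128, 64)
    activations: tuple[str, ...] = ("relu", "relu", "relu", "tanh")

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_shape", tuple(self.input_shape))
        object.__setattr__(self, "layer_sizes", tuple(self.layer_sizes))
        object.__setattr__(self, "activations", tuple(self.activations))
        if len(self.layer_sizes) != len(self.activations):
            raise ValueError("layer_sizes and activations must align")
        if not self.layer_sizes:
            raise ValueError("need at least one layer")
        for a in self.activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        if self.activations[-1] != "tanh":
            raise ValueError("final activation must be tanh")

    @property
    def widths(self) -> tuple[int, ...]:
        """Channel-axis widths (N_0, N_1, ..., N_L)."""
        return (self.input_shape[1],) + self.layer_sizes

    def param_count(self) -> int:
        w = self.widths
        return int(sum(w[i] * w[i + 1] + w[i + 1] for i in range(len(w) - 1)))


@dataclass
class TrainedModel:
    """CohereNet weights (list of (W, b) per layer) plus their spec."""

    spec: NetworkSpec
    weights: list[tuple[np.ndarray, np.ndarray]]
    init_seed: int = 0

    def param_count(self) -> int:
        return int(sum(w.size + b.size for w, b in self.weights))


@dataclass
class LossWeights:
    """Gaussian lag weights for the training loss (mu=0, sigma=25.6 default)."""

    values: np.ndarray
    mu: float = 0.0
    sigma: float = 25.6


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters: Adam, batch 128, 5 epochs, lr 0.001."""

    batch_size: int = 128
    epochs: int = 5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def init_model(spec: NetworkSpec, seed: int = 0) -> TrainedModel:
    """Fan-in-scaled random initialization, deterministic for a seed.

    He-normal weights for ReLU layers and Glorot-uniform for the tanh
    layer. Hidden biases start at zero; the output bias is warm-started at
    the inverse-tanh of the triangular coherence falloff ``1 - m/N`` so
    the untrained network already predicts the van Cittert-Zernike prior
    mean and the training budget is spent on kernel-to-kernel structure.
    """
    rng = np.random.default_rng(seed)
    widths = spec.widths
    weights = []
    for i, act in enumerate(spec.activations):
        fan_in, fan_out = widths[i], widths[i + 1]
        if act == "relu":
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        weights.append((w, np.zeros(fan_out)))
    n_out = widths[-1]
    tri = 1.0 - np.arange(1, n_out + 1) / float(n_out)
    w_last, _ = weights[-1]
    weights[-1] = (w_last, np.arctanh(np.clip(tri, -0.999, 0.999)))
    return TrainedModel(spec=spec, weights=weights, init_seed=seed)


def preprocess_blocks(blocks: np.ndarray) -> np.ndarray:
    """Zero-mean each channel over the kernel, then scale each channel to
    unit L2 norm.

    The reference coherence estimator is invariant to both operations, so
    the training target is unchanged. After this normalization every
    per-pair correlation in the reference estimator reduces to a plain dot
    product between channel columns, so the network only has to learn an
    average of bilinear forms rather than also approximating the per-pair
    energy normalization — which conditions training far better than
    block-level amplitude scaling. Zero-energy channels are left as zeros.
    """
    blocks = np.asarray(blocks, dtype=np.float64)
    single = blocks.ndim == 2
    if single:
        blocks = blocks[None]
    z = blocks - blocks.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.einsum("bki,bki->bi", z, z))[:, None, :]
    z = np.divide(z, norm, out=z, where=norm > 0)
    return z[0] if single else z


def _forward_cached(model: TrainedModel, x: np.ndarray):
    """Forward pass keeping pre/post-activation tensors for backprop.

    x: [B, k, N0]; dense layers act on the last axis, shared across rows.
    """
    acts = [x]
    h = x
    for (w, b), act in zip(model.weights, model.spec.activations):
        zlin = h @ w + b
        h = np.maximum(zlin, 0.0) if act == "relu" else np.tanh(zlin)
        acts.append(h)
    pooled = acts[-1].mean(axis=1)
    return pooled, acts


def forward(model: TrainedModel, block) -> np.ndarray:
    """Estimate the coherence function(s) for one block or a batch.

    Accepts a :class:`KernelBlock`, a [k, N] array, or a [B, k, N] batch;
    inputs are assumed already preprocessed (see
    :func:`preprocess_blocks`). Returns shape [N_L] or [B, N_L].
    """
    if isinstance(block, KernelBlock):
        x = block.samples
    else:
        x = np.asarray(block, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    k, n0 = model.spec.input_shape
    if x.shape[1] != k or x.shape[2] != n0:
        raise ValueError(f"expected input [*, {k}, {n0}], got {x.shape}")
    out, _ = _forward_cached(model, x)
    return out[0] if single else out


def gaussian_weights(
    n_lags: int = 64, mu: float = 0.0, sigma: float = 25.6
) -> LossWeights:
    """Unnormalized Gaussian weights over lags m = 1..n_lags."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    m = np.arange(1, n_lags + 1, dtype=np.float64)
    return LossWeights(
        values=np.exp(-((m - mu) ** 2) / (2.0 * sigma**2)), mu=mu, sigma=sigma
    )


def weighted_mse(estimate, target, w: LossWeights) -> float:
    """Lag-weighted mean squared error, averaged over lags (and any batch)."""
    est = np.asarray(estimate, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if est.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tgt.shape}")
    if est.shape[-1] != w.values.shape[0]:
        raise ValueError("weight vector length must match the lag axis")
    per = np.mean(w.values * (est - tgt) ** 2, axis=-1)
    return float(np.mean(per))


def loss_and_gradients(model: TrainedModel, x: np.ndarray, y: np.ndarray, w: LossWeights):
    """Weighted-MSE loss and analytic parameter gradients for one batch."""
    b, k, _ = x.shape
    n_lags = y.shape[1]
    pooled, acts = _forward_cached(model, x)
    diff = pooled - y
    loss = float(np.mean(w.values * diff**2))
    # d loss / d pooled, then broadcast back through the average pool.
    dpool = 2.0 * w.values * diff / (b * n_lags)
    grad = dpool[:, None, :].repeat(k, axis=1) / k
    grads = [None] * len(model.weights)
    for i in range(len(model.weights) - 1, -1, -1):
        act = model.spec.activations[i]
        a_out = acts[i + 1]
        dz = grad * (1.0 - a_out**2) if act == "tanh" else grad * (a_out > 0)
        a_in = acts[i]
        dw = np.einsum("bki,bkj->ij", a_in, dz)
        db = dz.sum(axis=(0, 1))
        grads[i] = (dw, db)
        if i > 0:
            grad = dz @ model.weights[i][0].T
    return loss, grads


def train(
    model: TrainedModel,
    train_set: "ExampleSet",
    val_set: Optional["ExampleSet"] = None,
    cfg: TrainConfig = TrainConfig(),
    loss_weights: Optional[LossWeights] = None,
) -> tuple[TrainedModel, TrainHistory]:
    """Mini-batch Adam training of the weighted-MSE objective.

    Inputs are preprocessed once up front. The model is updated in place
    and also returned. Training is deterministic for fixed model init and
    ``cfg.shuffle_seed`` on a single thread. Non-finite losses abort with
    a diagnostic.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    x = preprocess_blocks(train_set.inputs)
    y = np.asarray(train_set.targets, dtype=np.float64)
    if loss_weights is None:
        loss_weights = gaussian_weights(n_lags=y.shape[1])
    xv = yv = None
    if val_set is not None and len(val_set) > 0:
        xv = preprocess_blocks(val_set.inputs)
        yv = np.asarray(val_set.targets, dtype=np.float64)

    rng = np.random.default_rng(cfg.shuffle_seed)
    m_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in model.weights]
    v_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in model.weights]
    history = TrainHistory()
    step = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x))
        epoch_losses = []
        for start in range(0, len(x), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            loss, grads = loss_and_gradients(model, x[idx], y[idx], loss_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {step} (loss={loss})"
                )
            epoch_losses.append(loss)
            step += 1
            bc1 = 1.0 - cfg.beta1**step
            bc2 = 1.0 - cfg.beta2**step
            for i, (w, b) in enumerate(model.weights):
                gw, gb = grads[i]
                mw, mb = m_state[i]
                vw, vb = v_state[i]
                mw = cfg.beta1 * mw + (1 - cfg.beta1) * gw
                mb = cfg.beta1 * mb + (1 - cfg.beta1) * gb
                vw = cfg.beta2 * vw + (1 - cfg.beta2) * gw**2
                vb = cfg.beta2 * vb + (1 - cfg.beta2) * gb**2
                m_state[i] = (mw, mb)
                v_state[i] = (vw, vb)
                w -= cfg.learning_rate * (mw / bc1) / (np.sqrt(vw / bc2) + cfg.eps)
                b -= cfg.learning_rate * (mb / bc1) / (np.sqrt(vb / bc2) + cfg.eps)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if xv is not None:
            history.val_loss.append(
                weighted_mse(_predict_batched(model, xv), yv, loss_weights)
            )
    return model, history


def _predict_batched(
    model: TrainedModel, x: np.ndarray, chunk: int = 16384
) -> np.ndarray:
    outs = [forward(model, x[i : i + chunk]) for i in range(0, len(x), chunk)]
    return np.concatenate(outs, axis=0)


def predict_coherence(model: TrainedModel, blocks: np.ndarray) -> np.ndarray:
    """Preprocess raw kernel blocks and run the network."""
    return _predict_batched(model, preprocess_blocks(blocks))


def lag_band_mse(model: TrainedModel, example_set: "ExampleSet", split_lag: int = 25):
    """Unweighted MSE below/above a lag cutoff on a held-out example set.

    Returns (mse at lags <= split_lag, mse at lags > split_lag).
    """
    pred = predict_coherence(model, example_set.inputs)
    tgt = np.asarray(example_set.targets, dtype=np.float64)
    err = (pred - tgt) ** 2
    return float(err[:, :split_lag].mean()), float(err[:, split_lag:].mean())


def slsc_image_dnn(
    model: TrainedModel, data: "ChannelData", params: SLSCParams = SLSCParams()
) -> SLSCImage:
    """SLSC image with the learned estimator in place of the reference one.

    Pixel grid, preprocessing of each kernel, and edge handling are
    identical to the reference image; only the coherence computation is
    replaced by the network forward pass.
    """
    from .simulate import _frame_kernels

    a, n, lines = data.shape
    k, n0 = model.spec.input_shape
    if params.kernel_len != k or n != n0:
        raise ValueError(
            f"model expects kernels [{k}, {n0}]; got kernel_len="
            f"{params.kernel_len}, N={n}"
        )
    if params.short_lag > model.spec.layer_sizes[-1]:
        raise ValueError("short_lag exceeds the network output length")
    skip, _ = _edge_trim(params, a)
    kernels = _frame_kernels(data, k).reshape(-1, k, n)
    coh = predict_coherence(model, kernels)
    pixels = coh[:, : params.short_lag].sum(axis=1).reshape(a - k + 1, lines)
    extra = skip - params.half_kernel
    if extra > 0:
        pixels = pixels[extra : pixels.shape[0] - extra]
    return SLSCImage(pixels=pixels, params=params, variant="dnn", axial_offset=skip)


def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint: spec as JSON plus raw weight arrays."""
    spec_json = json.dumps(
        {
            "input_shape": list(model.spec.input_shape),
            "layer_sizes": list(model.spec.layer_sizes),
            "activations": list(model.spec.activations),
            "init_seed": model.init_seed,
        }
    )
    arrays = {}
    for i, (w, b) in enumerate(model.weights):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, spec=np.bytes_(spec_json.encode()), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["spec"]).decode())
        spec = NetworkSpec(
            input_shape=tuple(meta["input_shape"]),
            layer_sizes=tuple(meta["layer_sizes"]),
            activations=tuple(meta["activations"]),
        )
        weights = [
            (data[f"w{i}"].copy(), data[f"b{i}"].copy())
            for i in range(len(spec.layer_sizes))
        ]
    return TrainedModel(spec=spec, weights=weights, init_seed=meta["init_seed"])
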