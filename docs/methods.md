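# Methods

This note documents the models, estimators and design choices behind the
package, what the synthetic data does and does not emulate, and the
numerical conventions a user relying on the outputs should know.

## Reference coherence estimator

The spatial coherence function of one image pixel is estimated from a
`k x N` kernel of focus-aligned channel data (`k = 7` axial samples,
`N = 64` receive channels by default). Each channel column is zero-meaned
over the kernel; the coherence at lag `m` is the average over the `N - m`
element pairs of the per-pair normalized correlation, and the SLSC pixel
is the sum of the first `M = 25` lags. Conventions:

* The coherence vector has `N` entries for lags `1..N`; the lag-`N` entry
  is an empty pair sum and is fixed at 0. This reconciles the estimator
  (defined only to lag `N - 1`) with the network's `1 x 64` output.
* A pair containing a zero-energy channel (e.g. a constant column)
  contributes 0 to the lag average, while the `1/(N - m)` normalization
  keeps the full pair count; a lag where every pair is degenerate yields
  0. This avoids division by zero without biasing the usual case.
* Pixel `n` is the kernel center; for `k = 7` the kernel spans
  `n-3..n+3`, and the first/last three axial pixels of each image are
  dropped (`edge_skip`) because their kernels would be incomplete.
* The whole reference path runs in double precision; the vectorized
  implementation is verified against naive scalar-loop transcriptions at
  1e-12 in the test suite.

The single-sample "GPU-style" variant computes one correlation per time
sample with a single aggregate normalization per lag (no zero-meaning, no
kernel in the correlation itself) and reintroduces the kernel afterwards
by averaging the per-sample correlations over the kernel window. The
exact normalization grouping follows the published description of the
parallel implementation; it is a reconstruction from prose, fixed and
documented here rather than guaranteed identical to any particular GPU
kernel. On synthetic speckle it correlates with the reference image at
roughly 0.76–0.79, which is the quality gap the learned estimator closes.

## Speckle simulator

Frames are synthesized directly in the coherence domain rather than by
point-scatterer acoustics: independent Gaussian channel signals are
band-limited axially (Gaussian passband) and then colored across the
channel axis with the symmetric matrix square root of the target
covariance `C = c * T + (1 - c) * I`, where `T` is the triangular
van Cittert–Zernike matrix `T[i,j] = 1 - |i-j|/N` and
`c = coherence_scale`. This gives exact, per-frame control of the
coherence ground truth at desk-scale cost.

Parameters that matter:

* `center_freq_hz = 12.5 MHz`, `sampling_freq_hz = 40 MHz`,
  `fractional_bandwidth = 1.0`. These mirror a high-frequency 64-element
  linear array (transmit near 12.5 MHz, 40 MHz sampling). The broadband
  pulse is deliberate: the normalized-correlation estimator on a `k = 7`
  kernel has a negative bias that grows with the temporal correlation of
  kernel samples, and at this bandwidth the measured mean coherence of
  fully coherent speckle stays within ±0.05 of the triangle for
  `m <= N/2` (the estimator's intrinsic bias floor is ~0.03 at mid lags
  even for white kernel samples; narrower pulses push it past 0.06).
* `noise_db` adds channel-uncorrelated band-limited noise relative to
  the unit mean speckle power (−40 dB in the default study).
* Lesions are circles in (axial sample, scanline) index units whose
  signal amplitude is scaled by `10^(echogenicity_db/20)`. Coherence
  loss inside a lesion arises solely from the fixed noise floor
  dominating the attenuated signal — there is no separate clutter model.
  At −40 dB echogenicity against the −40 dB floor the interior keeps
  about half its coherent power, emulating a hypoechoic mass; −60 dB is
  effectively anechoic.

What the simulator does **not** emulate: transmit sequencing, element
directivity, attenuation, aberration, reverberation clutter, and the
axial/lateral anisotropy of real point spread functions (lesion "circles"
are circular in index units, not millimeters). Passing tests therefore
demonstrate correctness of the estimators and the learning pipeline under
controlled coherence, not clinical image quality.

## CohereNet

Four dense layers (64→64, 64→128, 128→128, 128→64) act along the channel
axis with weights shared across the `k` kernel rows — the only reading of
the layer shapes `7 x 64 / 7 x 128 / ...` consistent with the 37248
parameter count `sum_i (N_i N_{i+1} + N_{i+1})`. Three ReLU activations,
a final tanh bounding outputs in (−1, 1), then an average pool collapses
the kernel axis into the `1 x 64` coherence estimate.

Because no deep-learning framework is part of this package's dependency
footprint, the forward pass, analytic backpropagation and Adam optimizer
are implemented directly in NumPy (double precision). Gradients are
verified against central finite differences at 1e-4 relative tolerance;
training is bit-deterministic for fixed init/shuffle seeds on one thread.

Choices the architecture description leaves open, decided here:

* **Input normalization.** Each kernel is zero-meaned per channel and
  each channel scaled to unit L2 norm. The reference estimator is
  invariant to both, so targets are unchanged, and every per-pair
  correlation then reduces to a plain dot product — the network learns an
  average of bilinear forms instead of also having to approximate the
  per-pair energy division. Under the fixed training budget this is the
  difference between ~0.92 and ~0.99 image-to-image correlation with the
  reference.
* **Initialization.** He-normal weights for ReLU layers, Glorot-uniform
  for the tanh layer, zero hidden biases. The output bias is warm-started
  at `atanh(1 - m/N)` so the untrained network already predicts the
  triangular prior mean and the few thousand optimizer steps available
  are spent on kernel-to-kernel structure.
* **Loss.** Weighted MSE over all 64 output lags with unnormalized
  Gaussian lag weights (mu = 0, sigma = 25.6); the `1/M` prefactor (with
  `M` read as the 64-lag output length) absorbs scale. Adam uses its
  canonical defaults (0.9 / 0.999 / 1e-8).

Training hyperparameters are fixed: batch 128, five epochs, learning rate
0.001.

## Synthetic study design and problem sizes

The default experiment emulates subject-level splitting with disjoint
seed ranges: 18 train / 3 validation / 3 test "patients", two
400 x 64 x 64 frames each. Training and validation patients carry two
seeded random lesions (radius 8–16 samples, echogenicity −60…−15 dB) so
the network sees the full range of coherence levels; test patients carry
one fixed −40 dB lesion at a known position so ROI placement is
deterministic. ~100k training examples are drawn per run, with 25% of
each frame's quota sampled from lesion interiors — area-uniform sampling
would leave low-coherence kernels at a few percent of the data and
measurably biases the trained estimator inside lesions. These sizes keep
the full study at a few minutes on one CPU core while leaving the trained
estimator within ~1% of the reference image.

## Image-quality metrics

Contrast `20 log10(S_i/S_o)`, SNR `S_o/sigma_o`, CNR
`|S_i - S_o| / sqrt(sigma_i^2 + sigma_o^2)` and gCNR
`1 - sum min(p_i, p_o)` are computed on raw SLSC pixel values before any
display normalization. The gCNR histograms use 256 shared-range bins by
default (configurable; the analytic half-overlap check passes for any
`n_bins >= 64`, and results depend only weakly on the choice). On
synthetic frames the inside ROI is concentric with the lesion at 0.8 of
its radius; the background ROI is the same shape and size at the same
depth, laterally offset by 2.6 lesion radii (flipped to the other side
when it would leave the image). Zero denominators produce explicitly
undefined metrics, never infinities. Display normalization divides by the
brightest pixel and clamps negatives to zero.

## Known limitations

* The single-sample variant is a prose-faithful reconstruction, not a
  port of any specific GPU kernel.
* Wall-clock timings from `timing_sweep` are host-dependent and
  informational only; FLOP counts are the portable complexity measure.
* The homogeneous synthetic background yields SLSC SNR around 8 —
  higher than heterogeneous tissue (≈ 3) — so absolute SNR differences
  between reference and learned images run 2–3x larger here than the
  same relative fidelity would produce in vivo, even at short-lag
  estimation error (~0.002 MSE) matching the in vivo figure.
* The short-lag cutoff `M` is a parameter (default 25), not a claimed
  reproduction of any particular clinical setting.
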