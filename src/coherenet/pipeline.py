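"""End-to-end experiment orchestration on synthetic data.

Reproduces the experimental structure of a coherence-learning study
without scanner data: simulate per-"patient" speckle frames with seeded,
disjoint train/validation/test splits; build kernel/coherence example
sets; train the coherence network; beamform every test frame with the
reference, single-sample (GPU-style) and learned estimators; and compare
the variants by image-to-image correlation and lesion image-quality
metrics.

Subject-level splitting is emulated by giving every synthetic patient its
own seed range, so no test kernel can ever appear in training. Training
and validation patients carry randomized hypoechoic lesions (position,
size and echogenicity drawn from the patient seed) so the network sees
the full range of coherence levels; test patients carry one fixed lesion
so ROI placement is deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .beamform import SLSCParams, slsc_image_cpu, slsc_image_gpu_style
from .metrics import compute_metrics, image_correlation, lesion_roi_masks, roi_stats
from .network import (
    NetworkSpec,
    TrainConfig,
    init_model,
    lag_band_mse,
    slsc_image_dnn,
    train,
)
from .simulate import ChannelData, Lesion, SimConfig, generate_speckle_frame

_METRIC_KEYS = ("contrast_db", "snr", "cnr", "gcnr")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one synthetic train/evaluate experiment."""

    seed: int = 0
    base_sim: SimConfig = SimConfig()
    n_train_patients: int = 18
    n_val_patients: int = 3
    n_test_patients: int = 3
    frames_per_patient: int = 2
    slsc: SLSCParams = SLSCParams()
    network: NetworkSpec = NetworkSpec()
    train_cfg: TrainConfig = TrainConfig()
    n_train_examples: int = 100_000
    n_val_examples: int = 10_000
    lesion_sample_fraction: float = 0.25
    test_lesion: Lesion = Lesion(200.0, 20.0, 10.0, -40.0)
    metrics_bins: int = 256
    roi_fraction: float = 0.8
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_test_patients < 1:
            raise ValueError("need at least one test patient")
        if self.n_train_patients < 1:
            raise ValueError("need at least one training patient")
        if self.frames_per_patient < 1:
            raise ValueError("frames_per_patient must be >= 1")


def _patient_ids(cfg: ExperimentConfig) -> dict[str, list[int]]:
    """Disjoint integer patient ids per split."""
    return {
        "train": list(range(cfg.n_train_patients)),
        "val": [100 + i for i in range(cfg.n_val_patients)],
        "test": [200 + i for i in range(cfg.n_test_patients)],
    }


def _frame_seed(cfg: ExperimentConfig, patient_id: int, frame_idx: int) -> int:
    return cfg.seed * 100_000 + patient_id * 10 + frame_idx


def _random_lesions(cfg: ExperimentConfig, patient_id: int) -> tuple[Lesion, ...]:
    """Two seeded lesions with varied size/position/echogenicity."""
    rng = np.random.default_rng(cfg.seed * 100_000 + patient_id * 10 + 7)
    sim = cfg.base_sim
    lesions = []
    for _ in range(2):
        radius = rng.uniform(8.0, 16.0)
        lesions.append(
            Lesion(
                center_axial=rng.uniform(0.15 * sim.n_axial, 0.85 * sim.n_axial),
                center_lateral=rng.uniform(0.15 * sim.n_lines, 0.85 * sim.n_lines),
                radius=radius,
                echogenicity_db=rng.uniform(-60.0, -15.0),
            )
        )
    return tuple(lesions)


def _sample_balanced(frames, cfg: ExperimentConfig, n_examples, rng, split_tag):
    """Lesion-balanced kernel sampling across frames.

    Plain area-uniform sampling lets diffuse full-coherence speckle
    dominate the training set (lesions cover only a few percent of each
    frame), starving the network of low/intermediate-coherence examples.
    Mirroring the heterogeneity of tissue data, a fixed fraction of each
    frame's quota is drawn from within its lesions, the rest uniformly
    from the whole frame. Targets are computed by the reference estimator,
    exactly as in :func:`coherenet.simulate.sample_example_set`.
    """
    from .beamform import coherence_batch
    from .simulate import _frame_kernels, lesion_amplitude_map

    k = cfg.slsc.kernel_len
    h = (k - 1) // 2
    quotas = np.full(len(frames), n_examples // len(frames))
    quotas[: n_examples - quotas.sum()] += 1
    inputs = []
    for frame, quota in zip(frames, quotas):
        n_centers = frame.shape[0] - k + 1
        total = n_centers * frame.shape[2]
        if quota > total:
            raise ValueError("frame too small for its sampling quota")
        amp = lesion_amplitude_map(frame.meta)
        lesion_flat = (amp[h : h + n_centers] != 1.0).ravel()
        lesion_idx = np.flatnonzero(lesion_flat)
        n_lesion = min(
            int(round(cfg.lesion_sample_fraction * quota)), lesion_idx.size
        )
        chosen_lesion = (
            rng.choice(lesion_idx, size=n_lesion, replace=False)
            if n_lesion
            else np.empty(0, dtype=int)
        )
        rest_pool = np.setdiff1d(np.arange(total), chosen_lesion, assume_unique=False)
        chosen_rest = rng.choice(rest_pool, size=quota - n_lesion, replace=False)
        chosen = np.sort(np.concatenate([chosen_lesion, chosen_rest]))
        kern = _frame_kernels(frame, k).reshape(-1, k, frame.shape[1])
        inputs.append(kern[chosen])
    inputs = np.concatenate(inputs, axis=0)
    from .simulate import ExampleSet

    return ExampleSet(
        inputs=inputs, targets=coherence_batch(inputs), split_tag=split_tag
    )


def simulate_split(cfg: ExperimentConfig, split: str) -> list[ChannelData]:
    """Generate all frames of one split ('train', 'val' or 'test')."""
    frames = []
    for pid in _patient_ids(cfg)[split]:
        lesions = (
            (cfg.test_lesion,) if split == "test" else _random_lesions(cfg, pid)
        )
        for fi in range(cfg.frames_per_patient):
            sim = dataclasses.replace(
                cfg.base_sim, lesions=lesions, seed=_frame_seed(cfg, pid, fi)
            )
            frames.append(generate_speckle_frame(sim))
    return frames


def _frame_quality(image, lesion, bins, roi_fraction):
    inner, outer = lesion_roi_masks(
        image.pixels.shape, lesion, axial_offset=image.axial_offset,
        roi_fraction=roi_fraction,
    )
    stats = roi_stats(image.pixels, inner, outer, n_bins=bins)
    return compute_metrics(stats)


def _diff_summary(diffs: dict[str, list[float]]) -> dict:
    out = {}
    for key, vals in diffs.items():
        arr = np.asarray(vals, dtype=np.float64)
        out[key] = {
            "mean": float(arr.mean()),
            "std": float(arr.std()),
            "mean_abs": float(np.abs(arr).mean()),
        }
    return out


def run_experiment(cfg: ExperimentConfig = ExperimentConfig()) -> dict:
    """Run the full pipeline and return (and optionally write) the report.

    The report carries a manifest of every seed used, per-test-frame image
    correlations and quality metrics for all three variants, and aggregate
    means and standard deviations of the cross-variant differences. The
    whole run is deterministic for a fixed config.
    """
    ids = _patient_ids(cfg)
    train_frames = simulate_split(cfg, "train")
    val_frames = simulate_split(cfg, "val") if cfg.n_val_patients else []
    test_frames = simulate_split(cfg, "test")

    rng_sample = np.random.default_rng(cfg.seed * 100_000 + 50_000)
    train_set = _sample_balanced(
        train_frames, cfg, cfg.n_train_examples, rng_sample, "train"
    )
    del train_frames
    val_set = None
    if val_frames and cfg.n_val_examples:
        val_set = _sample_balanced(
            val_frames, cfg, cfg.n_val_examples, rng_sample, "val"
        )
    del val_frames

    model = init_model(cfg.network, seed=cfg.seed * 100_000 + 60_000)
    train_cfg = dataclasses.replace(
        cfg.train_cfg, shuffle_seed=cfg.seed * 100_000 + 60_001
    )
    model, history = train(model, train_set, val_set, train_cfg)

    mse_short = mse_long = None
    if val_set is not None:
        mse_short, mse_long = lag_band_mse(model, val_set, split_lag=cfg.slsc.short_lag)

    frame_rows = []
    diffs_dnn = {k: [] for k in _METRIC_KEYS}
    diffs_gpu = {k: [] for k in _METRIC_KEYS}
    corr_dnn, corr_gpu = [], []
    for frame in test_frames:
        img_cpu = slsc_image_cpu(frame, cfg.slsc)
        img_gpu = slsc_image_gpu_style(frame, cfg.slsc)
        img_dnn = slsc_image_dnn(model, frame, cfg.slsc)
        c_dnn = image_correlation(img_dnn.pixels, img_cpu.pixels)
        c_gpu = image_correlation(img_gpu.pixels, img_cpu.pixels)
        corr_dnn.append(c_dnn)
        corr_gpu.append(c_gpu)
        row = {"provenance": frame.provenance, "corr_dnn_cpu": c_dnn,
               "corr_gpu_cpu": c_gpu}
        quality = {}
        for name, img in (("cpu", img_cpu), ("gpu", img_gpu), ("dnn", img_dnn)):
            quality[name] = _frame_quality(
                img, cfg.test_lesion, cfg.metrics_bins, cfg.roi_fraction
            )
            for key in _METRIC_KEYS:
                row[f"{name}_{key}"] = getattr(quality[name], key)
        for key in _METRIC_KEYS:
            ref = getattr(quality["cpu"], key)
            for name, bucket in (("dnn", diffs_dnn), ("gpu", diffs_gpu)):
                val = getattr(quality[name], key)
                if ref is None or val is None:
                    raise RuntimeError(
                        f"metric {key} undefined on a test frame ({name} variant)"
                    )
                bucket[key].append(val - ref)
        frame_rows.append(row)

    report = {
        "manifest": {
            "seed": cfg.seed,
            "patient_ids": ids,
            "frame_seeds": {
                split: [
                    _frame_seed(cfg, pid, fi)
                    for pid in ids[split]
                    for fi in range(cfg.frames_per_patient)
                ]
                for split in ids
            },
            "n_train_examples": len(train_set),
            "n_val_examples": 0 if val_set is None else len(val_set),
            "slsc": {
                "kernel_len": cfg.slsc.kernel_len,
                "short_lag": cfg.slsc.short_lag,
                "edge_skip": cfg.slsc.edge_skip,
            },
            "train": {
                "batch_size": cfg.train_cfg.batch_size,
                "epochs": cfg.train_cfg.epochs,
                "learning_rate": cfg.train_cfg.learning_rate,
            },
            "frame_shape": [
                cfg.base_sim.n_axial, cfg.base_sim.n_channels, cfg.base_sim.n_lines
            ],
        },
        "history": {"train_loss": history.train_loss, "val_loss": history.val_loss},
        "frames": frame_rows,
        "aggregate": {
            "mean_corr_dnn_cpu": float(np.mean(corr_dnn)),
            "mean_corr_gpu_cpu": float(np.mean(corr_gpu)),
            "metric_diff_dnn_cpu": _diff_summary(diffs_dnn),
            "metric_diff_gpu_cpu": _diff_summary(diffs_gpu),
            "val_mse_short_lag": mse_short,
            "val_mse_long_lag": mse_long,
        },
    }

    if cfg.output_dir is not None:
        from .io import save_report

        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_report(report, out / "report.json")
        pd.DataFrame(frame_rows).to_csv(out / "frames.csv", index=False)
        from .network import save_model

        save_model(model, out / "model.ckpt.npz")

    report["_model"] = model  # in-memory convenience; not serialized
    return report
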