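"""Reading and writing channel-data containers and image files.

Channel data lives in HDF5 (dataset ``samples`` [axial, channel, line]
with acquisition attributes) or NPZ with the same names; the format is
chosen by file extension. SLSC images are written as NPZ plus an optional
8-bit PNG preview after linear display normalization.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .simulate import ChannelData, FrameMeta, Lesion, SimConfig

_H5_EXTS = {".h5", ".hdf5", ".hdf"}


def save_channel_data(data: ChannelData, path) -> None:
    path = Path(path)
    attrs = {
        "n_channels": data.meta.n_channels,
        "center_freq_hz": data.meta.center_freq_hz,
        "sampling_freq_hz": data.meta.sampling_freq_hz,
        "seed": -1 if getattr(data.meta, "seed", None) is None else data.meta.seed,
        "provenance": data.provenance,
    }
    if path.suffix in _H5_EXTS:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("samples", data=data.samples)
            for key, val in attrs.items():
                ds.attrs[key] = val
    elif path.suffix == ".npz":
        np.savez(path, samples=data.samples, **attrs)
    else:
        raise ValueError(f"unsupported channel-data extension {path.suffix!r}")


def load_channel_data(path) -> ChannelData:
    path = Path(path)
    if path.suffix in _H5_EXTS:
        with h5py.File(path, "r") as f:
            ds = f["samples"]
            samples = ds[...]
            attrs = dict(ds.attrs)
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            samples = npz["samples"]
            attrs = {k: npz[k][()] for k in npz.files if k != "samples"}
    else:
        raise ValueError(f"unsupported channel-data extension {path.suffix!r}")
    seed = int(attrs.get("seed", -1))
    meta = FrameMeta(
        n_channels=int(attrs["n_channels"]),
        center_freq_hz=float(attrs["center_freq_hz"]),
        sampling_freq_hz=float(attrs["sampling_freq_hz"]),
        seed=None if seed < 0 else seed,
    )
    provenance = str(attrs.get("provenance", f"file:{path.name}"))
    return ChannelData(samples=samples, meta=meta, provenance=provenance)


def save_image(image, path, png_preview: bool = False) -> None:
    """Write an SLSC image (or bare array) as NPZ; optionally a PNG preview."""
    from .beamform import SLSCImage
    from .metrics import normalize_display

    path = Path(path)
    if isinstance(image, SLSCImage):
        np.savez(
            path,
            pixels=image.pixels,
            variant=image.variant,
            kernel_len=image.params.kernel_len,
            short_lag=image.params.short_lag,
            edge_skip=image.params.edge_skip,
            axial_offset=image.axial_offset,
        )
        pixels = image.pixels
    else:
        pixels = np.asarray(image)
        np.savez(path, pixels=pixels)
    if png_preview:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # pragma: no cover
            return
        disp = normalize_display(pixels)
        plt.imsave(path.with_suffix(".png"), disp, cmap="gray", vmin=0.0, vmax=1.0)


def load_image(path):
    from .beamform import SLSCImage, SLSCParams

    with np.load(path, allow_pickle=False) as npz:
        if "variant" not in npz.files:
            return npz["pixels"]
        params = SLSCParams(
            kernel_len=int(npz["kernel_len"]),
            short_lag=int(npz["short_lag"]),
            edge_skip=int(npz["edge_skip"]),
        )
        return SLSCImage(
            pixels=npz["pixels"],
            params=params,
            variant=str(npz["variant"]),
            axial_offset=int(npz["axial_offset"]),
        )


def sim_config_from_dict(raw: dict) -> SimConfig:
    raw = dict(raw)
    lesions = tuple(
        Lesion(**l) if isinstance(l, dict) else Lesion(*l)
        for l in raw.pop("lesions", ())
    )
    return SimConfig(lesions=lesions, **raw)


def load_sim_config(path) -> SimConfig:
    """SimConfig from a YAML or JSON file."""
    path = Path(path)
    with open(path) as f:
        raw = json.load(f) if path.suffix == ".json" else yaml.safe_load(f)
    return sim_config_from_dict(raw)


def save_report(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
        f.write("\n")
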