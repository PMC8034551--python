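"""Image-quality metrics for beamformed images.

Contrast, SNR, CNR and generalized CNR (gCNR) computed from pixel
statistics inside/outside a target region, plus Pearson image-to-image
correlation and linear display normalization. All ROI statistics operate
on raw (pre-log-compression) pixel values.

    contrast = 20 log10(S_i / S_o)          [dB]
    SNR      = S_o / sigma_o
    CNR      = |S_i - S_o| / sqrt(sigma_i^2 + sigma_o^2)
    gCNR     = 1 - sum_x min{p_i(x), p_o(x)}

where S and sigma are ROI means and standard deviations and p_i, p_o are
normalized pixel-value histograms over shared bin edges. gCNR is bounded
in [0, 1] and invariant to monotone intensity transforms, making it a
robust lesion-detectability measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class ROIStats:
    """Pre-log pixel statistics of a target/background ROI pair."""

    mean_in: float
    mean_out: float
    std_in: float
    std_out: float
    hist_in: np.ndarray
    hist_out: np.ndarray


@dataclass
class QualityReport:
    """Metric values; entries are ``None`` where a denominator vanished."""

    contrast_db: Optional[float]
    snr: Optional[float]
    cnr: Optional[float]
    gcnr: float
    correlation_vs_reference: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "contrast_db": self.contrast_db,
            "snr": self.snr,
            "cnr": self.cnr,
            "gcnr": self.gcnr,
            "correlation_vs_reference": self.correlation_vs_reference,
        }


def roi_stats(
    image: np.ndarray,
    roi_in: np.ndarray,
    roi_out: np.ndarray,
    n_bins: int = 256,
) -> ROIStats:
    """Means, standard deviations and shared-edge histograms of two ROIs.

    Histogram edges span the combined min-max of both ROIs; a constant
    combined range degenerates to a single bin holding all mass.
    """
    image = np.asarray(image, dtype=np.float64)
    roi_in = np.asarray(roi_in, dtype=bool)
    roi_out = np.asarray(roi_out, dtype=bool)
    if roi_in.shape != image.shape or roi_out.shape != image.shape:
        raise ValueError("masks must match the image shape")
    if not roi_in.any() or not roi_out.any():
        raise ValueError("both ROIs must be non-empty")
    if np.any(roi_in & roi_out):
        raise ValueError("ROIs must be disjoint")
    vin = image[roi_in]
    vout = image[roi_out]
    lo = min(vin.min(), vout.min())
    hi = max(vin.max(), vout.max())
    if hi == lo:
        p_in = np.zeros(n_bins)
        p_out = np.zeros(n_bins)
        p_in[0] = 1.0
        p_out[0] = 1.0
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        p_in = np.histogram(vin, bins=edges)[0] / vin.size
        p_out = np.histogram(vout, bins=edges)[0] / vout.size
    return ROIStats(
        mean_in=float(vin.mean()),
        mean_out=float(vout.mean()),
        std_in=float(vin.std()),
        std_out=float(vout.std()),
        hist_in=p_in,
        hist_out=p_out,
    )


def compute_metrics(stats: ROIStats) -> QualityReport:
    """All four metrics from one ROI statistics object.

    Zero denominators (or non-positive means for the log contrast) produce
    ``None`` rather than infinities.
    """
    contrast = None
    if stats.mean_in > 0 and stats.mean_out > 0:
        contrast = float(20.0 * np.log10(stats.mean_in / stats.mean_out))
    snr = float(stats.mean_out / stats.std_out) if stats.std_out > 0 else None
    denom = np.hypot(stats.std_in, stats.std_out)
    cnr = float(abs(stats.mean_in - stats.mean_out) / denom) if denom > 0 else None
    gcnr = float(1.0 - np.minimum(stats.hist_in, stats.hist_out).sum())
    return QualityReport(contrast_db=contrast, snr=snr, cnr=cnr, gcnr=gcnr)


def image_correlation(image_a: np.ndarray, image_b: np.ndarray) -> Optional[float]:
    """Pearson correlation over all co-located pixels; ``None`` if either
    image is constant."""
    a = np.asarray(image_a, dtype=np.float64).ravel()
    b = np.asarray(image_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal shapes")
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def normalize_display(image: np.ndarray) -> np.ndarray:
    """Linear display normalization: divide by the brightest pixel and clamp
    negatives to zero, yielding values in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    peak = image.max()
    if peak <= 0:
        raise ValueError("image has no positive pixels to normalize against")
    return np.clip(image / peak, 0.0, None)


def circular_mask(shape, center, radius) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def lesion_roi_masks(
    image_shape,
    lesion,
    axial_offset: int = 0,
    roi_fraction: float = 0.8,
    background_lateral_offset: Optional[float] = None,
):
    """Inside/background ROI masks for a simulated lesion.

    The inside ROI is a circle concentric with the lesion at
    ``roi_fraction`` of its radius; the background ROI is the same shape
    and size at the same axial depth, laterally offset (default: 2.6 lesion
    radii, clear of the lesion boundary). ``axial_offset`` maps lesion
    coordinates (channel-data axial samples) into image rows.
    """
    row = lesion.center_axial - axial_offset
    r = roi_fraction * lesion.radius
    if background_lateral_offset is None:
        background_lateral_offset = 2.6 * lesion.radius
    inner = circular_mask(image_shape, (row, lesion.center_lateral), r)
    bg_col = lesion.center_lateral + background_lateral_offset
    if bg_col + r > image_shape[1] - 1:
        bg_col = lesion.center_lateral - background_lateral_offset
    outer = circular_mask(image_shape, (row, bg_col), r)
    if not inner.any() or not outer.any():
        raise ValueError("lesion ROIs fall outside the image")
    return inner, outer
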