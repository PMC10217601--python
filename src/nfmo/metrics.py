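"""Restoration quality metrics: per-channel MSE, PSNR and NCD.

PSNR is computed from the mean of the three channel MSEs,
PSNR = 10 log10(255^2 / MSE), and is +inf for identical images by
convention.  NCD (normalised colour difference) converts both images to a
luminance/chrominance space and returns the summed Euclidean error magnitude
divided by the summed magnitude of the original — lower is better, 0 means
identical.  The colour space is analog BT.601 YUV (matrix below).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .imaging_io import ColorImage, validate_image

#: RGB -> YUV (ITU-R BT.601 analog) conversion matrix, rows = (Y, U, V)
BT601_YUV = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.14713, -0.28886, 0.436],
        [0.615, -0.51499, -0.10001],
    ]
)

PEAK = 255.0


@dataclass
class QualityReport:
    """Quality measures for one (original, restored) image pair."""

    mse_per_channel: tuple[float, float, float]
    mse: float
    psnr: float
    ncd: float


def _as_pair(original, restored) -> tuple[np.ndarray, np.ndarray]:
    a = validate_image(original.data if isinstance(original, ColorImage) else original)
    b = validate_image(restored.data if isinstance(restored, ColorImage) else restored)
    if a.shape != b.shape:
        raise ValidationError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mse_per_channel(original, restored) -> tuple[float, float, float]:
    """Mean squared error of each colour plane, in double precision."""
    a, b = _as_pair(original, restored)
    diff = a.astype(np.float64) - b.astype(np.float64)
    return tuple(float(np.mean(diff[:, :, ch] ** 2)) for ch in range(3))


def psnr(original, restored) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    mses = mse_per_channel(original, restored)
    mean_mse = sum(mses) / 3.0
    if mean_mse == 0.0:
        return math.inf
    return 10.0 * math.log10(PEAK**2 / mean_mse)


def ncd(original, restored) -> float:
    """Normalised colour difference in BT.601 YUV space.

    Raises :class:`~nfmo.errors.UndefinedMetricError` when the original image
    has zero total YUV magnitude (an all-black reference).
    """
    a, b = _as_pair(original, restored)
    yuv_a = a.astype(np.float64) @ BT601_YUV.T
    yuv_b = b.astype(np.float64) @ BT601_YUV.T
    denom = float(np.sqrt((yuv_a**2).sum(axis=2)).sum())
    if denom == 0.0:
        raise UndefinedMetricError("NCD undefined: the original image is all black")
    num = float(np.sqrt(((yuv_a - yuv_b) ** 2).sum(axis=2)).sum())
    return num / denom


def evaluate(original, restored) -> QualityReport:
    """Full quality report for an image pair."""
    mses = mse_per_channel(original, restored)
    mean_mse = sum(mses) / 3.0
    p = math.inf if mean_mse == 0.0 else 10.0 * math.log10(PEAK**2 / mean_mse)
    return QualityReport(mse_per_channel=mses, mse=mean_mse, psnr=p, ncd=ncd(original, restored))
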