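"""Image-quality metrics and the tolerance-level error index.

Alongside the standard full-reference metrics (MAE, PSNR, SSIM), this module
implements a threshold-scanned decomposition of the absolute error map into

* an intensity error IE(i): the mean absolute difference over the pixels
  whose error is within the tolerance threshold i (a percentage of the
  bit-depth range), normalized by the full scale - small intensity mismatches
  that rarely change biological interpretation; and
* a spatial error SE(i): the area fraction of pixels whose error exceeds the
  threshold - signal predicted where there is none, or missing where there
  is - the errors that do drive misinterpretation.

The tolerance level is the minimum over the threshold scan (integer percents
0..99 by default) of the weighted sum ``beta1*IE(i) + beta2*SE(i)``; with
the default equal weights ``beta1 = beta2 = 0.5`` it lies in [0, 1].  Ties
are broken toward the smallest threshold.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .image_io import ChannelImage


def _check_pair(a: ChannelImage, b: ChannelImage) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.bit_depth != b.bit_depth:
        raise ValueError(f"bit depths differ: {a.bit_depth} vs {b.bit_depth}")


def mae(a: ChannelImage, b: ChannelImage) -> float:
    """Mean absolute difference divided by the full scale; in [0, 1]."""
    _check_pair(a, b)
    diff = np.abs(a.pixels.astype(np.float64) - b.pixels.astype(np.float64))
    return float(diff.mean() / a.full_scale)


def psnr(a: ChannelImage, b: ChannelImage) -> float:
    """Peak signal-to-noise ratio, ``20*log10(full_scale / RMSE)``, in dB.

    Identical images return ``+inf``.
    """
    _check_pair(a, b)
    diff = a.pixels.astype(np.float64) - b.pixels.astype(np.float64)
    mse = float(np.mean(diff ** 2))
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(a.full_scale / np.sqrt(mse)))


def ssim(a: ChannelImage, b: ChannelImage) -> float:
    """Mean structural similarity with the standard constants.

    Gaussian 11-pixel window with sigma 1.5, K1=0.01, K2=0.03, data range
    equal to the full bit-depth scale.
    """
    _check_pair(a, b)
    if min(a.shape) < 11:
        raise ValueError(f"image {a.shape} smaller than the 11-px SSIM window")
    return float(structural_similarity(
        a.pixels, b.pixels, data_range=a.full_scale,
        gaussian_weights=True, sigma=1.5, win_size=11,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def _abs_error(pred: ChannelImage, truth: ChannelImage) -> np.ndarray:
    return np.abs(pred.pixels.astype(np.float64) - truth.pixels.astype(np.float64))


def intensity_error(pred: ChannelImage, truth: ChannelImage,
                    threshold_percent: float, clipped_variant: bool = False) -> float:
    """IE(i): mean absolute error of the sub-threshold pixels, / full scale.

    Pixels qualify when ``|pred - truth| <= i/100 * full_scale``.  If no
    pixel qualifies the intensity error is 0.  With ``clipped_variant=True``
    the threshold-clipped error is averaged over *all* pixels instead (a
    documented alternative reading that keeps values comparable across
    thresholds).
    """
    _check_pair(pred, truth)
    if not 0 <= threshold_percent <= 99:
        raise ValueError("threshold_percent must be in [0, 99]")
    full = pred.full_scale
    err = _abs_error(pred, truth)
    level = threshold_percent / 100.0 * full
    if clipped_variant:
        return float(np.minimum(err, level).mean() / full)
    sub = err[err <= level]
    if sub.size == 0:
        return 0.0
    return float(sub.mean() / full)


def spatial_error(pred: ChannelImage, truth: ChannelImage,
                  threshold_percent: float) -> float:
    """SE(i): area fraction of pixels with ``|pred - truth| > i/100 * full``."""
    _check_pair(pred, truth)
    if not 0 <= threshold_percent <= 99:
        raise ValueError("threshold_percent must be in [0, 99]")
    full = pred.full_scale
    err = _abs_error(pred, truth)
    return float(np.mean(err > threshold_percent / 100.0 * full))


@dataclass
class ToleranceConfig:
    """Weights and threshold grid for the tolerance-level scan."""

    beta1: float = 0.5
    beta2: float = 0.5
    step: float = 1.0
    threshold_percents: np.ndarray | None = None
    clipped_variant: bool = False

    def __post_init__(self) -> None:
        if self.beta1 < 0 or self.beta2 < 0 or (self.beta1 == 0 and self.beta2 == 0):
            raise ValueError("beta1, beta2 must be >= 0 and not both 0")
        if self.threshold_percents is None:
            self.threshold_percents = np.arange(0.0, 99.0 + 1e-9, self.step)
        self.threshold_percents = np.asarray(self.threshold_percents, dtype=float)
        if self.threshold_percents.min() < 0 or self.threshold_percents.max() > 99:
            raise ValueError("threshold grid must lie within [0, 99]")


@dataclass
class ToleranceCurve:
    """IE and SE over the threshold scan plus the minimizing threshold."""

    thresholds: np.ndarray
    ie_values: np.ndarray
    se_values: np.ndarray
    tl: float
    argmin_threshold: float


def tolerance_level(pred: ChannelImage, truth: ChannelImage,
                    cfg: ToleranceConfig | None = None) -> ToleranceCurve:
    """Scan thresholds and minimize ``beta1*IE(i) + beta2*SE(i)``.

    Returns the full curve; ``tl`` is the minimum of the weighted sum and
    ``argmin_threshold`` the smallest threshold attaining it.
    """
    cfg = cfg or ToleranceConfig()
    _check_pair(pred, truth)
    full = pred.full_scale
    err = _abs_error(pred, truth)
    n = err.size
    thresholds = cfg.threshold_percents
    ie = np.empty(len(thresholds))
    se = np.empty(len(thresholds))
    for j, t in enumerate(thresholds):
        level = t / 100.0 * full
        below = err <= level
        nb = int(below.sum())
        if cfg.clipped_variant:
            ie[j] = np.minimum(err, level).mean() / full
        else:
            ie[j] = (err[below].mean() / full) if nb else 0.0
        se[j] = (n - nb) / n
    total = cfg.beta1 * ie + cfg.beta2 * se
    k = int(np.argmin(total))  # argmin returns the first (smallest) threshold on ties
    return ToleranceCurve(thresholds.copy(), ie, se, float(total[k]), float(thresholds[k]))


def segment_error_overlay(pred: ChannelImage, truth: ChannelImage,
                          threshold_percent: float) -> np.ndarray:
    """Grayscale prediction with above-threshold error pixels painted green.

    Returns an (H, W, 3) uint8 RGB array; the green mask is exactly the
    support of :func:`spatial_error` at the same threshold.
    """
    _check_pair(pred, truth)
    full = pred.full_scale
    err = _abs_error(pred, truth)
    mask = err > threshold_percent / 100.0 * full
    gray = np.round(pred.pixels.astype(np.float64) / full * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[mask] = (0, 255, 0)
    return rgb


def evaluate_folders(pred_dir: str, truth_dir: str,
                     cfg: ToleranceConfig | None = None):
    """Compare two folders of images matched by filename.

    Returns a pandas DataFrame with one row per matched file:
    ``file, mae, psnr, ssim, tl, argmin_threshold``.  Unmatched filenames are
    reported with a warning and skipped.
    """
    import pandas as pd

    from .image_io import read_image

    exts = (".tif", ".tiff", ".png")
    preds = {f for f in os.listdir(pred_dir) if f.lower().endswith(exts)}
    truths = {f for f in os.listdir(truth_dir) if f.lower().endswith(exts)}
    unmatched = sorted(preds ^ truths)
    if unmatched:
        warnings.warn(f"skipping unmatched files: {unmatched}", stacklevel=2)
    rows = []
    for name in sorted(preds & truths):
        p = read_image(os.path.join(pred_dir, name))
        t = read_image(os.path.join(truth_dir, name))
        curve = tolerance_level(p, t, cfg)
        rows.append({"file": name, "mae": mae(p, t), "psnr": psnr(p, t),
                     "ssim": ssim(p, t), "tl": curve.tl,
                     "argmin_threshold": curve.argmin_threshold})
    return pd.DataFrame(rows, columns=["file", "mae", "psnr", "ssim", "tl",
                                       "argmin_threshold"])
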