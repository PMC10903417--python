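"""Pixel-level image-quality metrics for virtual vs. chemical stains.

Three complementary views of prediction quality:

* ``nmae_px`` — mean absolute error normalised by the mean of the target
  image.  Scale-invariant under joint rescaling, so it reads the same on
  raw 16-bit data and on [0, 1]-normalised data; it is the intensity-centric
  metric that downstream feature extraction cares about.
* ``ssim`` — structural similarity with the canonical Gaussian window
  (sigma 1.5, 11 px support, K1 = 0.01, K2 = 0.03).
* ``psnr`` — peak signal-to-noise ratio in dB against a declared peak.

``evaluate_set`` aggregates all three per channel over a validation set as
mean +/- standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

CHANNEL_NAMES = ("droplets", "cytoplasm", "nuclei")


def _check_pair(pred: np.ndarray, target: np.ndarray) -> None:
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")


def nmae_px(pred: np.ndarray, target: np.ndarray) -> float:
    """mean(|pred - target|) / mean(target)."""
    _check_pair(pred, target)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    denom = target.mean()
    if denom == 0:
        raise ValueError("target has zero mean: nMAE normalisation undefined")
    return float(np.abs(pred - target).mean() / denom)


def ssim(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity over a Gaussian-weighted sliding window.

    Window support is ``2 * int(3.5 * sigma + 0.5) + 1`` pixels (11 for the
    default sigma); a margin of half the window is cropped before averaging
    so edge effects do not enter the score.
    """
    _check_pair(pred, target)
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    truncate = 3.5
    r = int(truncate * sigma + 0.5)
    win = 2 * r + 1
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}px SSIM window")

    def f(im):
        return gaussian_filter(im, sigma, mode="nearest", truncate=truncate)

    ux, uy = f(x), f(y)
    uxx, uyy, uxy = f(x * x), f(y * y), f(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    return float(s[r:-r, r:-r].mean())


def psnr(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0) -> float:
    """20 log10(MAX) - 10 log10(MSE) in dB; +inf for identical images."""
    _check_pair(pred, target)
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    mse = float(((x - y) ** 2).mean())
    if mse == 0:
        return float("inf")
    return 20.0 * np.log10(data_range) - 10.0 * np.log10(mse)


@dataclass
class MetricReport:
    """Per-image metrics and per-channel mean +/- std over a validation set."""

    per_image: pd.DataFrame  # columns: image, channel, nmae_px, ssim, psnr
    summary: pd.DataFrame    # index: channel; columns: <metric>_mean/_std

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {
            "per_image": self.per_image.to_dict(orient="records"),
            "summary": self.summary.reset_index().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_set(preds, targets, data_range: float = 1.0,
                 channel_names=CHANNEL_NAMES) -> MetricReport:
    """Compute nMAE/SSIM/PSNR per image and channel, then aggregate.

    ``preds`` and ``targets`` are equal-length sequences of (C, H, W)
    arrays.  The spread is the population standard deviation, so a single
    pair reports std 0.
    """
    preds, targets = list(preds), list(targets)
    if len(preds) != len(targets):
        raise ValueError(
            f"{len(preds)} predictions vs {len(targets)} targets")
    rows = []
    for i, (p, t) in enumerate(zip(preds, targets)):
        _check_pair(p, t)
        for c in range(p.shape[0]):
            name = channel_names[c] if c < len(channel_names) else str(c)
            rows.append({
                "image": i, "channel": name,
                "nmae_px": nmae_px(p[c], t[c]),
                "ssim": ssim(p[c], t[c], data_range=data_range),
                "psnr": psnr(p[c], t[c], data_range=data_range),
            })
    per_image = pd.DataFrame(rows)
    summary = per_image.groupby("channel", sort=False).agg(
        nmae_px_mean=("nmae_px", "mean"),
        nmae_px_std=("nmae_px", lambda s: float(np.std(s))),
        ssim_mean=("ssim", "mean"),
        ssim_std=("ssim", lambda s: float(np.std(s))),
        psnr_mean=("psnr", "mean"),
        psnr_std=("psnr", lambda s: float(np.std(s))),
    )
    return MetricReport(per_image=per_image, summary=summary)


__all__ = ["nmae_px", "ssim", "psnr", "evaluate_set", "MetricReport",
           "CHANNEL_NAMES"]
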