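"""Published benchmark summary used for metric-definition consistency checks.

Aggregated feature-comparison values from a published 60x-magnification
adipocyte virtual-staining validation set (15 image sets): per structure
class and feature, the target mean, the mean absolute error between
features extracted from virtually and chemically stained images, and the
printed normalised MAE in percent.  Pixel values are on the original
16-bit scale [0, 65535].

These numbers serve one purpose here: the nMAE definition used throughout
this package (MAE normalised by the target value) must reproduce each
printed percentage from the printed MAE and target cells.  They are inputs
to a consistency check, not results of this package.
"""

from __future__ import annotations

# (structure, feature) -> (target_mean, mae, printed_nmae_pct)
BENCHMARK_60X = {
    ("lipid_droplets", "pixel_value"): (1300.0, 150.0, 12.0),
    ("lipid_droplets", "count"): (6600.0, 1600.0, 24.0),
    ("lipid_droplets", "mean_area"): (400.0, 160.0, 41.0),
    ("cytoplasm", "pixel_value"): (320.0, 59.0, 18.0),
    ("cytoplasm", "count"): (34.0, 3.1, 9.7),
    ("nuclei", "pixel_value"): (290.0, 92.0, 32.0),
    ("nuclei", "count"): (34.0, 3.1, 9.7),
    ("nuclei", "mean_area"): (7400.0, 320.0, 4.2),
}

N_VALIDATION_IMAGES = 15


def consistency_ratios() -> dict:
    """Recompute each printed nMAE percentage from its MAE and target cells."""
    return {key: 100.0 * mae / target
            for key, (target, mae, _) in BENCHMARK_60X.items()}


__all__ = ["BENCHMARK_60X", "N_VALIDATION_IMAGES", "consistency_ratios"]
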