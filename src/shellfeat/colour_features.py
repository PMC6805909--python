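"""Colour histogram moments.

Per view, the R/G/B intensity histograms are taken over foreground
(shell-mask) pixels only, so the black photographic background never
contributes to the statistic.  The two views give a 256x6 count matrix
(columns R_A, G_A, B_A, R_B, G_B, B_B); each column is summarized by its
histogram-weighted mean and standard deviation, yielding the 12-element
colour feature (mu, s) per column, on the 0-255 intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_core import ShellImage, ShellMask, ShellSample

#: column order of the combined histogram matrix
COLUMN_NAMES = ("RA", "GA", "BA", "RB", "GB", "BB")

#: CSV column names of the 12-d feature, (mean, std) per histogram column
FEATURE_NAMES = tuple(
    f"{stat}{col}" for col in COLUMN_NAMES for stat in ("mu", "sd")
)


@dataclass(frozen=True)
class ColourHistogram:
    counts: np.ndarray  # (256, 6) int64
    n_pixels_a: int
    n_pixels_b: int


def channel_histograms(image: ShellImage, mask: ShellMask) -> np.ndarray:
    """256x3 histogram of the masked pixels, one column per RGB channel."""
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    fg = mask.foreground
    if not fg.any():
        raise ValueError(
            f"empty foreground for {image.source_id!r}: colour histogram undefined"
        )
    pixels = image.pixels[fg]  # (n, 3)
    counts = np.empty((256, 3), dtype=np.int64)
    for c in range(3):
        counts[:, c] = np.bincount(pixels[:, c], minlength=256)
    return counts


def colour_histogram(sample: ShellSample, masks: dict[str, ShellMask]) -> ColourHistogram:
    """Concatenate the per-view 256x3 histograms into the 256x6 matrix."""
    ha = channel_histograms(sample.view_a, masks["A"])
    hb = channel_histograms(sample.view_b, masks["B"])
    return ColourHistogram(
        counts=np.hstack([ha, hb]),
        n_pixels_a=int(ha[:, 0].sum()),
        n_pixels_b=int(hb[:, 0].sum()),
    )


def histogram_moments(counts: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation of each histogram column.

    ``ddof=0`` (population std) by default: the histogram summarizes the
    full pixel set of the specimen, not a sample from it.
    """
    counts = np.asarray(counts, dtype=np.float64)
    bins = np.arange(counts.shape[0], dtype=np.float64)
    n = counts.sum(axis=0)
    mu = (bins[:, None] * counts).sum(axis=0) / n
    var = ((bins[:, None] - mu) ** 2 * counts).sum(axis=0) / (n - ddof)
    return mu, np.sqrt(var)


def colour_feature(
    sample: ShellSample, masks: dict[str, ShellMask], ddof: int = 0
) -> np.ndarray:
    """The 12-d colour feature: (mu, s) per column of the 256x6 matrix."""
    hist = colour_histogram(sample, masks)
    mu, sd = histogram_moments(hist.counts, ddof=ddof)
    return np.column_stack([mu, sd]).ravel()
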