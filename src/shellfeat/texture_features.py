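"""Gabor-bank patch texture descriptor.

A bank of 20 complex Gabor filters (4 orientations x 5 frequencies) is
applied to 200 randomly placed 20x20 grayscale patches of the frontal
view, each patch lying fully inside the shell mask.  Every (patch,
filter) response is summarized by three statistics of its magnitude —
average, energy and entropy — giving a 4000x3 raw matrix whose columns
are sorted ascending.  The sorted matrices, flattened, are compressed by
PCA to 10 scores per sample.

The filter kernel is

    f(x, y) = 1/(2 pi sx sy) * exp(-((x/sx)^2 + (y/sy)^2)/2)
                             * exp(j w (x cos t + y sin t))

with spatial widths sx = sy tied to the carrier wavelength by default
(sigma = pi / w, about half a period).  The printed frequency values
{5, 10, 15, 20, 25} are interpreted as cycles per 20-px patch width,
i.e. w = 2 pi f / 20 radians per pixel; both rules are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .imaging_core import ShellImage, ShellMask, ShellSample

DEFAULT_FREQUENCIES = (5.0, 10.0, 15.0, 20.0, 25.0)  # cycles per patch width
DEFAULT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)  # degrees
DEFAULT_N_PATCHES = 200
DEFAULT_PATCH_SIZE = 20
N_COMPONENTS = 10
PATCH_WIDTH_PX = 20  # reference length for the frequency unit


def default_sigma_rule(omega: float) -> float:
    """sigma = pi / omega: the Gaussian envelope spans about one carrier
    period (2 sigma)."""
    return math.pi / omega


@dataclass(frozen=True)
class GaborFilter:
    omega: float  # radians per pixel
    theta: float  # degrees
    sigma_x: float
    sigma_y: float
    kernel: np.ndarray = field(repr=False)  # complex, K x K, K odd

    @property
    def size(self) -> int:
        return self.kernel.shape[0]


@dataclass(frozen=True)
class GaborBank:
    filters: tuple[GaborFilter, ...]

    def __len__(self) -> int:
        return len(self.filters)

    def __iter__(self):
        return iter(self.filters)


def make_filter(omega: float, theta_deg: float, sigma_x: float, sigma_y: float) -> GaborFilter:
    """Sample one complex Gabor kernel on an odd grid covering 3 sigma."""
    if omega <= 0 or sigma_x <= 0 or sigma_y <= 0:
        raise ValueError(
            f"omega and sigmas must be positive (omega={omega}, "
            f"sigma_x={sigma_x}, sigma_y={sigma_y})"
        )
    half = math.ceil(3.0 * max(sigma_x, sigma_y))
    coords = np.arange(-half, half + 1, dtype=np.float64)
    x = coords[None, :]  # columns
    y = coords[:, None]  # rows
    theta = math.radians(theta_deg)
    envelope = np.exp(-0.5 * ((x / sigma_x) ** 2 + (y / sigma_y) ** 2))
    carrier = np.exp(1j * omega * (x * math.cos(theta) + y * math.sin(theta)))
    kernel = envelope * carrier / (2.0 * math.pi * sigma_x * sigma_y)
    return GaborFilter(omega=omega, theta=theta_deg, sigma_x=sigma_x,
                       sigma_y=sigma_y, kernel=kernel)


def build_bank(
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES,
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
    sigma_rule=default_sigma_rule,
    patch_width: int = PATCH_WIDTH_PX,
) -> GaborBank:
    """One filter per (orientation, frequency) pair, orientation-major.

    ``frequencies`` are in cycles per ``patch_width`` pixels and are
    converted to radians per pixel before kernel construction.
    """
    if not frequencies or not orientations:
        raise ValueError("frequency and orientation lists must be non-empty")
    filters = []
    for theta in orientations:
        for freq in frequencies:
            omega = 2.0 * math.pi * freq / patch_width
            sigma = sigma_rule(omega)
            filters.append(make_filter(omega, theta, sigma, sigma))
    return GaborBank(tuple(filters))


@dataclass(frozen=True)
class Patch:
    pixels: np.ndarray  # (size, size) float grayscale, 0-255 scale
    origin: tuple[int, int]  # (x, y) of the top-left corner


def sample_patches(
    image: ShellImage | np.ndarray,
    mask: ShellMask,
    n: int = DEFAULT_N_PATCHES,
    size: int = DEFAULT_PATCH_SIZE,
    seed: int | np.random.Generator = 0,
) -> list[Patch]:
    """Draw ``n`` square patches uniformly (with replacement) from all
    placements whose footprint lies fully inside the mask.

    Deterministic for a fixed seed; raises if the mask admits no valid
    placement.
    """
    gray = image.grayscale() if isinstance(image, ShellImage) else np.asarray(image, float)
    fg = mask.foreground
    # a placement at (r, c) is valid iff the size x size window sum equals size^2
    window = np.lib.stride_tricks.sliding_window_view(fg, (size, size))
    valid = window.all(axis=(2, 3))
    rows, cols = np.nonzero(valid)
    if len(rows) == 0:
        raise ValueError(
            f"mask with {int(fg.sum())} foreground pixels admits no "
            f"{size}x{size} patch placement"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = rng.integers(0, len(rows), size=n)
    return [
        Patch(pixels=gray[rows[i]: rows[i] + size, cols[i]: cols[i] + size],
              origin=(int(cols[i]), int(rows[i])))
        for i in picks
    ]


def response_statistics(response: np.ndarray) -> tuple[float, float, float]:
    """Average, energy and entropy of a filter-response magnitude map.

    With m = |r| and N the patch pixel count:
    average = sum(m)/N, energy = sum(m^2)/N,
    entropy = -sum(p log p) with p = m/N, natural log, 0 log 0 := 0.
    """
    m = np.abs(response)
    n = m.size
    p = m / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return float(m.sum() / n), float((m * m).sum() / n), float(-plogp.sum())


def response_stats(patch: Patch, filt: GaborFilter) -> tuple[float, float, float]:
    """Statistics of one patch filtered by one Gabor kernel.

    The response is the same-size, zero-padded convolution of the patch
    with the complex kernel; all three statistics act on its magnitude.
    """
    r = signal.convolve(patch.pixels.astype(complex), filt.kernel, mode="same")
    return response_statistics(r)


@dataclass(frozen=True)
class RawTextureMatrix:
    """Column-sorted (n_patches * n_filters) x 3 patch-statistic matrix."""

    values: np.ndarray  # columns (average, energy, entropy), each sorted ascending

    @property
    def flattened(self) -> np.ndarray:
        return self.values.ravel(order="F")  # column blocks stay contiguous


def raw_texture_matrix(
    sample: ShellSample,
    bank: GaborBank,
    mask: ShellMask,
    n_patches: int = DEFAULT_N_PATCHES,
    patch_size: int = DEFAULT_PATCH_SIZE,
    seed: int | np.random.Generator = 0,
) -> RawTextureMatrix:
    """Texture statistics of the frontal view.

    Responses are computed for all (patch, filter) pairs in patch-major
    order, then each statistic column is sorted ascending — making the
    matrix invariant to the patch sampling order.
    """
    patches = sample_patches(sample.view_a, mask, n=n_patches, size=patch_size, seed=seed)
    stack = np.stack([p.pixels for p in patches]).astype(complex)  # (n, s, s)
    rows = np.empty((n_patches * len(bank), 3))
    for j, filt in enumerate(bank):
        # batched same-size convolution over the patch stack
        resp = signal.fftconvolve(stack, filt.kernel[None, :, :], mode="same", axes=(1, 2))
        m = np.abs(resp)
        n = m.shape[1] * m.shape[2]
        avg = m.sum(axis=(1, 2)) / n
        energy = (m * m).sum(axis=(1, 2)) / n
        p = m / n
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        ent = -plogp.sum(axis=(1, 2))
        rows[j:: len(bank)] = np.column_stack([avg, energy, ent])
    return RawTextureMatrix(np.sort(rows, axis=0))


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray  # (d,)
    components: np.ndarray  # (n_components, d), orthonormal rows
    explained_variance_ratio: np.ndarray  # (n_components,), non-increasing


def fit_pca(matrices: list[RawTextureMatrix], n_components: int = N_COMPONENTS) -> PCAModel:
    """Fit the texture PCA on flattened raw matrices (one row per sample).

    If fewer than ``n_components`` directions carry variance (small
    training sets), the trailing components are zero vectors so that
    projections always have length ``n_components``.
    """
    if len(matrices) < 2:
        raise ValueError(f"PCA needs >= 2 training samples, got {len(matrices)}")
    X = np.stack([m.flattened for m in matrices])
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centred data; at most n_samples - 1 informative directions
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (len(X) - 1)
    total = var.sum()
    k = min(n_components, len(s))
    components = np.zeros((n_components, X.shape[1]))
    ratio = np.zeros(n_components)
    components[:k] = vt[:k]
    if total > 0:
        ratio[:k] = var[:k] / total
    # sign convention: largest-magnitude loading positive, for reproducibility
    flip = np.sign(components[np.arange(n_components),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return PCAModel(mean=mean, components=components * flip[:, None],
                    explained_variance_ratio=ratio)


def project(model: PCAModel, matrix: RawTextureMatrix) -> np.ndarray:
    """PCA scores of one sample: its 10-d texture feature."""
    return (matrix.flattened - model.mean) @ model.components.T


def texture_features(
    samples: list[ShellSample],
    masks: list[ShellMask],
    bank: GaborBank | None = None,
    n_patches: int = DEFAULT_N_PATCHES,
    patch_size: int = DEFAULT_PATCH_SIZE,
    seed: int = 0,
    n_components: int = N_COMPONENTS,
) -> tuple[np.ndarray, PCAModel]:
    """Raw matrices for all samples, PCA fit on all of them, and the
    (n_samples, 10) score table.  Per-sample patch seeds are derived from
    ``seed`` so the pipeline is reproducible end to end."""
    bank = bank or build_bank()
    ss = np.random.SeedSequence(seed)
    mats = [
        raw_texture_matrix(s, bank, m, n_patches=n_patches, patch_size=patch_size,
                           seed=np.random.default_rng(child))
        for s, m, child in zip(samples, masks, ss.spawn(len(samples)))
    ]
    model = fit_pca(mats, n_components=n_components)
    scores = np.stack([project(model, m) for m in mats])
    return scores, model


def feature_names(n_components: int = N_COMPONENTS) -> tuple[str, ...]:
    return tuple(f"pc{i + 1:02d}" for i in range(n_components))
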