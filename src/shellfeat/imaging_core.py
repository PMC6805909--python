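"""Image loading, canonical resizing and black-background masking.

All downstream feature extractors share the conventions fixed here:

* images are 8-bit RGB arrays of shape ``(400, 300, 3)`` (H x W x 3),
  row-major with the origin at the top-left corner;
* ``x`` is the column index (rightwards), ``y`` the row index (downwards);
* a specimen is photographed twice, frontal view ``A`` and lateral
  view ``B``, against a near-black background.

The background is delimited by a flood fill grown from the four image
corners; its complement (largest connected component, interior holes
filled) is the shell mask that every extractor operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

#: canonical image width (columns) and height (rows), pixels
CANONICAL_WIDTH = 300
CANONICAL_HEIGHT = 400

#: default flood-fill intensity tolerance (8-bit levels)
DEFAULT_TOLERANCE = 10

# 4-connectivity: flood fill cannot leak through diagonal gaps
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class ShellImage:
    """One canonicalized view of a shell specimen."""

    pixels: np.ndarray  # (H, W, 3) uint8 RGB
    view: str = "A"  # 'A' frontal, 'B' lateral
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"ShellImage requires an HxWx3 RGB array, got shape {px.shape}"
            )
        if px.shape[:2] != (CANONICAL_HEIGHT, CANONICAL_WIDTH):
            raise ValueError(
                f"ShellImage must be {CANONICAL_HEIGHT}x{CANONICAL_WIDTH}, "
                f"got {px.shape[0]}x{px.shape[1]}; use canonicalize()"
            )
        if self.view not in ("A", "B"):
            raise ValueError(f"view must be 'A' or 'B', got {self.view!r}")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def grayscale(self) -> np.ndarray:
        """Luminance image as float64 on the 0-255 scale (ITU-R 601 weights)."""
        return self.pixels @ np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ShellMask:
    """Boolean pixel region aligned with a ShellImage."""

    foreground: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        fg = np.asarray(self.foreground, dtype=bool)
        if fg.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {fg.shape}")
        object.__setattr__(self, "foreground", fg)

    @property
    def n_foreground(self) -> int:
        return int(self.foreground.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.foreground.shape


@dataclass(frozen=True)
class ShellSample:
    """A specimen: species label plus its frontal (A) and lateral (B) views."""

    species: str
    sample_id: str
    view_a: ShellImage
    view_b: ShellImage

    def __post_init__(self) -> None:
        if self.view_a.view != "A" or self.view_b.view != "B":
            raise ValueError("view_a must have view='A' and view_b view='B'")


def canonicalize(image: np.ndarray, view: str = "A", source_id: str = "") -> ShellImage:
    """Resize a decoded RGB image to the canonical 300x400 frame.

    Aspect ratio is forced (no padding); bilinear interpolation. A
    single-channel input is rejected rather than promoted, because the
    colour feature is meaningless for it.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError(f"empty image (source_id={source_id!r})")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected a 3-channel colour image, got shape {arr.shape} "
            f"(source_id={source_id!r})"
        )
    if arr.shape[:2] == (CANONICAL_HEIGHT, CANONICAL_WIDTH):
        return ShellImage(arr.astype(np.uint8, copy=True), view=view, source_id=source_id)
    pil = Image.fromarray(arr.astype(np.uint8), mode="RGB")
    pil = pil.resize((CANONICAL_WIDTH, CANONICAL_HEIGHT), resample=Image.BILINEAR)
    return ShellImage(np.asarray(pil), view=view, source_id=source_id)


def load_image(path: str | Path, view: str = "A") -> ShellImage:
    """Read a JPEG/PNG file and canonicalize it."""
    path = Path(path)
    with Image.open(path) as pil:
        if pil.mode in ("L", "I", "I;16", "1"):
            raise ValueError(f"single-channel image not supported: {path}")
        arr = np.asarray(pil.convert("RGB"))
    return canonicalize(arr, view=view, source_id=path.stem)


def background_mask(image: ShellImage, tolerance: float = DEFAULT_TOLERANCE) -> ShellMask:
    """Grow the black background region by flood fill from the four corners.

    A pixel joins the region if it is 4-connected to a corner seed through
    pixels that are either near-black (max channel value <= ``tolerance``)
    or within ``tolerance`` of the seed colour in every channel.  The
    returned mask is the background itself (pre-inversion).
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    px = image.pixels.astype(np.int16)
    h, w = px.shape[:2]
    near_black = px.max(axis=2) <= tolerance

    region = np.zeros((h, w), dtype=bool)
    corners = [(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)]
    for r, c in corners:
        seed = px[r, c]
        candidates = near_black | (np.abs(px - seed) <= tolerance).all(axis=2)
        if not candidates[r, c]:
            continue
        labels, _ = ndimage.label(candidates, structure=_CROSS)
        region |= labels == labels[r, c]
    return ShellMask(region)


def shell_mask(background: ShellMask) -> ShellMask:
    """Invert a background mask into a single-component, hole-free shell mask.

    The complement is reduced to its largest 4-connected component and
    interior holes are filled so that boundary tracing sees one closed
    contour.
    """
    fg = ~background.foreground
    if not fg.any():
        raise ValueError("empty foreground: background covers the whole image")
    labels, n = ndimage.label(fg, structure=_CROSS)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return ShellMask(fg)


def mask_sample(sample: ShellSample, tolerance: float = DEFAULT_TOLERANCE) -> dict[str, ShellMask]:
    """Shell masks for both views, keyed 'A' and 'B'."""
    return {
        "A": shell_mask(background_mask(sample.view_a, tolerance)),
        "B": shell_mask(background_mask(sample.view_b, tolerance)),
    }


# ---------------------------------------------------------------------------
# manifest / inventory I/O

MANIFEST_COLUMNS = ("species", "sample_id", "view", "path")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CSV manifest with columns species, sample_id, view, path."""
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    bad = set(df["view"]) - {"A", "B"}
    if bad:
        raise ValueError(f"manifest {path}: view must be 'A' or 'B', found {sorted(bad)}")
    return df[list(MANIFEST_COLUMNS)]


def load_samples(manifest: pd.DataFrame, root: str | Path | None = None) -> list[ShellSample]:
    """Pair manifest rows into two-view ShellSamples.

    Raises if any sample_id lacks one of its views.
    """
    root = Path(root) if root is not None else None
    samples: list[ShellSample] = []
    for (species, sample_id), group in manifest.groupby(
        ["species", "sample_id"], sort=True
    ):
        views = dict(zip(group["view"], group["path"]))
        if set(views) != {"A", "B"}:
            raise ValueError(
                f"sample {sample_id!r} ({species}): needs exactly views A and B, "
                f"has {sorted(views)}"
            )
        paths = {v: (root / p if root else Path(p)) for v, p in views.items()}
        samples.append(
            ShellSample(
                species=str(species),
                sample_id=str(sample_id),
                view_a=load_image(paths["A"], view="A"),
                view_b=load_image(paths["B"], view="B"),
            )
        )
    return samples


def read_inventory(path: str | Path) -> pd.Series:
    """Species -> sample-count mapping from an XLSX inventory sheet.

    Expects the species name in the first column and the count in the
    second; extra columns are ignored.
    """
    df = pd.read_excel(path)
    return pd.Series(
        df.iloc[:, 1].astype(int).values, index=df.iloc[:, 0].astype(str), name="n_samples"
    )


def iter_view_images(samples: Iterable[ShellSample]):
    """Yield (sample, view_key, image) triples over both views."""
    for s in samples:
        yield s, "A", s.view_a
        yield s, "B", s.view_b
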