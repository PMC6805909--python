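"""Procedural two-view shell specimens with known ground truth.

Each synthetic species is defined by a base colour, a star-convex polar
outline r(a) = R * (1 + A * cos(m * a)), a sinusoidal stripe pattern and
a pixel-noise level; the lateral view (B) is the frontal view rendered
at a relative scale with an independent noise draw.  Because the outline
and colours are known in closed form, every extractor can be checked
against the generating parameters: the colour means recover the base
colour, the radial shape profile recovers r(a), and stripe-period shifts
move the texture scores.

Within a species, samples differ only by the noise realization (and the
patch-sampling seed downstream), so classes are separable by design —
the point of the generator is to exercise the pipeline, not to model
photographic variation between real specimens.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imaging_core import (
    CANONICAL_HEIGHT,
    CANONICAL_WIDTH,
    ShellImage,
    ShellSample,
)

DEFAULT_N_SPECIES = 10
DEFAULT_N_SAMPLES = 10
DEFAULT_NOISE_SD = 6.0
MAX_RADIUS_PX = 140  # outline must fit the 300-px-wide frame with margin


@dataclass(frozen=True)
class ShellSpec:
    """Ground-truth parameters of one synthetic species."""

    base_colour: tuple[int, int, int]
    radius: float  # R, pixels (frontal view)
    lobe_amplitude: float = 0.0  # A in r(a) = R(1 + A cos(m a)); <= 0.3
    lobe_count: int = 4  # m >= 2, so the outline centroid stays centred
    stripe_period: float = 12.0  # pixels
    stripe_contrast: float = 0.3  # in [0, 1]
    noise_sd: float = DEFAULT_NOISE_SD  # intensity units
    view_b_scale: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.lobe_amplitude <= 0.3:
            raise ValueError(
                f"lobe amplitude must be in [0, 0.3] for a star-convex outline, "
                f"got {self.lobe_amplitude}"
            )
        if self.lobe_count < 2:
            raise ValueError("lobe_count must be >= 2 (m = 1 shifts the centroid)")
        rmax = self.radius * (1 + self.lobe_amplitude) * max(1.0, self.view_b_scale)
        if rmax > MAX_RADIUS_PX:
            raise ValueError(
                f"outline radius {rmax:.0f} px exceeds the frame "
                f"(max {MAX_RADIUS_PX} px)"
            )

    def outline_radius(self, angle_rad: np.ndarray | float, view: str = "A") -> np.ndarray:
        """The generating polar radius r(a) for the given view."""
        scale = 1.0 if view == "A" else self.view_b_scale
        return scale * self.radius * (
            1.0 + self.lobe_amplitude * np.cos(self.lobe_count * np.asarray(angle_rad))
        )


@dataclass(frozen=True)
class SyntheticManifest:
    """Bookkeeping for a generated dataset."""

    frame: pd.DataFrame  # species, sample_id, view, path (path empty if unwritten)
    specs: dict[str, ShellSpec]
    seed: int
    samples: list[ShellSample] = field(repr=False, default_factory=list)


def render_shell(spec: ShellSpec, view: str = "A", seed: int | np.random.Generator = 0) -> ShellImage:
    """Render one 300x400 view on a pure-black background."""
    if view not in ("A", "B"):
        raise ValueError(f"view must be 'A' or 'B', got {view!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = CANONICAL_HEIGHT, CANONICAL_WIDTH
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    y, x = np.mgrid[0:h, 0:w]
    dx, dy = x - cx, y - cy
    angle = np.arctan2(dy, dx)
    inside = np.hypot(dx, dy) <= spec.outline_radius(angle, view)

    stripes = 1.0 + spec.stripe_contrast * np.sin(2.0 * np.pi * y / spec.stripe_period)
    img = np.zeros((h, w, 3))
    base = np.asarray(spec.base_colour, dtype=float)
    img[inside] = base * stripes[inside, None]
    if spec.noise_sd > 0:
        img[inside] += rng.normal(0.0, spec.noise_sd, size=(int(inside.sum()), 3))
    img[~inside] = 0.0
    return ShellImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), view=view)


def render_sample(
    spec: ShellSpec, species: str, sample_id: str, seed: int | np.random.SeedSequence
) -> ShellSample:
    """Both views of one specimen, with independent noise draws."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    return ShellSample(
        species=species,
        sample_id=sample_id,
        view_a=render_shell(spec, "A", np.random.default_rng(child_a)),
        view_b=render_shell(spec, "B", np.random.default_rng(child_b)),
    )


def species_grid(n_species: int, noise_sd: float = DEFAULT_NOISE_SD) -> dict[str, ShellSpec]:
    """A deterministic, well-separated parameter grid of species specs.

    Base colours are spread around the hue wheel; outline radius, lobe
    shape and stripe period cycle through coprime-length lists so every
    species gets a distinct combination.
    """
    if n_species < 2:
        raise ValueError(f"need at least 2 species, got {n_species}")
    outer_radii = (70.0, 85.0, 100.0, 115.0, 130.0)  # R * (1 + A)
    lobes = ((0.0, 4), (0.10, 3), (0.20, 5), (0.15, 6), (0.25, 4), (0.05, 7))
    periods = (6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0)
    specs = {}
    for i in range(n_species):
        hue = i / n_species
        r, g, b = colorsys.hsv_to_rgb(hue, 0.55, 0.70)
        amp, m = lobes[i % len(lobes)]
        specs[f"Synthetica_sp{i:03d}"] = ShellSpec(
            base_colour=(int(round(r * 255)), int(round(g * 255)), int(round(b * 255))),
            radius=outer_radii[i % len(outer_radii)] / (1.0 + amp),
            lobe_amplitude=amp,
            lobe_count=m,
            stripe_period=periods[i % len(periods)],
            noise_sd=noise_sd,
        )
    return specs


def generate_dataset(
    n_species: int = DEFAULT_N_SPECIES,
    n_samples_per_species: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    out_dir: str | Path | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SyntheticManifest:
    """Generate a labelled two-view dataset, optionally writing PNG files.

    Returns in-memory samples always; with ``out_dir`` also writes one PNG
    per view (named like ``Synthetica_sp000_03_A.png``) and a manifest CSV
    ``manifest.csv`` readable by the imaging module.
    """
    specs = species_grid(n_species, noise_sd=noise_sd)
    ss = np.random.SeedSequence(seed)
    rows = []
    samples = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for (species, spec), species_seed in zip(specs.items(), ss.spawn(len(specs))):
        for j, sample_seed in enumerate(species_seed.spawn(n_samples_per_species)):
            sample_id = f"{species}_{j:02d}"
            sample = render_sample(spec, species, sample_id, sample_seed)
            samples.append(sample)
            for view, img in (("A", sample.view_a), ("B", sample.view_b)):
                fname = f"{species}_{j:02d}_{view}.png"
                if out is not None:
                    Image.fromarray(img.pixels).save(out / fname)
                rows.append(
                    {"species": species, "sample_id": sample_id, "view": view,
                     "path": fname if out is not None else ""}
                )
    frame = pd.DataFrame(rows)
    if out is not None:
        frame.to_csv(out / "manifest.csv", index=False)
    return SyntheticManifest(frame=frame, specs=specs, seed=seed, samples=samples)


def shifted_stripe_spec(spec: ShellSpec, factor: float = 2.0) -> ShellSpec:
    """The same species with its stripe period rescaled — a texture-only
    contrast used to verify that texture features respond to pattern."""
    return replace(spec, stripe_period=spec.stripe_period * factor)
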