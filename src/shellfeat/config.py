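"""Run configuration and the end-to-end feature pipeline.

Defaults are the protocol constants: flood-fill tolerance 10, 5-degree
radial step, frequencies {5, 10, 15, 20, 25} at orientations
{0, 45, 90, 135} degrees, 200 patches of 20x20 px, 10 PCA components,
70% training fraction and 30 repetitions.

The texture PCA can be fitted on all samples (``pca_scope='all'``, as in
a fixed published feature table) or refitted on each training split
(``'train'``, the default — no information leaks from test to train).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colour_features, shape_features, texture_features
from .evaluation import FeatureTable
from .imaging_core import DEFAULT_TOLERANCE, ShellSample, mask_sample
from .texture_features import (
    DEFAULT_FREQUENCIES,
    DEFAULT_N_PATCHES,
    DEFAULT_ORIENTATIONS,
    DEFAULT_PATCH_SIZE,
    N_COMPONENTS,
    GaborBank,
    PCAModel,
    RawTextureMatrix,
    build_bank,
    fit_pca,
    project,
    raw_texture_matrix,
)

COMBINED_DIM = 12 + 144 + 10  # colour + shape + texture
_TEXTURE_OFFSET = {"combined": 12 + 144, "texture": 0}


@dataclass(frozen=True)
class RunConfig:
    tolerance: float = DEFAULT_TOLERANCE
    ccd_step: float = 5.0
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    n_patches: int = DEFAULT_N_PATCHES
    patch_size: int = DEFAULT_PATCH_SIZE
    n_components: int = N_COMPONENTS
    pca_scope: str = "train"  # 'train' or 'all'
    train_fraction: float = 0.7
    repetitions: int = 30
    seed: int = 0
    knn_k: int = 1
    rf_trees: int = 100

    def __post_init__(self) -> None:
        if self.pca_scope not in ("train", "all"):
            raise ValueError(f"pca_scope must be 'train' or 'all', got {self.pca_scope!r}")

    def bank(self) -> GaborBank:
        return build_bank(self.frequencies, self.orientations,
                          patch_width=self.patch_size)

    def digest(self) -> str:
        """Short hash identifying the extraction configuration."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ExtractedFeatures:
    """All per-sample features before the texture PCA is applied."""

    species: np.ndarray
    sample_ids: np.ndarray
    colour: np.ndarray  # (n, 12)
    shape: np.ndarray  # (n, 144)
    raw_texture: list[RawTextureMatrix] = field(repr=False, default_factory=list)
    config: RunConfig = field(default_factory=RunConfig)

    def __len__(self) -> int:
        return len(self.species)


def extract_features(samples: list[ShellSample], config: RunConfig = RunConfig()) -> ExtractedFeatures:
    """Masks, colour, shape and raw texture matrices for every sample."""
    if not samples:
        raise ValueError("no samples to extract")
    bank = config.bank()
    ss = np.random.SeedSequence(config.seed)
    colour_rows, shape_rows, raw = [], [], []
    for sample, child in zip(samples, ss.spawn(len(samples))):
        masks = mask_sample(sample, tolerance=config.tolerance)
        colour_rows.append(colour_features.colour_feature(sample, masks))
        shape_rows.append(shape_features.shape_feature(sample, masks, step=config.ccd_step))
        raw.append(
            raw_texture_matrix(
                sample, bank, masks["A"], n_patches=config.n_patches,
                patch_size=config.patch_size, seed=np.random.default_rng(child),
            )
        )
    return ExtractedFeatures(
        species=np.array([s.species for s in samples]),
        sample_ids=np.array([s.sample_id for s in samples]),
        colour=np.stack(colour_rows),
        shape=np.stack(shape_rows),
        raw_texture=raw,
        config=config,
    )


def texture_scores(extracted: ExtractedFeatures, model: PCAModel | None = None) -> tuple[np.ndarray, PCAModel]:
    """PCA scores of every sample; fits the model on all samples if absent."""
    if model is None:
        model = fit_pca(extracted.raw_texture, n_components=extracted.config.n_components)
    scores = np.stack([project(model, m) for m in extracted.raw_texture])
    return scores, model


def feature_table(
    extracted: ExtractedFeatures,
    kind: str = "combined",
    pca_model: PCAModel | None = None,
) -> FeatureTable:
    """Assemble a FeatureTable of the requested kind.

    ``combined`` concatenates colour (12) ++ shape (144) ++ texture (10)
    into the 166-dimensional vector.
    """
    if kind == "colour":
        values = extracted.colour
    elif kind == "shape":
        values = extracted.shape
    elif kind == "texture":
        values, _ = texture_scores(extracted, pca_model)
    elif kind == "combined":
        tex, _ = texture_scores(extracted, pca_model)
        values = np.hstack([extracted.colour, extracted.shape, tex])
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return FeatureTable(extracted.species, extracted.sample_ids, values, kind)


def extract_all(samples: list[ShellSample], config: RunConfig = RunConfig()) -> FeatureTable:
    """The combined 166-d feature table (texture PCA fitted on all samples)."""
    return feature_table(extract_features(samples, config), "combined")


def pca_refit_hook(extracted: ExtractedFeatures, kind: str = "combined"):
    """A repeat_eval split hook that refits the texture PCA on the training
    rows of each split and reprojects both sides — the leakage-free
    counterpart of fitting PCA once on everything."""
    offset = _TEXTURE_OFFSET[kind]
    ncomp = extracted.config.n_components
    mats = dict(zip(extracted.sample_ids, extracted.raw_texture))

    def hook(train: FeatureTable, test: FeatureTable, rng):
        model = fit_pca([mats[s] for s in train.sample_ids], n_components=ncomp)

        def reproject(tab: FeatureTable) -> FeatureTable:
            values = tab.values.copy()
            values[:, offset: offset + ncomp] = np.stack(
                [project(model, mats[s]) for s in tab.sample_ids]
            )
            return FeatureTable(tab.species, tab.sample_ids, values, tab.feature_kind)

        return reproject(train), reproject(test)

    return hook


def feature_column_names(kind: str, config: RunConfig = RunConfig()) -> tuple[str, ...]:
    colour_names = colour_features.FEATURE_NAMES
    shape_names = shape_features.feature_names(config.ccd_step)
    tex_names = texture_features.feature_names(config.n_components)
    return {
        "colour": colour_names,
        "shape": shape_names,
        "texture": tex_names,
        "combined": colour_names + shape_names + tex_names,
    }[kind]


# ---------------------------------------------------------------------------
# feature-table CSV I/O with a provenance header

def write_feature_csv(path: str | Path, table: FeatureTable, config: RunConfig = RunConfig()) -> None:
    """Write a feature table with a header comment carrying the feature
    kind and config hash, so mismatched tables are refused at load time."""
    names = feature_column_names(table.feature_kind, config)
    buf = io.StringIO()
    buf.write(f"# shellfeat feature_kind={table.feature_kind} config={config.digest()}\n")
    table.to_frame(names).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_feature_csv(path: str | Path, expect_kind: str | None = None) -> FeatureTable:
    text = Path(path).read_text()
    kind = "combined"
    if text.startswith("# shellfeat"):
        header, text = text.split("\n", 1)
        for tokens in header.split():
            if tokens.startswith("feature_kind="):
                kind = tokens.split("=", 1)[1]
    if expect_kind is not None and kind != expect_kind:
        raise ValueError(f"feature table {path} holds {kind!r} features, expected {expect_kind!r}")
    return FeatureTable.from_frame(pd.read_csv(io.StringIO(text)), kind)


def save_pca_model(path: str | Path, model: PCAModel) -> None:
    Path(path).write_text(json.dumps({
        "mean": model.mean.tolist(),
        "components": model.components.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
    }))


def load_pca_model(path: str | Path) -> PCAModel:
    d = json.loads(Path(path).read_text())
    return PCAModel(
        mean=np.array(d["mean"]),
        components=np.array(d["components"]),
        explained_variance_ratio=np.array(d["explained_variance_ratio"]),
    )
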