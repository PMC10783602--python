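"""Slide tiling, informative-tissue filtering and patch feature extraction.

A slide is any RGB raster with a known native resolution (microns per pixel);
real pyramidal WSIs plug in through the :class:`SlideReader` contract.  Tiles
are non-overlapping 512 px patches at a 0.50 MPP working resolution by
default; patches with less than 40% informative tissue (pixels darker than
intensity 200) are discarded.  Features default to a deterministic
colour/texture descriptor projected to 1024 dimensions; a pretrained CNN can
be plugged in through the :class:`FeatureExtractor` contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize


@dataclass
class PatchSpec:
    patch_size_px: int = 512
    target_mpp: float = 0.50
    min_informative_fraction: float = 0.40
    informative_intensity_threshold: int = 200
    # Tissue is darker than glass background, so pixels *below* the threshold
    # count as informative; set False to flip the comparison.
    informative_below_threshold: bool = True

    def __post_init__(self):
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if not 0 <= self.min_informative_fraction <= 1:
            raise ValueError("min_informative_fraction must lie in [0, 1]")


@dataclass(eq=False)  # identity equality: the pixel block is an array
class Patch:
    """One tile: 0-based top-left pixel origin (x, y) at the working MPP."""

    slide_id: str
    origin: tuple[int, int]
    size_px: int
    pixels: np.ndarray | None = field(default=None, repr=False)

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.origin[0] + self.size_px / 2, self.origin[1] + self.size_px / 2)


@runtime_checkable
class SlideReader(Protocol):
    """Contract for pyramidal slide backends (region-at-level API)."""

    @property
    def mpp(self) -> float: ...

    @property
    def dimensions(self) -> tuple[int, int]: ...  # (width, height) at base level

    def read_region(self, x: int, y: int, width: int, height: int) -> np.ndarray: ...


def tile_slide(
    image: np.ndarray,
    spec: PatchSpec | None = None,
    native_mpp: float | None = None,
    slide_id: str = "slide",
) -> list[Patch]:
    """Tile an RGB raster into a non-overlapping lattice at the target MPP.

    The image is resampled when its native MPP differs from the target;
    partial border tiles are dropped.  Ordering is deterministic row-major.
    """
    spec = spec or PatchSpec()
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if native_mpp is not None and native_mpp != spec.target_mpp:
        scale = native_mpp / spec.target_mpp
        out_shape = (round(image.shape[0] * scale), round(image.shape[1] * scale))
        if image.ndim == 3:
            out_shape = out_shape + (image.shape[2],)
        image = resize(image, out_shape, preserve_range=True,
                       anti_aliasing=scale < 1).astype(image.dtype)
    p = spec.patch_size_px
    n_rows, n_cols = image.shape[0] // p, image.shape[1] // p
    if n_rows == 0 or n_cols == 0:
        warnings.warn("image smaller than one patch; no tiles produced")
        return []
    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            x, y = c * p, r * p
            patches.append(
                Patch(slide_id, (x, y), p, pixels=image[y : y + p, x : x + p])
            )
    return patches


def informative_fraction(pixels: np.ndarray, spec: PatchSpec) -> float:
    """Fraction of patch pixels classed as tissue by the intensity rule."""
    if pixels.ndim == 3:
        gray = rgb2gray(pixels) * 255.0
    else:
        gray = pixels.astype(float)
    if spec.informative_below_threshold:
        informative = gray < spec.informative_intensity_threshold
    else:
        informative = gray > spec.informative_intensity_threshold
    return float(informative.mean())


def filter_patches(patches: list[Patch], spec: PatchSpec | None = None) -> list[Patch]:
    """Keep patches whose informative fraction is >= the minimum (boundary
    kept: only patches capturing *less than* the minimum are discarded)."""
    spec = spec or PatchSpec()
    kept = []
    for patch in patches:
        if patch.pixels is None:  # feature-table input: no pixels, no filter
            kept.append(patch)
            continue
        if informative_fraction(patch.pixels, spec) >= spec.min_informative_fraction:
            kept.append(patch)
    return kept


@runtime_checkable
class FeatureExtractor(Protocol):
    """Contract for patch feature extractors; must declare an output dim."""

    @property
    def dim(self) -> int: ...

    def __call__(self, pixels: np.ndarray) -> np.ndarray: ...


class ColorTextureExtractor:
    """Deterministic handcrafted descriptor projected to a fixed dimension.

    Per-channel 16-bin histograms, channel means/sds, grayscale histogram and
    gradient-magnitude statistics form a base descriptor, expanded to ``dim``
    by a fixed seeded Gaussian projection.  Purely a function of the pixels:
    identical patches always map to identical features.
    """

    _BASE = 16 * 3 + 6 + 16 + 4

    def __init__(self, dim: int = 1024):
        self._dim = dim
        proj_rng = np.random.default_rng(1024)  # fixed: part of the definition
        self._proj = proj_rng.normal(size=(self._BASE, dim)) / np.sqrt(self._BASE)

    @property
    def dim(self) -> int:
        return self._dim

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        px = np.asarray(pixels, dtype=float)
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        feats = []
        for c in range(3):
            h, _ = np.histogram(px[..., c], bins=16, range=(0, 256))
            feats.append(h / px[..., c].size)
        feats.append([px[..., c].mean() / 255.0 for c in range(3)])
        feats.append([px[..., c].std() / 255.0 for c in range(3)])
        gray = px.mean(axis=-1)
        h, _ = np.histogram(gray, bins=16, range=(0, 256))
        feats.append(h / gray.size)
        gy, gx = np.gradient(gray)
        mag = np.hypot(gx, gy)
        feats.append([mag.mean(), mag.std(), gray.mean() / 255.0, gray.std() / 255.0])
        base = np.concatenate([np.atleast_1d(np.asarray(f, dtype=float)) for f in feats])
        return base @ self._proj


def extract_features(patches: list[Patch], extractor: FeatureExtractor) -> np.ndarray:
    """Stack per-patch feature vectors; row i corresponds to patch i."""
    rows = []
    for patch in patches:
        h = np.asarray(extractor(patch.pixels))
        if h.shape != (extractor.dim,):
            raise ValueError(
                f"extractor contract violation: got shape {h.shape}, "
                f"declared dim {extractor.dim}"
            )
        rows.append(h)
    return np.stack(rows) if rows else np.empty((0, extractor.dim))
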