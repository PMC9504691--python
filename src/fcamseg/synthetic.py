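"""Procedural color textures, mosaics with ground truth, and toy
fixtures.

The generator emulates Prague-style color texture mosaics: several
texture classes with distinct color and orientation statistics composed
into one frame along straight or irregular (Voronoi) boundaries, with a
site-aligned integer ground truth and a pure training tile per class.
Three texture kinds are provided:

- ``stripes``: colors alternate along a stated orientation with a
  stated period;
- ``checker``: a two-color checkerboard of a stated cell size;
- ``correlated_noise``: a base color plus Gaussian noise, optionally
  smoothed to a stated correlation length.

All generators are deterministic given their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .superpixel import SuperpixelPartition

TEXTURE_KINDS = ("stripes", "checker", "correlated_noise")

RED = (220, 40, 40)
GREEN = (40, 200, 40)
BLUE = (40, 40, 220)


@dataclass(frozen=True)
class TextureSpec:
    """One procedural texture class."""

    kind: str
    colors: tuple = (RED, GREEN)
    orientation: float = 0.0  # degrees; 0 = varies along columns
    period: int = 4  # sites per stripe / checker cell
    noise: float = 0.0  # additive Gaussian noise std (levels)
    correlation_length: float = 0.0  # Gaussian smoothing radius of the noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_KINDS:
            raise InvalidParameterError(f"unknown texture kind {self.kind!r}")
        if self.period < 1:
            raise InvalidParameterError("period must be >= 1")
        for col in self.colors:
            if len(col) != 3 or any(not 0 <= v <= 255 for v in col):
                raise InvalidParameterError(f"invalid RGB color {col!r}")


@dataclass(frozen=True)
class MosaicSpec:
    """A frame composed of several textures with aligned ground truth."""

    size: tuple[int, int]
    textures: tuple
    layout: str = "vertical_split"  # or "grid" or "voronoi"
    layout_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.textures) < 2:
            raise InvalidParameterError("a mosaic needs at least 2 textures")
        if self.layout not in ("vertical_split", "grid", "voronoi"):
            raise InvalidParameterError(f"unknown layout {self.layout!r}")


def make_texture(spec: TextureSpec, size: tuple[int, int]) -> np.ndarray:
    """Render one deterministic 8-bit RGB texture tile."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    colors = np.asarray(spec.colors, dtype=np.float64)
    if spec.kind == "stripes":
        theta = math.radians(spec.orientation)
        proj = xx * math.cos(theta) + yy * math.sin(theta)
        idx = np.floor(proj / spec.period).astype(np.int64) % len(colors)
        img = colors[idx]
    elif spec.kind == "checker":
        idx = (
            np.floor(xx / spec.period).astype(np.int64)
            + np.floor(yy / spec.period).astype(np.int64)
        ) % len(colors)
        img = colors[idx]
    else:  # correlated_noise
        img = np.broadcast_to(colors[0], (h, w, 3)).copy()
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise, size=(h, w, 3))
        if spec.correlation_length > 0:
            noise = ndimage.gaussian_filter(
                noise, sigma=(spec.correlation_length, spec.correlation_length, 0)
            )
            # keep the requested amplitude after smoothing
            std = noise.std()
            if std > 0:
                noise *= spec.noise / std
        img = img + noise
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class MosaicSample:
    """A rendered mosaic: image, ground truth, per-class training tiles."""

    image: np.ndarray
    gt: np.ndarray  # class indices 1..K
    tiles: list  # pure training tile per class, same size as the frame
    spec: MosaicSpec


def _layout_map(spec: MosaicSpec) -> np.ndarray:
    h, w = spec.size
    k = len(spec.textures)
    if spec.layout == "vertical_split":
        edges = np.linspace(0, w, k + 1)
        cols = np.arange(w)
        gt_cols = np.searchsorted(edges, cols, side="right")
        return np.broadcast_to(gt_cols, (h, w)).copy()
    if spec.layout == "grid":
        side = math.ceil(math.sqrt(k))
        yy, xx = np.mgrid[0:h, 0:w]
        cell = (yy * side // h) * side + (xx * side // w)
        return cell % k + 1
    # voronoi: one seed per texture, irregular cells
    rng = np.random.default_rng(spec.layout_seed)
    seeds = np.stack(
        [rng.uniform(0, h, size=k), rng.uniform(0, w, size=k)], axis=1
    )
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d2 = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
    return np.argmin(d2, axis=2) + 1


def make_mosaic(spec: MosaicSpec) -> MosaicSample:
    """Compose textures per the layout; emit aligned ground truth and
    one pure training tile per class."""
    h, w = spec.size
    gt = _layout_map(spec).astype(np.int64)
    image = np.zeros((h, w, 3), dtype=np.uint8)
    tiles = []
    for i, tex in enumerate(spec.textures, start=1):
        tile = make_texture(tex, (h, w))
        tiles.append(make_texture(replace(tex, seed=tex.seed + 7919), (h, w)))
        image[gt == i] = tile[gt == i]
    return MosaicSample(image=image, gt=gt, tiles=tiles, spec=spec)


# ---------------------------------------------------------------------------
# documented presets


def mosaic3(size: int = 256, seed: int = 0) -> MosaicSample:
    """Three-class mosaic with distinct stripe, checker and noise
    textures (vertical bands)."""
    textures = (
        TextureSpec(
            kind="stripes",
            colors=((200, 60, 60), (60, 160, 60)),
            orientation=45.0,
            period=6,
            noise=8.0,
            seed=seed,
        ),
        TextureSpec(
            kind="checker",
            colors=((50, 60, 200), (220, 200, 60)),
            period=6,
            noise=8.0,
            seed=seed + 1,
        ),
        TextureSpec(
            kind="correlated_noise",
            colors=((150, 150, 150),),
            noise=40.0,
            correlation_length=3.0,
            seed=seed + 2,
        ),
    )
    return make_mosaic(MosaicSpec(size=(size, size), textures=textures))


def size_contrast(size: int = 128, seed: int = 0) -> MosaicSample:
    """Two checkerboards of identical mean color but different
    micro-pattern scale, split vertically.

    The two halves cannot be told apart by mean color, only by the
    scale of the pattern, which is exactly what the regional feature of
    the two-pass SLIC is meant to expose.
    """
    colors = ((70, 70, 190), (190, 190, 70))
    textures = (
        TextureSpec(kind="checker", colors=colors, period=1, noise=10.0, seed=seed),
        TextureSpec(
            kind="checker", colors=colors, period=12, noise=10.0, seed=seed + 1
        ),
    )
    return make_mosaic(MosaicSpec(size=(size, size), textures=textures))


def fig2_toy():
    """The 7x7 two-texture toy image and its two 2-superpixel
    partitions.

    Left three columns: red/green vertical stripes (R, G, R). Right
    three columns: red/blue horizontal stripes (rows R, B, R, ...).
    The fourth (separating) column repeats R, G, B from the top — the
    composition is fixed by this module; no consumer relies on the
    per-site counts inside that column.

    Returns
    -------
    image : (7, 7, 3) uint8
    partition_b : left superpixel covers columns 0-3
    partition_c : left superpixel covers columns 0-2
    """
    img = np.zeros((7, 7, 3), dtype=np.uint8)
    left_cols = {0: RED, 1: GREEN, 2: RED}
    for col, c in left_cols.items():
        img[:, col] = c
    for row in range(7):
        img[row, 4:7] = RED if row % 2 == 0 else BLUE
    cycle = (RED, GREEN, BLUE)
    for row in range(7):
        img[row, 3] = cycle[row % 3]

    labels_b = np.ones((7, 7), dtype=np.int64)
    labels_b[:, 4:] = 2
    labels_c = np.ones((7, 7), dtype=np.int64)
    labels_c[:, 3:] = 2
    return (
        img,
        SuperpixelPartition(labels=labels_b, count=2),
        SuperpixelPartition(labels=labels_c, count=2),
    )
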