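"""Fuzzy color palettes and membership functions.

A fuzzy color palette reduces the 256^3 RGB cube to a small set of C
representative colors by uniform quantization: channel k is split into
C_k intervals of width L_k = ceil(256 / C_k), and the interval centers
define the palette. Each palette color carries a membership function
grading how strongly an arbitrary RGB value belongs to it. Four kinds
are supported:

``crisp``
    1 inside the quantization cell (per-channel distance at most
    floor(L_k / 2)), 0 outside.
``gaussian``
    exp(-d^2 / (2 sigma^2)) on the per-channel-scaled Euclidean
    distance d, with sigma chosen so the degree is exactly 0.5 when the
    color sits on a cell bound (a single-channel offset of L_k / 2).
``triangular``
    max(1 - d, 0) on the same scaled distance; also 0.5 at a bound.
``fcm``
    the fuzzy C-means membership with fuzzifier zeta (> 1, default 2),
    normalized over the whole palette; one-hot at an exact center.

Distances are anisotropic: channel differences are divided by the
per-channel interval width before the Euclidean norm, so that palettes
with unequal C_k (e.g. the default 2x4x2) keep the 0.5-at-bound
property on every channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FormatError, InvalidParameterError

MEMBERSHIP_KINDS = ("crisp", "gaussian", "triangular", "fcm")

# sigma of the scaled Gaussian: exp(-d^2/(2 sigma^2)) = 0.5 at d = 1/2
_GAUSS_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class FuzzyPalette:
    """A reduced fuzzy color palette from uniform RGB quantization.

    Attributes
    ----------
    counts : tuple of int
        Intervals per channel (C_R, C_G, C_B).
    widths : tuple of int
        Interval widths L_k = ceil(256 / C_k).
    centers : ndarray of shape (C, 3)
        Interval-center colors, ordered lexicographically by
        (R, G, B) center index. This order is a contract: FCAM
        features are indexed by it.
    kind : str
        Membership kind, one of ``MEMBERSHIP_KINDS``.
    alpha : tuple of float
        Per-channel Gaussian span alpha_k = L_k / (2 sqrt(2 ln 2)).
    beta : tuple of float
        Per-channel triangular span beta_k = L_k.
    zeta : float
        FCM fuzzifier (> 1).
    """

    counts: tuple[int, int, int]
    widths: tuple[int, int, int]
    centers: np.ndarray = field(repr=False)
    kind: str
    alpha: tuple[float, float, float]
    beta: tuple[float, float, float]
    zeta: float = 2.0

    @property
    def n_colors(self) -> int:
        return int(self.centers.shape[0])

    def to_text(self) -> str:
        """Serialize to a flat key-value document (auditable)."""
        lines = [
            f"counts: {self.counts[0]} {self.counts[1]} {self.counts[2]}",
            f"widths: {self.widths[0]} {self.widths[1]} {self.widths[2]}",
            f"kind: {self.kind}",
            f"alpha: {self.alpha[0]!r} {self.alpha[1]!r} {self.alpha[2]!r}",
            f"beta: {self.beta[0]!r} {self.beta[1]!r} {self.beta[2]!r}",
            f"zeta: {self.zeta!r}",
            "centers:",
        ]
        for c in self.centers:
            lines.append(f"  {c[0]} {c[1]} {c[2]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FuzzyPalette":
        fields: dict[str, str] = {}
        for line in text.splitlines():
            if ":" in line and not line.startswith(" "):
                key, _, val = line.partition(":")
                fields[key.strip()] = val.strip()
        counts = tuple(int(v) for v in fields["counts"].split())
        kind = fields["kind"]
        zeta = float(fields["zeta"])
        return build_palette(counts, kind=kind, zeta=zeta)


def _channel_centers(count: int) -> tuple[int, np.ndarray]:
    """Interval width and centers for one channel split into `count` bins.

    Centers follow floor(((2 i + 1) L - 1) / 2) for i = 0..count-1,
    clipped to 255 (the last interval is truncated when count does not
    divide 256).
    """
    width = math.ceil(256 / count)
    idx = np.arange(count)
    centers = ((2 * idx + 1) * width - 1) // 2
    return width, np.minimum(centers, 255)


def build_palette(
    counts: Sequence[int], kind: str = "gaussian", zeta: float = 2.0
) -> FuzzyPalette:
    """Build a fuzzy palette by uniform quantization of the RGB cube.

    Parameters
    ----------
    counts : (C_R, C_G, C_B)
        Number of intervals per channel, each in [1, 256].
    kind : str
        Membership kind.
    zeta : float
        FCM fuzzifier, > 1. Ignored by the other kinds.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3:
        raise InvalidParameterError("counts must have exactly three entries")
    for c in counts:
        if not 1 <= c <= 256:
            raise InvalidParameterError(f"channel count {c} outside [1, 256]")
    if kind not in MEMBERSHIP_KINDS:
        raise InvalidParameterError(f"unknown membership kind {kind!r}")
    if zeta <= 1:
        raise InvalidParameterError("zeta must be > 1")

    widths = []
    per_channel = []
    for c in counts:
        w, centers = _channel_centers(c)
        widths.append(w)
        per_channel.append(centers)
    # lexicographic (R, G, B) enumeration: B fastest
    rr, gg, bb = np.meshgrid(*per_channel, indexing="ij")
    centers = np.stack([rr.ravel(), gg.ravel(), bb.ravel()], axis=1).astype(np.int64)
    widths = tuple(int(w) for w in widths)
    beta = tuple(float(w) for w in widths)
    alpha = tuple(w / (2.0 * math.sqrt(2.0 * math.log(2.0))) for w in widths)
    return FuzzyPalette(
        counts=counts,
        widths=widths,
        centers=centers,
        kind=kind,
        alpha=alpha,
        beta=beta,
        zeta=float(zeta),
    )


def _membership_of_colors(colors: np.ndarray, palette: FuzzyPalette) -> np.ndarray:
    """Membership degrees of `colors` (n, 3) to every palette color -> (n, C)."""
    colors = np.asarray(colors, dtype=np.float64)
    centers = palette.centers.astype(np.float64)
    beta = np.asarray(palette.beta, dtype=np.float64)
    # scaled differences: (n, C, 3)
    diff = colors[:, None, :] - centers[None, :, :]
    if palette.kind == "crisp":
        half = np.array([w // 2 for w in palette.widths], dtype=np.float64)
        inside = np.all(np.abs(diff) <= half[None, None, :], axis=2)
        return inside.astype(np.float64)
    d2 = np.sum((diff / beta[None, None, :]) ** 2, axis=2)
    if palette.kind == "gaussian":
        return np.exp(-d2 / (2.0 * _GAUSS_SIGMA**2))
    if palette.kind == "triangular":
        return np.maximum(1.0 - np.sqrt(d2), 0.0)
    # fcm: one-hot at exact centers, otherwise normalized inverse distances
    expo = 1.0 / (palette.zeta - 1.0)
    out = np.empty_like(d2)
    exact = d2 <= 0.0
    any_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d2 ** (-expo)
    reg = ~any_exact
    out[reg] = w[reg] / np.sum(w[reg], axis=1, keepdims=True)
    if any_exact.any():
        rows = np.nonzero(any_exact)[0]
        out[rows] = 0.0
        # exact-center convention: one-hot on the (unique) matching center
        cols = np.argmax(exact[rows], axis=1)
        out[rows, cols] = 1.0
    return out


def membership(x: Sequence[int], palette: FuzzyPalette) -> np.ndarray:
    """Membership degrees of a single RGB color to every palette color."""
    x = np.asarray(x, dtype=np.float64).reshape(1, 3)
    if np.any(x < 0) or np.any(x > 255):
        raise InvalidParameterError("color components must lie in [0, 255]")
    return _membership_of_colors(x, palette)[0]


@dataclass
class MembershipStack:
    """Per-site membership degrees to every fuzzy color.

    ``degrees`` has shape (H, W, C); ``degrees[r, c, k]`` is the degree
    of the site at row r, column c to palette color k.
    """

    degrees: np.ndarray
    palette: FuzzyPalette

    @property
    def height(self) -> int:
        return self.degrees.shape[0]

    @property
    def width(self) -> int:
        return self.degrees.shape[1]


def membership_stack(image: np.ndarray, palette: FuzzyPalette) -> MembershipStack:
    """Evaluate memberships for every site of an 8-bit RGB image.

    Evaluation is memoized over the distinct colors actually present,
    which is value-identical to direct per-site evaluation.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError("expected an RGB image of shape (H, W, 3)")
    if image.dtype != np.uint8:
        raise FormatError(f"expected 8-bit image, got dtype {image.dtype}")
    h, w, _ = image.shape
    codes = (
        image[..., 0].astype(np.int64) * 65536
        + image[..., 1].astype(np.int64) * 256
        + image[..., 2].astype(np.int64)
    ).ravel()
    uniq, inverse = np.unique(codes, return_inverse=True)
    uniq_colors = np.stack(
        [(uniq >> 16) & 255, (uniq >> 8) & 255, uniq & 255], axis=1
    )
    table = _membership_of_colors(uniq_colors, palette)
    degrees = table[inverse].reshape(h, w, palette.n_colors)
    return MembershipStack(degrees=degrees, palette=palette)
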