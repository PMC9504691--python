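"""Crisp color aura sets and fuzzy color aura matrices (FCAMs).

The aura of a color site set S_x with respect to another set S_x' inside
a region P is the subset of S_x' lying in the (Chebyshev-radius-d)
neighborhood of sites of S_x, with both the sites and their neighbors
restricted to P. Its cardinal counts how much x' surrounds x; the matrix
of cardinals over all color pairs is a texture descriptor. Note the
relation is in general asymmetric: the aura of blue with respect to
green is not the aura of green with respect to blue.

The fuzzy generalization replaces the hard color sets by fuzzy color
site sets (membership degrees to a reduced palette) and the set algebra
by min/sup. With the binary in-region neighborhood function, the FCAM
entry for the color pair (c, c') over region P is

    m[c, c'] = sum over r in P of min( max_{s in N_r ∩ P} mu_c(s),
                                       mu_c'(r) ),

where the inner max (the sup collapsed over the binary neighborhood) is
taken over the in-region Chebyshev neighbors of r and is 0 when r has
none. ``fcam_reference`` evaluates the literal sup/min definition by
exhaustive loops and serves as the correctness oracle for the
vectorized ``compute_fcam``.

Normalized FCAMs (entries divided by their total) make regions of
different sizes comparable; each superpixel is then described by the
C^2 entries of its normalized FCAM, flattened row-major in palette
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter

from .errors import DegenerateRegionError, InvalidParameterError, ZeroMassError
from .fuzzy_color import FuzzyPalette, MembershipStack, membership_stack


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Chebyshev neighborhood of radius ``radius`` (center excluded)."""

    radius: int = 1

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise InvalidParameterError("neighborhood radius must be >= 1")

    def footprint(self) -> np.ndarray:
        k = 2 * self.radius + 1
        fp = np.ones((k, k), dtype=bool)
        fp[self.radius, self.radius] = False
        return fp

    def offsets(self) -> list[tuple[int, int]]:
        d = self.radius
        return [
            (dr, dc)
            for dr in range(-d, d + 1)
            for dc in range(-d, d + 1)
            if (dr, dc) != (0, 0)
        ]


@dataclass
class FCAM:
    """A C x C matrix of fuzzy color aura cardinals for one region.

    Rows index the reference color c, columns the aura color c', both in
    palette order.
    """

    values: np.ndarray
    region: object = None
    normalized: bool = False

    @property
    def n_colors(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major C^2 feature vector."""
        return self.values.ravel().copy()


def _as_mask(region, shape) -> np.ndarray:
    region = np.asarray(region)
    if region.dtype == bool and region.shape == tuple(shape):
        return region
    mask = np.zeros(shape, dtype=bool)
    coords = region.reshape(-1, 2)
    mask[coords[:, 0], coords[:, 1]] = True
    return mask


def crisp_aura_set(
    image: np.ndarray,
    x: Sequence[int],
    x_prime: Sequence[int],
    region,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
) -> set[tuple[int, int]]:
    """Sites of color x' in `region` neighboring at least one in-region
    site of color x. Exhaustive enumeration — this is the exact oracle.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    mask = _as_mask(region, (h, w))
    if not mask.any():
        raise InvalidParameterError("region must be nonempty")
    x = np.asarray(x)
    xp = np.asarray(x_prime)
    result: set[tuple[int, int]] = set()
    sources = [
        (r, c)
        for r, c in zip(*np.nonzero(mask))
        if np.array_equal(image[r, c], x)
    ]
    for r, c in sources:
        for dr, dc in nbhd.offsets():
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                if np.array_equal(image[rr, cc], xp):
                    result.add((rr, cc))
    return result


def crisp_aura_cardinal(image, x, x_prime, region, nbhd=NeighborhoodSpec()) -> int:
    """Cardinality of the crisp aura set."""
    return len(crisp_aura_set(image, x, x_prime, region, nbhd))


def crisp_aura_matrix(
    image: np.ndarray,
    colors: np.ndarray,
    region,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
) -> np.ndarray:
    """Matrix of crisp aura cardinals over an ordered color list."""
    colors = np.asarray(colors)
    n = colors.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            out[i, j] = crisp_aura_cardinal(image, colors[i], colors[j], region, nbhd)
    return out


def compute_fcam(
    stack: MembershipStack,
    region,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
) -> FCAM:
    """Unnormalized FCAM of a region, vectorized.

    One neighbor-max pass per palette color (a masked maximum filter on
    the region's bounding box) followed by an O(C^2 |region|)
    min/sum combination; value-identical to ``fcam_reference``.
    """
    degrees = stack.degrees
    h, w, ncol = degrees.shape
    mask = _as_mask(region, (h, w))
    rows, cols = np.nonzero(mask)
    if rows.size < 2:
        raise DegenerateRegionError("region must contain at least 2 sites")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    sub = degrees[r0 : r1 + 1, c0 : c1 + 1, :]
    submask = mask[r0 : r1 + 1, c0 : c1 + 1]

    masked = np.where(submask[..., None], sub, -np.inf)
    fp = nbhd.footprint()[..., None]  # do not mix palette channels
    neigh_max = maximum_filter(masked, footprint=fp, mode="constant", cval=-np.inf)
    neigh_max = np.maximum(neigh_max, 0.0)  # empty sup -> 0

    m = neigh_max[submask]  # (n, C): max_{s in N_r ∩ P} mu_c(s)
    mu = sub[submask]  # (n, C): mu_c'(r)
    values = np.minimum(m.T[:, None, :], mu.T[None, :, :]).sum(axis=2)
    return FCAM(values=values, normalized=False)


def fcam_reference(
    stack: MembershipStack,
    region,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
) -> FCAM:
    """Literal sup/min evaluation of the FCAM definition (slow oracle)."""
    degrees = stack.degrees
    h, w, ncol = degrees.shape
    mask = _as_mask(region, (h, w))
    sites = list(zip(*np.nonzero(mask)))
    if len(sites) < 2:
        raise DegenerateRegionError("region must contain at least 2 sites")
    offsets = nbhd.offsets()
    values = np.zeros((ncol, ncol), dtype=np.float64)
    for c in range(ncol):
        for cp in range(ncol):
            total = 0.0
            for r, rc in sites:
                sup = 0.0
                for dr, dc in offsets:
                    sr, sc = r + dr, rc + dc
                    if 0 <= sr < h and 0 <= sc < w and mask[sr, sc]:
                        sup = max(sup, degrees[sr, sc, c])
                total += min(sup, degrees[r, rc, cp])
            values[c, cp] = total
    return FCAM(values=values, normalized=False)


def normalize_fcam(fcam: FCAM) -> FCAM:
    """Element-wise normalization to unit total mass."""
    total = float(fcam.values.sum())
    if total <= 0.0:
        raise ZeroMassError("FCAM has zero total mass")
    return FCAM(values=fcam.values / total, region=fcam.region, normalized=True)


def fcam_features(
    image: np.ndarray,
    palette: FuzzyPalette,
    regions,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
):
    """Per-region normalized FCAM feature vectors.

    Parameters
    ----------
    regions : SuperpixelPartition or iterable of region masks/site arrays
        For a partition, labels are processed in increasing order.

    Returns
    -------
    features : ndarray of shape (n_regions, C^2)
    flags : ndarray of bool
        True where the region was degenerate (singleton or zero-mass);
        such rows are all-zero and must be handled by the caller (the
        segmenter routes them to the refinement rule).
    """
    stack = membership_stack(image, palette)
    masks = _iter_region_masks(regions, image.shape[:2])
    c2 = palette.n_colors**2
    feats = np.zeros((len(masks), c2), dtype=np.float64)
    flags = np.zeros(len(masks), dtype=bool)
    for i, mask in enumerate(masks):
        try:
            fcam = normalize_fcam(compute_fcam(stack, mask, nbhd))
        except (DegenerateRegionError, ZeroMassError):
            flags[i] = True
            continue
        feats[i] = fcam.flatten()
    return feats, flags


def _iter_region_masks(regions, shape) -> list[np.ndarray]:
    # SuperpixelPartition duck-typed via a `labels` array attribute
    labels = getattr(regions, "labels", None)
    if labels is not None:
        out = []
        for lab in range(1, int(labels.max()) + 1):
            out.append(labels == lab)
        return out
    return [_as_mask(r, shape) for r in regions]
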