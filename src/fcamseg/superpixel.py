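"""SLIC superpixels and the regional two-pass variant.

Basic SLIC clusters sites on a joint color + position feature with a
localized k-means: cluster centers start on a regular grid of step
S = sqrt(N / P), each center only competes for sites inside its
2S x 2S window, and the distance between a site and a center is

    D = sqrt( d_c^2 + m^2 * d_s^2 / S^2 ),

with d_c the Euclidean distance of the three color-like channels and
d_s the Euclidean spatial distance. A compactness m = 1 (default)
balances Lab-scale color against position. After the iterations a
connectivity pass absorbs small 4-connected fragments into the adjacent
region sharing the largest border, so every superpixel is connected and
the final count P' never exceeds the requested P.

The regional variant runs basic SLIC on (L, a, b, x, y), summarizes
each superpixel R by the regional feature

    f_R = [p_R - p_R ln p_R] + mean over neighbors R' of
          [p_R' - p_R' ln p_R'],

(p_R the area fraction, neighbors under 4-adjacency), rescales f_R to
[0, 100] so it is commensurate with the L channel it replaces, and runs
SLIC a second time on (f_R, a, b, x, y). The second pass sees texture
scale through f_R: regions of fine fragmented texture get small
superpixels and hence a low f_R, which separates them from coarse
regions of similar mean color.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import measure

from .errors import FormatError, InvalidParameterError


@dataclass
class SuperpixelPartition:
    """A connected, exhaustive, disjoint labeling into P' superpixels.

    ``labels`` holds integers 1..count in raster layout.
    """

    labels: np.ndarray
    count: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def sites(self, label: int) -> np.ndarray:
        """(n, 2) row/col coordinates of one superpixel, raster order."""
        return np.argwhere(self.labels == label)

    def areas(self) -> np.ndarray:
        """Site counts indexed by label-1."""
        return np.bincount(self.labels.ravel(), minlength=self.count + 1)[1:]

    def area_fractions(self) -> np.ndarray:
        return self.areas() / self.labels.size

    def boundary_mask(self) -> np.ndarray:
        """Sites with a 4-neighbor of a different label."""
        return _boundary_mask(self.labels)


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    b = np.zeros(labels.shape, dtype=bool)
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    b[1:, :] |= labels[1:, :] != labels[:-1, :]
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    return b


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """8-bit sRGB to CIE L*a*b* (D65); L in [0, 100]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError("expected an RGB image of shape (H, W, 3)")
    if image.dtype != np.uint8:
        raise FormatError(f"expected 8-bit image, got dtype {image.dtype}")
    return skcolor.rgb2lab(image)


def _grid_centers(h: int, w: int, p: int, step: float) -> np.ndarray:
    """Regular grid of at most `p` seed positions (row, col), float."""
    nr = max(1, round(h / step))
    nc = max(1, round(w / step))
    while nr * nc > p:
        if nr >= nc and nr > 1:
            nr -= 1
        elif nc > 1:
            nc -= 1
        else:
            break
    rows = (np.arange(nr) + 0.5) * h / nr
    cols = (np.arange(nc) + 0.5) * w / nc
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def slic(
    features: np.ndarray,
    P: int,
    m: float = 1.0,
    max_iter: int = 10,
) -> SuperpixelPartition:
    """Localized k-means superpixel clustering.

    Parameters
    ----------
    features : ndarray (H, W, 3)
        Three color-like channels per site; spatial coordinates are the
        raster grid and are appended internally.
    P : int
        Requested superpixel count (1 <= P <= number of sites).
    m : float
        Compactness; 0 reduces D to pure color distance.
    max_iter : int
        Fixed number of assignment/update iterations.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3 or features.shape[2] != 3:
        raise FormatError("expected a feature raster of shape (H, W, 3)")
    h, w = features.shape[:2]
    n = h * w
    if not 1 <= P <= n:
        raise InvalidParameterError(f"P={P} outside [1, {n}]")
    if m < 0:
        raise InvalidParameterError("compactness m must be >= 0")
    step = math.sqrt(n / P)

    pos = _grid_centers(h, w, P, step)
    k = pos.shape[0]
    cen_color = np.empty((k, 3))
    for i, (cy, cx) in enumerate(pos):
        cen_color[i] = features[min(int(cy), h - 1), min(int(cx), w - 1)]
    cen_pos = pos.copy()

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    labels = np.zeros((h, w), dtype=np.int64)
    win = int(math.ceil(step))
    for _ in range(max_iter):
        dist = np.full((h, w), np.inf)
        labels.fill(0)
        for i in range(k):
            cy, cx = cen_pos[i]
            r0 = max(0, int(cy) - win)
            r1 = min(h, int(cy) + win + 1)
            c0 = max(0, int(cx) - win)
            c1 = min(w, int(cx) + win + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            fc = features[r0:r1, c0:c1]
            dc2 = np.sum((fc - cen_color[i]) ** 2, axis=2)
            ds2 = (yy[r0:r1, c0:c1] - cy) ** 2 + (xx[r0:r1, c0:c1] - cx) ** 2
            d = np.sqrt(dc2 + m * m * ds2 / (step * step))
            sel = d < dist[r0:r1, c0:c1]
            dist[r0:r1, c0:c1][sel] = d[sel]
            labels[r0:r1, c0:c1][sel] = i + 1
        # fallback for sites outside every window (degenerate grids)
        orphan = labels == 0
        if orphan.any():
            oy, ox = np.nonzero(orphan)
            for r, c in zip(oy, ox):
                dc2 = np.sum((cen_color - features[r, c]) ** 2, axis=1)
                ds2 = (cen_pos[:, 0] - r) ** 2 + (cen_pos[:, 1] - c) ** 2
                d = np.sqrt(dc2 + m * m * ds2 / (step * step))
                labels[r, c] = int(np.argmin(d)) + 1
        # update step
        flat = labels.ravel() - 1
        cnt = np.bincount(flat, minlength=k).astype(np.float64)
        nonzero = cnt > 0
        for ch in range(3):
            s = np.bincount(flat, weights=features[..., ch].ravel(), minlength=k)
            cen_color[nonzero, ch] = s[nonzero] / cnt[nonzero]
        sy = np.bincount(flat, weights=yy.ravel(), minlength=k)
        sx = np.bincount(flat, weights=xx.ravel(), minlength=k)
        cen_pos[nonzero, 0] = sy[nonzero] / cnt[nonzero]
        cen_pos[nonzero, 1] = sx[nonzero] / cnt[nonzero]

    labels = _enforce_connectivity(labels, min_size=step * step / 4.0)
    return SuperpixelPartition(labels=labels, count=int(labels.max()))


def _enforce_connectivity(labels: np.ndarray, min_size: float) -> np.ndarray:
    """Absorb fragments so each final region is 4-connected and P' <= P.

    A 4-connected component is absorbed when it is smaller than
    ``min_size`` or when it is not the largest component of its k-means
    label; it is merged, in raster order, into the adjacent component
    with the largest shared border.
    """
    comp = measure.label(labels, connectivity=1)
    ncomp = int(comp.max())
    sizes = np.bincount(comp.ravel(), minlength=ncomp + 1)
    first = _first_indices(comp, ncomp)

    # largest component per original label (ties: earliest in raster order)
    keep_of_label: dict[int, int] = {}
    order = sorted(range(1, ncomp + 1), key=lambda i: (-sizes[i], first[i]))
    comp_label = {}
    flat_labels = labels.ravel()
    for i in range(1, ncomp + 1):
        comp_label[i] = int(flat_labels[first[i]])
    for i in order:
        keep_of_label.setdefault(comp_label[i], i)

    absorb = [
        i
        for i in range(1, ncomp + 1)
        if sizes[i] < min_size or keep_of_label[comp_label[i]] != i
    ]
    if len(absorb) == ncomp:  # never absorb everything
        biggest = max(range(1, ncomp + 1), key=lambda i: (sizes[i], -first[i]))
        absorb = [i for i in absorb if i != biggest]
    absorb.sort(key=lambda i: first[i])

    comp = comp.copy()
    for frag in absorb:
        mask = comp == frag
        if not mask.any():  # already merged away
            continue
        neigh = _border_counts(comp, mask)
        neigh.pop(frag, None)
        if not neigh:
            continue
        target = max(neigh.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        comp[mask] = target

    # relabel 1..P' in raster order of first occurrence
    flat = comp.ravel()
    uniq, idx = np.unique(flat, return_index=True)
    order = uniq[np.argsort(idx)]
    remap = np.zeros(int(comp.max()) + 1, dtype=np.int64)
    for newlab, old in enumerate(order, start=1):
        remap[old] = newlab
    return remap[comp]


def _first_indices(comp: np.ndarray, ncomp: int) -> np.ndarray:
    flat = comp.ravel()
    first = np.full(ncomp + 1, flat.size, dtype=np.int64)
    idx = np.arange(flat.size)
    np.minimum.at(first, flat, idx)
    return first


def _border_counts(comp: np.ndarray, mask: np.ndarray) -> dict[int, int]:
    """Shared-border edge counts between `mask` and adjacent components."""
    counts: dict[int, int] = {}
    h, w = comp.shape
    rows, cols = np.nonzero(mask)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rr = rows + dr
        cc = cols + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        vals = comp[rr[ok], cc[ok]]
        out = vals[~mask[rr[ok], cc[ok]]]
        for v, n in zip(*np.unique(out, return_counts=True)):
            counts[int(v)] = counts.get(int(v), 0) + int(n)
    return counts


def adjacency(partition: SuperpixelPartition) -> dict[int, set[int]]:
    """Symmetric 4-adjacency between superpixel labels."""
    labels = partition.labels
    base = partition.count + 1
    codes = []
    for a, b in (
        (labels[:-1, :], labels[1:, :]),
        (labels[:, :-1], labels[:, 1:]),
    ):
        a = a.ravel()
        b = b.ravel()
        diff = a != b
        codes.append(a[diff].astype(np.int64) * base + b[diff])
    uniq = np.unique(np.concatenate(codes)) if codes else np.array([], dtype=np.int64)
    out: dict[int, set[int]] = {lab: set() for lab in range(1, base)}
    for code in uniq:
        x, y = int(code // base), int(code % base)
        out[x].add(y)
        out[y].add(x)
    return out


def regional_feature(partition: SuperpixelPartition) -> np.ndarray:
    """Per-label regional feature f_R (indexed by label-1).

    f_R = h(p_R) + mean over 4-adjacent neighbors of h(p_R'), with
    h(p) = p - p ln p (natural log). The neighbor term is 0 for a
    partition with a single superpixel.
    """
    p = partition.area_fractions()
    h = p - p * np.log(p)
    adj = adjacency(partition)
    out = np.empty_like(h)
    for lab in range(1, partition.count + 1):
        neigh = adj[lab]
        ctx = float(np.mean([h[r - 1] for r in neigh])) if neigh else 0.0
        out[lab - 1] = h[lab - 1] + ctx
    return out


def regional_slic(
    image: np.ndarray,
    P: int = 400,
    m: float = 1.0,
    max_iter: int = 10,
) -> SuperpixelPartition:
    """Two-pass regional SLIC on an 8-bit RGB image.

    Pass 1 clusters (L, a, b, x, y); the per-superpixel regional feature
    is rescaled to [0, 100] and substituted for L; pass 2 clusters
    (f_R, a, b, x, y) from a fresh grid initialization.
    """
    lab = rgb_to_lab(image)
    part1 = slic(lab, P, m, max_iter)
    f = regional_feature(part1)
    fmap = f[part1.labels - 1]
    span = fmap.max() - fmap.min()
    if span > 0:
        fmap = (fmap - fmap.min()) / span * 100.0
    else:
        fmap = np.zeros_like(fmap)
    feats = np.stack([fmap, lab[..., 1], lab[..., 2]], axis=2)
    return slic(feats, P, m, max_iter)
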