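"""Quality metrics for superpixel partitions and segmentations.

Superpixel metrics (against a ground-truth region map):

- ASA, achievable segmentation accuracy: fraction of sites recovered
  when every superpixel is assigned to its best-overlapping ground
  truth region.
- BR, boundary recall: fraction of ground-truth boundary sites lying
  within a Chebyshev tolerance (default 2) of a partition boundary.
- UE, under-segmentation error: total leakage of superpixels across
  ground-truth regions, min(inside, outside) summed over overlapping
  pairs, divided by the image size.
- COM, compactness: area-weighted isoperimetric quotient
  4*pi*A / perimeter^2 with the perimeter counted as 4-neighbor
  boundary edges (image border included).

Segmentation scores (against a ground-truth class map, shared class
vocabulary): per-class recall (CO), precision (CC), and Jaccard class
accuracy (CA), each averaged over the classes present in the ground
truth; plus the global and local consistency errors (GCE, LCE) of the
region-comparison literature, which are tolerant of mutual refinement.
All bounded scores are reported as fractions in [0, 1]; the pretty
printer shows CO/CC/CA as percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .superpixel import SuperpixelPartition, _boundary_mask


@dataclass
class MetricReport:
    """Named metric values with optional per-class breakdown."""

    values: dict
    per_class: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    PERCENT = ("CO", "CC", "CA")

    def __getitem__(self, key):
        return self.values[key]

    def to_csv(self) -> str:
        lines = ["metric,value"]
        for k, v in self.values.items():
            lines.append(f"{k},{v!r}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        rows = []
        for k, v in self.values.items():
            if k in self.PERCENT:
                rows.append(f"{k:>5s}: {100 * v:6.2f} %")
            else:
                rows.append(f"{k:>5s}: {v:8.4f}")
        if self.params:
            rows.append("params: " + ", ".join(f"{k}={v}" for k, v in self.params.items()))
        return "\n".join(rows)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise InvalidParameterError(f"shape mismatch: {a.shape} vs {b.shape}")


def _contingency(a: np.ndarray, b: np.ndarray):
    """Joint count table over the label values of two maps."""
    av, ai = np.unique(a.ravel(), return_inverse=True)
    bv, bi = np.unique(b.ravel(), return_inverse=True)
    table = np.zeros((av.size, bv.size), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table, av, bv


def superpixel_metrics(
    partition: SuperpixelPartition,
    gt: np.ndarray,
    tolerance: int = 2,
) -> MetricReport:
    """BR, UE, ASA and COM of a partition against a region map."""
    labels = partition.labels
    gt = np.asarray(gt)
    _check_same_shape(labels, gt)
    n = labels.size

    table, _, _ = _contingency(labels, gt)
    asa = table.max(axis=1).sum() / n
    inside = table
    outside = table.sum(axis=1, keepdims=True) - table
    ue = np.where(table > 0, np.minimum(inside, outside), 0).sum() / n

    gt_b = _boundary_mask(gt)
    part_b = _boundary_mask(labels)
    if gt_b.any():
        size = 2 * tolerance + 1
        near = ndimage.maximum_filter(part_b.astype(np.uint8), size=size) > 0
        br = float(np.count_nonzero(gt_b & near) / np.count_nonzero(gt_b))
    else:
        br = 1.0  # no ground-truth boundary to recall

    com = _compactness(labels, partition.count)

    return MetricReport(
        values={"BR": br, "UE": float(ue), "ASA": float(asa), "COM": com},
        params={"boundary_tolerance": tolerance},
    )


def _compactness(labels: np.ndarray, count: int) -> float:
    n = labels.size
    areas = np.bincount(labels.ravel(), minlength=count + 1)[1:]
    perim = np.zeros(count + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(padded, shift, axis=axis)[1:-1, 1:-1]
        edges = labels != neighbor
        np.add.at(perim, labels[edges], 1)
    perim = perim[1:]
    q = 4.0 * math.pi * areas / np.maximum(perim, 1) ** 2
    return float(np.sum(areas / n * q))


def segmentation_scores(pred: np.ndarray, gt: np.ndarray) -> MetricReport:
    """CO, CC, CA, GCE and LCE for class maps with a shared vocabulary."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_same_shape(pred, gt)
    n = pred.size

    gt_classes = np.unique(gt)
    recalls, precisions, jaccards = {}, {}, {}
    for g in gt_classes:
        gmask = gt == g
        pmask = pred == g
        tp = np.count_nonzero(gmask & pmask)
        recalls[g] = tp / np.count_nonzero(gmask)
        npred = np.count_nonzero(pmask)
        precisions[g] = tp / npred if npred else 0.0
        union = np.count_nonzero(gmask | pmask)
        jaccards[g] = tp / union if union else 0.0
    co = float(np.mean(list(recalls.values())))
    cc = float(np.mean(list(precisions.values())))
    ca = float(np.mean(list(jaccards.values())))

    gce, lce = consistency_errors(pred, gt)
    return MetricReport(
        values={"CO": co, "CC": cc, "CA": ca, "GCE": gce, "LCE": lce},
        per_class={
            "recall": recalls,
            "precision": precisions,
            "jaccard": jaccards,
        },
    )


def consistency_errors(s1: np.ndarray, s2: np.ndarray) -> tuple[float, float]:
    """Global and local consistency errors between two segmentations.

    The local refinement error at a site p from s1 to s2 is
    |R1(p) \\ R2(p)| / |R1(p)|. GCE forces one direction for the whole
    image and takes the better one; LCE picks the better direction per
    site, hence LCE <= GCE.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    _check_same_shape(s1, s2)
    n = s1.size
    table, _, _ = _contingency(s1, s2)
    r1 = table.sum(axis=1, keepdims=True)  # |R1_i|
    r2 = table.sum(axis=0, keepdims=True)  # |R2_j|
    e12 = (r1 - table) / r1  # per-site error, pixels counted via table
    e21 = (r2 - table) / r2
    sum12 = float((table * e12).sum())
    sum21 = float((table * e21).sum())
    gce = min(sum12, sum21) / n
    lce = float((table * np.minimum(e12, e21)).sum()) / n
    return gce, lce
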