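"""Supervised segmentation pipeline: prototypes, ELM, classification,
refinement.

Training draws T prototype patches per class from the class's training
image, describes each patch by its normalized FCAM, and fits an extreme
learning machine (ELM): a single hidden layer of 100*K logistic units
with random input weights, whose output weights are the minimum-norm
least-squares solution mapping hidden activations to one-hot class
targets. Segmentation runs regional SLIC on the test image, computes
one normalized FCAM per superpixel, classifies it with the ELM, and
assigns the class to every site of the superpixel. An optional
refinement reassigns superpixels smaller than 0.5% of the image to the
class of their largest adjacent superpixel.

Everything is deterministic given the seeds: prototype sampling and the
ELM's random layer are driven by explicit generators, and SLIC itself
has no random component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .aura import NeighborhoodSpec, compute_fcam, normalize_fcam
from .errors import (
    InvalidParameterError,
    TrainingError,
    ZeroMassError,
)
from .errors import DegenerateRegionError
from .fuzzy_color import FuzzyPalette, membership_stack
from .superpixel import SuperpixelPartition, adjacency, regional_slic


def patch_halfwidth(N: int, P: int) -> int:
    """Half-width W of the training patch: the smallest odd side
    (2W+1) whose area reaches N/P sites.
    """
    if not 1 <= P <= N:
        raise InvalidParameterError("need N >= P >= 1")
    side = math.ceil(math.sqrt(N / P))
    if side % 2 == 0:
        side += 1
    return (side - 1) // 2


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACTIVATIONS = {"sigmoid": sigmoid}


@dataclass
class ELMModel:
    """Extreme learning machine: random hidden layer + least-squares
    output weights."""

    input_weights: np.ndarray  # (H, F)
    biases: np.ndarray  # (H,)
    output_weights: np.ndarray  # (H, K)
    classes: list  # ordered class labels
    activation: str = "sigmoid"
    seed: int = 0

    @property
    def hidden_count(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def elm_train(
    features: np.ndarray,
    labels,
    K: int | None = None,
    hidden: int | None = None,
    seed: int = 0,
    activation: str = "sigmoid",
) -> ELMModel:
    """Fit an ELM on (n, F) features with class labels.

    Hidden size defaults to 100*K. Input weights and biases are drawn
    uniformly from [-1, 1]; output weights are the minimum-norm
    least-squares solution for one-hot targets.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise TrainingError("feature matrix must be (n, F) with n >= 1")
    if not np.any(X):
        raise TrainingError("feature matrix is all-zero")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    k = len(classes)
    if K is not None and K != k:
        raise TrainingError(f"K={K} does not match {k} distinct labels")
    if k < 2:
        raise TrainingError("need at least 2 classes")
    h = hidden if hidden is not None else 100 * k
    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-1.0, 1.0, size=(h, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=h)
    act = _ACTIVATIONS[activation]
    hmat = act(X @ w_in.T + b)
    targets = np.zeros((X.shape[0], k))
    index = {c: i for i, c in enumerate(classes)}
    for row, lab in enumerate(labels.tolist()):
        targets[row, index[lab]] = 1.0
    # Moore-Penrose minimum-norm least squares (classic ELM solution)
    w_out = np.linalg.pinv(hmat) @ targets
    return ELMModel(
        input_weights=w_in,
        biases=b,
        output_weights=w_out,
        classes=classes,
        activation=activation,
        seed=int(seed),
    )


def elm_raw_output(model: ELMModel, features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise InvalidParameterError(
            f"feature length {X.shape[1]} != model input {model.n_features}"
        )
    act = _ACTIVATIONS[model.activation]
    return act(X @ model.input_weights.T + model.biases) @ model.output_weights


def elm_predict(model: ELMModel, features: np.ndarray):
    """Class of one feature vector, or array of classes for a batch.

    Argmax over the K output activations; ties break toward the lowest
    class index.
    """
    features = np.asarray(features, dtype=np.float64)
    single = features.ndim == 1
    out = elm_raw_output(model, features)
    idx = np.argmax(out, axis=1)  # first maximum = lowest class index
    preds = np.asarray([model.classes[i] for i in idx])
    return preds[0] if single else preds


def sample_prototypes(
    train_images: dict,
    T: int,
    W: int,
    palette: FuzzyPalette,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
    seed: int = 0,
):
    """Draw T prototype patches per class and compute their features.

    Parameters
    ----------
    train_images : dict class -> 8-bit RGB image
        Classes are processed in sorted order for determinism.

    Returns
    -------
    features : (K*T, C^2) normalized FCAM vectors
    labels : (K*T,) class labels

    Patch centers are drawn uniformly with the (2W+1)^2 patch fully
    inside the training image.
    """
    if T < 1:
        raise InvalidParameterError("T must be >= 1")
    side = 2 * W + 1
    rng = np.random.default_rng(seed)
    feats = []
    labs = []
    for cls in sorted(train_images):
        image = np.asarray(train_images[cls])
        h, w = image.shape[:2]
        if h < side or w < side:
            raise InvalidParameterError(
                f"training image for class {cls!r} smaller than the "
                f"{side}x{side} patch"
            )
        stack = membership_stack(image, palette)
        rows = rng.integers(W, h - W, size=T)
        cols = rng.integers(W, w - W, size=T)
        for r, c in zip(rows, cols):
            mask = np.zeros((h, w), dtype=bool)
            mask[r - W : r + W + 1, c - W : c + W + 1] = True
            fcam = normalize_fcam(compute_fcam(stack, mask, nbhd))
            feats.append(fcam.flatten())
            labs.append(cls)
    return np.asarray(feats), np.asarray(labs)


@dataclass
class SegmentationResult:
    """Per-site class map plus per-superpixel assignments."""

    labels: np.ndarray  # (H, W) class labels
    superpixel_classes: np.ndarray  # class per superpixel (index = label-1)
    partition: SuperpixelPartition
    degenerate: np.ndarray = None  # bool per superpixel: zero-mass/singleton
    refined: bool = False


def refine(
    result: SegmentationResult,
    partition: SuperpixelPartition | None = None,
    min_frac: float = 0.005,
) -> SegmentationResult:
    """Reassign superpixels smaller than ``min_frac`` of the image to
    the class of their largest adjacent superpixel.

    Superpixels are processed smallest-first in a single pass; areas
    and adjacency are frozen from the input partition, while the class
    looked up on the chosen neighbor reflects earlier reassignments in
    the same pass.
    """
    part = partition if partition is not None else result.partition
    areas = part.areas()
    adj = adjacency(part)
    classes = result.superpixel_classes.copy()
    n = part.labels.size
    threshold = min_frac * n
    order = sorted(range(1, part.count + 1), key=lambda lab: (areas[lab - 1], lab))
    for lab in order:
        if areas[lab - 1] >= threshold:
            break
        neigh = adj[lab]
        if not neigh:
            continue
        target = max(neigh, key=lambda r: (areas[r - 1], -r))
        classes[lab - 1] = classes[target - 1]
    labels = np.asarray(classes)[part.labels - 1]
    return SegmentationResult(
        labels=labels,
        superpixel_classes=classes,
        partition=part,
        degenerate=result.degenerate,
        refined=True,
    )


def segment(
    image: np.ndarray,
    model: ELMModel,
    palette: FuzzyPalette,
    P: int = 400,
    m: float = 1.0,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
    refine_flag: bool = True,
    min_frac: float = 0.005,
) -> SegmentationResult:
    """Segment an RGB image: regional SLIC, per-superpixel FCAM, ELM.

    Zero-mass or singleton superpixels cannot carry a feature; they are
    assigned by the refinement rule (class of the largest adjacent
    superpixel) regardless of ``refine_flag``.
    """
    if model.n_features != palette.n_colors**2:
        raise InvalidParameterError(
            "model feature length does not match palette size squared"
        )
    partition = regional_slic(image, P=P, m=m)
    stack = membership_stack(image, palette)
    c2 = palette.n_colors**2
    feats = np.zeros((partition.count, c2))
    flags = np.zeros(partition.count, dtype=bool)
    for lab in range(1, partition.count + 1):
        mask = partition.labels == lab
        try:
            fcam = normalize_fcam(compute_fcam(stack, mask, nbhd))
        except (DegenerateRegionError, ZeroMassError):
            flags[lab - 1] = True
            continue
        feats[lab - 1] = fcam.flatten()

    classes = np.empty(partition.count, dtype=object)
    ok = ~flags
    if ok.any():
        classes[ok] = elm_predict(model, feats[ok])
    if flags.any():
        areas = partition.areas()
        adj = adjacency(partition)
        for lab in np.nonzero(flags)[0] + 1:
            neigh = [r for r in adj[lab] if not flags[r - 1]]
            if neigh:
                target = max(neigh, key=lambda r: (areas[r - 1], -r))
                classes[lab - 1] = classes[target - 1]
            else:
                classes[lab - 1] = model.classes[0]
    classes = np.asarray(classes.tolist())
    labels = classes[partition.labels - 1]
    result = SegmentationResult(
        labels=labels,
        superpixel_classes=classes,
        partition=partition,
        degenerate=flags,
        refined=False,
    )
    if refine_flag:
        result = refine(result, partition, min_frac=min_frac)
    return result


# ---------------------------------------------------------------------------
# model persistence: a directory with a YAML manifest + CSV matrices


def save_model(model: ELMModel, palette: FuzzyPalette, path, extra: dict | None = None):
    """Persist an ELM model and its palette as a manifest + CSV archive."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": model.seed,
        "K": model.n_classes,
        "classes": [str(c) for c in model.classes],
        "activation": model.activation,
        "hidden": model.hidden_count,
        "input_weight_distribution": "uniform[-1,1]",
        "palette_counts": list(palette.counts),
        "palette_kind": palette.kind,
        "palette_zeta": palette.zeta,
    }
    if extra:
        manifest.update(extra)
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (path / "palette.txt").write_text(palette.to_text())
    np.savetxt(path / "input_weights.csv", model.input_weights, delimiter=",")
    np.savetxt(path / "biases.csv", model.biases, delimiter=",")
    np.savetxt(path / "output_weights.csv", model.output_weights, delimiter=",")


def load_model(path):
    """Load a persisted model; returns (ELMModel, FuzzyPalette, manifest)."""
    path = Path(path)
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    palette = FuzzyPalette.from_text((path / "palette.txt").read_text())
    model = ELMModel(
        input_weights=np.loadtxt(path / "input_weights.csv", delimiter=",", ndmin=2),
        biases=np.loadtxt(path / "biases.csv", delimiter=","),
        output_weights=np.loadtxt(path / "output_weights.csv", delimiter=",", ndmin=2),
        classes=list(manifest["classes"]),
        activation=manifest["activation"],
        seed=int(manifest["seed"]),
    )
    return model, palette, manifest
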