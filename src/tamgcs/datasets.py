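"""Seeded synthetic generators for every input kind the toolkit consumes.

Point clouds (Gaussian classes, concentric rings, label-flip noise)
emulate the separable / overlapping / noisy regimes the geometric
classification score distinguishes; textured scenes carry regions with
closed-form co-occurrence statistics; BOLD-like volumes are smooth blobs
on noise with the canonical 64x64x18 acquisition shape; motif image sets
stand in for a small image-classification task.  Every generator is a
pure function of its arguments — the same seed gives byte-identical
output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcs import LabeledDataset

__all__ = [
    "NoiseSpec",
    "make_gaussian_classes",
    "make_ring_data",
    "flip_labels",
    "make_texture_scene",
    "make_bold_like_volume",
    "make_labeled_imageset",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Label-flip noise: fraction of points whose label is reassigned."""

    flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_fraction < 1:
            raise ValueError(f"flip_fraction must be in [0, 1), got {self.flip_fraction}")


def make_gaussian_classes(
    n_per_class: int = 60,
    n_classes: int = 2,
    separation: float = 4.0,
    dim: int = 2,
    spread: float = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """K isotropic Gaussian clusters with centers ``separation`` apart.

    Centers are placed on the coordinate axes (and their negatives), so
    consecutive class centers are ``separation`` (or more) apart in
    Euclidean distance.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_classes, dim))
    for k in range(n_classes):
        axis = (k // 2) % dim
        sign = 1.0 if k % 2 == 0 else -1.0
        centers[k, axis] = sign * separation * (1 + k // (2 * dim)) / 2.0
    points = np.concatenate(
        [rng.normal(centers[k], spread, size=(n_per_class, dim)) for k in range(n_classes)]
    )
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return LabeledDataset(points=points, labels=labels)


def make_ring_data(
    n_per_ring: int = 80,
    radii: tuple[float, float] = (1.0, 2.0),
    noise: float = 0.05,
    seed: int = 0,
) -> LabeledDataset:
    """Two concentric rings (non-linearly separable 2-class data).

    Angles are uniform; radii get Gaussian jitter of standard deviation
    ``noise``.
    """
    if len(set(radii)) != len(radii):
        raise ValueError("radii must be distinct")
    rng = np.random.default_rng(seed)
    points, labels = [], []
    for k, r in enumerate(radii):
        theta = rng.uniform(0, 2 * np.pi, size=n_per_ring)
        rr = r + rng.normal(0, noise, size=n_per_ring)
        points.append(np.column_stack([rr * np.cos(theta), rr * np.sin(theta)]))
        labels.append(np.full(n_per_ring, k))
    return LabeledDataset(points=np.concatenate(points), labels=np.concatenate(labels))


def flip_labels(data: LabeledDataset, spec: NoiseSpec) -> LabeledDataset:
    """Reassign exactly ``floor(fraction * M)`` labels, each to a different class."""
    m = data.n_samples
    n_flip = int(np.floor(spec.flip_fraction * m))
    labels = data.labels.copy()
    if n_flip == 0:
        return LabeledDataset(points=data.points.copy(), labels=labels)
    rng = np.random.default_rng(spec.seed)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to flip labels")
    idx = rng.choice(m, size=n_flip, replace=False)
    for i in idx:
        choices = classes[classes != labels[i]]
        labels[i] = rng.choice(choices)
    return LabeledDataset(points=data.points.copy(), labels=labels)


REGION_KINDS = ("constant", "checkerboard", "random")


def make_texture_scene(
    shape: tuple[int, int] = (48, 48),
    region_layout: tuple[str, ...] = ("constant", "checkerboard", "random"),
    level_low: float = 0.0,
    level_high: float = 255.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise image of vertical bands with known texture statistics.

    Each band is one region kind: ``constant`` (entropy 0, homogeneity
    1), ``checkerboard`` of the two extreme levels (entropy log 2,
    contrast 1, homogeneity 0.5 at offset (0, 1) with 2 levels) or
    ``random`` uniform levels.  Returns ``(image, region_mask)`` where
    the mask holds the band index of every pixel.
    """
    for kind in region_layout:
        if kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {kind!r}")
    h, w = shape
    rng = np.random.default_rng(seed)
    image = np.zeros((h, w), dtype=float)
    mask = np.zeros((h, w), dtype=np.int64)
    bounds = np.linspace(0, w, len(region_layout) + 1).astype(int)
    for b, kind in enumerate(region_layout):
        c0, c1 = bounds[b], bounds[b + 1]
        mask[:, c0:c1] = b
        if kind == "constant":
            image[:, c0:c1] = (level_low + level_high) / 2.0
        elif kind == "checkerboard":
            rr, cc = np.indices((h, c1 - c0))
            image[:, c0:c1] = np.where((rr + cc) % 2 == 0, level_low, level_high)
        else:
            image[:, c0:c1] = rng.uniform(level_low, level_high, size=(h, c1 - c0))
    return image, mask


def make_bold_like_volume(
    shape: tuple[int, int, int] = (64, 64, 18),
    n_blobs: int = 5,
    amplitude: float = 100.0,
    blob_sigma: float = 3.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth activation blobs on background noise, BOLD-acquisition shaped.

    Blobs are truncated 3-D Gaussians (support cut at three sigma), so
    with ``noise_sd = 0`` the background outside the returned blob mask
    is exactly zero.  Default shape is the 64x64x18 voxel cube of one
    BOLD record.
    """
    rng = np.random.default_rng(seed)
    vol = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    grids = np.indices(shape).astype(float)
    for _ in range(n_blobs):
        center = np.array([rng.uniform(0, s - 1) for s in shape])
        d2 = sum((grids[a] - center[a]) ** 2 for a in range(3))
        support = d2 <= (3.0 * blob_sigma) ** 2
        vol[support] += amplitude * np.exp(-d2[support] / (2.0 * blob_sigma**2))
        mask |= support
    return vol, mask


_MOTIFS = ("hstripes", "vstripes", "disk", "checker")


def _motif_image(kind: str, size: int) -> np.ndarray:
    rr, cc = np.indices((size, size))
    if kind == "hstripes":
        return ((rr // 3) % 2).astype(float)
    if kind == "vstripes":
        return ((cc // 3) % 2).astype(float)
    if kind == "disk":
        c = (size - 1) / 2.0
        return ((rr - c) ** 2 + (cc - c) ** 2 <= (size / 3.0) ** 2).astype(float)
    return (((rr // 3) + (cc // 3)) % 2).astype(float)


def make_labeled_imageset(
    n_per_class: int = 200,
    image_size: int = 24,
    n_classes: int = 4,
    motif_strength: float = 2.0,
    noise_sd: float = 1.0,
    test_fraction: float = 0.25,
    seed: int = 0,
):
    """Small grayscale image classification task with geometric motifs.

    Each class is a distinct motif (stripes, disk, checkerboard) of
    amplitude ``motif_strength`` plus unit-scale Gaussian noise, split
    stratified into train and test sets.  Returns
    ``(x_train, y_train, x_test, y_test)`` with channels-last images.
    """
    if not 2 <= n_classes <= len(_MOTIFS):
        raise ValueError(f"n_classes must be in [2, {len(_MOTIFS)}]")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for k in range(n_classes):
        motif = _motif_image(_MOTIFS[k], image_size) * motif_strength
        noise = rng.normal(0.0, noise_sd, size=(n_per_class, image_size, image_size))
        images.append(motif[None] + noise)
        labels.append(np.full(n_per_class, k))
    x = np.concatenate(images)[..., None]
    y = np.concatenate(labels)
    n_test_per = int(round(test_fraction * n_per_class))
    train_idx, test_idx = [], []
    for k in range(n_classes):
        idx = rng.permutation(np.flatnonzero(y == k))
        test_idx.append(idx[:n_test_per])
        train_idx.append(idx[n_test_per:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return x[train_idx], y[train_idx], x[test_idx], y[test_idx]
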