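"""Geometric classification score (GCS) of a labeled point set.

A point of class ``k`` is a *noise point* when it is surrounded by the
other classes: it lies inside the convex hull of the other-class points
found strictly within a radius ``r`` of it.  With ``NS_k`` the number of
noise points of class ``k``::

    GCS_k = 1 - |NS_k| / |C_k|

so a class scores 1 when none of its points are engulfed by the others
and 0 when all of them are.  The aggregate score (unweighted mean over
classes) tracks how classifiable a data set — or a network layer's
representation of it — is: near 1 for clean, separable data, approaching
0 as label noise mixes the classes.

Hull membership is decided by linear feasibility (does a convex
combination of the neighbors reproduce the point?), never by explicit
facet construction, so it works in arbitrary dimension and on affinely
degenerate neighbor sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "LabeledDataset",
    "GCSConfig",
    "GCSReport",
    "normalize_minmax",
    "euclidean_distance",
    "neighbors_within_radius",
    "in_convex_hull",
    "class_noise",
    "gcs",
    "default_radius",
]


@dataclass
class LabeledDataset:
    """``M`` points in ``N``-dimensional space with a class label each."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.points.ndim != 2:
            raise ValueError(f"points must be 2-D (M x N), got shape {self.points.shape}")
        if self.points.shape[0] < 2:
            raise ValueError("need at least 2 points")
        if self.labels.shape != (self.points.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match {self.points.shape[0]} points"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    @property
    def n_features(self) -> int:
        return self.points.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class GCSConfig:
    """Parameters of the GCS computation.

    ``radius`` may be a positive float or ``"auto"`` (a fixed fraction of
    the bounding-box diameter, see :func:`default_radius`).  ``tolerance``
    bounds the residual accepted by the convex-combination feasibility
    test.  ``min_neighbors`` short-circuits the hull test: fewer than two
    distinct neighbors can never strictly contain another point.
    """

    radius: float | str = "auto"
    tolerance: float = 1e-9
    normalize: bool = False
    min_neighbors: int = 2
    auto_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.radius, str):
            if self.radius != "auto":
                raise ValueError(f"radius must be a positive number or 'auto', got {self.radius!r}")
        elif not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if not 0 < self.auto_fraction <= 1:
            raise ValueError(f"auto_fraction must be in (0, 1], got {self.auto_fraction}")


@dataclass
class GCSReport:
    """Per-point noise flags, per-class counts and scores, and provenance."""

    noise_flags: np.ndarray
    ns_per_class: dict
    gcs_per_class: dict
    aggregate: float
    radius_used: float
    tolerance_used: float
    normalized: bool

    def to_dict(self) -> dict:
        return {
            "noise_flags": [bool(f) for f in self.noise_flags],
            "ns_per_class": {str(k): int(v) for k, v in self.ns_per_class.items()},
            "gcs_per_class": {str(k): float(v) for k, v in self.gcs_per_class.items()},
            "aggregate": float(self.aggregate),
            "radius_used": float(self.radius_used),
            "tolerance_used": float(self.tolerance_used),
            "normalized": bool(self.normalized),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def normalize_minmax(data: LabeledDataset) -> LabeledDataset:
    """Affinely map each feature to [0, 1]; constant features map to 0."""
    pts = data.points
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    out = np.zeros_like(pts)
    nz = span > 0
    out[:, nz] = (pts[:, nz] - lo[nz]) / span[nz]
    return LabeledDataset(points=out, labels=data.labels.copy())


def euclidean_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Euclidean norm of ``x - y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def neighbors_within_radius(v: np.ndarray, others: np.ndarray, r: float) -> np.ndarray:
    """Indices of points strictly within radius ``r`` of ``v`` (input order)."""
    if not r > 0:
        raise ValueError(f"radius must be > 0, got {r}")
    others = np.asarray(others, dtype=float)
    if others.size == 0:
        return np.empty(0, dtype=np.int64)
    d = np.linalg.norm(others - np.asarray(v, dtype=float), axis=1)
    return np.flatnonzero(d < r)


def in_convex_hull(v: np.ndarray, subset: np.ndarray, tolerance: float = 1e-9) -> bool:
    """Is ``v`` a convex combination of the points in ``subset``?

    Decided by linear feasibility: exist ``lam_i >= 0``, ``sum lam_i = 1``
    with ``sum lam_i u_i = v`` within ``tolerance``.  Points on the hull
    boundary count as inside.  Works in any dimension; the subset may be
    affinely degenerate (the query is first projected onto the subset's
    affine span, rejecting off-span points immediately).
    """
    subset = np.atleast_2d(np.asarray(subset, dtype=float))
    v = np.asarray(v, dtype=float).ravel()
    if subset.size == 0:
        return False
    if subset.shape[1] != v.shape[0]:
        raise ValueError(f"dimension mismatch: subset {subset.shape[1]}-D vs point {v.shape[0]}-D")
    m = subset.shape[0]
    scale = max(1.0, float(np.abs(subset).max()), float(np.abs(v).max()))
    center = subset.mean(axis=0)
    uc = subset - center
    vc = v - center
    # Orthonormal basis of the affine span; rank cut at the tolerance scale.
    _, s, vt = np.linalg.svd(uc, full_matrices=False)
    rank = int(np.sum(s > tolerance * scale * max(subset.shape)))
    if rank == 0:
        return bool(np.linalg.norm(vc) <= tolerance * scale)
    basis = vt[:rank]
    v_coords = basis @ vc
    residual = np.linalg.norm(vc - basis.T @ v_coords)
    if residual > tolerance * scale * max(subset.shape):
        return False
    coords = uc @ basis.T  # (m, rank)
    a_eq = np.vstack([coords.T, np.ones((1, m))])
    b_eq = np.concatenate([v_coords, [1.0]])
    res = linprog(np.zeros(m), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    return res.status == 0


def default_radius(data: LabeledDataset, fraction: float = 0.3) -> float:
    """``fraction`` times the diameter of the point cloud's bounding box."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    span = data.points.max(axis=0) - data.points.min(axis=0)
    diameter = float(np.linalg.norm(span))
    if diameter == 0:
        raise ValueError("all points are identical; cannot derive a radius")
    return fraction * diameter


def class_noise(
    data: LabeledDataset, k, config: GCSConfig, radius: float | None = None
) -> tuple[np.ndarray, int]:
    """Noise flags for the points of class ``k`` against the other classes.

    A point is noise iff it has at least ``min_neighbors`` other-class
    points strictly within the radius *and* lies inside their convex
    hull.  Returns ``(flags over C_k in input order, NS_k)``.
    """
    mask_k = data.labels == k
    if not mask_k.any():
        raise ValueError(f"class {k!r} is empty")
    if radius is None:
        radius = config.radius if not isinstance(config.radius, str) else default_radius(
            data, config.auto_fraction
        )
    own = data.points[mask_k]
    others = data.points[~mask_k]
    flags = np.zeros(own.shape[0], dtype=bool)
    for i, v in enumerate(own):
        idx = neighbors_within_radius(v, others, radius)
        if idx.size < config.min_neighbors:
            continue
        flags[i] = in_convex_hull(v, others[idx], config.tolerance)
    return flags, int(flags.sum())


def gcs(data: LabeledDataset, config: GCSConfig | None = None) -> GCSReport:
    """Geometric classification score of a labeled data set.

    Optionally min-max normalizes the features, then scores every class
    against the union of the others and aggregates with an unweighted
    mean: ``GCS_k = 1 - NS_k / |C_k|``.
    """
    config = config or GCSConfig()
    classes = data.classes
    if classes.size < 2:
        raise ValueError(f"need at least 2 classes, got {classes.size}")
    work = normalize_minmax(data) if config.normalize else data
    radius = (
        config.radius
        if not isinstance(config.radius, str)
        else default_radius(work, config.auto_fraction)
    )
    noise_flags = np.zeros(work.n_samples, dtype=bool)
    ns: dict = {}
    scores: dict = {}
    for k in classes:
        flags, ns_k = class_noise(work, k, config, radius=radius)
        noise_flags[work.labels == k] = flags
        size_k = int((work.labels == k).sum())
        ns[k] = ns_k
        scores[k] = 1.0 - ns_k / size_k
    aggregate = float(np.mean(list(scores.values())))
    return GCSReport(
        noise_flags=noise_flags,
        ns_per_class=ns,
        gcs_per_class=scores,
        aggregate=aggregate,
        radius_used=float(radius),
        tolerance_used=config.tolerance,
        normalized=config.normalize,
    )
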