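"""Anchor-shape priors from bounding-box clustering.

A region-proposal network needs a small set of prior box shapes ("anchors")
whose widths and heights resemble the objects in the data.  Rather than
hand-picking scales and aspect ratios, the shapes are fitted to the observed
population of ground-truth boxes by clustering in (width, height) space —
either crisp k-means, or fuzzy c-means (FCM) in which every box holds a
graded membership in every cluster.

For fuzzifier m > 1, point j at distance :math:`d_{ij}` from center i gets

.. math::

    u_{ij} = \\Bigl[\\sum_{k=1}^{c} (d_{ij} / d_{kj})^{2/(m-1)}\\Bigr]^{-1}

so each column of memberships sums to one over the c centers, and m -> 1+
recovers crisp nearest-center assignment.  Centers are the u^m-weighted means
of the points, and the two updates alternate until the centers stop moving.
The default fuzzifier is m = 2.

Both fitters are exposed sklearn-style (:class:`FuzzyCMeans`,
:class:`BoxKMeans`) and as thin functions (:func:`fcm_fit`, :func:`kmeans_fit`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans, kmeans_plusplus

__all__ = [
    "BoxWH",
    "FCMConfig",
    "MembershipMatrix",
    "AnchorSet",
    "FuzzyCMeans",
    "BoxKMeans",
    "fcm_memberships",
    "fcm_fit",
    "kmeans_fit",
    "mean_best_iou",
]


class BoxWH(NamedTuple):
    """A box shape: width and height in pixels (position-free)."""

    width: float
    height: float


@dataclass(frozen=True)
class FCMConfig:
    """Fuzzy c-means settings: c clusters, fuzzifier m > 1, stopping rule."""

    c: int = 5
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0
    distance: str = "euclidean"  # or "iou" (1 - centred IoU)

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.distance not in ("euclidean", "iou"):
            raise ValueError("distance must be 'euclidean' or 'iou'")


@dataclass(frozen=True)
class MembershipMatrix:
    """Fuzzy memberships u, shape (n_points, c); every row sums to 1."""

    u: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 2:
            raise ValueError("membership matrix must be 2-D")
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(u.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        object.__setattr__(self, "u", u)


@dataclass(frozen=True)
class AnchorSet:
    """A fitted set of anchor shapes plus the method/config that produced it."""

    shapes: tuple[BoxWH, ...]
    method: str = "manual"
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = tuple(BoxWH(float(w), float(h)) for w, h in self.shapes)
        if any(s.width <= 0 or s.height <= 0 for s in shapes):
            raise ValueError("anchor shapes must be positive")
        object.__setattr__(self, "shapes", shapes)

    def __len__(self) -> int:
        return len(self.shapes)


def _as_points(points: Sequence[BoxWH] | np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) width/height pairs")
    if np.any(pts <= 0):
        raise ValueError("box dimensions must be positive")
    return pts


def _centred_iou_wh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU of (w,h) shapes co-centred at the origin; a (n,2) vs b (c,2)."""
    inter = np.minimum(a[:, None, 0], b[None, :, 0]) * np.minimum(a[:, None, 1], b[None, :, 1])
    union = a[:, 0:1] * a[:, 1:2] + (b[:, 0] * b[:, 1])[None, :] - inter
    return inter / union


def _distances(pts: np.ndarray, centers: np.ndarray, kind: str) -> np.ndarray:
    if kind == "euclidean":
        return np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    return 1.0 - _centred_iou_wh(pts, centers)


def fcm_memberships(
    points: Sequence[BoxWH] | np.ndarray,
    centers: Sequence[BoxWH] | np.ndarray,
    m: float = 2.0,
    distance: str = "euclidean",
) -> MembershipMatrix:
    """Fuzzy membership of each point in each cluster center.

    Implements the FCM membership rule with exponent 2/(m-1) on distance
    ratios.  A point coinciding with a center (zero distance) receives
    membership 1 there — ties broken toward the lowest center index — and 0
    elsewhere.
    """
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")
    pts = _as_points(points)
    ctr = _as_points(centers)
    d = _distances(pts, ctr, distance)
    return MembershipMatrix(_memberships_from_distances(d, m))


def _memberships_from_distances(d: np.ndarray, m: float) -> np.ndarray:
    n, c = d.shape
    u = np.zeros((n, c))
    zero_rows = np.where(np.any(d <= 0, axis=1))[0]
    ok = np.ones(n, dtype=bool)
    ok[zero_rows] = False
    if ok.any():
        ratio = d[ok][:, :, None] / d[ok][:, None, :]  # d_ij / d_kj
        u[ok] = 1.0 / np.sum(ratio ** (2.0 / (m - 1.0)), axis=2)
    for j in zero_rows:
        u[j, int(np.argmin(d[j]))] = 1.0
    return u


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering of box shapes (sklearn-style estimator).

    Parameters mirror :class:`FCMConfig`.  After :meth:`fit`:

    ``cluster_centers_`` : (c, 2) array of fitted shapes;
    ``membership_`` : (n, c) fuzzy memberships;
    ``objective_trace_`` : value of sum_j sum_i u_ij^m d_ij^2 per iteration
    (non-increasing);
    ``n_iter_`` : iterations run;
    ``labels_`` : argmax-membership crisp assignment.
    """

    def __init__(
        self,
        c: int = 5,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        seed: int = 0,
        distance: str = "euclidean",
    ) -> None:
        self.c = c
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.distance = distance

    def fit(self, X, y=None):
        cfg = FCMConfig(self.c, self.m, self.tol, self.max_iter, self.seed, self.distance)
        pts = _as_points(X)
        n = pts.shape[0]
        if n < cfg.c:
            raise ValueError(f"need at least c={cfg.c} points, got {n}")
        rng = np.random.RandomState(cfg.seed)
        if cfg.c == 1:
            centers = pts.mean(axis=0, keepdims=True)
        else:
            centers, _ = kmeans_plusplus(pts, n_clusters=cfg.c, random_state=rng)
        trace: list[float] = []
        u = None
        for it in range(cfg.max_iter):
            d = _distances(pts, centers, cfg.distance)
            u = _memberships_from_distances(d, cfg.m)
            w = u ** cfg.m
            denom = w.sum(axis=0)
            # empty-cluster guard: keep the old center if nothing supports it
            new_centers = centers.copy()
            nz = denom > 0
            new_centers[nz] = (w.T @ pts)[nz] / denom[nz, None]
            trace.append(float(np.sum(w * _distances(pts, new_centers, cfg.distance) ** 2)))
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < cfg.tol:
                break
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = u.argmax(axis=1)
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        return self

    def anchor_set(self) -> AnchorSet:
        return AnchorSet(
            shapes=tuple(BoxWH(*c) for c in self.cluster_centers_),
            method="fcm",
            config=self.get_params(),
        )


class BoxKMeans(ClusterMixin, BaseEstimator):
    """Crisp k-means over box shapes; thin wrapper around sklearn Lloyd's."""

    def __init__(self, k: int = 5, seed: int = 0, n_init: int = 10) -> None:
        self.k = k
        self.seed = seed
        self.n_init = n_init

    def fit(self, X, y=None):
        pts = _as_points(X)
        if pts.shape[0] < self.k:
            raise ValueError(f"need at least k={self.k} points, got {pts.shape[0]}")
        km = KMeans(n_clusters=self.k, n_init=self.n_init, random_state=self.seed)
        km.fit(pts)
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = km.inertia_
        return self

    def anchor_set(self) -> AnchorSet:
        return AnchorSet(
            shapes=tuple(BoxWH(*c) for c in self.cluster_centers_),
            method="kmeans",
            config=self.get_params(),
        )


def fcm_fit(
    points: Sequence[BoxWH] | np.ndarray, config: FCMConfig
) -> tuple[AnchorSet, MembershipMatrix, np.ndarray]:
    """Fit FCM anchors; returns (anchor set, memberships, objective trace)."""
    est = FuzzyCMeans(**{k: getattr(config, k) for k in
                         ("c", "m", "tol", "max_iter", "seed", "distance")}).fit(points)
    return est.anchor_set(), MembershipMatrix(est.membership_), est.objective_trace_


def kmeans_fit(points: Sequence[BoxWH] | np.ndarray, k: int, seed: int = 0) -> AnchorSet:
    """Fit k anchor shapes by k-means (best of 10 restarts)."""
    return BoxKMeans(k=k, seed=seed).fit(points).anchor_set()


def mean_best_iou(
    boxes: Sequence[BoxWH] | np.ndarray, anchors: AnchorSet | Sequence[BoxWH]
) -> float:
    """Mean over boxes of the best IoU against any anchor, both co-centred.

    A scalar anchor-quality score in [0, 1]: 1.0 means every box shape is
    matched exactly by some anchor.
    """
    pts = _as_points(boxes)
    shapes = getattr(anchors, "shapes", anchors)
    ctr = _as_points([tuple(s) for s in shapes])
    if pts.shape[0] == 0 or ctr.shape[0] == 0:
        raise ValueError("boxes and anchors must be nonempty")
    return float(_centred_iou_wh(pts, ctr).max(axis=1).mean())
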