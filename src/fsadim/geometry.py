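"""Point clouds and exact k-nearest-neighbor radii.

The two-scale dimension estimators in :mod:`fsadim.estimators` consume the
distance to the k-th and 2k-th nearest neighbor of every sample point.  The
ratio of these consecutive order statistics is what carries the dimension
signal, so neighbor search here is always *exact* — a tree or a brute-force
scan, never an approximate index.

Two boundary conventions are supported:

``hard``
    Plain Euclidean distance in the ambient space.

``periodic_unit``
    Minimum-image Euclidean distance on the unit torus: each coordinate
    difference is wrapped to ``min(|d|, 1 - |d|)``.  This is the circular
    boundary convention used to remove edge effects when sampling unit
    hypercubes; it requires every coordinate to lie in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

__all__ = ["PointCloud", "NeighborRadii", "pair_distance", "knn_radii"]

_BOUNDARIES = ("hard", "periodic_unit")


@dataclass(frozen=True)
class PointCloud:
    """A sample of n points in an m-dimensional ambient space.

    Parameters
    ----------
    coords
        Array of shape (n, m); all entries must be finite.
    boundary
        ``"hard"`` or ``"periodic_unit"``.  Under ``periodic_unit`` every
        coordinate must lie in [0, 1); out-of-range clouds are rejected
        rather than wrapped silently.
    label
        Optional free-text tag carried through reports.
    """

    coords: np.ndarray
    boundary: str = "hard"
    label: Optional[str] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if coords.ndim != 2 or coords.shape[0] < 1 or coords.shape[1] < 1:
            raise ValueError("coords must be a non-empty n x m matrix")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if self.boundary not in _BOUNDARIES:
            raise ValueError(f"boundary must be one of {_BOUNDARIES}")
        if self.boundary == "periodic_unit":
            if coords.min() < 0.0 or coords.max() >= 1.0:
                raise ValueError(
                    "periodic_unit clouds must have all coordinates in [0, 1)"
                )
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class NeighborRadii:
    """Per-point distances to the k-th and 2k-th nearest neighbor."""

    k: int
    r_k: np.ndarray
    r_2k: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        r_k = np.asarray(self.r_k, dtype=float)
        r_2k = np.asarray(self.r_2k, dtype=float)
        if r_k.shape != r_2k.shape or r_k.ndim != 1:
            raise ValueError("r_k and r_2k must be 1-d arrays of equal length")
        if np.any(r_k < 0) or np.any(r_2k + 1e-15 < r_k):
            raise ValueError("radii must satisfy 0 <= r_k <= r_2k")
        object.__setattr__(self, "r_k", r_k)
        object.__setattr__(self, "r_2k", r_2k)

    @property
    def n(self) -> int:
        return self.r_k.shape[0]


def pair_distance(a, b, boundary: str = "hard") -> float:
    """Distance between two points under the given boundary convention.

    ``hard`` is the Euclidean distance; ``periodic_unit`` replaces each
    coordinate difference with its minimum image min(|d|, 1 - |d|) on the
    unit torus.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("points must have the same dimension")
    if boundary not in _BOUNDARIES:
        raise ValueError(f"boundary must be one of {_BOUNDARIES}")
    diff = np.abs(a - b)
    if boundary == "periodic_unit":
        if a.min() < 0 or a.max() >= 1 or b.min() < 0 or b.max() >= 1:
            raise ValueError("periodic_unit points must lie in [0, 1)")
        diff = np.minimum(diff, 1.0 - diff)
    return float(np.sqrt(np.sum(diff * diff)))


def _neighbor_distances(cloud: PointCloud, n_neighbors: int) -> np.ndarray:
    """Sorted distances to the first n_neighbors neighbors of every point.

    The query point itself is excluded.  Returns shape (n, n_neighbors).
    """
    coords = cloud.coords
    if cloud.boundary == "periodic_unit":
        tree = cKDTree(coords, boxsize=1.0)
        dist, _ = tree.query(coords, k=n_neighbors + 1)
        return dist[:, 1:]
    # Hard boundary: trees degrade in high ambient dimension, where a
    # BLAS-backed brute-force scan wins.
    if cloud.m > 12 or cloud.n <= 500:
        nn = NearestNeighbors(n_neighbors=n_neighbors + 1, algorithm="brute")
    else:
        nn = NearestNeighbors(n_neighbors=n_neighbors + 1)
    nn.fit(coords)
    dist, _ = nn.kneighbors(coords)
    return dist[:, 1:]


def knn_radii(cloud: PointCloud, k: int) -> NeighborRadii:
    """Exact k-th and 2k-th neighbor distances for every point of the cloud.

    Requires n > 2k so that the 2k-th neighbor exists for every point.
    Ties are resolved by the order statistic itself: equal distances yield
    equal radii regardless of point indices.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if cloud.n <= 2 * k:
        raise ValueError(
            f"need n > 2k points (n={cloud.n}, k={k}) to locate the 2k-th neighbor"
        )
    dist = _neighbor_distances(cloud, 2 * k)
    return NeighborRadii(k=k, r_k=dist[:, k - 1], r_2k=dist[:, 2 * k - 1])
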