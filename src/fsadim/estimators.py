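"""Local and global intrinsic-dimension estimators.

The local two-scale (FSA) estimate at a sample point compares the distance
to its k-th and 2k-th nearest neighbors,

    delta_k(x_i) = ln 2 / ln(R_2k / R_k),

so that a locally uniform density on a D-dimensional manifold makes
delta_k an unbiased-in-median estimate of D at *every* k.  Three global
aggregates are provided:

* ``fsa_mean`` — the original mean of local estimates (diverges at k = 1);
* ``fsa_median`` — the median (mFSA), robust down to k = 1;
* ``ml_dimension`` — the maximum-likelihood solution under the exact local
  law, which reduces to the Levina–Bickel / MIND 1-ML closed form at k = 1.

``levina_bickel`` is included as a reference baseline.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import optimize

from .geometry import NeighborRadii, PointCloud, _neighbor_distances, knn_radii

__all__ = [
    "LocalEstimates",
    "GlobalEstimate",
    "local_fsa",
    "fsa_mean",
    "fsa_median",
    "ml_dimension",
    "levina_bickel",
    "estimate_over_k",
    "mfsa",
]

LN2 = math.log(2.0)
logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocalEstimates:
    """Per-point local dimension estimates delta_k.

    ``delta`` entries are positive; +inf marks points whose radii were
    degenerate (R_k = R_2k, or R_k = 0 with duplicates present).
    ``n_degenerate`` counts the R_k = 0 points that were remapped to +inf.
    """

    k: int
    delta: np.ndarray
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        if delta.ndim != 1 or delta.size < 1:
            raise ValueError("delta must be a non-empty 1-d array")
        if np.any(delta <= 0) or np.any(np.isnan(delta)):
            raise ValueError("delta entries must be positive (or +inf)")
        object.__setattr__(self, "delta", delta)

    @property
    def n(self) -> int:
        return self.delta.shape[0]

    @property
    def n_finite(self) -> int:
        return int(np.isfinite(self.delta).sum())


@dataclass(frozen=True)
class GlobalEstimate:
    """A single global dimension estimate and how it was aggregated."""

    value: float
    statistic: str
    k: int
    n_effective: int


def local_fsa(radii: NeighborRadii) -> LocalEstimates:
    """Local two-scale estimates from k-th/2k-th neighbor radii.

    Points with R_k = R_2k > 0 (exact distance ties across the two scales)
    get delta = +inf.  Points with R_k = 0 < R_2k (duplicated samples) would
    formally give delta = 0, which is meaningless; they are flagged as
    degenerate and also mapped to +inf so the median stays robust.  A cloud
    where some R_2k = 0 (at least 2k+1 coincident points) is rejected.
    """
    r_k, r_2k = radii.r_k, radii.r_2k
    if np.any(r_2k == 0):
        raise ValueError(
            "degenerate cloud: some point has 2k coincident neighbors (R_2k = 0)"
        )
    delta = np.full(r_k.shape, np.inf)
    zero_rk = r_k == 0
    n_degenerate = int(zero_rk.sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} point(s) with R_k = 0 (duplicate samples); "
            "their local estimates are set to +inf",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = (~zero_rk) & (r_2k > r_k)
    delta[ok] = LN2 / np.log(r_2k[ok] / r_k[ok])
    return LocalEstimates(k=radii.k, delta=delta, n_degenerate=n_degenerate)


def fsa_mean(local: LocalEstimates) -> GlobalEstimate:
    """Mean of the local estimates (the original FSA aggregate).

    Any +inf local estimate makes the mean +inf; in particular the k = 1
    mean has no finite expectation even in the ideal model.
    """
    value = float(np.mean(local.delta))
    return GlobalEstimate(
        value=value, statistic="mean", k=local.k, n_effective=local.n_finite
    )


def fsa_median(local: LocalEstimates) -> GlobalEstimate:
    """Median of the local estimates (the mFSA aggregate).

    Finite whenever more than half the local estimates are finite.  Even
    counts use the midpoint of the two central order statistics.
    """
    value = float(np.median(local.delta))
    return GlobalEstimate(
        value=value, statistic="median", k=local.k, n_effective=local.n_finite
    )


def _ml_score(D: float, delta: np.ndarray, k: int) -> float:
    """Derivative of the log-likelihood of the exact local law w.r.t. D."""
    n = delta.size
    inv = 1.0 / delta
    s = n / D - LN2 * k * inv.sum()
    if k > 1:
        with np.errstate(over="ignore"):
            denom = np.expm1(D * LN2 * inv)
        s += LN2 * (k - 1) * (inv / denom).sum()
    return s


def _ml_loglik(D: float, delta: np.ndarray, k: int) -> float:
    """Log-likelihood of the exact local law (additive constants dropped)."""
    n = delta.size
    inv = 1.0 / delta
    ll = n * math.log(D) - D * k * LN2 * inv.sum()
    if k > 1:
        ll += (k - 1) * np.log(-np.expm1(-D * LN2 * inv)).sum()
    return float(ll)


def ml_dimension(
    local: LocalEstimates, k: int | None = None, bracket_cap: float = 1e6
) -> GlobalEstimate:
    """Maximum-likelihood global dimension under the exact local law.

    For k = 1 the score has the closed-form root D = n / sum(ln(R_2/R_1))
    = n / (ln 2 * sum(1/delta)).  For k > 1 the score equation is
    transcendental and the unique positive root is found by bracketing and
    Brent's method.  Non-finite local estimates make the likelihood
    undefined and raise.
    """
    if k is None:
        k = local.k
    delta = local.delta
    if not np.all(np.isfinite(delta)):
        raise ValueError("ml_dimension requires all local estimates finite")
    n = delta.size
    if k == 1:
        value = n / (LN2 * float(np.sum(1.0 / delta)))
        return GlobalEstimate(value=value, statistic="ml", k=k, n_effective=n)
    lo, hi = 1e-6, 10.0 * max(1.0, float(np.median(delta)))
    while _ml_score(hi, delta, k) > 0:
        hi *= 2.0
        if hi > bracket_cap:
            raise RuntimeError("ML score root could not be bracketed")
    if _ml_score(lo, delta, k) < 0:
        raise RuntimeError("ML score root could not be bracketed from below")
    root = optimize.brentq(
        _ml_score, lo, hi, args=(delta, k), xtol=1e-12, rtol=8.9e-16
    )
    # polish: the score at the root should be numerically zero
    if abs(_ml_score(root, delta, k)) > 1e-6 * n:
        raise RuntimeError("ML root finding did not converge")
    return GlobalEstimate(value=float(root), statistic="ml", k=k, n_effective=n)


def _levina_bickel_from_distances(dist: np.ndarray, convention: str) -> float:
    """Levina–Bickel estimate from an (n, k) matrix of sorted neighbor
    distances.

    Per-point estimate: m_k(x_i) = [ (1/(k-1)) sum_{j<k} ln(R_k/R_j) ]^-1.
    ``global_inverse`` inverts the average of the per-point inverses (a
    single pooled ML estimate); ``mean_local`` averages the per-point
    estimates directly.
    """
    n, kk = dist.shape
    k = kk
    if k < 2:
        raise ValueError("levina_bickel requires k >= 2")
    if np.any(dist[:, :-1] <= 0):
        raise ValueError("duplicate points make the Levina-Bickel sum diverge")
    logs = np.log(dist[:, -1][:, None] / dist[:, :-1])  # (n, k-1)
    inv_local = logs.mean(axis=1)  # 1 / m_k(x_i)
    if convention == "global_inverse":
        return float(1.0 / inv_local.mean())
    if convention == "mean_local":
        return float((1.0 / inv_local).mean())
    raise ValueError("convention must be 'global_inverse' or 'mean_local'")


def levina_bickel(
    cloud: PointCloud, k: int, convention: str = "global_inverse"
) -> GlobalEstimate:
    """Classical Levina–Bickel ML dimension estimate (reference baseline)."""
    if k < 2:
        raise ValueError("levina_bickel requires k >= 2")
    if cloud.n <= k:
        raise ValueError("need n > k points")
    dist = _neighbor_distances(cloud, k)
    value = _levina_bickel_from_distances(dist, convention)
    return GlobalEstimate(
        value=value, statistic="ml", k=k, n_effective=cloud.n
    )


_STATISTICS = {"mean": fsa_mean, "median": fsa_median, "ml": ml_dimension}


def estimate_over_k(
    cloud: PointCloud, k_min: int, k_max: int, statistic: str = "median"
) -> Tuple[List[Tuple[int, GlobalEstimate]], float]:
    """Global estimates for every k in [k_min, k_max], plus their mean.

    Neighbor distances are computed once up to order 2*k_max and sliced per
    k, so a k-sweep costs a single neighbor query.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if cloud.n <= 2 * k_max:
        raise ValueError("need n > 2*k_max points")
    dist = _neighbor_distances(cloud, 2 * k_max)
    results: List[Tuple[int, GlobalEstimate]] = []
    for k in range(k_min, k_max + 1):
        radii = NeighborRadii(k=k, r_k=dist[:, k - 1], r_2k=dist[:, 2 * k - 1])
        local = local_fsa(radii)
        if statistic == "ml":
            est = ml_dimension(local, k)
        else:
            est = _STATISTICS[statistic](local)
        results.append((k, est))
    mean_over_k = float(np.mean([e.value for _, e in results]))
    return results, mean_over_k


def mfsa(cloud: PointCloud, k: int) -> GlobalEstimate:
    """Convenience one-call median-FSA estimate of a cloud at scale k."""
    return fsa_median(local_fsa(knn_radii(cloud, k)))
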