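"""Synthetic manifold samplers and a coupled logistic-map simulator.

These generators produce the test beds on which the estimators are
validated and calibrated:

* uniform unit hypercubes (hard or periodic-unit boundary) — the
  calibration family for the corrected estimator;
* standard multivariate Gaussians — non-uniform density;
* Cauchy-norm clouds — heavy-tailed radial density (uniform direction,
  half-Cauchy radius);
* uniform hypersphere surfaces — curvature with near-uniform density
  (intrinsic dimension D, ambient dimension D + 1);
* three coupled chaotic logistic maps, two independent drivers forcing a
  third variable, whose delay-embedded dynamics has intrinsic dimension
  close to 3.

All samplers are pure functions of their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .geometry import PointCloud

__all__ = [
    "ManifoldSpec",
    "LogisticMapParams",
    "sample_hypercube",
    "sample_gaussian",
    "sample_cauchy_ball",
    "sample_sphere_surface",
    "sample_manifold",
    "simulate_coupled_logistic",
    "delay_embed",
]

_FAMILIES = ("hypercube", "gaussian", "cauchy_ball", "sphere_surface")


@dataclass(frozen=True)
class ManifoldSpec:
    """What to sample: family, intrinsic dimension, count, boundary, seed."""

    family: str
    D: int
    n: int
    seed: int = 0
    boundary: str = "hard"  # meaningful for hypercubes only

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.D < 1 or self.n < 1:
            raise ValueError("D and n must be positive integers")
        if self.boundary == "periodic_unit" and self.family != "hypercube":
            raise ValueError("periodic_unit applies to hypercubes only")


@dataclass(frozen=True)
class LogisticMapParams:
    """Parameters of the driven logistic-map system.

    Two independent logistic maps x, y with growth rates r_x, r_y drive a
    third map z through couplings beta_zx, beta_zy:

        x(t+1) = r_x x (1 - x)
        y(t+1) = r_y y (1 - y)
        z(t+1) = r_z z (1 - z - beta_zx x - beta_zy y)

    States are kept on the unit interval with periodic boundary (wrapped
    modulo 1 each step; ``wrap_state=False`` leaves the raw z trajectory,
    for the reading where only embedded-space distances are periodic).
    """

    r_x: float = 3.99
    r_y: float = 3.99
    r_z: float = 3.99
    beta_zx: float = 0.3
    beta_zy: float = 0.3
    n: int = 1000
    transient: int = 1000
    seed: int = 0
    wrap_state: bool = True

    def __post_init__(self) -> None:
        if self.n < 1 or self.transient < 0:
            raise ValueError("n must be >= 1 and transient >= 0")


def sample_hypercube(spec: ManifoldSpec) -> PointCloud:
    """n i.i.d. points uniform on [0, 1)^D; boundary flag copied through."""
    if spec.family != "hypercube":
        raise ValueError("spec.family must be 'hypercube'")
    rng = np.random.default_rng(spec.seed)
    coords = rng.random((spec.n, spec.D))
    return PointCloud(coords, boundary=spec.boundary, label=f"hypercube-{spec.D}d")


def sample_gaussian(spec: ManifoldSpec) -> PointCloud:
    """n i.i.d. standard D-variate normal points (zero mean, identity cov)."""
    if spec.family != "gaussian":
        raise ValueError("spec.family must be 'gaussian'")
    rng = np.random.default_rng(spec.seed)
    coords = rng.standard_normal((spec.n, spec.D))
    return PointCloud(coords, boundary="hard", label=f"gaussian-{spec.D}d")


def _unit_directions(rng: np.random.Generator, n: int, D: int) -> np.ndarray:
    z = rng.standard_normal((n, D))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


def sample_cauchy_ball(spec: ManifoldSpec) -> PointCloud:
    """Heavy-tailed cloud: uniform direction times a half-Cauchy radius.

    Directions are normalized D-variate Gaussians (uniform on the sphere);
    radii are |standard Cauchy| draws, so the norms follow the half-Cauchy
    law with median 1.
    """
    if spec.family != "cauchy_ball":
        raise ValueError("spec.family must be 'cauchy_ball'")
    rng = np.random.default_rng(spec.seed)
    z = _unit_directions(rng, spec.n, spec.D)
    u = np.abs(rng.standard_cauchy(spec.n))
    return PointCloud(u[:, None] * z, boundary="hard", label=f"cauchy-{spec.D}d")


def sample_sphere_surface(spec: ManifoldSpec) -> PointCloud:
    """n points uniform on the unit sphere surface in R^(D+1).

    Intrinsic dimension D, ambient dimension D + 1.
    """
    if spec.family != "sphere_surface":
        raise ValueError("spec.family must be 'sphere_surface'")
    rng = np.random.default_rng(spec.seed)
    coords = _unit_directions(rng, spec.n, spec.D + 1)
    return PointCloud(coords, boundary="hard", label=f"sphere-{spec.D}d")


_SAMPLERS = {
    "hypercube": sample_hypercube,
    "gaussian": sample_gaussian,
    "cauchy_ball": sample_cauchy_ball,
    "sphere_surface": sample_sphere_surface,
}


def sample_manifold(spec: ManifoldSpec) -> PointCloud:
    """Dispatch to the sampler named by ``spec.family``."""
    return _SAMPLERS[spec.family](spec)


def simulate_coupled_logistic(
    params: LogisticMapParams,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the driven logistic-map system.

    Initial states are drawn uniform in (0, 1) from the seeded generator;
    ``transient`` steps are discarded and ``n`` states of (x, y, z) are
    returned.  With ``wrap_state`` the coupled z-update, which can exit
    [0, 1], is wrapped modulo 1 each step (periodic boundary on the unit
    interval).
    """
    rng = np.random.default_rng(params.seed)
    x, y, z = rng.uniform(1e-6, 1.0 - 1e-6, size=3)
    total = params.transient + params.n
    xs = np.empty(total)
    ys = np.empty(total)
    zs = np.empty(total)
    for t in range(total):
        x = params.r_x * x * (1.0 - x)
        y = params.r_y * y * (1.0 - y)
        z = params.r_z * z * (1.0 - z - params.beta_zx * x - params.beta_zy * y)
        if params.wrap_state:
            x %= 1.0
            y %= 1.0
            z %= 1.0
        xs[t], ys[t], zs[t] = x, y, z
    sl = slice(params.transient, None)
    return xs[sl], ys[sl], zs[sl]


def delay_embed(
    series, E: int, tau: int, boundary: str = "hard", label: Optional[str] = None
) -> PointCloud:
    """Time-delay embedding X(t) = [x(t), x(t-tau), ..., x(t-(E-1)tau)].

    Returns a cloud with len(series) - (E-1)*tau rows and E columns; row t
    holds the present value first and the most lagged value last.
    """
    series = np.asarray(series, dtype=float).ravel()
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be positive integers")
    n_rows = series.size - (E - 1) * tau
    if n_rows < 1:
        raise ValueError("series too short for the requested embedding")
    cols = [series[(E - 1 - j) * tau : (E - 1 - j) * tau + n_rows] for j in range(E)]
    coords = np.column_stack(cols)  # column 0 = x(t), column j = x(t - j*tau)
    return PointCloud(coords, boundary=boundary, label=label)
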