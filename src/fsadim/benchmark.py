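"""Benchmark metrics and the evaluation harness.

Estimator quality on a battery of known-dimension manifolds is summarized
by two metrics:

* mean percentage error, MPE = 100/(M N) * sum_j sum_i |D_j - d_ij| / D_j,
  over M manifold types and N realizations each;
* the error rate H_j, the fraction of realizations whose integer-mode
  estimate misses the true dimension, averaged unweighted over manifolds.

The harness generates realizations of the built-in manifold families
(hypercubes and Gaussians; other families plug in through
``BenchmarkSpec.sampler``), runs an estimator on each, and aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CorrectionModel, cmfsa
from .estimators import mfsa
from .geometry import PointCloud
from .manifolds import ManifoldSpec, sample_manifold

__all__ = ["BenchmarkSpec", "BenchmarkResult", "mpe", "error_rate", "run_benchmark"]


def mpe(estimates, true_dims) -> float:
    """Mean percentage error of an M x N estimate matrix against M truths."""
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    dims = np.asarray(true_dims, dtype=float).ravel()
    if est.shape[0] != dims.size:
        raise ValueError("one row of estimates per true dimension required")
    if np.any(dims <= 0):
        raise ValueError("true dimensions must be positive")
    return float(100.0 * np.mean(np.abs(dims[:, None] - est) / dims[:, None]))


def error_rate(estimates, true_D: int) -> float:
    """Fraction of integer-mode estimates that miss the true dimension."""
    est = np.asarray(estimates)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.mean(est.astype(int) != int(true_D)))


@dataclass(frozen=True)
class BenchmarkSpec:
    """One manifold entry of a benchmark run."""

    name: str
    true_D: int
    n: int
    family: str = "hypercube"
    boundary: str = "hard"
    #: optional user generator ``sampler(D, n, seed) -> PointCloud`` for
    #: families the built-ins do not cover
    sampler: Optional[Callable[[int, int, int], PointCloud]] = None

    def sample(self, seed: int) -> PointCloud:
        if self.sampler is not None:
            return self.sampler(self.true_D, self.n, seed)
        spec = ManifoldSpec(
            family=self.family, D=self.true_D, n=self.n, seed=seed,
            boundary=self.boundary,
        )
        return sample_manifold(spec)


@dataclass
class BenchmarkResult:
    """Per-manifold estimates plus the aggregate MPE and mean error rate."""

    table: pd.DataFrame
    estimates: Dict[str, np.ndarray]
    mpe: float
    mean_error_rate: Optional[float]

    def to_csv(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def run_benchmark(
    specs: Sequence[BenchmarkSpec],
    k: int,
    n_realizations: int,
    seed: int = 0,
    estimator: str = "mfsa",
    model: Optional[CorrectionModel] = None,
    mode: str = "integer",
) -> BenchmarkResult:
    """Run an estimator over N realizations of each benchmark manifold.

    ``estimator`` is ``"mfsa"`` (raw median-FSA) or ``"cmfsa"`` (corrected;
    requires ``model``).  Error rates are reported for integer-valued
    estimates only: raw or fractal estimates are rounded first.  Results
    are bit-identical under a fixed seed.
    """
    if estimator not in ("mfsa", "cmfsa"):
        raise ValueError("estimator must be 'mfsa' or 'cmfsa'")
    if estimator == "cmfsa" and model is None:
        raise ValueError("cmfsa benchmark requires a correction model")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs))
    rows: List[dict] = []
    all_estimates: Dict[str, np.ndarray] = {}
    for spec, ss in zip(specs, children):
        seeds = ss.generate_state(n_realizations) % (2**31)
        vals = np.empty(n_realizations)
        for i in range(n_realizations):
            cloud = spec.sample(int(seeds[i]))
            if estimator == "mfsa":
                vals[i] = mfsa(cloud, k).value
            else:
                vals[i] = cmfsa(cloud, k, model, mode=mode).value
        all_estimates[spec.name] = vals
        rounded = np.array([math.floor(v + 0.5) for v in vals])
        rows.append(
            {
                "manifold": spec.name,
                "true_D": spec.true_D,
                "mean_estimate": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n_realizations > 1 else 0.0,
                "error_rate": error_rate(rounded, spec.true_D),
            }
        )
    table = pd.DataFrame(rows)
    agg_mpe = mpe(
        np.vstack([all_estimates[s.name] for s in specs]),
        [s.true_D for s in specs],
    )
    mean_h = float(table["error_rate"].mean())
    return BenchmarkResult(
        table=table, estimates=all_estimates, mpe=agg_mpe, mean_error_rate=mean_h
    )
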