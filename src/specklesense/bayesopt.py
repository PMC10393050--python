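"""Gaussian-process Bayesian optimization for hyperparameter search.

A compact sequential model-based optimizer: an initial space-filling sample
of the (log-scaled) box, then expected-improvement acquisitions under a
Matérn-5/2 Gaussian process fit to the observed objective values. All
randomness flows from the caller's seed, so a search is exactly repeatable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import warnings

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["Dimension", "BayesOptResult", "minimize"]


@dataclass(frozen=True)
class Dimension:
    """One box-constrained search dimension; log dims are sampled in log10."""

    low: float
    high: float
    log: bool = False

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.log:
            return 10.0 ** rng.uniform(np.log10(self.low), np.log10(self.high), size)
        return rng.uniform(self.low, self.high, size)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.log10(x) if self.log else np.asarray(x, dtype=float)


@dataclass
class BayesOptResult:
    best_x: np.ndarray
    best_value: float
    x_history: np.ndarray
    value_history: np.ndarray


def _expected_improvement(
    gp: GaussianProcessRegressor, candidates: np.ndarray, best: float
) -> np.ndarray:
    mu, sigma = gp.predict(candidates, return_std=True)
    sigma = np.maximum(sigma, 1e-12)
    gamma = (best - mu) / sigma
    return sigma * (gamma * norm.cdf(gamma) + norm.pdf(gamma))


def minimize(
    objective: Callable[[np.ndarray], float],
    dimensions: Sequence[Dimension],
    n_calls: int = 20,
    n_initial: int | None = None,
    seed: int = 0,
    n_candidates: int = 512,
) -> BayesOptResult:
    """Minimize a black-box objective over a box with GP expected improvement.

    n_initial points (default: max(4, n_calls // 3)) are drawn uniformly in
    the (log-)box; the remaining budget is spent on EI acquisitions evaluated
    over a seeded random candidate pool.
    """
    rng = np.random.default_rng(seed)
    dims = list(dimensions)
    if n_initial is None:
        n_initial = max(4, n_calls // 3)
    n_initial = min(n_initial, n_calls)

    xs: list[np.ndarray] = []
    values: list[float] = []

    init = np.column_stack([d.sample(rng, n_initial) for d in dims])
    for row in init:
        xs.append(row)
        values.append(float(objective(row)))

    kernel = ConstantKernel(1.0) * Matern(
        length_scale=np.ones(len(dims)), nu=2.5
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))

    for _ in range(n_calls - n_initial):
        X = np.array([[d.transform(x[i]) for i, d in enumerate(dims)] for x in xs])
        y = np.asarray(values)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=0, n_restarts_optimizer=1
        )
        with warnings.catch_warnings():
            # hyperparameters pinned at their bounds are fine for acquisition
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y)
        cand = np.column_stack([d.sample(rng, n_candidates) for d in dims])
        cand_t = np.column_stack(
            [d.transform(cand[:, i]) for i, d in enumerate(dims)]
        )
        ei = _expected_improvement(gp, cand_t, float(y.min()))
        pick = cand[int(np.argmax(ei))]
        xs.append(pick)
        values.append(float(objective(pick)))

    values_arr = np.asarray(values)
    best = int(np.argmin(values_arr))
    return BayesOptResult(
        best_x=np.asarray(xs[best]),
        best_value=float(values_arr[best]),
        x_history=np.asarray(xs),
        value_history=values_arr,
    )
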