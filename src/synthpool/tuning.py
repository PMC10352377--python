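"""Sequential model-based hyperparameter search for the synthesis models.

A small Bayesian-optimization loop: candidate boosted-tree configurations
are scored by five-fold cross-validation, a Gaussian-process surrogate is
fitted to the observed (configuration, score) pairs on the unit cube, and
the next trial maximizes expected improvement over a random candidate set.
The first ``n_initial`` trials are space-filling random draws. With
``n_trials = 0`` the search is skipped and the documented fixed defaults are
used (the desk-scale pipeline setting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern


@dataclass(frozen=True)
class Param:
    """One search dimension: [low, high], optionally log-scaled / integer."""

    name: str
    low: float
    high: float
    integer: bool = False
    log: bool = False

    def decode(self, u: float):
        lo, hi = (np.log(self.low), np.log(self.high)) if self.log else (self.low, self.high)
        x = lo + u * (hi - lo)
        if self.log:
            x = np.exp(x)
        return int(round(x)) if self.integer else float(x)


#: documented default search space for the boosted-tree conditionals
DEFAULT_SPACE = (
    Param("num_boost_round", 20, 300, integer=True, log=True),
    Param("num_leaves", 4, 64, integer=True, log=True),
    Param("learning_rate", 0.01, 0.3, log=True),
    Param("min_data_in_leaf", 5, 100, integer=True, log=True),
)

#: fixed defaults used when tuning is disabled (n_trials = 0)
FIXED_DEFAULTS = {
    "num_boost_round": 60,
    "num_leaves": 15,
    "learning_rate": 0.1,
    "min_data_in_leaf": 40,
}


@dataclass(frozen=True)
class TuningConfig:
    """Budget and space of the per-variable hyperparameter search."""

    n_trials: int = 25
    n_initial: int = 8
    n_candidates: int = 256
    space: tuple = DEFAULT_SPACE
    min_rows: int = 50  # complete-row floor below which fitting refuses


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def minimize(objective: Callable[[dict], float], config: TuningConfig,
             seed: int) -> tuple:
    """Minimize a CV-score objective over the search space.

    Returns ``(best_params, best_score, history)`` where history is the list
    of (params, score) pairs in trial order. Deterministic for a given seed.
    """
    if config.n_trials <= 0:
        params = dict(FIXED_DEFAULTS)
        return params, float("nan"), []
    rng = np.random.default_rng(seed)
    dims = len(config.space)
    X, y, history = [], [], []

    def run(u):
        params = {p.name: p.decode(ui) for p, ui in zip(config.space, u)}
        score = float(objective(params))
        X.append(u)
        y.append(score)
        history.append((params, score))

    n_init = min(config.n_initial, config.n_trials)
    for _ in range(n_init):
        run(rng.random(dims))

    for _ in range(config.n_trials - n_init):
        Xa, ya = np.array(X), np.array(y)
        finite = np.isfinite(ya)
        if finite.sum() < 2:
            run(rng.random(dims))
            continue
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(dims, 0.3)),
            normalize_y=True, alpha=1e-6, random_state=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xa[finite], ya[finite])
        cand = rng.random((config.n_candidates, dims))
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, ya[finite].min())
        run(cand[int(np.argmax(ei))])

    best = int(np.nanargmin(y))
    return history[best][0], float(y[best]), history
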