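"""Minimal Gaussian-process Bayesian optimization for hyperparameter search.

Sequential model-based optimization: after a handful of random evaluations, a
GP with a Matern-5/2 kernel is fit to the observed objective values on the
unit hypercube (log-scaled dimensions are warped first) and the next point
maximizes expected improvement over a random candidate pool. Deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["Dimension", "Integer", "Real", "Categorical", "gp_minimize"]


@dataclass(frozen=True)
class Dimension:
    name: str


@dataclass(frozen=True)
class Integer(Dimension):
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Real(Dimension):
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Categorical(Dimension):
    choices: tuple


def _to_unit(dim: Dimension, value):
    if isinstance(dim, Categorical):
        return dim.choices.index(value) / max(len(dim.choices) - 1, 1)
    lo, hi = dim.low, dim.high
    if dim.log:
        return (np.log(value) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return (value - lo) / (hi - lo)


def _from_unit(dim: Dimension, u: float):
    if isinstance(dim, Categorical):
        return dim.choices[int(round(u * (len(dim.choices) - 1)))]
    lo, hi = dim.low, dim.high
    if dim.log:
        v = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
    else:
        v = float(lo + u * (hi - lo))
    if isinstance(dim, Integer):
        return int(np.clip(round(v), lo, hi))
    return v


def gp_minimize(
    objective,
    space: list[Dimension],
    n_calls: int = 20,
    n_initial: int = 8,
    n_candidates: int = 256,
    seed: int = 0,
):
    """Minimize ``objective(dict)`` over the space; returns (best_params, best_value).

    The first ``n_initial`` points are uniform random draws; the remainder are
    chosen by expected improvement under a GP surrogate evaluated on a random
    candidate pool.
    """
    rng = np.random.default_rng(seed)
    d = len(space)
    U: list[np.ndarray] = []
    vals: list[float] = []

    def eval_at(u: np.ndarray) -> None:
        params = {dim.name: _from_unit(dim, ui) for dim, ui in zip(space, u)}
        vals.append(float(objective(params)))
        U.append(u)

    for _ in range(min(n_initial, n_calls)):
        eval_at(rng.uniform(size=d))
    kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.3), nu=2.5) + WhiteKernel(
        noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1)
    )
    for _ in range(n_calls - len(vals)):
        X = np.vstack(U)
        y = np.asarray(vals)
        y_mean, y_sd = y.mean(), max(y.std(), 1e-12)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, random_state=int(rng.integers(2**31))
        )
        gp.fit(X, (y - y_mean) / y_sd)
        cand = rng.uniform(size=(n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        best = (y.min() - y_mean) / y_sd
        imp = best - mu
        sd = np.maximum(sd, 1e-12)
        z = imp / sd
        ei = imp * norm.cdf(z) + sd * norm.pdf(z)
        eval_at(cand[int(np.argmax(ei))])
    i = int(np.argmin(vals))
    best_params = {dim.name: _from_unit(dim, ui) for dim, ui in zip(space, U[i])}
    return best_params, vals[i]
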