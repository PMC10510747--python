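"""Training-set construction: library sampling biases and measurement noise.

Strains are assembled in a one-pot fashion: each enzyme's level is drawn
independently from a per-enzyme probability vector over the P grid levels,
so duplicate designs are permitted. Three named scenarios mirror typical DNA
library biases: ``equal`` (uniform), ``strong_effect_bias`` (mass pushed to
levels far from the initial strain, extra mass on upregulation) and
``mild_effect_bias`` (mass concentrated near the initial strain level).

Measured relative fluxes carry additive Gaussian noise, either homoscedastic
(constant sigma) or heteroscedastic (sigma proportional to the signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dbtlsim.design_space import DesignGrid
from dbtlsim.kinetics import ConfigurationError

__all__ = [
    "SamplingScenario",
    "NoiseModel",
    "TrainingSet",
    "make_scenario",
    "sample_designs",
    "add_noise",
    "make_training_set",
]

# default bias vectors over the default 6-level grid (0.125 ... 4)
_STRONG_6 = (0.20, 0.15, 0.075, 0.075, 0.20, 0.30)
_MILD_6 = (0.05, 0.10, 0.25, 0.30, 0.20, 0.10)


@dataclass(frozen=True)
class SamplingScenario:
    """Per-enzyme level-sampling distributions (rows: enzymes, cols: levels)."""

    name: str
    probs: np.ndarray  # shape (N, P)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2:
            raise ConfigurationError("probs must be a (N, P) matrix")
        if np.any(p < 0):
            raise ConfigurationError("probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise ConfigurationError("each probability vector must sum to 1")
        object.__setattr__(self, "probs", p)


def _bias_weights(levels: np.ndarray, kind: str) -> np.ndarray:
    """Monotone-in-|log2 level| bias shapes for arbitrary grids."""
    dist = np.abs(np.log2(levels))
    if kind == "strong":
        w = (1.0 + dist) * np.where(levels > 1.0, 1.5, 1.0)
    else:  # mild: concentrate near the initial strain
        w = 1.0 / (1.0 + dist)
    return w / w.sum()


def make_scenario(name: str, grid: DesignGrid, probs=None) -> SamplingScenario:
    """Build one of the named scenarios (or a custom one) for a grid."""
    N, P = grid.n_enzymes, grid.n_levels
    levels = np.asarray(grid.levels)
    if name == "custom":
        if probs is None:
            raise ConfigurationError("custom scenario requires an explicit probs matrix")
        p = np.asarray(probs, dtype=float)
        if p.ndim == 1:
            p = np.tile(p, (N, 1))
        return SamplingScenario("custom", p)
    if probs is not None:
        raise ConfigurationError("probs only allowed with the custom scenario")
    if name == "equal":
        vec = np.full(P, 1.0 / P)
    elif name == "strong_effect_bias":
        vec = np.array(_STRONG_6) if P == 6 else _bias_weights(levels, "strong")
    elif name == "mild_effect_bias":
        vec = np.array(_MILD_6) if P == 6 else _bias_weights(levels, "mild")
    else:
        raise ConfigurationError(f"unknown scenario {name!r}")
    return SamplingScenario(name, np.tile(vec, (N, 1)))


def sample_designs(
    scenario: SamplingScenario, grid: DesignGrid, n: int, seed: int
) -> np.ndarray:
    """Draw n designs, each enzyme level independently from its distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if scenario.probs.shape != (grid.n_enzymes, grid.n_levels):
        raise ConfigurationError(
            f"scenario probability matrix {scenario.probs.shape} does not match "
            f"grid (N={grid.n_enzymes}, P={grid.n_levels})"
        )
    rng = np.random.default_rng(seed)
    levels = np.asarray(grid.levels)
    out = np.empty((n, grid.n_enzymes))
    for j in range(grid.n_enzymes):
        out[:, j] = rng.choice(levels, size=n, p=scenario.probs[j])
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise on the relative flux."""

    kind: str = "none"  # homoscedastic | heteroscedastic | none
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("homoscedastic", "heteroscedastic", "none"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


def add_noise(fluxes: np.ndarray, model: NoiseModel, seed: int) -> np.ndarray:
    """y + eps with eps ~ N(0, sigma) or N(0, sigma*|y|); sigma = 0 is the identity."""
    y = np.asarray(fluxes, dtype=float)
    if model.kind == "none" or model.sigma == 0.0:
        return y.copy()
    rng = np.random.default_rng(seed)
    if model.kind == "homoscedastic":
        return y + rng.normal(0.0, model.sigma, size=y.shape)
    return y + rng.normal(0.0, 1.0, size=y.shape) * model.sigma * np.abs(y)


@dataclass(frozen=True)
class TrainingSet:
    """Sampled designs with noisy measured fluxes plus provenance."""

    designs: np.ndarray  # (n, N)
    y: np.ndarray  # noisy relative fluxes
    y_clean: np.ndarray  # noiseless relative fluxes
    scenario: str
    seed: int

    @property
    def n(self) -> int:
        return len(self.y)

    def to_frame(self, grid: DesignGrid) -> pd.DataFrame:
        df = pd.DataFrame(self.designs, columns=list(grid.enzymes))
        df["relative_flux"] = self.y
        return df


def make_training_set(
    landscape: pd.DataFrame,
    scenario: SamplingScenario,
    grid: DesignGrid,
    n: int,
    seed: int,
    noise: NoiseModel = NoiseModel(),
    restrict_to_landscape: bool = False,
) -> TrainingSet:
    """Sample a training set and look its noiseless fluxes up in the landscape.

    With ``restrict_to_landscape`` the designs are drawn from the landscape's
    own rows, each weighted by its scenario probability (for landscapes that
    cover only an evaluation subset of the space); otherwise designs are
    sampled freely from the grid and must all be present in the landscape.
    Non-converged landscape rows are never sampled.
    """
    land = landscape[landscape["converged"]].reset_index(drop=True)
    X_land = land[list(grid.enzymes)].to_numpy()
    y_land = land["relative_flux"].to_numpy()
    rng_seed = np.random.default_rng(seed)
    if restrict_to_landscape:
        idx = grid.level_index(X_land)  # (n_rows, N)
        logw = np.sum(np.log(scenario.probs[np.arange(grid.n_enzymes)[None, :], idx]), axis=1)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        rows = rng_seed.choice(len(land), size=n, replace=True, p=w)
        designs = X_land[rows]
        y_clean = y_land[rows]
    else:
        designs = sample_designs(scenario, grid, n, seed)
        lookup = {tuple(x): y for x, y in zip(X_land, y_land)}
        try:
            y_clean = np.array([lookup[tuple(d)] for d in designs])
        except KeyError as exc:
            raise ConfigurationError(
                "sampled design missing from the landscape; simulate the full "
                "grid or pass restrict_to_landscape=True"
            ) from exc
    y = add_noise(y_clean, noise, seed + 1)
    return TrainingSet(
        designs=designs, y=y, y_clean=y_clean, scenario=scenario.name, seed=seed
    )
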