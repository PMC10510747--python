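"""Model-free design recommendation via a threshold sweep and AUC normalization.

Given predicted fluxes for the full design space, a threshold lambda* is
swept from 0 to the maximum prediction. At each threshold only designs
predicted at or above it survive, and the frequency of each enzyme level
among survivors is recorded, normalized by the survivor count. At
lambda* = 0 every level's frequency is exactly 1/P. The area under each
level's frequency-versus-threshold curve, normalized per enzyme, yields a
probability distribution over levels for each enzyme — the sampling
distribution for the next DBTL cycle. The algorithm consumes only the
prediction table; which model produced it is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dbtlsim.design_space import DesignGrid
from dbtlsim.kinetics import ConfigurationError
from dbtlsim.scenarios import SamplingScenario, sample_designs

__all__ = [
    "ThresholdCurve",
    "RecommendationDistribution",
    "threshold_sweep",
    "curve_to_distribution",
    "recommend_designs",
]


@dataclass(frozen=True)
class ThresholdCurve:
    """Per-enzyme, per-level survivor frequencies along the threshold grid."""

    thresholds: np.ndarray  # ascending, shape (T,)
    frequencies: np.ndarray  # shape (T, N, P); rows sum to 1 over levels
    n_survivors: np.ndarray  # shape (T,), all >= 1
    grid: DesignGrid


@dataclass(frozen=True)
class RecommendationDistribution:
    """AUC-normalized per-enzyme probability vectors over the P levels."""

    probs: np.ndarray  # shape (N, P)
    grid: DesignGrid

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("each enzyme's probabilities must sum to 1")

    def as_scenario(self) -> SamplingScenario:
        return SamplingScenario("recommended", self.probs)


def threshold_sweep(
    predictions: np.ndarray,
    designs: np.ndarray,
    grid: DesignGrid,
    n_eval: int = 100,
) -> ThresholdCurve:
    """Survivor-frequency curves over a uniform threshold grid in [0, y_max].

    Negative predictions are clipped to 0 before the sweep. Past the last
    threshold with surviving designs the curve is truncated, never
    extrapolated. Survivor counts are computed exactly via a descending sort
    and cumulative level counts.
    """
    y = np.clip(np.asarray(predictions, dtype=float), 0.0, None)
    X = np.asarray(designs, dtype=float)
    if len(y) != len(X):
        raise ConfigurationError("predictions and designs must align")
    if n_eval < 2:
        raise ValueError("n_eval must be >= 2")
    if np.all(y <= 0):
        raise ValueError("all predictions are <= 0: degenerate landscape")
    N, P = grid.n_enzymes, grid.n_levels
    lvl = grid.level_index(X)  # (n, N) ints
    order = np.argsort(-y, kind="stable")
    y_sorted = y[order]
    lvl_sorted = lvl[order]
    # cumulative per-enzyme level counts over the sorted prefix
    onehot = np.zeros((len(y), N, P), dtype=np.int32)
    onehot[np.arange(len(y))[:, None], np.arange(N)[None, :], lvl_sorted] = 1
    cum = np.cumsum(onehot, axis=0)
    y_max = float(y_sorted[0])
    thresholds = np.linspace(0.0, y_max, n_eval)
    freqs = []
    counts = []
    kept = []
    for lam in thresholds:
        # survivors: y >= lam on the descending sort -> prefix length
        n_surv = int(np.searchsorted(-y_sorted, -lam, side="right"))
        if n_surv == 0:
            break
        kept.append(lam)
        counts.append(n_surv)
        freqs.append(cum[n_surv - 1] / n_surv)
    return ThresholdCurve(
        thresholds=np.asarray(kept),
        frequencies=np.asarray(freqs),
        n_survivors=np.asarray(counts),
        grid=grid,
    )


def curve_to_distribution(curve: ThresholdCurve) -> RecommendationDistribution:
    """Trapezoidal AUC of each level's frequency curve, normalized per enzyme."""
    if len(curve.thresholds) == 0:
        raise ValueError("empty threshold curve")
    if len(curve.thresholds) == 1:
        # degenerate single-point curve: use the frequencies directly
        auc = curve.frequencies[0]
    else:
        auc = np.trapezoid(curve.frequencies, x=curve.thresholds, axis=0)
    totals = auc.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero total area under the curve; cannot normalize")
    return RecommendationDistribution(probs=auc / totals, grid=curve.grid)


def recommend_designs(
    dist: RecommendationDistribution, n: int, seed: int
) -> np.ndarray:
    """Sample n designs, each enzyme level independently from its distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sample_designs(dist.as_scenario(), dist.grid, n, seed)
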