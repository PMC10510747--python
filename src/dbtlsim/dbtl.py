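"""Multi-cycle DBTL experiments and strategy comparison.

Each experiment runs a fixed strain budget split over cycles. Cycle 1 samples
designs from the equal scenario; every later cycle samples its budget from
the recommendation distribution derived from the previous cycle's model
predictions. The model is retrained each cycle on all measurements collected
so far (duplicates retained — their noisy measurements differ). Per-cycle
metrics are computed against the noiseless landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dbtlsim.design_space import DesignGrid
from dbtlsim.kinetics import ConfigurationError
from dbtlsim.learn import ModelSpec, _stable_key, fit_model, score_r2, score_top100
from dbtlsim.recommend import curve_to_distribution, recommend_designs, threshold_sweep
from dbtlsim.scenarios import NoiseModel, add_noise, make_scenario, sample_designs

__all__ = [
    "DBTLStrategy",
    "CycleReport",
    "default_strategies",
    "run_dbtl",
    "compare_strategies",
]


@dataclass(frozen=True)
class DBTLStrategy:
    """Per-cycle strain budgets summing to the total build budget."""

    budgets: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.budgets or any(b < 1 for b in self.budgets):
            raise ConfigurationError("budgets must be positive counts")
        if not self.name:
            object.__setattr__(self, "name", str(self.budgets))

    @property
    def total(self) -> int:
        return sum(self.budgets)


def default_strategies() -> list[DBTLStrategy]:
    """The three shipped 250-strain strategies: constant, front- and back-loaded."""
    return [
        DBTLStrategy((50, 50, 50, 50, 50), "constant"),
        DBTLStrategy((150, 50, 25, 25), "front_loaded"),
        DBTLStrategy((25, 25, 50, 150), "back_loaded"),
    ]


@dataclass
class CycleReport:
    cycle: int  # 1-based
    n_cumulative: int
    r2: float
    topk: int
    distribution: np.ndarray | None  # recommendation produced for the next cycle
    seed: int


def _lookup_fluxes(
    landscape: pd.DataFrame, grid: DesignGrid, designs: np.ndarray
) -> np.ndarray:
    X = landscape[list(grid.enzymes)].to_numpy()
    lookup = {tuple(x): y for x, y in zip(X, landscape["relative_flux"].to_numpy())}
    try:
        return np.array([lookup[tuple(d)] for d in designs])
    except KeyError as exc:
        raise ConfigurationError(
            "sampled design missing from the landscape; the landscape must "
            "cover the full grid"
        ) from exc


def run_dbtl(
    strategy: DBTLStrategy,
    model: ModelSpec,
    landscape: pd.DataFrame,
    grid: DesignGrid,
    noise: NoiseModel = NoiseModel("homoscedastic", 0.15),
    repeats: int = 30,
    seed: int = 0,
    k: int = 100,
    n_eval: int = 100,
) -> list[list[CycleReport]]:
    """Run a multi-cycle DBTL experiment ``repeats`` times.

    Returns one list of per-cycle reports per repeat. The whole experiment is
    a pure function of (arguments, seed): the master seed spawns per-repeat
    seeds, which spawn per-cycle seeds.
    """
    if strategy.budgets[0] < 10:
        raise ConfigurationError(
            "cycle-1 budget must be >= 10 designs (the model-fitting minimum)"
        )
    land = landscape[landscape["converged"]].reset_index(drop=True)
    X_eval = land[list(grid.enzymes)].to_numpy()
    y_true = land["relative_flux"].to_numpy()
    k = min(k, len(y_true))
    equal = make_scenario("equal", grid)
    repeat_seqs = np.random.SeedSequence((seed, _stable_key("dbtl", strategy.name))).spawn(
        repeats
    )
    all_reports: list[list[CycleReport]] = []
    for rep_seq in repeat_seqs:
        cycle_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in rep_seq.spawn(len(strategy.budgets))
        ]
        X_train = np.empty((0, grid.n_enzymes))
        y_train = np.empty(0)
        dist = None
        reports: list[CycleReport] = []
        for ci, (budget, cs) in enumerate(zip(strategy.budgets, cycle_seeds)):
            if dist is None:
                new = sample_designs(equal, grid, budget, cs)
            else:
                new = recommend_designs(dist, budget, cs)
            y_clean = _lookup_fluxes(land, grid, new)
            y_meas = add_noise(y_clean, noise, cs + 1)
            X_train = np.vstack([X_train, new])
            y_train = np.concatenate([y_train, y_meas])
            est = fit_model(model, (X_train, y_train), cs)
            pred = est.predict(X_eval)
            flagged = np.ptp(pred) == 0
            r2 = 0.0 if flagged else score_r2(pred, y_true)
            topk = score_top100(pred, y_true, k=k)
            curve = threshold_sweep(pred, X_eval, grid, n_eval=n_eval)
            dist = curve_to_distribution(curve)
            reports.append(
                CycleReport(
                    cycle=ci + 1,
                    n_cumulative=len(y_train),
                    r2=r2,
                    topk=topk,
                    distribution=dist.probs.copy(),
                    seed=cs,
                )
            )
        all_reports.append(reports)
    return all_reports


def reports_to_frame(all_reports: list[list[CycleReport]], strategy: DBTLStrategy) -> pd.DataFrame:
    rows = [
        (strategy.name, rep, r.cycle, r.n_cumulative, r.r2, r.topk)
        for rep, reports in enumerate(all_reports)
        for r in reports
    ]
    return pd.DataFrame(
        rows, columns=["strategy", "repeat", "cycle", "n_cumulative", "r2", "topk"]
    )


def _permutation_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int, seed: int) -> float:
    """Two-sided permutation test on the difference of means."""
    rng = np.random.default_rng(seed)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[: len(a)].mean() - perm[len(a):].mean())
        if d >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def compare_strategies(
    strategies: list[DBTLStrategy],
    model: ModelSpec,
    landscape: pd.DataFrame,
    grid: DesignGrid,
    noise: NoiseModel = NoiseModel("homoscedastic", 0.15),
    repeats: int = 30,
    seed: int = 0,
    k: int = 100,
    n_perm: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strategy, per-cycle metric table plus final-cycle pairwise tests.

    Strategies should share the same total budget for a fair comparison;
    unequal budgets are flagged with a warning but still compared. Pairwise
    differences of final-cycle metrics are assessed with a two-sided
    permutation test on the repeat-level values.

    With ``repeats = 0`` both tables are returned empty with their schema.
    """
    totals = {s.total for s in strategies}
    unequal = len(totals) > 1
    if unequal:
        warnings.warn(f"strategies have unequal total budgets: {sorted(totals)}")
    per_cycle_cols = [
        "strategy", "cycle", "n_cumulative", "r2_mean", "r2_sd", "topk_mean",
        "topk_sd", "unequal_budgets",
    ]
    pair_cols = ["strategy_a", "strategy_b", "metric", "p_value"]
    if repeats == 0:
        return pd.DataFrame(columns=per_cycle_cols), pd.DataFrame(columns=pair_cols)
    frames = {}
    for strat in strategies:
        reports = run_dbtl(
            strat, model, landscape, grid, noise=noise, repeats=repeats, seed=seed, k=k
        )
        frames[strat.name] = reports_to_frame(reports, strat)
    rows = []
    for name, df in frames.items():
        g = df.groupby("cycle")
        for cycle, sub in g:
            rows.append(
                (
                    name, cycle, int(sub["n_cumulative"].iloc[0]),
                    sub["r2"].mean(), sub["r2"].std(),
                    sub["topk"].mean(), sub["topk"].std(), unequal,
                )
            )
    per_cycle = pd.DataFrame(rows, columns=per_cycle_cols)
    pair_rows = []
    names = [s.name for s in strategies]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a_df, b_df = frames[names[i]], frames[names[j]]
            for metric in ("r2", "topk"):
                a = a_df[a_df["cycle"] == a_df["cycle"].max()][metric].to_numpy()
                b = b_df[b_df["cycle"] == b_df["cycle"].max()][metric].to_numpy()
                p = _permutation_pvalue(
                    a.astype(float), b.astype(float), n_perm,
                    _stable_key(names[i], names[j], metric) % (2**31),
                )
                pair_rows.append((names[i], names[j], metric, p))
    return per_cycle, pd.DataFrame(pair_rows, columns=pair_cols)
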