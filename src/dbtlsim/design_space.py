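"""Combinatorial enzyme-level design space.

A design assigns each of the N engineered enzymes one of P discrete relative
expression levels (fold-changes w.r.t. the initial strain, level 1.0 = wild
type). The full space has P^N designs; its simulated relative product fluxes
form the ground-truth landscape used for training and evaluating models.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dbtlsim.kinetics import (
    ConfigurationError,
    KineticParameterSet,
    simulate_steady_state,
)

DEFAULT_LEVELS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0)

__all__ = [
    "DesignGrid",
    "default_grid",
    "enumerate_designs",
    "encode_design",
    "design_to_index",
    "index_to_design",
    "simulate_landscape",
    "DEFAULT_LEVELS",
]


@dataclass(frozen=True)
class DesignGrid:
    """Ordered enzyme names and the ascending level grid shared by all enzymes."""

    enzymes: tuple[str, ...]
    levels: tuple[float, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ConfigurationError("grid needs at least one enzyme")
        if any(l <= 0 for l in self.levels):
            raise ConfigurationError("all levels must be strictly positive")
        if list(self.levels) != sorted(self.levels):
            raise ConfigurationError("levels must be ascending")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError("levels must be distinct")
        if 1.0 not in self.levels:
            raise ConfigurationError("the wild-type level 1.0 must be on the grid")

    @property
    def n_enzymes(self) -> int:
        return len(self.enzymes)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def size(self) -> int:
        return self.n_levels**self.n_enzymes

    def level_index(self, designs: np.ndarray) -> np.ndarray:
        """Map level values to their grid indices (vectorized, exact match)."""
        lv = np.asarray(self.levels)
        idx = np.searchsorted(lv, designs)
        idx = np.clip(idx, 0, len(lv) - 1)
        if not np.allclose(lv[idx], designs, rtol=0, atol=0):
            raise ConfigurationError("design contains levels not on the grid")
        return idx


def default_grid(spec=None, levels: Sequence[float] = DEFAULT_LEVELS) -> DesignGrid:
    """Grid over all pathway enzymes: P = 6 log2-spaced levels by default."""
    if spec is None:
        from dbtlsim.kinetics import default_pathway

        spec = default_pathway()
    return DesignGrid(enzymes=spec.reaction_names, levels=tuple(levels))


def enumerate_designs(grid: DesignGrid, cap: int = 300_000) -> np.ndarray:
    """All P^N designs in lexicographic order over (enzyme index, level index).

    The first enzyme varies slowest. Refuses to materialize spaces larger
    than ``cap`` designs.
    """
    if grid.size > cap:
        raise ConfigurationError(
            f"design space has {grid.size} designs, above the cap of {cap}; "
            "raise the cap explicitly to enumerate it"
        )
    mesh = np.meshgrid(*([np.asarray(grid.levels)] * grid.n_enzymes), indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def index_to_design(grid: DesignGrid, index: int) -> np.ndarray:
    """Design at a given position of the lexicographic enumeration."""
    if not 0 <= index < grid.size:
        raise IndexError(f"index {index} outside [0, {grid.size})")
    P = grid.n_levels
    digits = []
    for _ in range(grid.n_enzymes):
        digits.append(index % P)
        index //= P
    return np.asarray(grid.levels)[np.array(digits[::-1])]


def design_to_index(grid: DesignGrid, design: np.ndarray) -> int:
    """Inverse of :func:`index_to_design`."""
    idx = grid.level_index(np.asarray(design, dtype=float))
    P = grid.n_levels
    out = 0
    for d in idx:
        out = out * P + int(d)
    return out


def encode_design(
    grid: DesignGrid, up_down: Mapping[str, float] | None = None
) -> np.ndarray:
    """Encode a set of fold-changes as a design vector.

    Enzymes not named in ``up_down`` stay at the wild-type level 1.0; e.g.
    a twofold upregulation of the second enzyme and a twofold downregulation
    of the fourth yields (1, 2, 1, 0.5, 1, ..., 1).
    """
    vec = np.ones(grid.n_enzymes)
    if up_down:
        unknown = set(up_down) - set(grid.enzymes)
        if unknown:
            raise ConfigurationError(f"unknown enzymes: {sorted(unknown)}")
        for name, fold in up_down.items():
            if fold not in grid.levels:
                raise ConfigurationError(
                    f"fold-change {fold} for {name!r} is not on the grid; "
                    f"allowed levels: {grid.levels}"
                )
            vec[grid.enzymes.index(name)] = fold
    return vec


def _landscape_key(params: KineticParameterSet, grid: DesignGrid, designs: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(params.to_frame().to_csv(index=False).encode())
    h.update(repr((grid.enzymes, grid.levels)).encode())
    h.update(np.ascontiguousarray(designs).tobytes())
    return h.hexdigest()


def simulate_landscape(
    params: KineticParameterSet,
    grid: DesignGrid,
    designs: np.ndarray | None = None,
    cache: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate the relative product flux of every design.

    Returns a table with one enzyme column per grid enzyme plus
    ``relative_flux`` (terminal-reaction steady-state flux divided by the
    simulated wild-type flux; the wild-type row is exactly 1) and
    ``converged``. Non-converged rows are flagged so downstream training can
    exclude them.

    If ``cache`` names a file, results are persisted there and reloaded on a
    later call with identical parameters and designs; a corrupt or mismatched
    cache triggers a recompute.
    """
    if designs is None:
        designs = enumerate_designs(grid)
    designs = np.asarray(designs, dtype=float)
    if designs.ndim != 2 or designs.shape[1] != grid.n_enzymes:
        raise ConfigurationError("designs must be a (n, N) array matching the grid")
    if designs.shape[0] == 0:
        raise ConfigurationError("designs must be non-empty")
    key = _landscape_key(params, grid, designs)
    if cache is not None:
        try:
            with open(cache) as fh:
                first = fh.readline().strip()
                if not first.startswith("# landscape "):
                    raise ValueError("missing landscape header")
                if first == f"# landscape {key}":
                    df = pd.read_csv(fh)
                    if len(df) != len(designs):
                        raise ValueError("cached row count mismatch")
                    return df
                # stale cache (different inputs): recompute silently
        except FileNotFoundError:
            pass
        except Exception:
            import warnings

            warnings.warn(f"landscape cache {cache!r} is corrupt; recomputing")

    product = params.spec.reaction_names[-1]
    wt = simulate_steady_state(params)
    j_wt = wt.fluxes[product]
    rel = np.empty(len(designs))
    conv = np.empty(len(designs), dtype=bool)
    iterator = enumerate(designs)
    if progress:
        from tqdm import tqdm

        iterator = enumerate(tqdm(designs, desc="landscape"))
    enzyme_levels = dict.fromkeys(params.spec.reaction_names, 1.0)
    for i, d in iterator:
        if np.all(d == 1.0):
            rel[i], conv[i] = 1.0, True  # wild type normalizes to itself
            continue
        enzyme_levels = {e: float(v) for e, v in zip(grid.enzymes, d)}
        res = simulate_steady_state(params, enzyme_levels)
        rel[i] = res.fluxes[product] / j_wt
        conv[i] = res.converged
    df = pd.DataFrame(designs, columns=list(grid.enzymes))
    df["relative_flux"] = rel
    df["converged"] = conv
    if cache is not None:
        with open(cache, "w") as fh:
            fh.write(f"# landscape {key}\n")
            df.to_csv(fh, index=False)
    return df
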