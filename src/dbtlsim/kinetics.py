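"""Kinetic ODE model of the synthetic pathway.

The pathway is a standalone ODE system: host metabolites (pep, e4p, pi,
cofactors) and the product sink G are fixed boundary concentrations, the
pathway intermediates A--F carry ODEs. Enzyme-level engineering enters the
model exclusively through a multiplicative scaling of each reaction's Vmax
(Vmax = kcat * [E], so a relative change in enzyme concentration scales Vmax
proportionally).

Kinetic parameters are not taken from any database; they are generated by a
thermodynamically consistent sampler: equilibrium constants follow from the
reaction standard Gibbs energies (Keq = exp(-dG0/RT)), reference
concentrations and Km values are sampled within configured bounds, Vmax
values are back-calculated so that the reference state is an exact steady
state of the chain, and candidate sets are rejected unless that steady state
is locally asymptotically stable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

R_GAS = 8.314  # J/(mol K)

MECHANISMS = ("IrrevMM", "RevMM", "GenRevHill")

__all__ = [
    "PathwaySpec",
    "Reaction",
    "ReactionKinetics",
    "KineticParameterSet",
    "SteadyStateResult",
    "BioprocessState",
    "ConfigurationError",
    "GenerationError",
    "default_pathway",
    "load_pathway",
    "rate",
    "generate_parameters",
    "simulate_steady_state",
    "solve_steady_state_root",
    "simulate_batch",
]


class ConfigurationError(ValueError):
    """Invalid pathway/mechanism configuration."""


class GenerationError(RuntimeError):
    """No stable parameter set found within the attempt budget."""


@dataclass(frozen=True)
class Reaction:
    name: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    mechanism: str
    dG_kJ_mol: float

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"unknown mechanism {self.mechanism!r} for reaction {self.name!r}; "
                f"expected one of {MECHANISMS}"
            )

    @property
    def reversible(self) -> bool:
        return self.mechanism in ("RevMM", "GenRevHill")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.substrates) + tuple(s for s, _ in self.products)


@dataclass(frozen=True)
class PathwaySpec:
    """Ground-truth pathway definition: stoichiometry, mechanisms, dG."""

    reactions: tuple[Reaction, ...]
    boundary: dict[str, float]  # fixed concentrations, mM
    dynamic: tuple[str, ...]  # species with ODEs
    temperature_K: float = 298.15
    km_bounds: tuple[float, float] = (1e-3, 1.0)
    conc_bounds: tuple[float, float] = (1e-2, 1.0)
    dilution_per_h: float = 0.1  # growth dilution of intermediates, 1/h
    name: str = "pathway"

    def __post_init__(self) -> None:
        known = set(self.boundary) | set(self.dynamic)
        for rxn in self.reactions:
            missing = set(rxn.species) - known
            if missing:
                raise ConfigurationError(
                    f"reaction {rxn.name!r} references unknown species {sorted(missing)}"
                )
        if set(self.boundary) & set(self.dynamic):
            raise ConfigurationError("a species cannot be both boundary and dynamic")

    @property
    def reaction_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.reactions)

    def keq(self, reaction: Reaction) -> float:
        """Equilibrium constant from the standard Gibbs energy, Keq = exp(-dG0/RT)."""
        return float(np.exp(-reaction.dG_kJ_mol * 1e3 / (R_GAS * self.temperature_K)))

    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix restricted to dynamic species (n_dyn x n_rxn)."""
        idx = {s: i for i, s in enumerate(self.dynamic)}
        S = np.zeros((len(self.dynamic), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s, coef in rxn.substrates:
                if s in idx:
                    S[idx[s], j] -= coef
            for s, coef in rxn.products:
                if s in idx:
                    S[idx[s], j] += coef
        return S


def load_pathway(path) -> PathwaySpec:
    """Read a pathway definition from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _pathway_from_dict(raw)


def _pathway_from_dict(raw: dict) -> PathwaySpec:
    reactions = tuple(
        Reaction(
            name=r["name"],
            substrates=tuple(r["substrates"].items()),
            products=tuple(r["products"].items()),
            mechanism=r["mechanism"],
            dG_kJ_mol=float(r["dG_kJ_mol"]),
        )
        for r in raw["reactions"]
    )
    bounds = raw.get("bounds", {})
    return PathwaySpec(
        reactions=reactions,
        boundary={k: float(v) for k, v in raw["boundary"].items()},
        dynamic=tuple(raw["dynamic"]),
        temperature_K=float(raw.get("temperature_K", 298.15)),
        km_bounds=tuple(bounds.get("km_mM", (1e-3, 1.0))),
        conc_bounds=tuple(bounds.get("conc_mM", (1e-2, 1.0))),
        dilution_per_h=float(raw.get("dilution_per_h", 0.1)),
        name=raw.get("name", "pathway"),
    )


def default_pathway() -> PathwaySpec:
    """The seven-reaction synthetic pathway shipped with the package."""
    ref = importlib.resources.files("dbtlsim.data") / "pathway.yaml"
    return _pathway_from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionKinetics:
    """Kinetic parameters of a single reaction."""

    reaction: Reaction
    vmax: float  # mM/h at wild-type enzyme level
    km: dict[str, float]  # mM, per species that saturates the enzyme
    keq: float | None = None  # dimensionless, reversible mechanisms only
    hill: float = 1.0  # GenRevHill only


def _mass_action_ratio(rxn: Reaction, conc: Mapping[str, float]) -> float:
    num = 1.0
    den = 1.0
    for s, coef in rxn.products:
        num *= conc[s] ** coef
    for s, coef in rxn.substrates:
        den *= conc[s] ** coef
    return num / den


def rate(
    mechanism: str,
    concentrations: Mapping[str, float],
    params: ReactionKinetics,
    level: float = 1.0,
) -> float:
    """Reaction rate under the given mechanism at the given state.

    ``level`` is the relative enzyme level; the effective Vmax is
    ``level * params.vmax`` (enzyme concentration scales Vmax proportionally).
    Reversible mechanisms vanish at thermodynamic equilibrium (Gamma = Keq).
    """
    if mechanism not in MECHANISMS:
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    if level <= 0:
        raise ValueError("enzyme level must be strictly positive")
    rxn = params.reaction
    for s in rxn.species:
        if concentrations[s] < 0:
            raise ValueError(f"negative concentration for species {s!r}")
    vmax = level * params.vmax
    if mechanism == "IrrevMM":
        sat = 1.0
        for s, coef in rxn.substrates:
            c = concentrations[s]
            sat *= (c / (params.km[s] + c)) ** coef
        return vmax * sat
    if mechanism == "RevMM":
        (s_name, _), = rxn.substrates
        (p_name, _), = rxn.products
        s, p = concentrations[s_name], concentrations[p_name]
        km_s, km_p = params.km[s_name], params.km[p_name]
        return vmax * (s - p / params.keq) / (km_s * (1.0 + s / km_s + p / km_p))
    # GenRevHill: saturating Hill terms per substrate times a thermodynamic
    # driving factor (1 - Gamma/Keq) that sets the sign of the net flux.
    h = params.hill
    sat = 1.0
    for s, coef in rxn.substrates:
        c = concentrations[s]
        if c == 0.0:
            return 0.0
        sat *= (c**h / (params.km[s] ** h + c**h)) ** coef
    gamma = _mass_action_ratio(rxn, concentrations)
    return vmax * sat * (1.0 - gamma / params.keq)


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameterSet:
    """Per-reaction kinetics plus the reference (wild-type) steady state."""

    spec: PathwaySpec
    kinetics: tuple[ReactionKinetics, ...]  # aligned with spec.reactions
    ref_conc: dict[str, float]  # dynamic species, mM
    ref_flux: float  # steady-state chain flux, mM/h
    seed: int | None = None

    def __getitem__(self, reaction_name: str) -> ReactionKinetics:
        for k in self.kinetics:
            if k.reaction.name == reaction_name:
                return k
        raise KeyError(reaction_name)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form (reaction, name, value, units), one row per parameter."""
        rows = []
        for k in self.kinetics:
            rows.append((k.reaction.name, "vmax", k.vmax, "mM/h"))
            for s, v in k.km.items():
                rows.append((k.reaction.name, f"km_{s}", v, "mM"))
            if k.keq is not None:
                rows.append((k.reaction.name, "keq", k.keq, "1"))
            if k.reaction.mechanism == "GenRevHill":
                rows.append((k.reaction.name, "hill", k.hill, "1"))
        for s, c in self.ref_conc.items():
            rows.append(("_reference", f"conc_{s}", c, "mM"))
        rows.append(("_reference", "flux", self.ref_flux, "mM/h"))
        if self.seed is not None:
            rows.append(("_reference", "seed", float(self.seed), "1"))
        return pd.DataFrame(rows, columns=["reaction", "name", "value", "units"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, spec: PathwaySpec, path) -> "KineticParameterSet":
        df = pd.read_csv(path)
        by_rxn = {name: dict(zip(g["name"], g["value"])) for name, g in df.groupby("reaction")}
        kinetics = []
        for rxn in spec.reactions:
            p = by_rxn[rxn.name]
            km = {k[3:]: v for k, v in p.items() if k.startswith("km_")}
            kinetics.append(
                ReactionKinetics(
                    reaction=rxn,
                    vmax=p["vmax"],
                    km=km,
                    keq=p.get("keq"),
                    hill=p.get("hill", 1.0),
                )
            )
        ref = by_rxn["_reference"]
        ref_conc = {k[5:]: v for k, v in ref.items() if k.startswith("conc_")}
        seed = int(ref["seed"]) if "seed" in ref else None
        return cls(
            spec=spec,
            kinetics=tuple(kinetics),
            ref_conc=ref_conc,
            ref_flux=ref["flux"],
            seed=seed,
        )


@_njit(cache=False)
def _rates_core(
    y, levels, c, n_dyn, mech, sub_ptr, sub_idx, km_sub, prod_ptr, prod_idx, km_prod,
    keq, hill, vmax, out,
):
    for i in range(n_dyn):
        c[i] = y[i] if y[i] > 0.0 else 0.0
    for j in range(mech.shape[0]):
        v = levels[j] * vmax[j]
        if mech[j] == 0:  # irreversible Michaelis-Menten
            sat = 1.0
            for t in range(sub_ptr[j], sub_ptr[j + 1]):
                cc = c[sub_idx[t]]
                sat *= cc / (km_sub[t] + cc)
            out[j] = v * sat
        elif mech[j] == 1:  # reversible Michaelis-Menten (uni-uni)
            t = sub_ptr[j]
            s = c[sub_idx[t]]
            p = c[prod_idx[prod_ptr[j]]]
            ks = km_sub[t]
            out[j] = v * (s - p / keq[j]) / (ks * (1.0 + s / ks + p / km_prod[j]))
        else:  # generalized reversible Hill
            sat = 1.0
            den = 1.0
            h = hill[j]
            for t in range(sub_ptr[j], sub_ptr[j + 1]):
                cc = c[sub_idx[t]]
                sat *= cc**h / (km_sub[t] ** h + cc**h)
                den *= cc
            if den == 0.0:
                out[j] = 0.0
            else:
                num = 1.0
                for t in range(prod_ptr[j], prod_ptr[j + 1]):
                    num *= c[prod_idx[t]]
                out[j] = v * sat * (1.0 - num / (den * keq[j]))


@_njit(cache=False)
def _rhs_core(y, rates_, S, mu, dy):
    for i in range(S.shape[0]):
        acc = 0.0
        for j in range(S.shape[1]):
            acc += S[i, j] * rates_[j]
        dy[i] = acc - mu * y[i]


class _CompiledModel:
    """Array-packed RHS of the pathway ODE system for one parameter set.

    State vector = dynamic species concentrations; boundary species are
    constants folded into the full concentration vector. The inner loops are
    numba-compiled when numba is importable.
    """

    def __init__(self, params: KineticParameterSet):
        spec = params.spec
        self.spec = spec
        self.params = params
        self.species = tuple(spec.dynamic) + tuple(spec.boundary)
        self.n_dyn = len(spec.dynamic)
        idx = {s: i for i, s in enumerate(self.species)}
        self._c = np.empty(len(self.species))
        for s, v in spec.boundary.items():
            self._c[idx[s]] = v
        self.S = spec.stoichiometry()
        mech_code = {"IrrevMM": 0, "RevMM": 1, "GenRevHill": 2}
        n = len(params.kinetics)
        self.mech = np.array([mech_code[k.reaction.mechanism] for k in params.kinetics])
        sub_idx, km_sub, prod_idx = [], [], []
        sub_ptr, prod_ptr = [0], [0]
        self.km_prod = np.zeros(n)
        self.keq = np.ones(n)
        self.hill = np.array([k.hill for k in params.kinetics])
        self.vmax = np.array([k.vmax for k in params.kinetics])
        for j, k in enumerate(params.kinetics):
            rxn = k.reaction
            for s, _ in rxn.substrates:
                sub_idx.append(idx[s])
                km_sub.append(k.km[s])
            for s, _ in rxn.products:
                prod_idx.append(idx[s])
            sub_ptr.append(len(sub_idx))
            prod_ptr.append(len(prod_idx))
            if k.keq is not None:
                self.keq[j] = k.keq
            if rxn.mechanism == "RevMM":
                self.km_prod[j] = k.km[rxn.products[0][0]]
        self.sub_idx = np.array(sub_idx, dtype=np.int64)
        self.km_sub = np.array(km_sub)
        self.prod_idx = np.array(prod_idx, dtype=np.int64)
        self.sub_ptr = np.array(sub_ptr, dtype=np.int64)
        self.prod_ptr = np.array(prod_ptr, dtype=np.int64)
        self._out = np.empty(n)
        self._dy = np.empty(self.n_dyn)

    def rates(self, y: np.ndarray, levels: np.ndarray) -> np.ndarray:
        _rates_core(
            y, levels, self._c, self.n_dyn, self.mech, self.sub_ptr, self.sub_idx,
            self.km_sub, self.prod_ptr, self.prod_idx, self.km_prod, self.keq,
            self.hill, self.vmax, self._out,
        )
        return self._out.copy()

    def rhs(self, t: float, y: np.ndarray, levels: np.ndarray) -> np.ndarray:
        # growth dilution keeps intermediate pools bounded when a downstream
        # step saturates below the upstream influx
        _rates_core(
            y, levels, self._c, self.n_dyn, self.mech, self.sub_ptr, self.sub_idx,
            self.km_sub, self.prod_ptr, self.prod_idx, self.km_prod, self.keq,
            self.hill, self.vmax, self._out,
        )
        _rhs_core(y, self._out, self.S, self.spec.dilution_per_h, self._dy)
        return self._dy.copy()

    def jacobian(self, y: np.ndarray, levels: np.ndarray, eps: float = 1e-7) -> np.ndarray:
        """Numerical Jacobian of the RHS at state y (central differences)."""
        n = len(y)
        J = np.empty((n, n))
        for i in range(n):
            h = eps * max(abs(y[i]), 1e-3)
            yp, ym = y.copy(), y.copy()
            yp[i] += h
            ym[i] -= h
            J[:, i] = (self.rhs(0.0, yp, levels) - self.rhs(0.0, ym, levels)) / (2 * h)
        return J


def _levels_vector(spec: PathwaySpec, levels) -> np.ndarray:
    """Normalize a levels argument (mapping or sequence) to a per-reaction array."""
    names = spec.reaction_names
    if levels is None:
        return np.ones(len(names))
    if isinstance(levels, Mapping):
        unknown = set(levels) - set(names)
        if unknown:
            raise ConfigurationError(f"unknown reactions in levels: {sorted(unknown)}")
        vec = np.array([float(levels.get(n, 1.0)) for n in names])
    else:
        vec = np.asarray(levels, dtype=float)
        if vec.shape != (len(names),):
            raise ConfigurationError(
                f"levels must have length {len(names)}, got shape {vec.shape}"
            )
    if np.any(vec <= 0):
        raise ValueError("all enzyme levels must be strictly positive")
    return vec


def generate_parameters(
    spec: PathwaySpec,
    seed: int,
    constraints: Mapping[str, tuple[float, float]] | None = None,
    max_attempts: int = 500,
    flux_sd: float = 0.2,
    driving_margin: float = 0.8,
) -> KineticParameterSet:
    """Sample a thermodynamically consistent, stable kinetic parameter set.

    Procedure per attempt: sample reference concentrations (log-uniform within
    bounds) and Km values (log-uniform within bounds); reject states where any
    reversible reaction is at or beyond ``driving_margin`` of equilibrium
    (Gamma/Keq >= margin would force the back-calculated Vmax towards
    infinity); sample the terminal product flux from a lognormal around
    1 mM/h; solve the steady-state flux balance S J = mu c_ref (dilution
    included) for the per-reaction reference fluxes, anchored at the sampled
    product flux; back-calculate each Vmax so the reference state is an exact
    steady state; accept only if all Jacobian eigenvalues have negative real
    parts.

    Identical (spec, seed) yields a bitwise-identical set.
    """
    rng = np.random.default_rng(seed)
    km_lo, km_hi = constraints.get("km_mM", spec.km_bounds) if constraints else spec.km_bounds
    c_lo, c_hi = (
        constraints.get("conc_mM", spec.conc_bounds) if constraints else spec.conc_bounds
    )
    for attempt in range(1, max_attempts + 1):
        conc = {
            s: float(np.exp(rng.uniform(np.log(c_lo), np.log(c_hi))))
            for s in spec.dynamic
        }
        full = dict(spec.boundary, **conc)
        # thermodynamic feasibility: every reversible reaction must run forward
        # with some driving force left at the reference state
        ok = True
        for rxn in spec.reactions:
            if rxn.reversible:
                gamma = _mass_action_ratio(rxn, full)
                if gamma / spec.keq(rxn) >= driving_margin:
                    ok = False
                    break
        if not ok:
            continue
        j_ref = float(np.exp(rng.normal(0.0, flux_sd)))
        # steady-state flux balance with dilution: S J = mu c_ref, anchored at
        # the terminal reaction carrying j_ref
        S = spec.stoichiometry()
        mu = spec.dilution_per_h
        c_ref = np.array([conc[s] for s in spec.dynamic])
        anchor = np.zeros(len(spec.reactions))
        anchor[-1] = 1.0
        A = np.vstack([S, anchor])
        b = np.concatenate([mu * c_ref, [j_ref]])
        fluxes, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ fluxes - b)) > 1e-9 * max(1.0, j_ref) or np.any(
            fluxes <= 0
        ):
            continue
        kinetics = []
        for j_rxn, rxn in zip(fluxes, spec.reactions):
            km_species = [s for s, _ in rxn.substrates]
            if rxn.mechanism == "RevMM":
                km_species += [s for s, _ in rxn.products]
            km = {
                s: float(np.exp(rng.uniform(np.log(km_lo), np.log(km_hi))))
                for s in km_species
            }
            keq = spec.keq(rxn) if rxn.reversible else None
            probe = ReactionKinetics(reaction=rxn, vmax=1.0, km=km, keq=keq)
            phi = rate(rxn.mechanism, full, probe, level=1.0)
            if phi <= 0:
                ok = False
                break
            kinetics.append(
                ReactionKinetics(reaction=rxn, vmax=j_rxn / phi, km=km, keq=keq)
            )
        if not ok:
            continue
        candidate = KineticParameterSet(
            spec=spec,
            kinetics=tuple(kinetics),
            ref_conc=conc,
            ref_flux=j_ref,
            seed=seed,
        )
        model = _CompiledModel(candidate)
        y0 = np.array([conc[s] for s in spec.dynamic])
        levels = np.ones(len(spec.reactions))
        eig = np.linalg.eigvals(model.jacobian(y0, levels))
        if np.all(eig.real < 0):
            return candidate
    raise GenerationError(
        f"no stable parameter set found in {max_attempts} attempts for seed {seed}"
    )


# ---------------------------------------------------------------------------
# Steady-state simulation
# ---------------------------------------------------------------------------


@dataclass
class SteadyStateResult:
    concentrations: dict[str, float]  # dynamic species, mM
    fluxes: dict[str, float]  # per reaction, mM/h
    converged: bool
    residual: float  # max |dC/dt| relative to the reference flux scale


def _residual(model: _CompiledModel, y: np.ndarray, levels: np.ndarray) -> float:
    scale = max(model.params.ref_flux, 1e-12)
    return float(np.max(np.abs(model.rhs(0.0, y, levels))) / scale)


def simulate_steady_state(
    params: KineticParameterSet,
    levels=None,
    tol: float = 1e-9,
    horizon: float = 1e5,
) -> SteadyStateResult:
    """Integrate the ODE system from the reference state to steady state.

    The initial value problem starts at the wild-type reference concentrations
    and runs over geometrically growing windows until the residual
    max|dC/dt| / J_ref drops below ``tol`` or the horizon is exhausted.
    Non-convergence is flagged on the result, not raised.
    """
    lv = _levels_vector(params.spec, levels)
    model = _CompiledModel(params)
    y = np.array([params.ref_conc[s] for s in params.spec.dynamic])
    if _residual(model, y, lv) >= tol:
        t = 0.0
        t_end = 500.0
        while t < horizon:
            t_end = min(t_end, horizon)
            sol = solve_ivp(
                model.rhs,
                (t, t_end),
                y,
                args=(lv,),
                method="LSODA",
                rtol=1e-8,
                atol=1e-12,
            )
            if not sol.success:
                raise RuntimeError(f"ODE solver failed: {sol.message}")
            y = np.maximum(sol.y[:, -1], 0.0)
            t = t_end
            if _residual(model, y, lv) < tol:
                break
            t_end *= 10.0
    res = _residual(model, y, lv)
    rates_ = model.rates(y, lv)
    return SteadyStateResult(
        concentrations=dict(zip(params.spec.dynamic, y)),
        fluxes=dict(zip(params.spec.reaction_names, rates_)),
        converged=bool(res < tol),
        residual=res,
    )


def solve_steady_state_root(
    params: KineticParameterSet,
    levels=None,
    tol: float = 1e-12,
) -> SteadyStateResult:
    """Independent steady-state solve: root-finding on dC/dt = 0.

    Solves in log-concentration space (enforcing positivity) with a
    trust-region nonlinear least-squares method driven to zero residual,
    started from the reference state. Serves as the oracle counterpart to
    :func:`simulate_steady_state`.
    """
    lv = _levels_vector(params.spec, levels)
    model = _CompiledModel(params)
    y0 = np.array([params.ref_conc[s] for s in params.spec.dynamic])

    def g(z):
        return model.rhs(0.0, np.exp(z), lv)

    sol = least_squares(
        g, np.log(y0), method="trf", xtol=3e-16, ftol=3e-16, gtol=3e-16
    )
    y = np.exp(sol.x)
    res = _residual(model, y, lv)
    return SteadyStateResult(
        concentrations=dict(zip(params.spec.dynamic, y)),
        fluxes=dict(zip(params.spec.reaction_names, model.rates(y, lv))),
        converged=bool(res < max(tol, 1e-9)),
        residual=res,
    )


# ---------------------------------------------------------------------------
# Batch bioprocess
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BioprocessState:
    time: float  # h
    glucose: float  # g/L
    biomass: float  # g
    product: float  # g/L
    volume: float = 1.0  # L

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.biomass < 0 or self.glucose < 0 or self.product < 0:
            raise ValueError("bioprocess quantities must be non-negative")


DEFAULT_BIOPROCESS = BioprocessState(time=0.0, glucose=10.0, biomass=1.0, product=0.0)


def simulate_batch(
    params: KineticParameterSet,
    levels=None,
    init: BioprocessState = DEFAULT_BIOPROCESS,
    horizon: float = 24.0,
    mu_max: float = 0.4,
    ks: float = 0.05,
    yield_xs: float = 0.5,
    qp_ref: float = 0.05,
    n_points: int = 200,
    burden=None,
) -> pd.DataFrame:
    """Simulate a batch reactor run of a strain carrying the pathway.

    Monod growth on glucose; the specific production rate scales with the
    strain's relative steady-state pathway flux. Growth and production both
    cease when glucose is depleted. ``burden`` is an optional hook mapping the
    levels vector to a multiplicative inhibition factor on growth (default:
    no metabolic burden).

    Returns a trajectory table (time, glucose, biomass, product, volume).
    """
    if init.biomass <= 0:
        raise ValueError("initial biomass must be positive")
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return pd.DataFrame(
            [
                {
                    "time": init.time,
                    "glucose": init.glucose,
                    "biomass": init.biomass,
                    "product": init.product,
                    "volume": init.volume,
                }
            ]
        )
    ss = simulate_steady_state(params, levels)
    wt = simulate_steady_state(params, None)
    rel_flux = ss.fluxes[params.spec.reaction_names[-1]] / wt.fluxes[
        params.spec.reaction_names[-1]
    ]
    inhibition = 1.0 if burden is None else float(burden(_levels_vector(params.spec, levels)))
    vol = init.volume

    def rhs(t, y):
        s, x, p = np.maximum(y, 0.0)
        mu = mu_max * inhibition * s / (ks + s)
        qp = qp_ref * rel_flux * s / (ks + s)
        return [-(mu / yield_xs) * x / vol, mu * x, qp * x / vol]

    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [init.glucose, init.biomass, init.product],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"bioprocess integration failed: {sol.message}")
    y = np.maximum(sol.y, 0.0)
    if np.any(sol.y < -1e-6):
        raise RuntimeError("negative state encountered in bioprocess integration")
    return pd.DataFrame(
        {
            "time": init.time + sol.t,
            "glucose": y[0],
            "biomass": y[1],
            "product": y[2],
            "volume": vol,
        }
    )
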