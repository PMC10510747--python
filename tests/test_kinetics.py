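import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbtlsim import (
    BioprocessState,
    KineticParameterSet,
    default_pathway,
    generate_parameters,
    rate,
    simulate_batch,
    simulate_steady_state,
    solve_steady_state_root,
)
from dbtlsim.kinetics import (
    R_GAS,
    ConfigurationError,
    ReactionKinetics,
    _CompiledModel,
    _mass_action_ratio,
)


class TestPathwaySpec:
    def test_default_matches_shipped_definition(self, spec):
        assert len(spec.reactions) == 7
        assert [r.dG_kJ_mol for r in spec.reactions] == [
            -12.03, -16.12, -8.47, 1.10, -6.40, 0.41, -11.77,
        ]
        assert [r.mechanism for r in spec.reactions] == [
            "IrrevMM", "IrrevMM", "RevMM", "GenRevHill", "GenRevHill",
            "GenRevHill", "IrrevMM",
        ]
        assert set(spec.boundary) == {"pep", "e4p", "pi", "nadph", "nadp", "atp", "adp", "G"}
        assert spec.dynamic == ("A", "B", "C", "D", "E", "F")

    def test_all_reaction_species_are_declared(self, spec):
        known = set(spec.boundary) | set(spec.dynamic)
        for rxn in spec.reactions:
            assert set(rxn.species) <= known

    def test_keq_closed_form(self, spec):
        # reaction A: dG0 = -12.03 kJ/mol at 298.15 K
        rxn = spec.reactions[0]
        assert spec.keq(rxn) == pytest.approx(
            np.exp(12030.0 / (8.314 * 298.15)), rel=1e-12
        )


class TestRateLaws:
    def _kin(self, spec, i, **kw):
        rxn = spec.reactions[i]
        km = {s: 0.1 for s, _ in rxn.substrates}
        km.update({s: 0.1 for s, _ in rxn.products} if rxn.mechanism == "RevMM" else {})
        defaults = dict(reaction=rxn, vmax=2.0, km=km, keq=spec.keq(rxn))
        defaults.update(kw)
        return ReactionKinetics(**defaults)

    def test_no_substrate_no_flux(self, spec):
        kin = self._kin(spec, 1)  # rB: A -> B, IrrevMM
        conc = {"A": 0.0, "B": 0.3}
        assert rate("IrrevMM", conc, kin) == 0.0

    def test_half_saturation_identity(self, spec):
        kin = self._kin(spec, 1)
        conc = {"A": kin.km["A"], "B": 0.0}
        assert rate("IrrevMM", conc, kin, level=1.0) == pytest.approx(kin.vmax / 2)

    def test_reversible_rate_vanishes_at_equilibrium(self, spec):
        kin = self._kin(spec, 2)  # rC: B <-> C, RevMM
        conc = {"B": 0.2, "C": 0.2 * kin.keq}
        assert rate("RevMM", conc, kin) == pytest.approx(0.0, abs=1e-12)
        kin_h = self._kin(spec, 3)  # rD: GenRevHill
        conc = {"C": 0.2, "nadph": 0.1, "D": 0.0, "nadp": 0.3}
        conc["D"] = kin_h.keq * conc["C"] * conc["nadph"] / conc["nadp"]
        assert rate("GenRevHill", conc, kin_h) == pytest.approx(0.0, abs=1e-12)

    def test_level_scales_vmax_proportionally(self, spec):
        kin = self._kin(spec, 0)
        conc = {"pep": 1.0, "e4p": 0.3, "A": 0.1, "pi": 5.0}
        assert rate("IrrevMM", conc, kin, level=2.0) == pytest.approx(
            2.0 * rate("IrrevMM", conc, kin, level=1.0), rel=1e-14
        )

    def test_unknown_mechanism_and_negative_concentration(self, spec):
        kin = self._kin(spec, 1)
        with pytest.raises(ConfigurationError):
            rate("MassAction", {"A": 1.0, "B": 0.0}, kin)
        with pytest.raises(ValueError):
            rate("IrrevMM", {"A": -0.1, "B": 0.0}, kin)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        b=st.floats(1e-4, 10.0),
        c=st.floats(1e-4, 10.0),
    )
    def test_net_flux_sign_matches_thermodynamic_driving_force(self, spec, b, c):
        """Reversible net flux sign equals sign(1 - Gamma/Keq) at any state."""
        kin = self._kin(spec, 2)
        conc = {"B": b, "C": c}
        gamma = _mass_action_ratio(kin.reaction, conc)
        v = rate("RevMM", conc, kin)
        assert np.sign(v) == np.sign(1.0 - gamma / kin.keq)


class TestParameterGeneration:
    def test_keq_honours_gibbs_energies(self, spec, params):
        for kin in params.kinetics:
            if kin.reaction.reversible:
                assert kin.keq == pytest.approx(spec.keq(kin.reaction), rel=1e-6)

    def test_all_parameters_positive(self, params):
        for kin in params.kinetics:
            assert kin.vmax > 0
            assert all(v > 0 for v in kin.km.values())
        assert all(v > 0 for v in params.ref_conc.values())

    def test_reference_state_is_steady(self, params):
        model = _CompiledModel(params)
        y = np.array([params.ref_conc[s] for s in params.spec.dynamic])
        resid = np.abs(model.rhs(0.0, y, np.ones(7)))
        assert np.max(resid) < 1e-9 * params.ref_flux

    def test_reference_state_is_stable(self, params):
        model = _CompiledModel(params)
        y = np.array([params.ref_conc[s] for s in params.spec.dynamic])
        eig = np.linalg.eigvals(model.jacobian(y, np.ones(7)))
        assert np.all(eig.real < 0)

    def test_same_seed_bitwise_identical(self, spec):
        a = generate_parameters(spec, seed=3)
        b = generate_parameters(spec, seed=3)
        assert a.to_frame().equals(b.to_frame())

    def test_roundtrip_serialization(self, spec, params, tmp_path):
        path = tmp_path / "params.csv"
        params.save(path)
        loaded = KineticParameterSet.load(spec, path)
        for k1, k2 in zip(params.kinetics, loaded.kinetics):
            assert k1.vmax == pytest.approx(k2.vmax, rel=1e-12)
            assert k1.km == pytest.approx(k2.km, rel=1e-12)


class TestSteadyState:
    def test_wildtype_flux_equals_reference(self, params, wildtype):
        assert wildtype.converged
        assert wildtype.fluxes["rG"] == pytest.approx(params.ref_flux, rel=1e-9)

    def test_flux_balance_at_steady_state(self, params):
        res = simulate_steady_state(params, {"rA": 2.0, "rG": 0.5})
        assert res.converged
        # production = consumption + dilution for every intermediate
        mu = params.spec.dilution_per_h
        S = params.spec.stoichiometry()
        v = np.array([res.fluxes[r] for r in params.spec.reaction_names])
        c = np.array([res.concentrations[s] for s in params.spec.dynamic])
        assert np.max(np.abs(S @ v - mu * c)) < 1e-8 * params.ref_flux

    def test_ode_and_root_solves_agree(self, params):
        rng = np.random.default_rng(7)
        for _ in range(5):
            lv = dict(zip(params.spec.reaction_names, rng.choice([0.25, 0.5, 1, 2, 4], 7)))
            a = simulate_steady_state(params, lv)
            b = solve_steady_state_root(params, lv)
            assert a.fluxes["rG"] == pytest.approx(b.fluxes["rG"], rel=1e-6)

    def test_local_sweep_monotone_or_unimodal(self, params, wildtype):
        """Single-enzyme perturbations over [0.125, 8] give smooth responses."""
        folds = [0.125, 0.25, 0.5, 1, 2, 4, 8]
        for rn in params.spec.reaction_names:
            rel = np.array(
                [simulate_steady_state(params, {rn: f}).fluxes["rG"] for f in folds]
            ) / wildtype.fluxes["rG"]
            d = np.diff(rel)
            sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-9])) != 0)
            assert sign_changes <= 1, f"{rn} response is neither monotone nor unimodal"

    def test_invalid_levels_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_steady_state(params, {"rA": -1.0})
        with pytest.raises(ConfigurationError):
            simulate_steady_state(params, {"nope": 2.0})


class TestBatchBioprocess:
    def test_zero_horizon_returns_initial_state(self, params):
        traj = simulate_batch(params, horizon=0.0)
        assert len(traj) == 1
        assert traj.iloc[0]["glucose"] == 10.0
        assert traj.iloc[0]["biomass"] == 1.0

    def test_glucose_depletes_and_biomass_grows(self, params):
        traj = simulate_batch(params)
        assert traj["glucose"].iloc[-1] < 0.01 * traj["glucose"].iloc[0]
        assert traj["biomass"].iloc[-1] > traj["biomass"].iloc[0]
        assert np.all(np.diff(traj["glucose"]) <= 1e-9)
        assert np.all(np.diff(traj["product"]) >= -1e-9)

    def test_growth_stops_after_depletion(self, params):
        traj = simulate_batch(params)
        depleted = traj[traj["glucose"] < 1e-4]
        assert len(depleted) > 2
        x = depleted["biomass"].to_numpy()
        assert np.max(np.abs(np.diff(x))) < 1e-4 * x[0]

    def test_invalid_initial_state(self, params):
        with pytest.raises(ValueError):
            BioprocessState(time=0.0, glucose=10.0, biomass=1.0, product=0.0, volume=0.0)
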