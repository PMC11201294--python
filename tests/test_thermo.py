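"""Reaction free energies: standard values, temperature correction,
reaction quotients, and the critical-concentration inversion."""

import math

import numpy as np
import pytest

from syntherm.thermo import (
    P_STANDARD,
    R_KJ,
    T_REF,
    ChemicalState,
    Reaction,
    ThermoError,
    compute_delta_g,
    compute_delta_g_standard,
    compute_reaction_quotient,
    critical_concentration,
    delta_g_standard_at_ph,
    gibbs_helmholtz,
)

T_CULT = 310.15


def _state(pr=None, ac=None, ph2=None, pco2=None, pch4=None, pH=7.0, T=T_CULT):
    solutes = {}
    if pr is not None:
        solutes["propionate"] = pr
    if ac is not None:
        solutes["acetate"] = ac
    gases = {}
    if ph2 is not None:
        gases["H2"] = ph2
    if pco2 is not None:
        gases["CO2"] = pco2
    if pch4 is not None:
        gases["CH4"] = pch4
    return ChemicalState(solute_concentrations=solutes, gas_partial_pressures=gases,
                         pH=pH, temperature=T)


class TestStandardFreeEnergy:
    def test_bundled_reactions_are_balanced(self, reactions, species_table):
        for rxn in reactions.values():
            assert rxn.charge_imbalance(species_table) == pytest.approx(0.0)
            assert rxn.elemental_imbalance() == {}

    def test_empty_stoichiometry_sums_to_zero(self, species_table):
        empty = Reaction(name="null", stoichiometry={})
        assert compute_delta_g_standard(empty, species_table) == (0.0, 0.0)

    def test_missing_species_error_names_species(self, species_table):
        rxn = Reaction(name="bad", stoichiometry={"lactate": -1})
        with pytest.raises(ThermoError, match="lactate"):
            compute_delta_g_standard(rxn, species_table)

    def test_ph7_view_shifts_only_proton_reactions(self, reactions, species_table):
        # propionate oxidation has no H+ term: the pH-7 view equals dG0
        rxn = reactions["propionate_oxidation"]
        dg0, _ = compute_delta_g_standard(rxn, species_table)
        assert delta_g_standard_at_ph(rxn, species_table, pH=7.0) == pytest.approx(dg0)
        # acetate oxidation consumes one proton: shifted by -RT ln(1e-7)
        rxn1 = reactions["acetate_oxidation"]
        dg1, _ = compute_delta_g_standard(rxn1, species_table)
        expected = dg1 - R_KJ * T_REF * math.log(1e-7)
        assert delta_g_standard_at_ph(rxn1, species_table, pH=7.0) == pytest.approx(expected)


class TestGibbsHelmholtz:
    def test_identity_at_reference_temperature(self):
        assert gibbs_helmholtz(73.7, 202.9, T_REF) == pytest.approx(73.7)

    def test_closed_form_matches_hand_arithmetic(self):
        dg, dh = 73.7, 202.911
        expected = 73.7 * (310.15 / 298.15) + 202.911 * (298.15 - 310.15) / 298.15
        assert gibbs_helmholtz(dg, dh, 310.15) == pytest.approx(expected, abs=1e-12)

    def test_entropy_free_limit(self):
        # dH = dG means dS = 0, so dG is temperature-independent
        for T in (250.0, 298.15, 310.15, 400.0):
            assert gibbs_helmholtz(-42.0, -42.0, T) == pytest.approx(-42.0)

    def test_linear_in_both_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g1, g2, h1, h2, a, b = rng.normal(0, 100, 6)
            T = rng.uniform(270, 360)
            combined = gibbs_helmholtz(a * g1 + b * g2, a * h1 + b * h2, T)
            parts = a * gibbs_helmholtz(g1, h1, T) + b * gibbs_helmholtz(g2, h2, T)
            assert combined == pytest.approx(parts, rel=1e-12, abs=1e-9)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ThermoError):
            gibbs_helmholtz(1.0, 1.0, 0.0)


class TestReactionQuotient:
    def test_unit_state_gives_unity(self, reactions, species_table):
        state = _state(pr=1.0, ac=1.0, ph2=P_STANDARD, pco2=P_STANDARD,
                       pch4=P_STANDARD, pH=0.0 + 1e-12)
        for rxn in reactions.values():
            assert compute_reaction_quotient(rxn, state, species_table) == pytest.approx(1.0)

    def test_standard_state_gases_methanogenesis(self, reactions, species_table):
        state = _state(ph2=1e5, pco2=1e5, pch4=1e5)
        q = compute_reaction_quotient(
            reactions["hydrogenotrophic_methanogenesis"], state, species_table
        )
        assert q == pytest.approx(1.0)

    def test_term_by_term_product(self, reactions, species_table):
        # independent manual product of the four activity terms of Eq. 2
        state = _state(pr=0.058, ac=0.01, ph2=5.3, pco2=26700.0)
        manual = (0.01 * (26700.0 / 1e5) * (5.3 / 1e5) ** 3) / 0.058
        q = compute_reaction_quotient(
            reactions["propionate_oxidation"], state, species_table
        )
        assert q == pytest.approx(manual, rel=1e-12)

    def test_zero_reactant_activity_is_error(self, reactions, species_table):
        state = _state(pr=0.0, ac=0.01, ph2=5.3, pco2=26700.0)
        with pytest.raises(ThermoError, match="propionate"):
            compute_reaction_quotient(reactions["propionate_oxidation"], state, species_table)

    def test_missing_measurement_is_error(self, reactions, species_table):
        state = _state(pr=0.05, ac=0.01, pco2=26700.0)  # no H2
        with pytest.raises(ThermoError, match="H2"):
            compute_reaction_quotient(reactions["propionate_oxidation"], state, species_table)


class TestComputeDeltaG:
    def test_q_of_one_returns_standard_value(self, reactions, species_table):
        state = _state(ph2=1e5, pco2=1e5, pch4=1e5)
        res = compute_delta_g(reactions["hydrogenotrophic_methanogenesis"], state, species_table)
        assert res.reaction_quotient == pytest.approx(1.0)
        assert res.delta_g == pytest.approx(res.delta_g0_T)

    def test_spreadsheet_recomputation(self, reactions, species_table):
        # Eq. 3 at 310.15 K, pH2 = 10 Pa, pCO2 = 3e4 Pa, pCH4 = 6e4 Pa
        state = _state(ph2=10.0, pco2=3e4, pch4=6e4)
        rxn = reactions["hydrogenotrophic_methanogenesis"]
        res = compute_delta_g(rxn, state, species_table)
        dg298, dh298 = compute_delta_g_standard(rxn, species_table)
        dg0_t = dg298 * 310.15 / 298.15 + dh298 * (298.15 - 310.15) / 298.15
        q = (6e4 / 1e5) / ((10.0 / 1e5) ** 4 * (3e4 / 1e5))
        assert res.delta_g == pytest.approx(dg0_t + R_KJ * 310.15 * math.log(q), rel=1e-12)

    def test_result_internal_consistency(self, reactions, species_table):
        state = _state(pr=0.05, ac=0.02, ph2=4.0, pco2=26700.0)
        res = compute_delta_g(reactions["propionate_oxidation"], state, species_table)
        recomputed = res.delta_g0_T + R_KJ * res.temperature * math.log(res.reaction_quotient)
        assert abs(res.delta_g - recomputed) < 1e-9

    def test_zero_product_gives_unbounded_exergonic_sentinel(self, reactions, species_table):
        state = _state(pr=0.05, ac=0.02, ph2=4.0, pco2=26700.0, pch4=0.0)
        res = compute_delta_g(reactions["hydrogenotrophic_methanogenesis"],
                              _state(ph2=4.0, pco2=26700.0, pch4=0.0), species_table)
        assert res.unbounded_exergonic
        assert res.delta_g == -math.inf
        assert res.reaction_quotient == 0.0


class TestCriticalConcentration:
    def test_equilibrium_at_unit_activity(self, species_table):
        # a reaction with dG0_T = 0 and all other activities 1 equilibrates
        # at 1 mol/L of the target species
        rxn = Reaction(name="iso", stoichiometry={"acetate": 1, "propionate": -1})
        dg298, dh298 = compute_delta_g_standard(rxn, species_table)
        # build a species table variant where the transfer is thermoneutral
        from syntherm.thermo import ThermoSpecies

        table = dict(species_table)
        table["acetate"] = ThermoSpecies("acetate", "aqueous",
                                         table["propionate"].delta_g_f,
                                         table["propionate"].delta_h_f, -1)
        state = _state(pr=1.0)
        c = critical_concentration(rxn, state, table, "acetate")
        assert c == pytest.approx(1.0, rel=1e-12)

    def test_round_trip_gives_zero_delta_g(self, reactions, species_table):
        state = _state(pr=0.058, ph2=5.3, pco2=26700.0)
        rxn = reactions["propionate_oxidation"]
        c = critical_concentration(rxn, state, species_table, "acetate")
        state.solute_concentrations["acetate"] = c
        res = compute_delta_g(rxn, state, species_table)
        assert abs(res.delta_g) < 1e-6

    def test_gas_target_rejected(self, reactions, species_table):
        state = _state(pr=0.058, ac=0.01, pco2=26700.0, ph2=5.3)
        with pytest.raises(ThermoError, match="aqueous"):
            critical_concentration(reactions["propionate_oxidation"], state,
                                   species_table, "H2")

    def test_zero_coefficient_rejected(self, reactions, species_table):
        state = _state(pr=0.058, ph2=5.3, pco2=26700.0)
        with pytest.raises(ThermoError):
            critical_concentration(reactions["hydrogenotrophic_methanogenesis"],
                                   state, species_table, "acetate")


class TestThermodynamicProperties:
    """Randomized invariants of the free-energy surface."""

    @staticmethod
    def _random_state(rng):
        return _state(
            pr=rng.uniform(1e-4, 1.0),
            ac=rng.uniform(1e-4, 1.0),
            ph2=rng.uniform(0.1, 1e5),
            pco2=rng.uniform(10.0, 1e5),
            pch4=rng.uniform(10.0, 1e5),
            pH=rng.uniform(4.0, 10.0),
            T=rng.uniform(280.0, 340.0),
        )

    def test_monotone_in_product_and_reactant_activities(self, reactions, species_table):
        rng = np.random.default_rng(11)
        rxn = reactions["propionate_oxidation"]
        for _ in range(200):
            state = self._random_state(rng)
            base = compute_delta_g(rxn, state, species_table).delta_g
            state.solute_concentrations["acetate"] *= 1.5  # product up
            g_up = compute_delta_g(rxn, state, species_table).delta_g
            assert g_up > base
            state.solute_concentrations["propionate"] *= 2.0  # reactant up
            g_down = compute_delta_g(rxn, state, species_table).delta_g
            assert g_down < g_up

    def test_hess_additivity(self, reactions, species_table):
        rng = np.random.default_rng(12)
        eq1 = reactions["acetate_oxidation"]
        eq3 = reactions["hydrogenotrophic_methanogenesis"]
        summed_st = {}
        for rxn in (eq1, eq3):
            for sp, nu in rxn.stoichiometry.items():
                summed_st[sp] = summed_st.get(sp, 0.0) + nu
        summed = Reaction(name="acetate_to_methane", stoichiometry=summed_st)
        for _ in range(100):
            state = self._random_state(rng)
            g1 = compute_delta_g(eq1, state, species_table).delta_g
            g3 = compute_delta_g(eq3, state, species_table).delta_g
            gsum = compute_delta_g(summed, state, species_table).delta_g
            assert gsum == pytest.approx(g1 + g3, rel=1e-9, abs=1e-9)

    def test_propionate_oxidation_is_ph_invariant(self, reactions, species_table):
        rng = np.random.default_rng(13)
        rxn = reactions["propionate_oxidation"]
        for _ in range(100):
            state = self._random_state(rng)
            g_at = []
            for pH in (4.0, 7.0, 10.0):
                state.pH = pH
                g_at.append(compute_delta_g(rxn, state, species_table).delta_g)
            assert max(g_at) - min(g_at) < 1e-9

    def test_closed_form_matches_bisection(self, reactions, species_table):
        from scipy.optimize import brentq

        rng = np.random.default_rng(14)
        rxn = reactions["propionate_oxidation"]
        for _ in range(100):
            state = self._random_state(rng)
            c_star = critical_concentration(rxn, state, species_table, "acetate")

            def f(log_c):
                state.solute_concentrations["acetate"] = math.exp(log_c)
                return compute_delta_g(rxn, state, species_table).delta_g

            root = brentq(f, math.log(c_star) - 5, math.log(c_star) + 5, xtol=1e-12)
            assert math.exp(root) == pytest.approx(c_star, rel=1e-6)
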