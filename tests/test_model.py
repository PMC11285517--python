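"""Model compilation: species, reactions, rates, ATP scaling, dynamics."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import finetoggle as ft

DEF = ft.RateSet()


def hand_coded_rhs(y, r):
    """Direct transcription of the ten governing equations for the dimer
    model, written independently of the reaction compiler (the oracle)."""
    pro1, pro2, propp1, propp2, rna1, rna2, p1, p2, pp1, pp2 = y
    z1 = z2 = 1.0
    return np.array([
        r.cd2 * propp2 - r.ca2 * pro1 * pp2,
        r.cd2 * propp1 - r.ca2 * pro2 * pp1,
        -r.cd2 * propp1 + r.ca2 * pro2 * pp1,
        -r.cd2 * propp2 + r.ca2 * pro1 * pp2,
        r.lambda2 * pro1 * z1 - r.gamma2 * rna1,
        r.lambda2 * pro2 * z2 - r.gamma2 * rna2,
        r.lambda3 * rna1 - 2 * r.ca1 * p1 ** 2 + 2 * r.cd1 * pp1 - r.gamma3 * p1,
        r.lambda3 * rna2 - 2 * r.ca1 * p2 ** 2 + 2 * r.cd1 * pp2 - r.gamma3 * p2,
        r.ca1 * p1 ** 2 - r.cd1 * pp1 - r.ca2 * pp1 * pro2 - r.gamma4 * pp1 + r.cd2 * propp1,
        r.ca1 * p2 ** 2 - r.cd1 * pp2 - r.ca2 * pp2 * pro1 - r.gamma4 * pp2 + r.cd2 * propp2,
    ])


class TestRateSet:
    def test_defaults_match_reference_parameterization(self):
        assert DEF.lambda2 == 0.0067
        assert DEF.lambda3 == 0.0474
        assert DEF.ca1 == 0.0023
        assert DEF.cd1 == 0.00023
        assert DEF.ca2 == 0.1038
        assert DEF.cd2 == 1.04
        assert DEF.gamma2 == 0.00023
        assert DEF.gamma3 == 0.00077
        assert DEF.gamma4 == 0.00058
        assert DEF.atp == 1.0 and DEF.atp_mode == "both"

    @pytest.mark.parametrize("bad", [{"lambda2": -1}, {"atp": -0.5}, {"atp_mode": "bogus"}])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            ft.RateSet(**bad)

    def test_scaled_by_relative_factors(self):
        scaled = DEF.scaled_by({"gamma3": 10, "cd2": 0.1})
        assert scaled.gamma3 == pytest.approx(0.0077)
        assert scaled.cd2 == pytest.approx(0.104)
        assert scaled.lambda2 == DEF.lambda2
        with pytest.raises(KeyError):
            DEF.scaled_by({"nope": 2})
        with pytest.raises(ValueError):
            DEF.scaled_by({"gamma3": 0})


class TestAtpScaling:
    def test_both_mode_scales_expression_rates(self):
        eff = ft.apply_atp_scaling(DEF.replace(atp=2.0))
        assert eff.lambda2 == pytest.approx(0.0134)
        assert eff.lambda3 == pytest.approx(0.0948)
        assert eff.gamma3 == DEF.gamma3

    @pytest.mark.parametrize("mode", ft.ATP_MODES)
    def test_unit_multiplier_is_identity(self, mode):
        eff = ft.apply_atp_scaling(DEF.replace(atp=1.0, atp_mode=mode))
        for name in ft.RATE_NAMES:
            assert getattr(eff, name) == getattr(DEF, name)

    def test_zero_atp_halts_expression(self):
        eff = ft.apply_atp_scaling(DEF.replace(atp=0.0))
        assert eff.lambda2 == 0.0 and eff.lambda3 == 0.0

    def test_single_process_modes(self):
        tx = ft.apply_atp_scaling(DEF.replace(atp=3.0, atp_mode="transcription"))
        assert (tx.lambda2, tx.lambda3) == (pytest.approx(0.0201), DEF.lambda3)
        tl = ft.apply_atp_scaling(DEF.replace(atp=3.0, atp_mode="translation"))
        assert (tl.lambda2, tl.lambda3) == (DEF.lambda2, pytest.approx(0.1422))

    def test_degradation_mode_scales_gamma3_only(self):
        eff = ft.apply_atp_scaling(DEF.replace(atp=2.0, atp_mode="both_plus_degradation"))
        assert eff.gamma3 == pytest.approx(2 * DEF.gamma3)
        assert eff.gamma2 == DEF.gamma2 and eff.gamma4 == DEF.gamma4


class TestBuildModel:
    def test_dimer_variant_species_and_reactions(self, dimer_model):
        assert set(dimer_model.species) == {
            "pro1", "pro2", "propp1", "propp2", "rna1", "rna2",
            "p1", "p2", "pp1", "pp2",
        }
        # 7 process families per gene, two of them reversible pairs
        assert dimer_model.n_reactions == 18

    def test_monomer_variant_has_no_oligomers(self):
        m = ft.build_model(1)
        assert not any("pp" in s for s in m.species)
        binding = [r for r in m.reactions if r.rate_name == "ca2"]
        reactant_sets = [set(dict(r.reactants)) for r in binding]
        assert {"pro2", "p1"} in reactant_sets and {"pro1", "p2"} in reactant_sets

    def test_tetramer_variant_top_oligomer_binds(self):
        m = ft.build_model(4)
        for s in ("pp1", "ppp1", "pppp1", "propppp1"):
            assert s in m.species
        binding = [r for r in m.reactions if r.rate_name == "ca2"]
        for r in binding:
            species = set(dict(r.reactants))
            assert species in ({"pro1", "pppp2"}, {"pro2", "pppp1"})
        # every free oligomer order has its gamma4 degradation channel
        degraded = {dict(r.reactants).popitem()[0]
                    for r in m.reactions if r.rate_name == "gamma4"}
        assert degraded == {"pp1", "pp2", "ppp1", "ppp2", "pppp1", "pppp2"}

    @pytest.mark.parametrize("order,n_species,n_reactions",
                             [(1, 8, 12), (2, 10, 18), (3, 12, 24), (4, 14, 30)])
    def test_variant_sizes_deterministic(self, order, n_species, n_reactions):
        m = ft.build_model(order)
        assert (m.n_species, m.n_reactions) == (n_species, n_reactions)

    @pytest.mark.parametrize("order", [0, 5, -1])
    def test_order_out_of_range_rejected(self, order):
        with pytest.raises(ValueError):
            ft.build_model(order)

    def test_json_export_round_trips(self, dimer_model):
        payload = json.loads(dimer_model.to_json())
        assert payload["oligomer_order"] == 2
        assert len(payload["reactions"]) == dimer_model.n_reactions
        assert payload["species"] == list(dimer_model.species)


class TestOdeRhs:
    def test_matches_hand_coded_equations_on_random_states(self, dimer_model, rng):
        """Generic mass-action compilation reduces to the explicit
        ten-equation system for the dimer model, to machine precision."""
        for _ in range(1000):
            y = rng.uniform(0, 100, size=10)
            np.testing.assert_allclose(
                dimer_model.ode_rhs(y), hand_coded_rhs(y, DEF), rtol=1e-13, atol=1e-13
            )

    def test_initial_condition_derivative(self, dimer_model):
        y = dimer_model.initial_state()
        dy = dimer_model.ode_rhs(y)
        by_name = dict(zip(dimer_model.species, dy))
        assert by_name["rna1"] == pytest.approx(0.0067)
        assert by_name["p1"] == 0.0
        assert by_name["pro1"] == 0.0

    def test_promoter_binding_term(self, dimer_model):
        y = np.zeros(10)
        y[dimer_model.species_index("pro1")] = 1.0
        y[dimer_model.species_index("pp2")] = 1.0
        dy = dimer_model.ode_rhs(y)
        assert dy[dimer_model.species_index("pro1")] == pytest.approx(-0.1038)
        assert dy[dimer_model.species_index("propp2")] == pytest.approx(0.1038)

    def test_dimension_mismatch_rejected(self, dimer_model):
        with pytest.raises(ValueError):
            dimer_model.ode_rhs(np.zeros(7))

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_swap_equivariance(self, order, rng):
        """Exchanging gene labels in the state swaps the derivatives."""
        m = ft.build_model(order)
        perm = m.swap_permutation()
        for _ in range(20):
            y = rng.uniform(0, 50, size=m.n_species)
            np.testing.assert_allclose(
                m.ode_rhs(y)[perm], m.ode_rhs(y[perm]), rtol=1e-12, atol=1e-12
            )

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_promoter_totals_conserved_by_flow(self, order, rng):
        m = ft.build_model(order)
        for _ in range(50):
            dy = m.ode_rhs(rng.uniform(0, 50, size=m.n_species))
            d1, d2 = m.promoter_totals(dy)
            assert abs(d1) < 1e-12 and abs(d2) < 1e-12


class TestPropensities:
    def test_homodimerization_uses_combinatorial_count(self, dimer_model):
        x = np.zeros(10)
        x[dimer_model.species_index("p1")] = 3
        a = dimer_model.propensities(x)
        dimer_rxn = next(
            i for i, r in enumerate(dimer_model.reactions)
            if r.rate_name == "ca1" and ("p1", 2) in r.reactants
        )
        assert a[dimer_rxn] == pytest.approx(0.0023 * 3 * 2)

    def test_promoter_binding_channel(self, dimer_model):
        x = np.zeros(10)
        x[dimer_model.species_index("pro1")] = 1
        x[dimer_model.species_index("pp2")] = 1
        a = dimer_model.propensities(x)
        binding = next(
            i for i, r in enumerate(dimer_model.reactions)
            if r.rate_name == "ca2" and ("pp2", 1) in r.reactants
        )
        assert a[binding] == pytest.approx(0.1038)

    def test_fresh_promoters_only_transcribe(self, dimer_model):
        a = dimer_model.propensities(dimer_model.initial_state())
        nonzero = {dimer_model.reactions[i].rate_name for i in np.nonzero(a)[0]}
        assert nonzero == {"lambda2"}
        assert a.sum() == pytest.approx(2 * 0.0067)

    def test_atp_scales_transcription_propensity(self):
        m = ft.build_model(2, DEF.replace(atp=2.0))
        a = m.propensities(m.initial_state())
        assert a.sum() == pytest.approx(2 * 2 * 0.0067)

    def test_negative_counts_rejected(self, dimer_model):
        x = np.zeros(10)
        x[0] = -1
        with pytest.raises(ValueError):
            dimer_model.propensities(x)

    def test_swap_equivariance(self, dimer_model, rng):
        perm_s = dimer_model.swap_permutation()
        for _ in range(20):
            x = rng.integers(0, 30, size=10).astype(float)
            a = dimer_model.propensities(x)
            a_swapped = dimer_model.propensities(x[perm_s])
            # reactions come in gene-1/gene-2 pairs in compile order
            assert sorted(a) == pytest.approx(sorted(a_swapped))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.floats(0.1, 10),
    st.sampled_from([1, 2, 3, 4]),
    st.sampled_from(list(ft.ATP_MODES)),
)
def test_mean_field_drift_matches_rhs_at_large_counts(atp, order, mode):
    """SSA drift sum_r a_r(x) * S_r equals the ODE derivative up to the
    O(1/x) combinatorial correction of homo-oligomerization channels."""
    m = ft.build_model(order, DEF.replace(atp=atp, atp_mode=mode))
    x = np.full(m.n_species, 1000.0)
    drift = m.propensities(x) @ m.stoich
    dy = m.ode_rhs(x)
    # the only discrepancy is ca1 * x for the two 2P->PP channels
    np.testing.assert_allclose(drift, dy, rtol=2e-3, atol=2e-3 * np.abs(dy).max())
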