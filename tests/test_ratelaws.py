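"""Unit tests for the rate laws: Hill functions, regulatory edges,
mass-action fluxes, and the assembled right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from israpop.params import default_params
from israpop.ratelaws import (
    BINDING_PAIRS, RhsSwitches, binding_fluxes, caspase_fluxes,
    drug_and_tf_rhs, effector_activation_flux, hill_down, hill_up, make_rhs,
    max_production_rates, net_survival_balance, proliferation_death_rates,
    regulation_factor, tf_regulated_production,
)
from israpop.states import IDX, N_STATES, TOTALS, state_template, total

ZERO_DELAYED = {k: 0.0 for k in ("myc_ven", "myc_ted", "chop_ven", "chop_ted")}


class TestHill:
    @pytest.mark.parametrize("n", [0.5, 1.0, 2.0, 7.3])
    def test_half_saturation(self, n):
        assert hill_up(3.7, 3.7, n) == pytest.approx(0.5)
        assert hill_down(3.7, 3.7, n) == pytest.approx(0.5)

    def test_boundary_values(self):
        assert hill_up(0.0, 5.0, 2.0) == 0.0
        assert hill_down(0.0, 5.0, 2.0) == 1.0
        assert hill_up(2 * 7.0, 7.0, 2.0) == pytest.approx(0.8)
        assert hill_down(2 * 7.0, 7.0, 2.0) == pytest.approx(0.2)

    def test_monotone_increasing(self):
        xs = np.linspace(0, 50, 200)
        h = np.array([hill_up(x, 10.0, 3.0) for x in xs])
        assert np.all(np.diff(h) > 0)
        assert h.max() < 1.0

    @pytest.mark.parametrize("bad", [dict(K=0.0, n=1.0), dict(K=-1.0, n=1.0),
                                     dict(K=1.0, n=0.0), dict(K=1.0, n=-2.0)])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            hill_up(1.0, **bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(x=st.floats(0.0, 1e6), K=st.floats(1e-6, 1e6),
           n=st.floats(0.1, 10.0))
    def test_up_down_partition_of_unity(self, x, K, n):
        assert hill_up(x, K, n) + hill_down(x, K, n) == pytest.approx(1.0, abs=1e-15)


class TestRegulation:
    def test_no_tf_gives_basal_rate_exactly(self, params):
        rates = max_production_rates(params)
        for prot in ("bcl2", "mcl1", "bim", "bax", "bak"):
            out = tf_regulated_production(prot, 0.0, 0.0, params)
            assert out == rates[prot]

    def test_chop_saturation_limit_matches_closed_form(self, params):
        # at saturating Chop every chop edge contributes its full amplitude
        myc = 0.0
        chop_big = 1e9
        got = regulation_factor("bak", myc, chop_big, params)
        expected = 1.0 + params["reg_chop_bak_up_amp"]   # hill_up -> 1
        assert got == pytest.approx(expected, rel=1e-6)
        got_mcl1 = regulation_factor("mcl1", myc, chop_big, params)
        assert got_mcl1 == pytest.approx(1.0 - params["reg_chop_mcl1_down_amp"],
                                         rel=1e-6)

    def test_unknown_protein_raises(self, params):
        with pytest.raises(KeyError):
            tf_regulated_production("puma", 1.0, 1.0, params)

    def test_hormetic_profile_single_slope_sign_change(self, params):
        grid = np.linspace(0.0, 1000.0, 500)
        bal = net_survival_balance(params, grid)
        d = np.diff(bal)
        signs = np.sign(d[np.abs(d) > 1e-12])
        changes = np.sum(signs[1:] != signs[:-1])
        assert changes == 1
        # cancer zone precedes apoptosis zone: rises first, then falls
        assert signs[0] > 0 and signs[-1] < 0

    def test_survival_edges_saturate_before_apoptotic_edges(self, params):
        for surv, apo in [("reg_myc_bcl2_up_K", "reg_myc_bcl2_down_K"),
                          ("reg_myc_mcl1_up_K", "reg_myc_bim_up_K")]:
            assert params[surv] < params[apo]


class TestFluxes:
    def test_binding_zero_states_zero_flux(self, params):
        y = state_template()
        assert all(v == 0.0 for v in binding_fluxes(y, params).values())

    def test_binding_detailed_balance(self, params):
        # [A][B] = K_D [C]  =>  net flux 0
        kd = params["koff_bcl2_bim"] / params["kon_bcl2_bim"]
        y = state_template(bcl2_free=4.0, bim_free=kd / 4.0 * 2.0, cx_bcl2_bim=2.0)
        assert binding_fluxes(y, params)["bcl2_bim"] == pytest.approx(0.0, abs=1e-12)

    def test_binding_numeric_example(self, params):
        p = params.copy()
        p["kon_bcl2_bim"] = 1.0
        p["koff_bcl2_bim"] = 10.0
        y = state_template(bcl2_free=5.0, bim_free=5.0, cx_bcl2_bim=1.0)
        assert binding_fluxes(y, p)["bcl2_bim"] == pytest.approx(15.0)

    def test_venetoclax_affinity_strictly_highest(self, params):
        kd = {k: params[f"koff_{k}"] / params[f"kon_{k}"]
              for k, *_ in BINDING_PAIRS}
        ven_kd = kd.pop("bcl2_ven")
        for pair, v in kd.items():
            if pair.startswith("bcl2"):
                assert ven_kd < v

    def test_activation_flux(self, params):
        assert effector_activation_flux(state_template(), params)["bax"] == 0.0
        p = params.copy()
        p["k_act_bax"] = 0.5
        y = state_template(cx_bim_bax=4.0)
        assert effector_activation_flux(y, p)["bax"] == pytest.approx(2.0)

    def test_activation_conserves_bax_total(self, params):
        rhs = make_rhs(params, RhsSwitches(synthesis=False, degradation=False,
                                           binding=False, caspase=False,
                                           cleavage=False, drugs=False,
                                           population=False))
        y = state_template(cx_bim_bax=5.0, cx_bim_bak=2.0, bax_active=1.0)
        dy = rhs(0.0, y, ZERO_DELAYED)
        for prot in ("bax", "bak", "bim"):
            cols = [IDX[m] for m in TOTALS[prot]]
            assert abs(dy[cols].sum()) < 1e-14

    def test_caspase_fluxes(self, params):
        y = state_template(casp3_inactive=100.0)
        fx = caspase_fluxes(y, params)
        assert fx["activation"] == 0.0
        assert fx["cleave_bcl2"] == 0.0 and fx["cleave_mcl1"] == 0.0
        # half-saturation: activation at K_momp equals half the saturated rate
        y_half = state_template(casp3_inactive=100.0, bax_active=params["K_momp"])
        y_sat = state_template(casp3_inactive=100.0, bax_active=1e12)
        half = caspase_fluxes(y_half, params)["activation"]
        sat = caspase_fluxes(y_sat, params)["activation"]
        assert half == pytest.approx(sat / 2.0, rel=1e-6)


class TestDrugTfLayer:
    def test_basal_steady_tf_derivatives_zero(self, params):
        from israpop.ratelaws import basal_tf_levels
        myc0, chop0 = basal_tf_levels(params)
        y = state_template(myc=myc0, chop=chop0)
        d = drug_and_tf_rhs(0.0, y, ZERO_DELAYED, params)
        assert d["myc"] == pytest.approx(0.0, abs=1e-12)
        assert d["chop"] == pytest.approx(0.0, abs=1e-12)

    def test_extracellular_decay_closed_form(self, params):
        # dVe/dt = -(k_up + k_dec_ext) Ve
        y = state_template(venetoclax_ext=400.0)
        d = drug_and_tf_rhs(0.0, y, ZERO_DELAYED, params)
        k = params["ven_k_uptake"] + params["ven_k_decay_ext"]
        assert d["venetoclax_ext"] == pytest.approx(-k * 400.0)

    def test_missing_delay_raises(self, params):
        with pytest.raises(KeyError):
            drug_and_tf_rhs(0.0, state_template(), {"myc_ven": 0.0}, params)

    def test_chop_combination_exceeds_monotherapies(self, params):
        """Superadditivity: at equal drug inputs the combination production
        term exceeds the sum of the monotherapy increments."""
        vi, ti = 300.0, 3000.0
        def chop_prod(v, t):
            y = state_template()
            d = drug_and_tf_rhs(0.0, y, {"myc_ven": v, "myc_ted": t,
                                         "chop_ven": v, "chop_ted": t}, params)
            return d["chop"]
        base = chop_prod(0.0, 0.0)
        inc_v = chop_prod(vi, 0.0) - base
        inc_t = chop_prod(0.0, ti) - base
        inc_c = chop_prod(vi, ti) - base
        assert inc_c > inc_v + inc_t


class TestPopulation:
    def test_death_at_zero_caspase_is_basal(self, params):
        y = state_template(casp3_inactive=100.0, bcl2_free=50.0, myc=100.0)
        assert proliferation_death_rates(y, params)["d"] == params["d0"]

    def test_growth_vanishes_at_saturating_tedizolid(self, params):
        y = state_template(casp3_inactive=100.0, bcl2_free=50.0,
                           tedizolid_int=1e12)
        assert proliferation_death_rates(y, params)["g"] < 1e-6

    def test_zero_caspase_pool_is_degenerate(self, params):
        with pytest.raises(ValueError):
            proliferation_death_rates(state_template(bcl2_free=1.0), params)


class TestAssembledRhs:
    def test_consistency_with_component_fluxes(self, params):
        """The fast closure must agree with the readable per-component flux
        functions on random states."""
        rng = np.random.default_rng(7)
        rhs = make_rhs(params, RhsSwitches(synthesis=False, degradation=False,
                                           activation=False, caspase=False,
                                           cleavage=False, drugs=False,
                                           population=False))
        for _ in range(20):
            y = rng.uniform(0, 50, N_STATES)
            dy = rhs(0.0, y, ZERO_DELAYED)
            fx = binding_fluxes(y, params)
            # reconstruct the complex derivatives from the pair fluxes
            for key, a, b, c in BINDING_PAIRS:
                assert dy[IDX[c]] == pytest.approx(fx[key], rel=1e-12, abs=1e-12)

    def test_binding_conserves_every_total(self, params):
        rng = np.random.default_rng(11)
        rhs = make_rhs(params, RhsSwitches(synthesis=False, degradation=False,
                                           activation=False, caspase=False,
                                           cleavage=False, drugs=False,
                                           population=False))
        for _ in range(10):
            y = rng.uniform(0, 100, N_STATES)
            dy = rhs(0.0, y, ZERO_DELAYED)
            for prot in ("bcl2", "mcl1", "bim", "bax", "bak"):
                cols = [IDX[m] for m in TOTALS[prot]]
                assert abs(dy[cols].sum()) < 1e-10

    def test_steady_state_is_a_fixed_point(self, params, steady):
        rhs = make_rhs(params, RhsSwitches(population=False))
        dy = rhs(0.0, steady.state, ZERO_DELAYED)
        protein_idx = [i for i in range(N_STATES) if i not in (26, 27)]
        assert np.max(np.abs(dy[protein_idx])) < 1e-7

    def test_nonfinite_state_raises(self, params):
        rhs = make_rhs(params)
        y = state_template(bcl2_free=np.nan)
        with pytest.raises(FloatingPointError):
            rhs(0.0, y, ZERO_DELAYED)

    def test_three_species_oracle(self, params):
        """Species-wise binding fluxes on a single-pair subnetwork match a
        hand-assembled 3-species system."""
        p = params.copy()
        kon, koff = 0.8, 4.0
        p["kon_bcl2_bim"], p["koff_bcl2_bim"] = kon, koff
        A, B, C = 30.0, 12.0, 5.0
        y = state_template(bcl2_free=A, bim_free=B, cx_bcl2_bim=C)
        rhs = make_rhs(p, RhsSwitches(synthesis=False, degradation=False,
                                      activation=False, caspase=False,
                                      cleavage=False, drugs=False,
                                      population=False))
        dy = rhs(0.0, y, ZERO_DELAYED)
        flux = kon * A * B - koff * C   # oracle: written out by hand
        assert dy[IDX["bcl2_free"]] == pytest.approx(-flux)
        assert dy[IDX["bim_free"]] == pytest.approx(-flux)
        assert dy[IDX["cx_bcl2_bim"]] == pytest.approx(flux)
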