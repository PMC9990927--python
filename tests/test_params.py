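"""Parameter engine: unit conversions, derived coefficients, table values."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glymphsim import units
from glymphsim.params import (ParameterError, apply_variation, baseline_table,
                              csf_volume, effective_diffusion, flow_gamma,
                              gamma_tilde, kozeny_carman_factor, lambda_coeff,
                              membrane_gamma, pair_key, pvs_sleep_factors)


class TestUnits:
    def test_mmhg_conversion_values(self):
        assert units.mmhg_to_pa(0.0) == 0.0
        assert units.mmhg_to_pa(1.0) == pytest.approx(133.322)
        assert units.mmhg_to_pa(40.0) == pytest.approx(5332.9, abs=0.1)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-1e4, 1e4, allow_nan=False))
    def test_mmhg_round_trip(self, p):
        assert units.pa_to_mmhg(units.mmhg_to_pa(p)) == pytest.approx(
            p, rel=1e-12, abs=1e-12)

    def test_non_finite_pressure_rejected(self):
        with pytest.raises(ValueError):
            units.mmhg_to_pa(math.nan)

    def test_flow_conversions(self):
        assert units.ul_per_min_to_mm3_per_s(60.0) == pytest.approx(1.0)
        assert units.ml_per_min_to_mm3_per_s(2.32) == pytest.approx(38.667,
                                                                    rel=1e-4)
        # cerebral blood flow: 116 mL/100g/min for a 2 g brain
        assert units.perfusion_to_mm3_per_s(116.0, 2.0) == pytest.approx(
            38.667, rel=1e-4)


class TestDerivations:
    def test_effective_diffusion(self):
        # free inulin diffusion through tortuosity 1.7 tissue
        assert effective_diffusion(2.98e-4, 1.7) == pytest.approx(1.03e-4,
                                                                  rel=5e-3)
        assert effective_diffusion(0.123, 1.0) == 0.123
        assert effective_diffusion(0.0, 1.7) == 0.0
        with pytest.raises(ParameterError):
            effective_diffusion(1e-4, 0.9)

    def test_membrane_gamma(self):
        # arterial wall: L = 9.1e-10 mm/(s Pa), S/V = 3 /mm
        assert membrane_gamma(9.1e-10, 3.0) == pytest.approx(2.7e-9, rel=0.02)
        # capillary wall: L = 1.0e-10, S/V = 9
        assert membrane_gamma(1.0e-10, 9.0) == pytest.approx(9.0e-10)
        assert membrane_gamma(1e-9, 0.0) == 0.0

    def test_flow_gamma(self):
        # artery->capillary branching: CBF over 40 mmHg drop and brain volume
        g = flow_gamma(38.667, units.mmhg_to_pa(40.0), 2313.0)
        assert g == pytest.approx(3.14e-6, rel=5e-3)
        # periarterial->pericapillary: CSF production over 1 mmHg
        g = flow_gamma(3.38 / 60.0, units.mmhg_to_pa(1.0), 2313.0)
        assert g == pytest.approx(1.83e-7, rel=5e-3)
        assert flow_gamma(0.0, 10.0, 100.0) == 0.0
        with pytest.raises(ParameterError):
            flow_gamma(1.0, 0.0, 2313.0)
        with pytest.raises(ParameterError):
            flow_gamma(1.0, 10.0, -1.0)

    def test_gamma_tilde(self):
        assert gamma_tilde(5.5e-7, 1.0) == 0.0
        assert gamma_tilde(5.5e-7, 0.0) == 5.5e-7
        assert gamma_tilde(2.19e-7, 0.2) == pytest.approx(1.752e-7)
        with pytest.raises(ParameterError):
            gamma_tilde(1e-7, 1.5)

    def test_lambda_coeff(self):
        # pericapillary endfeet: P = 4.1e-4 mm/s, S/V = 9 /mm
        assert lambda_coeff(4.1e-4, 9.0) == pytest.approx(3.70e-3, rel=5e-3)
        assert lambda_coeff(0.0, 9.0) == 0.0
        assert lambda_coeff(1.2e-3, 3.0) == pytest.approx(3.6e-3)

    def test_kozeny_carman(self):
        # awake -> sleep ECS porosity change 0.14 -> 0.23
        assert kozeny_carman_factor(0.14, 0.23) == pytest.approx(5.5, rel=0.01)
        assert kozeny_carman_factor(0.3, 0.3) == 1.0
        # hand evaluation: (0.2^3/0.8^2) / (0.1^3/0.9^2) = 0.0125/0.00123457
        assert kozeny_carman_factor(0.1, 0.2) == pytest.approx(10.125,
                                                               rel=1e-6)
        with pytest.raises(ParameterError):
            kozeny_carman_factor(0.0, 0.2)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.01, 0.95), st.floats(0.01, 0.95))
    def test_kozeny_carman_reciprocal(self, a, b):
        assert kozeny_carman_factor(a, b) * kozeny_carman_factor(b, a) == \
            pytest.approx(1.0, rel=1e-9)

    def test_pvs_sleep_factors(self):
        assert pvs_sleep_factors(4.0) == (4.0, 16.0)
        assert pvs_sleep_factors(1.0) == (1.0, 1.0)
        assert pvs_sleep_factors(2.0) == (2.0, 4.0)

    def test_csf_volume(self):
        # 10.8% of intracranial volume -> ~0.12 x brain volume
        assert csf_volume(2313.0, 0.108) == pytest.approx(0.121 * 2313.0,
                                                          rel=5e-3)
        assert csf_volume(100.0, 0.0) == 0.0
        assert csf_volume(100.0, 0.5) == pytest.approx(100.0)
        with pytest.raises(ParameterError):
            csf_volume(100.0, 1.0)


# Every published baseline cell: (kind, key, value)
PUBLISHED_TABLE1 = {
    "kappa": {"a": 3.30e-6, "v": 6.59e-6, "c": 8.8e-9, "pa": 1.0e-11,
              "pv": 6.51e-9, "pc": 3.54e-13, "e": 2.0e-11},
    "phi": {"e": 0.14, "a": 0.0071, "c": 0.011, "v": 0.016,
            "pa": 0.0021, "pc": 0.0033, "pv": 0.0046},
    "mu": {"a": 2.67e-3, "c": 2.67e-3, "v": 2.67e-3,
           "pa": 7.0e-4, "pc": 7.0e-4, "pv": 7.0e-4, "e": 7.0e-4},
}
PUBLISHED_GAMMA = {
    ("a", "e"): 2.7e-9, ("c", "e"): 9.0e-10, ("v", "e"): 6.0e-11,
    ("pa", "e"): 2.19e-7, ("pv", "e"): 1.95e-7, ("pc", "e"): 9.20e-9,
    ("a", "pa"): 2.76e-9, ("v", "pv"): 6.00e-11, ("c", "pc"): 9.98e-10,
    ("a", "c"): 3.14e-6, ("c", "v"): 9.65e-6,
    ("pa", "pc"): 1.83e-7, ("pc", "pv"): 7.31e-7,
}
PUBLISHED_LAMBDA = {("pa", "e"): 3.70e-3, ("pv", "e"): 3.72e-3,
                    ("pc", "e"): 3.70e-3}


class TestBaselineTable:
    def test_case3_reproduces_every_published_cell(self, table3):
        for name, cells in PUBLISHED_TABLE1.items():
            stored = getattr(table3, name)
            for j, value in cells.items():
                assert stored[j] == pytest.approx(value, rel=1e-12), \
                    f"{name}[{j}]"
        assert table3.d_free == 2.98e-4
        assert table3.diffusion["e"] == 1.03e-4
        for pair, value in PUBLISHED_GAMMA.items():
            assert table3.gamma(*pair) == pytest.approx(value, rel=1e-12), \
                f"gamma{pair}"
        for pair, value in PUBLISHED_LAMBDA.items():
            assert table3.lam(*pair) == pytest.approx(value, rel=1e-12), \
                f"lambda{pair}"
        # boundary and flow scalars
        assert table3.L_pvspial_pa == 1.25e-6
        assert table3.L_e_sas == 3.13e-7
        assert table3.q_csf == pytest.approx(3.38 / 60.0)
        assert table3.b_blood == pytest.approx(38.667, rel=1e-4)
        assert table3.p_sas == pytest.approx(units.mmhg_to_pa(3.26))
        assert table3.p_pvspial == pytest.approx(units.mmhg_to_pa(4.74))
        assert table3.p_v_boundary == pytest.approx(units.mmhg_to_pa(7.0))
        # osmotic pressures: blood 20 mmHg, extravascular 20% of that
        assert table3.pi["c"] == pytest.approx(units.mmhg_to_pa(20.0))
        assert table3.pi["e"] == pytest.approx(units.mmhg_to_pa(4.0))

    def test_case_restriction(self):
        t1 = baseline_table(1)
        assert t1.compartments == ("e",)
        assert t1.diffusion["e"] == 1.03e-4
        assert not t1.pairs
        t2 = baseline_table(2)
        assert set(t2.compartments) == {"pa", "pc", "pv", "e"}
        assert all(i in t2.compartments and j in t2.compartments
                   for (i, j) in t2.pairs)
        assert t2.kappa["pa"] == 1.0e-11
        assert t2.gamma("pa", "e") == 2.19e-7

    def test_fully_reflecting_pairs_transfer_no_solute(self, table3):
        for (i, j), coeffs in table3.pairs.items():
            blood_pair = {i, j} & {"a", "c", "v"}
            if coeffs.kind == "branching" or blood_pair:
                assert coeffs.sigma_reflect == 1.0
                assert coeffs.gamma_tilde == 0.0
                assert coeffs.lam == 0.0

    def test_absent_pairs_have_zero_coupling(self, table3):
        assert not table3.connected("a", "pv")
        assert table3.gamma("a", "pv") == 0.0
        assert table3.lam("pa", "pv") == 0.0

    def test_sleep_variants(self):
        base = baseline_table(2)
        sleep = baseline_table(2, "sleep_ecs")
        assert sleep.phi["e"] == 0.23
        assert sleep.kappa["e"] / base.kappa["e"] == pytest.approx(5.5,
                                                                   rel=0.01)
        assert sleep.phi["pa"] == base.phi["pa"]
        both = baseline_table(2, "sleep_ecs_pvs")
        for j in ("pa", "pc", "pv"):
            assert both.phi[j] == pytest.approx(4.0 * base.phi[j])
            assert both.kappa[j] == pytest.approx(16.0 * base.kappa[j])

    def test_invalid_case_and_variant(self):
        with pytest.raises(ParameterError):
            baseline_table(4)
        with pytest.raises(ParameterError):
            baseline_table(2, "hibernation")

    def test_alpha_defaults_to_csf_turnover(self, table2):
        volume = 2313.0
        expected = table2.q_csf / (0.12 * volume)
        assert table2.sas_alpha(volume) == pytest.approx(expected)
        table2.alpha = 1e-3
        assert table2.sas_alpha(volume) == 1e-3

    def test_report_dataframe_lists_all_parameters(self, table2):
        frame = table2.to_dataframe()
        names = set(frame["parameter"])
        assert {"kappa_e", "phi_pa", "gamma_e,pa", "lambda_e,pa",
                "p_sas", "c_phi"} <= names


class TestVariations:
    def test_multiplicative_and_invertible(self, table2):
        for name in ("kappa_e", "kappa_pa", "p_sas", "D", "phi_pa", "P_pa_e"):
            varied = apply_variation(table2, name, 8.0)
            back = apply_variation(varied, name, 1.0 / 8.0)
            assert back.kappa["e"] == pytest.approx(table2.kappa["e"],
                                                    rel=1e-12)
            assert back.p_sas == pytest.approx(table2.p_sas, rel=1e-12)
            assert back.diffusion["e"] == pytest.approx(
                table2.diffusion["e"], rel=1e-12)
            key = pair_key("pa", "e")
            assert back.pairs[key].lam == pytest.approx(
                table2.pairs[key].lam, rel=1e-12)

    def test_published_factor_example(self, table2):
        varied = apply_variation(table2, "kappa_e", 1000.0)
        assert varied.kappa["e"] == pytest.approx(2.0e-8)
        assert table2.kappa["e"] == 2.0e-11  # original untouched

    def test_dependent_coefficients_rescaled(self, table2):
        varied = apply_variation(table2, "P_pa_e", 0.01)
        key = pair_key("pa", "e")
        assert varied.pairs[key].lam == pytest.approx(
            0.01 * table2.pairs[key].lam)
        assert varied.pairs[key].permeability == pytest.approx(
            0.01 * table2.pairs[key].permeability)

    def test_gamma_variation_rescales_gamma_tilde(self, table3):
        varied = apply_variation(table3, "gamma_pa_a", 5.0)
        key = pair_key("a", "pa")
        assert varied.pairs[key].gamma == pytest.approx(
            5.0 * table3.pairs[key].gamma)
        # sigma_reflect = 1 on the BBB, so gamma~ stays exactly zero
        assert varied.pairs[key].gamma_tilde == 0.0

    def test_symbolic_aliases(self, table2):
        varied = apply_variation(table2, "κ_e", 10.0)
        assert varied.kappa["e"] == pytest.approx(2.0e-10)

    def test_identity_factor(self, table2):
        varied = apply_variation(table2, "D", 1.0)
        assert varied.diffusion["e"] == table2.diffusion["e"]

    def test_unknown_name_and_bad_factor(self, table2):
        with pytest.raises(ParameterError):
            apply_variation(table2, "kappa_q", 2.0)
        with pytest.raises(ParameterError):
            apply_variation(table2, "kappa_e", -1.0)
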