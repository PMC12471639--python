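"""Blood-gas physiology: acid-base solver, saturation curves, contents,
analytic derivatives against finite-difference oracles, effective
diffusivities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxyflux import physiology as phys
from oxyflux.parameters import (BloodParameters, GasTransportConstants,
                                ParameterError)

P = BloodParameters()
C = GasTransportConstants()


def central_diff(f, x, h=1e-3):
    return (f(x + h) - f(x - h)) / (2 * h)


class TestBufferPower:
    @pytest.mark.parametrize("hb, expected", [
        (0.0, 7.7),          # plasma-only limit
        (0.118, 24.574),
        (0.15, 29.15),
    ])
    def test_linear_in_hemoglobin(self, hb, expected):
        assert phys.buffer_power(hb) == pytest.approx(expected, abs=1e-12)

    def test_negative_hb_rejected(self):
        with pytest.raises(ParameterError):
            phys.buffer_power(-0.01)


class TestAcidBase:
    def test_reference_ph_at_venous_pco2(self):
        state = phys.solve_acid_base(44.0, P)
        assert state.pH == pytest.approx(7.357, abs=1e-3)

    def test_ph_74_recovers_standard_bicarbonate(self):
        # at pH 7.4 the buffer line gives exactly 24.4 mmol/L regardless of
        # beta_NC; the corresponding PCO2 is 24.4/(alpha*10^(7.4-pKa))
        pco2 = 24.4 / (0.0307 * 10 ** (7.4 - P.pKa))
        for hb in (0.05, 0.118, 0.2):
            s = phys.solve_acid_base(pco2, BloodParameters(Hb=hb))
            assert s.pH == pytest.approx(7.400, abs=1e-6)
            assert s.C_HCO3_mmol == pytest.approx(24.4, abs=1e-4)

    def test_both_equations_satisfied(self):
        for pco2 in (5.0, 20.0, 44.0, 80.0, 200.0):
            s = phys.solve_acid_base(pco2, P)
            assert s.residual <= 1e-10
            hh = s.pH - P.pKa - np.log10(s.C_HCO3_mmol / (0.0307 * pco2))
            assert abs(hh) <= 1e-9
            buffer_line = 24.4 - s.beta_NC * (s.pH - 7.4)
            assert s.C_HCO3_mmol == pytest.approx(buffer_line, rel=1e-12)
            assert s.C_HCO3_ml == pytest.approx(0.02226 * s.C_HCO3_mmol,
                                                rel=1e-14)

    def test_ph_strictly_decreasing_in_pco2(self):
        grid = np.linspace(P.pco2_floor, P.pco2_ceil, 40)
        ph = phys.solve_acid_base(grid, P).pH
        assert (np.diff(ph) < 0).all()
        assert phys.solve_acid_base(44.0, P).pH > phys.solve_acid_base(60.0, P).pH

    def test_bicarbonate_increasing_in_pco2(self):
        grid = np.linspace(P.pco2_floor, P.pco2_ceil, 40)
        c = phys.solve_acid_base(grid, P).C_HCO3_mmol
        assert (np.diff(c) > 0).all()

    def test_vectorized_matches_scalar(self):
        grid = np.array([[10.0, 44.0], [80.0, 150.0]])
        ph = phys.solve_acid_base(grid, P).pH
        for idx in np.ndindex(grid.shape):
            assert ph[idx] == pytest.approx(
                phys.solve_acid_base(grid[idx], P).pH, rel=1e-12)


class TestBohrAdjustment:
    def test_identity_at_standard_conditions(self):
        assert phys.adjusted_po2(50.0, 37.0, 7.4, 40.0) == pytest.approx(50.0)

    def test_reference_venous_point(self):
        ph = phys.solve_acid_base(44.0, P).pH
        assert phys.adjusted_po2(35.9, 37.0, ph, 44.0) == pytest.approx(
            34.31, abs=5e-3)

    def test_rising_pco2_lowers_adjusted_po2(self):
        a = phys.adjusted_po2(50.0, 37.0, 7.4, 40.0)
        b = phys.adjusted_po2(50.0, 37.0, 7.4, 60.0)
        assert b < a


class TestKelmanCurve:
    def test_zero_and_plateau(self):
        assert phys.kelman_saturation(0.0, C) == 0.0
        assert phys.kelman_saturation(10_000.0, C) == pytest.approx(1.0,
                                                                    abs=1e-2)

    def test_reference_point(self):
        assert phys.kelman_saturation(34.31, C) == pytest.approx(0.6496,
                                                                 abs=1e-3)

    def test_clamped_to_unit_interval(self):
        x = np.linspace(0.0, 800.0, 400)
        s = phys.kelman_saturation(x, C)
        assert (s >= 0).all() and (s <= 1).all()

    def test_slope_zero_in_clamped_region(self):
        # raw rational dips below zero under ~4 mmHg
        assert phys.kelman_slope(1.0, C) == 0.0
        assert phys.kelman_slope(34.31, C) > 0


class TestOxygenSaturation:
    def test_inlet_saturation_reference(self):
        assert round(phys.so2(35.9, 44.0, P, C), 2) == 0.65

    def test_zero_po2_gives_zero(self):
        assert phys.so2(0.0, 44.0, P, C) == 0.0

    def test_bohr_direction(self):
        assert phys.so2(35.9, 60.0, P, C) < phys.so2(35.9, 44.0, P, C)

    def test_degenerates_to_bare_kelman_without_bohr_terms(self):
        po2 = np.array([10.0, 35.9, 80.0])
        bare = phys.kelman_saturation(po2, C)
        off = phys.so2(po2, np.full_like(po2, 90.0), P, C,
                       bohr_coeffs=(0.0, 0.0, 0.0))
        np.testing.assert_allclose(off, bare, rtol=1e-12)


class TestHaldaneAdjustment:
    def test_identity_at_standard_conditions(self):
        assert phys.adjusted_pco2(40.0, 37.0, 7.4, 100.0) == pytest.approx(40.0)

    def test_reference_venous_point(self):
        assert phys.adjusted_pco2(40.0, 37.0, 7.357, 35.9) == pytest.approx(
            34.640, abs=1e-3)

    def test_rising_po2_lowers_adjusted_pco2(self):
        a = phys.adjusted_pco2(40.0, 37.0, 7.4, 100.0)
        b = phys.adjusted_pco2(40.0, 37.0, 7.4, 300.0)
        assert b < a


class TestCO2Saturation:
    def test_half_saturation_at_p50(self):
        assert phys.hill_sco2(265.0, C) == pytest.approx(0.5, rel=1e-12)

    def test_standard_conditions_value(self):
        s = phys.sco2(40.0, 100.0, 7.4, 37.0, C, P)
        assert s == pytest.approx(0.13240, abs=2e-5)

    def test_zero_pressure(self):
        assert phys.hill_sco2(0.0, C) == 0.0
        assert phys.sco2(0.0, 100.0, 7.4, 37.0, C, P) < 0.01  # clamped floor

    def test_monotone_in_pco2_at_fixed_ph(self):
        grid = np.linspace(1.0, 150.0, 50)
        s = phys.sco2(grid, np.full_like(grid, 100.0), 7.4, 37.0, C, P)
        assert (np.diff(s) > 0).all()

    def test_degenerates_to_bare_hill_without_haldane_terms(self):
        pco2 = np.array([10.0, 40.0, 90.0])
        bare = phys.hill_sco2(pco2, C)
        off = phys.sco2(pco2, np.full_like(pco2, 40.0), 7.1, 30.0, C, P,
                        haldane_coeffs=(0.0, 0.0, 0.0))
        np.testing.assert_allclose(off, bare, rtol=1e-12)


class TestDerivatives:
    @pytest.mark.parametrize("po2", [20.0, 35.9, 80.0])
    def test_dso2_dpo2_matches_finite_difference(self, po2):
        ana = phys.dso2_dpo2(po2, 44.0, P, C)
        num = central_diff(lambda x: phys.so2(x, 44.0, P, C), po2)
        assert ana == pytest.approx(num, rel=1e-6)
        assert ana > 0

    def test_dso2_dpo2_vanishes_on_plateau(self):
        assert phys.dso2_dpo2(600.0, 44.0, P, C) < 1e-5
        assert phys.dso2_dpo2(600.0, 44.0, P, C) < \
            1e-3 * phys.dso2_dpo2(35.9, 44.0, P, C)
        grid = np.linspace(5.0, 150.0, 30)
        assert (np.asarray(phys.dso2_dpo2(grid, np.full_like(grid, 44.0),
                                          P, C)) > 0).all()

    @pytest.mark.parametrize("pco2", [10.0, 40.0, 44.0])
    def test_dsco2_dpco2_frozen_ph_matches_finite_difference(self, pco2):
        ph = phys.solve_acid_base(pco2, P).pH
        ana = phys.dsco2_dpco2(pco2, 35.9, P, C, mode="frozen_pH")
        num = central_diff(lambda x: phys.sco2(x, 35.9, ph, P.T, C, P), pco2)
        assert ana == pytest.approx(num, rel=1e-6)
        assert ana > 0

    @pytest.mark.parametrize("pco2", [10.0, 40.0, 44.0])
    def test_dsco2_dpco2_buffer_line_matches_finite_difference(self, pco2):
        def s_along_buffer(x):
            ph = phys.solve_acid_base(x, P).pH
            return phys.sco2(x, 35.9, ph, P.T, C, P)
        ana = phys.dsco2_dpco2(pco2, 35.9, P, C, mode="buffer_line")
        num = central_diff(s_along_buffer, pco2)
        assert ana == pytest.approx(num, rel=1e-6)

    def test_frozen_ph_slope_is_hill_chain_at_standard_state(self):
        # at T=37, pH=7.4, PO2=100 the Haldane factor is 1, so the frozen-pH
        # slope is the bare Hill derivative
        params74 = BloodParameters(pKa=6.082)
        pco2 = 24.4 / (0.0307 * 10 ** (7.4 - params74.pKa))
        ana = phys.dsco2_dpco2(pco2, 100.0, params74, C, mode="frozen_pH")
        hill = phys.hill_slope(pco2, C)
        assert ana == pytest.approx(hill, rel=1e-9)

    @pytest.mark.parametrize("pco2", [20.0, 44.0, 80.0])
    def test_dchco3_dpco2_matches_finite_difference(self, pco2):
        ana = phys.dchco3_dpco2(pco2, P)
        num = central_diff(lambda x: phys.solve_acid_base(x, P).C_HCO3_ml,
                           pco2)
        assert ana == pytest.approx(num, rel=1e-6)

    def test_dchco3_positive_across_range(self):
        grid = np.linspace(1.0, 250.0, 60)
        assert (np.asarray(phys.dchco3_dpco2(grid, P)) > 0).all()

    def test_dchco3_vanishes_for_zero_buffer_power(self):
        # beta_NC -> 7.7 is the Hb=0 floor; emulate beta -> 0 by checking the
        # analytic form scales with beta
        d1 = phys.dchco3_dpco2(44.0, BloodParameters(Hb=0.0))
        d2 = phys.dchco3_dpco2(44.0, BloodParameters(Hb=0.118))
        assert 0 < d1 < d2


class TestContents:
    def test_o2_content_zero_at_zero_po2(self):
        # the evaluation floor (0.01 mmHg) leaves only a vanishing dissolved
        # contribution
        assert phys.o2_content(0.0, 44.0, P, C) == pytest.approx(0.0, abs=1e-6)

    def test_o2_content_reference_value(self):
        assert phys.o2_content(35.9, 44.0, P, C) == pytest.approx(0.10380,
                                                                  abs=2e-5)

    def test_o2_content_increasing_in_po2(self):
        grid = np.linspace(1.0, 300.0, 60)
        c = np.asarray(phys.o2_content(grid, np.full_like(grid, 44.0), P, C))
        assert (np.diff(c) > 0).all()

    def test_co2_content_variants_differ_by_correction_strength(self):
        kel = phys.co2_content(44.0, 35.9, P, C, variant="kelman_grouping")
        pri = phys.co2_content(44.0, 35.9, P, C, variant="as_printed")
        assert kel == pytest.approx(0.49482, abs=5e-5)
        assert pri == pytest.approx(0.55941, abs=5e-5)
        assert kel < pri  # stronger correction removes more CO2 capacity

    def test_co2_content_chained_hand_formula(self):
        # independent chain: acid-base -> Kelman saturation -> McHardy factor
        ab = phys.solve_acid_base(44.0, P)
        s = phys.so2(35.9, 44.0, P, C)
        expected = ab.C_HCO3_ml * (
            1 - 0.02924 * 11.8 / ((2.244 - 0.422 * s) * (8.74 - ab.pH)))
        assert phys.co2_content(44.0, 35.9, P, C) == pytest.approx(
            expected, rel=1e-12)

    def test_haldane_direction_in_content(self):
        lo = phys.co2_content(44.0, 35.9, P, C)
        hi = phys.co2_content(44.0, 150.0, P, C)
        assert hi < lo

    def test_zero_correction_returns_bicarbonate(self):
        ab = phys.solve_acid_base(44.0, BloodParameters(Hb=0.0))
        got = phys.co2_content(44.0, 35.9, BloodParameters(Hb=0.0), C)
        assert got == pytest.approx(ab.C_HCO3_ml, rel=1e-12)

    def test_dissolved_co2_optional(self):
        base = phys.co2_content(44.0, 35.9, P, C)
        plus = phys.co2_content(44.0, 35.9, P, C, include_dissolved=True)
        assert plus == pytest.approx(base + C.alpha_CO2_ml * 44.0, rel=1e-12)


class TestEffectiveDiffusivities:
    def test_deff_o2_weighted_mean_formula(self):
        slope = phys.dso2_dpo2(35.9, 44.0, P, C)
        w2 = C.k_O2 * P.Hb * slope
        expected = (C.D_O2 * C.alpha_O2 + C.D_HbO2 * w2) / (C.alpha_O2 + w2)
        assert phys.deff_o2(35.9, 44.0, P, C) == pytest.approx(expected,
                                                               rel=1e-12)
        assert min(C.D_O2, C.D_HbO2) < expected < max(C.D_O2, C.D_HbO2)

    def test_deff_o2_plateau_limit_is_free_diffusivity(self):
        assert phys.deff_o2(700.0, 44.0, P, C) == pytest.approx(C.D_O2,
                                                                rel=1e-2)

    def test_deff_o2_equal_endpoint_collapse(self):
        c_eq = GasTransportConstants(D_HbO2=C.D_O2)
        assert phys.deff_o2(35.9, 44.0, P, c_eq) == pytest.approx(C.D_O2,
                                                                  rel=1e-12)

    def test_deff_co2_three_pool_weighted_mean(self):
        d, (w1, w2, w3) = phys.deff_co2(44.0, 35.9, P, C, return_weights=True)
        expected = (C.D_CO2 * w1 + C.D_HbCO2 * w2 + C.D_HCO3 * w3) / (
            w1 + w2 + w3)
        assert d == pytest.approx(expected, rel=1e-12)
        assert w1 > 0 and w3 > 0

    def test_deff_co2_bounds(self, physiological_grid):
        po2, pco2 = physiological_grid
        d = np.asarray(phys.deff_co2(pco2, po2, P, C))
        assert (d >= min(C.D_CO2, C.D_HbCO2, C.D_HCO3)).all()
        assert (d <= max(C.D_CO2, C.D_HbCO2, C.D_HCO3)).all()

    def test_deff_co2_slope_free_limit(self):
        # with carbamino and bicarbonate weights suppressed the CO2
        # diffusivity must collapse to the dissolved-gas value
        d, (w1, w2, w3) = phys.deff_co2(44.0, 35.9, BloodParameters(Hb=0.0),
                                        C, return_weights=True)
        manual = (C.D_CO2 * w1 + C.D_HbCO2 * w2 + C.D_HCO3 * w3) / (w1 + w2 + w3)
        assert d == pytest.approx(manual, rel=1e-12)


class TestSourceTerms:
    def test_paper_mode_is_zero(self):
        assert phys.source_terms(35.9, 44.0, P, C, mode="paper") == (0.0, 0.0)

    def test_diagnostic_mode_zero_gradient(self):
        s1, s2 = phys.source_terms(35.9, 44.0, P, C, mode="diagnostic",
                                   grad_po2_sq=0.0, grad_pco2_sq=0.0)
        assert s1 == pytest.approx(0.0, abs=1e-30)
        assert s2 == pytest.approx(0.0, abs=1e-30)

    def test_diagnostic_mode_linear_in_gradient_magnitude(self):
        s1, _ = phys.source_terms(35.9, 44.0, P, C, mode="diagnostic",
                                  grad_po2_sq=1e6)
        s2, _ = phys.source_terms(35.9, 44.0, P, C, mode="diagnostic",
                                  grad_po2_sq=2e6)
        assert np.isfinite(s1) and np.isfinite(s2)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-9)


class TestEvaluateState:
    def test_state_fields_consistent(self, physiological_grid):
        po2, pco2 = physiological_grid
        st = phys.evaluate_state(po2, pco2, P, C)
        assert ((np.asarray(st.SO2) >= 0) & (np.asarray(st.SO2) <= 1)).all()
        assert ((np.asarray(st.SCO2) >= 0) & (np.asarray(st.SCO2) <= 1)).all()
        assert (np.asarray(st.C_O2) >= 0).all()
        assert (np.asarray(st.C_CO2) >= 0).all()
        np.testing.assert_allclose(
            np.asarray(st.Deff_O2),
            np.asarray(phys.deff_o2(po2, pco2, P, C)), rtol=1e-12)

    def test_clamp_events_counted(self):
        st = phys.evaluate_state(np.array([0.0, 50.0]), np.array([0.0, 40.0]),
                                 P, C)
        assert st.n_clamped_po2 == 1
        assert st.n_clamped_pco2 == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(po2=st.floats(1.0, 200.0), pco2=st.floats(5.0, 120.0),
       dpo2=st.floats(0.5, 50.0), dpco2=st.floats(0.5, 50.0))
def test_saturation_monotonicity_properties(po2, pco2, dpo2, dpco2):
    """Bohr/Haldane directions hold across random physiological states."""
    assert phys.so2(po2 + dpo2, pco2, P, C) >= phys.so2(po2, pco2, P, C)
    assert phys.so2(po2, pco2 + dpco2, P, C) <= phys.so2(po2, pco2, P, C)
    ph = 7.35
    assert phys.sco2(pco2 + dpco2, po2, ph, P.T, C, P) >= \
        phys.sco2(pco2, po2, ph, P.T, C, P)
    assert phys.sco2(pco2, po2 + dpo2, ph, P.T, C, P) <= \
        phys.sco2(pco2, po2, ph, P.T, C, P)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(pco2=st.floats(1.0, 240.0))
def test_acid_base_invariants_random_states(pco2):
    s = phys.solve_acid_base(pco2, P)
    assert s.residual <= 1e-10
    assert 5.5 < s.pH < 8.4
    assert s.C_HCO3_mmol > 0
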