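"""Thermodynamic identities, unit conversions and the heat-capacity fit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from itcthermo import (
    BindingParameters,
    delta_g_from_k,
    derive_profile,
    ds_b_from_entropy_term,
    entropy_term,
    fit_delta_cp,
    kd_from_kb,
    round_half_away,
)


class TestDeltaG:
    @pytest.mark.parametrize(
        "k_mM, temp_c, expected, decimals",
        [
            (64.0, 30.0, -6.67, 2),  # micromolar-affinity nucleotide complex
            (1e-3, 30.0, 0.0, 9),  # 1 M^-1: the standard-state reference
            (288.0, 30.0, -7.6, 1),  # effector-protein complex
        ],
    )
    def test_reference_values(self, constants, k_mM, temp_c, expected, decimals):
        assert delta_g_from_k(k_mM, temp_c, constants) == pytest.approx(
            expected, abs=0.5 * 10**-decimals
        )

    def test_rejects_nonpositive_k(self, constants):
        with pytest.raises(ValueError):
            delta_g_from_k(0.0, 30.0, constants)
        with pytest.raises(ValueError):
            delta_g_from_k(-5.0, 30.0, constants)

    @given(st.floats(min_value=-4, max_value=8), st.floats(min_value=5.0, max_value=60.0))
    def test_round_trip_through_k(self, constants, log10_k, temp_c):
        """Solving -RT ln K back for K reproduces the input to 1e-9 relative."""
        k = 10.0**log10_k
        dg = delta_g_from_k(k, temp_c, constants)
        k_back = math.exp(-dg / constants.rt_kcal(temp_c)) / 1e3
        assert k_back == pytest.approx(k, rel=1e-9)


class TestEntropyTerm:
    @pytest.mark.parametrize(
        "dg, dh, expected",
        [(-6.67, 1.07, -7.74), (-3.3, -3.3, 0.0), (-7.6, -6.3, -1.3)],
    )
    def test_gibbs_identity_values(self, dg, dh, expected):
        assert entropy_term(dg, dh) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "mtds, temp_c, expected",
        [(-2.20, 30.0, 7.26), (0.0, 17.0, 0.0), (-7.74, 30.0, 25.5)],
    )
    def test_entropy_unit_conversion(self, mtds, temp_c, expected):
        assert ds_b_from_entropy_term(mtds, temp_c) == pytest.approx(expected, abs=0.05)


class TestKd:
    @pytest.mark.parametrize(
        "k_mM, expected_uM", [(64.0, 15.6), (1000.0, 1.0), (288.0, 3.47)]
    )
    def test_reciprocal_conversion(self, k_mM, expected_uM):
        assert kd_from_kb(k_mM) == pytest.approx(expected_uM, abs=0.05)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kd_from_kb(-1.0)


class TestProfile:
    @given(
        st.floats(min_value=-3, max_value=6),
        st.floats(min_value=-15, max_value=15),
        st.floats(min_value=5.0, max_value=45.0),
    )
    def test_gibbs_relation_holds_exactly(self, constants, log10_k, dh, temp_c):
        bp = BindingParameters("p", temp_c, K_mM=10.0**log10_k, dH_kcal=dh)
        prof = derive_profile(bp, constants)
        assert abs(prof.dG_kcal - (prof.dH_kcal + prof.minus_TdS_kcal)) < 1e-9

    def test_favourable_binding_has_negative_dg(self, constants):
        prof = derive_profile(BindingParameters("p", 30.0, K_mM=64.0, dH_kcal=1.0), constants)
        assert prof.dG_kcal < 0


class TestCpFit:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([(25, -6.6), (30, -7.7), (35, -9.1)], -250.0),
            ([(25, -4.3), (30, -6.3), (35, -8.7)], -440.0),
            ([(25, 2.0), (30, 2.0), (35, 2.0)], 0.0),
        ],
    )
    def test_slope_values(self, series, expected):
        assert fit_delta_cp(series).dCp_cal == pytest.approx(expected, abs=1e-9)

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError):
            fit_delta_cp([(30.0, -5.0), (30.0, -5.1)])

    def test_agrees_with_two_point_slope_oracle(self):
        """On 3 equally spaced points the OLS slope equals (y3-y1)/(T3-T1)."""
        series = [(25.0, 1.04), (30.0, 1.07), (35.0, 1.12)]
        oracle = (1.12 - 1.04) / 10.0 * 1000.0
        assert fit_delta_cp(series).dCp_cal == pytest.approx(oracle, abs=1e-12)

    @given(
        st.permutations([(25.0, -3.1), (30.0, -4.1), (35.0, -5.8)]),
        st.floats(min_value=-50, max_value=50),
    )
    def test_invariant_to_permutation_and_offset(self, perm, offset):
        base = fit_delta_cp([(25.0, -3.1), (30.0, -4.1), (35.0, -5.8)]).dCp_cal
        shifted = fit_delta_cp([(t, h + offset) for t, h in perm]).dCp_cal
        assert shifted == pytest.approx(base, abs=1e-9)


@pytest.mark.parametrize(
    "value, decimals, expected",
    [(0.5, 0, 1.0), (-0.5, 0, -1.0), (2.25, 1, 2.3), (-2.25, 1, -2.3), (21.2, 0, 21.0)],
)
def test_round_half_away(value, decimals, expected):
    assert round_half_away(value, decimals) == expected
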