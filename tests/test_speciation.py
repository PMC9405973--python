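"""Speciation solvers against independent bisection/grid oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from itcthermo import (
    MgCouplingConstants,
    apparent_constant,
    solve_binary_speciation,
    solve_mg_nucleotide,
    solve_ternary,
)

MGC = MgCouplingConstants(K_MgG=1e4, K_Mg2G=1e2)


from oracles import binary_oracle, ternary_oracle


class TestBinary:
    def test_stoichiometric_limit(self):
        _, _, c = solve_binary_speciation(10e-6, 25e-6, 1e15)
        assert c == pytest.approx(10e-6, rel=1e-6)

    def test_effector_excess_saturates_protein(self):
        """8-fold effector excess over a ~3.4 uM Kd leaves >80 % protein bound."""
        e, _, c = solve_binary_speciation(40e-6, 320e-6, 1.0 / 3.4e-6)
        assert c / 40e-6 > 0.80

    def test_matches_bisection_oracle(self):
        _, _, c = solve_binary_speciation(10e-6, 10e-6, 1e5)
        assert c == pytest.approx(binary_oracle(10e-6, 10e-6, 1e5), rel=1e-10)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            solve_binary_speciation(-1e-6, 1e-6, 1e5)

    @given(
        st.floats(min_value=1e-8, max_value=1e-3),
        st.floats(min_value=1e-8, max_value=1e-2),
        st.floats(min_value=1.0, max_value=1e9),
    )
    def test_mass_balance_and_positivity(self, e_tot, g_tot, k):
        e, g, c = solve_binary_speciation(e_tot, g_tot, k)
        assert min(e, g, c) >= 0
        assert e + c == pytest.approx(e_tot, rel=1e-10)
        assert g + c == pytest.approx(g_tot, rel=1e-10)


class TestMgNucleotide:
    def test_no_metal(self):
        g, mgg, mg2g, m = solve_mg_nucleotide(2e-3, 0.0, MGC)
        assert (mgg, mg2g, m) == (0.0, 0.0, 0.0)
        assert g == pytest.approx(2e-3)

    def test_diphosphate_never_binds_second_ion(self):
        gdp = MgCouplingConstants(K_MgG=10**3.5, K_Mg2G=0.0)
        _, _, mg2g, _ = solve_mg_nucleotide(2e-3, 50e-3, gdp)
        assert mg2g == 0.0

    def test_matches_nested_bisection_oracle(self):
        g, mgg, mg2g, m = solve_mg_nucleotide(2e-3, 5e-3, MGC)
        ref = ternary_oracle(0.0, 2e-3, 5e-3, 0.0, 0.0, MGC)
        assert g == pytest.approx(ref["G"], rel=1e-8)
        assert mgg == pytest.approx(ref["MgG"], rel=1e-8)
        assert mg2g == pytest.approx(ref["Mg2G"], rel=1e-8)
        assert m == pytest.approx(ref["Mg"], rel=1e-8)


class TestTernary:
    def test_no_metal_reduces_to_binary(self):
        st_ = solve_ternary(40e-6, 500e-6, 0.0, 1.56e5, 6.4e4, MGC)
        _, _, c = solve_binary_speciation(40e-6, 500e-6, 1.56e5)
        assert st_.EG == pytest.approx(c, rel=1e-10)
        assert st_.EMG == 0.0

    def test_indistinguishable_ligand_limit(self):
        """With K_EMG = K_EG and no Mg2G, bound protein equals the binary
        solution applied to the total nucleotide pool."""
        mgc = MgCouplingConstants(K_MgG=1e4, K_Mg2G=0.0)
        st_ = solve_ternary(40e-6, 500e-6, 5e-3, 1e5, 1e5, mgc)
        _, _, c = solve_binary_speciation(40e-6, 500e-6, 1e5)
        assert st_.bound_protein == pytest.approx(c, rel=1e-8)

    def test_reference_condition_matches_oracle(self):
        mgc = MgCouplingConstants(K_MgG=1e4, K_Mg2G=0.0)
        st_ = solve_ternary(40e-6, 500e-6, 5e-3, 1.56e5, 6.4e4, mgc)
        ref = ternary_oracle(40e-6, 500e-6, 5e-3, 1.56e5, 6.4e4, mgc)
        for name in ("E", "G", "Mg", "MgG", "EG", "EMG"):
            assert getattr(st_, name) == pytest.approx(ref[name], rel=1e-6)

    def test_mass_balances_to_1e10(self):
        st_ = solve_ternary(40e-6, 2e-3, 5e-3, 1.56e5, 6.4e4, MGC)
        assert st_.total_protein == pytest.approx(40e-6, rel=1e-10)
        assert st_.total_nucleotide == pytest.approx(2e-3, rel=1e-10)
        assert st_.total_mg == pytest.approx(5e-3, rel=1e-10)

    def test_continuity_in_totals(self):
        base = solve_ternary(40e-6, 500e-6, 5e-3, 1.56e5, 6.4e4, MGC)
        bumped = solve_ternary(40e-6 + 1e-9, 500e-6, 5e-3, 1.56e5, 6.4e4, MGC)
        for name in ("E", "G", "Mg", "MgG", "Mg2G", "EG", "EMG"):
            a, b = getattr(base, name), getattr(bumped, name)
            if a > 0:
                assert abs(b - a) / a < 1e-4

    def test_rejects_negative_totals(self):
        with pytest.raises(ValueError):
            solve_ternary(-1e-6, 1e-3, 1e-3, 1e5, 1e5, MGC)


class TestApparentConstant:
    def test_zero_metal_gives_intrinsic(self):
        assert apparent_constant(1.56e5, 6.4e4, 0.0, MGC) == 1.56e5

    def test_saturating_metal_tends_to_metal_bound_constant(self):
        mgc = MgCouplingConstants(K_MgG=1e4, K_Mg2G=0.0)
        k = apparent_constant(1.56e5, 6.4e4, 10.0, mgc)
        assert k == pytest.approx(6.4e4, rel=1e-3)

    def test_consistent_with_trace_protein_speciation(self):
        mgc = MgCouplingConstants(K_MgG=1e4, K_Mg2G=1e2)
        state = solve_ternary(1e-12, 500e-6, 5e-3, 1.56e5, 6.4e4, mgc)
        ratio = (state.EG + state.EMG) / (state.E * (state.G + state.MgG + state.Mg2G))
        assert ratio == pytest.approx(
            apparent_constant(1.56e5, 6.4e4, state.Mg, mgc), rel=1e-6
        )

    @given(st.lists(st.floats(min_value=1e-6, max_value=0.1), min_size=2, max_size=6))
    def test_monotone_decreasing_when_metal_weakens_binding(self, mg_levels):
        mgc = MgCouplingConstants(K_MgG=1e4, K_Mg2G=0.0)
        ks = [apparent_constant(1.56e5, 6.4e4, m, mgc) for m in sorted(mg_levels)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))
        ks_up = [apparent_constant(6.4e4, 1.56e5, m, mgc) for m in sorted(mg_levels)]
        assert all(a <= b for a, b in zip(ks_up, ks_up[1:]))
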