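"""Forward injection-heat model and nonlinear isotherm fitting."""

import numpy as np
import pytest
from scipy.optimize import brentq

from itcthermo import (
    BindingParameters,
    GeneratorSpec,
    MgCouplingConstants,
    TitrationProtocol,
    apparent_constant,
    fit_one_site,
    fit_ternary,
    generate_coupled_pair,
    generate_isotherm,
    predict_injection_heats,
    solve_ternary,
    subtract_dilution,
)
from itcthermo.itc import _cell_totals, read_isotherm_csv, write_isotherm_csv

TRUTH = BindingParameters("truth", 30.0, K_mM=64.0, dH_kcal=1.07)


class TestForwardModel:
    def test_zero_enthalpy_gives_zero_heats(self, protocol):
        iso = predict_injection_heats(protocol, BindingParameters("z", 30.0, K_mM=64.0, dH_kcal=0.0))
        assert np.allclose(iso.ndh_kcal_per_mol, 0.0)

    def test_heat_conservation_at_saturation(self, protocol):
        """At >=99 % saturation the summed heat equals n*dH*(cell protein moles)."""
        tight = BindingParameters("t", 30.0, K_mM=1e6, dH_kcal=-5.0)
        iso = predict_injection_heats(protocol, tight)
        total_kcal = iso.raw_heat_ucal.sum() * 1e-9
        expected = tight.n * tight.dH_kcal * (protocol.cell_protein_uM * 1e-6) * (
            protocol.cell_volume_uL * 1e-6
        )
        assert total_kcal == pytest.approx(expected, rel=0.01)

    def test_per_injection_heats_match_rootfinding_oracle(self, protocol):
        """The closed-form quadratic route agrees with an independent
        bisection solution of the binding polynomial per injection."""
        iso = predict_injection_heats(protocol, TRUTH)
        e_tot, g_tot, _ = _cell_totals(protocol)
        k = TRUTH.K_mM * 1e3
        v0 = protocol.cell_volume_uL * 1e-6
        prev = 0.0
        for i, dv_uL in enumerate(protocol.injection_volumes_uL):
            c = brentq(
                lambda c: k * (e_tot[i] - c) * (g_tot[i] - c) - c,
                0.0,
                min(e_tot[i], g_tot[i]),
                xtol=1e-30,
                rtol=1e-15,
            )
            dv = dv_uL * 1e-6
            q = TRUTH.dH_kcal * (v0 * (c - prev) + dv * 0.5 * (c + prev))
            ndh = q / (dv * protocol.syringe_ligand_mM * 1e-3)
            assert iso.ndh_kcal_per_mol[i] == pytest.approx(ndh, rel=1e-8)
            prev = c

    def test_partition_invariance_in_negligible_displacement_limit(self):
        """Cumulative heat is independent of how injections are split once the
        displaced volume is negligible; at real geometry the displacement
        bookkeeping makes partitioning matter only at the 1e-3 level."""
        for v0, tol in ((2e5, 1e-9), (200.0, 1e-2)):
            a = TitrationProtocol(cell_volume_uL=v0, discard_first=False)
            b = TitrationProtocol(
                cell_volume_uL=v0,
                injection_volumes_uL=(4.0,) + (2.0,) * 17,
                discard_first=False,
            )
            qa = predict_injection_heats(a, TRUTH).raw_heat_ucal.sum()
            qb = predict_injection_heats(b, TRUTH).raw_heat_ucal.sum()
            assert abs(qa - qb) / abs(qa) < tol

    def test_wiseman_limit(self):
        """As injections shrink, the normalised heat tends to the closed-form
        Wiseman derivative evaluated at the (diluted) cell composition."""
        k, dh = 64e3, 1.07
        errors = []
        for n_inj, dv in ((19, 2.0), (190, 0.2), (1900, 0.02)):
            p = TitrationProtocol(injection_volumes_uL=(dv,) * n_inj, discard_first=False)
            iso = predict_injection_heats(p, TRUTH)
            e_tot, g_tot, _ = _cell_totals(p)
            xr = g_tot / e_tot
            r = 1.0 / (k * e_tot)
            wiseman = dh * (0.5 + (1 - xr - r) / (2 * np.sqrt((1 + xr + r) ** 2 - 4 * xr)))
            i = int(np.argmin(np.abs(xr - 1.0)))
            errors.append(abs(iso.ndh_kcal_per_mol[i] - wiseman[i]) / abs(wiseman[i]))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 5e-3

    def test_zero_ligand_warns_and_returns_zero(self):
        p = TitrationProtocol(syringe_ligand_mM=0.0)
        with pytest.warns(UserWarning, match="zero ligand"):
            iso = predict_injection_heats(p, TRUTH)
        assert np.allclose(iso.ndh_kcal_per_mol, 0.0)


class TestSubtractDilution:
    def test_zero_blank_is_identity(self, protocol):
        sample = predict_injection_heats(protocol, TRUTH)
        blank = predict_injection_heats(
            protocol, BindingParameters("b", 30.0, K_mM=64.0, dH_kcal=0.0)
        )
        out = subtract_dilution(sample, blank)
        assert np.allclose(out.ndh_kcal_per_mol, sample.ndh_kcal_per_mol)
        assert out.blank_subtracted

    def test_sample_equal_blank_gives_zero(self, protocol):
        sample = predict_injection_heats(protocol, TRUTH)
        assert np.allclose(subtract_dilution(sample, sample).ndh_kcal_per_mol, 0.0)

    def test_schedule_mismatch_raises(self, protocol):
        sample = predict_injection_heats(protocol, TRUTH)
        other = predict_injection_heats(
            TitrationProtocol(injection_volumes_uL=(2.0,) * 15), TRUTH
        )
        with pytest.raises(ValueError):
            subtract_dilution(sample, other)

    def test_constant_offset_blank_recovers_model(self, protocol):
        """A generator blank with a constant dilution offset subtracts away."""
        spec = GeneratorSpec(
            truth=TRUTH, protocol=protocol, noise_sd_ucal=0.02, blank_offset_ucal=0.2, seed=1
        )
        sample, blank = generate_isotherm(spec)
        model = predict_injection_heats(protocol, TRUTH)
        corrected = subtract_dilution(sample, blank)
        resid = corrected.raw_heat_ucal - model.raw_heat_ucal
        assert np.all(np.abs(resid) < 6 * 0.02 * np.sqrt(2))


class TestOneSiteFit:
    def test_noise_free_self_consistency(self, protocol):
        iso = predict_injection_heats(protocol, TRUTH)
        fit = fit_one_site(iso, protocol)
        assert fit.n == pytest.approx(1.0, rel=1e-6)
        assert fit.K_mM == pytest.approx(64.0, rel=1e-6)
        assert fit.dH_kcal == pytest.approx(1.07, rel=1e-6)

    def test_scale_consistency(self, protocol):
        """Scaling all heats rescales dH and leaves K unchanged."""
        iso = predict_injection_heats(protocol, TRUTH)
        scaled = predict_injection_heats(
            protocol, BindingParameters("s", 30.0, K_mM=64.0, dH_kcal=3 * 1.07)
        )
        f1, f2 = fit_one_site(iso, protocol), fit_one_site(scaled, protocol)
        assert f2.K_mM == pytest.approx(f1.K_mM, rel=1e-8)
        assert f2.dH_kcal == pytest.approx(3 * f1.dH_kcal, rel=1e-8)

    def test_cross_model_consistency_with_apparent_constant(self):
        """An isotherm generated by the ternary model, fitted one-site at
        fixed 5 mM Mg, returns the Mg-averaged apparent constant."""
        mgc = MgCouplingConstants(K_MgG=1e4, K_Mg2G=0.0)
        p = TitrationProtocol(total_mg_mM=5.0)
        eg = BindingParameters("EG", 30.0, K_mM=156.0, dH_kcal=1.7)
        emg = BindingParameters("EMG", 30.0, K_mM=64.0, dH_kcal=1.07)
        iso = predict_injection_heats(p, eg, mode="ternary", mg_constants=mgc, params_mg=emg)
        fit = fit_one_site(iso, p)
        trace = solve_ternary(1e-12, 1e-12, 5e-3, 156e3, 64e3, mgc)
        k_app = apparent_constant(156e3, 64e3, trace.Mg, mgc) / 1e3
        assert fit.K_mM == pytest.approx(k_app, rel=0.05)

    def test_low_c_value_warns(self):
        p = TitrationProtocol(cell_protein_uM=0.1)
        weak = BindingParameters("w", 30.0, K_mM=1.0, dH_kcal=-2.0)
        iso = predict_injection_heats(p, weak)
        with pytest.warns(UserWarning, match="c-value"):
            fit_one_site(iso, p, init=weak, fix_n=1.0)

    def test_too_few_injections_rejected(self):
        p = TitrationProtocol(injection_volumes_uL=(2.0,) * 5)
        iso = predict_injection_heats(p, TRUTH)
        with pytest.raises(ValueError, match="injections"):
            fit_one_site(iso, p)


class TestTernaryFit:
    MGC = MgCouplingConstants(K_MgG=1e4, K_Mg2G=0.0)
    EG = BindingParameters("EG", 30.0, K_mM=156.0, dH_kcal=1.7)
    EMG = BindingParameters("EMG", 30.0, K_mM=64.0, dH_kcal=1.07)

    def _pair(self, noise, seed):
        base = GeneratorSpec(
            truth=self.EG, protocol=TitrationProtocol(), noise_sd_ucal=noise, seed=seed
        )
        spec_no, spec_mg = generate_coupled_pair(self.EG, self.EMG, self.MGC, base)
        return spec_no, spec_mg

    def test_noise_free_round_trip(self):
        spec_no, spec_mg = self._pair(0.0, 0)
        iso_no, _ = generate_isotherm(spec_no)
        iso_mg, _ = generate_isotherm(spec_mg)
        fit = fit_ternary(iso_mg, iso_no, spec_mg.protocol, spec_no.protocol, self.MGC)
        assert fit.K_EG_mM == pytest.approx(156.0, rel=1e-4)
        assert fit.K_EMG_mM == pytest.approx(64.0, rel=1e-4)
        assert fit.dH_EG_kcal == pytest.approx(1.7, rel=1e-4)
        assert fit.dH_EMG_kcal == pytest.approx(1.07, rel=1e-4)

    def test_noisy_kappa_recovery(self):
        """At 0.05 ucal noise the cooperativity ratio is recovered within 25 %."""
        spec_no, spec_mg = self._pair(0.05, 7)
        iso_no, _ = generate_isotherm(spec_no)
        iso_mg, _ = generate_isotherm(spec_mg)
        fit = fit_ternary(iso_mg, iso_no, spec_mg.protocol, spec_no.protocol, self.MGC)
        true_kappa = 64.0 / 156.0
        assert fit.kappa == pytest.approx(true_kappa, rel=0.25)

    def test_identical_conditions_rejected(self):
        spec_no, _ = self._pair(0.0, 0)
        iso_no, _ = generate_isotherm(spec_no)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_ternary(iso_no, iso_no, spec_no.protocol, spec_no.protocol, self.MGC)

    def test_temperature_mismatch_rejected(self):
        spec_no, spec_mg = self._pair(0.0, 0)
        iso_no, _ = generate_isotherm(spec_no)
        iso_mg, _ = generate_isotherm(spec_mg)
        from dataclasses import replace

        with pytest.raises(ValueError, match="temperature"):
            fit_ternary(
                iso_mg,
                iso_no,
                replace(spec_mg.protocol, temperature_c=25.0),
                spec_no.protocol,
                self.MGC,
            )


def test_isotherm_csv_round_trip(tmp_path, protocol):
    iso = predict_injection_heats(protocol, TRUTH)
    path = tmp_path / "iso.csv"
    write_isotherm_csv(iso, path)
    back = read_isotherm_csv(path)
    assert np.allclose(back.ndh_kcal_per_mol, iso.ndh_kcal_per_mol)
    assert np.allclose(back.injection_volumes_uL, iso.injection_volumes_uL)
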