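"""Heterotropic cooperativity cycles.

The mutual effect of two different ligands (e.g. Mg(2+) and a nucleotide, or
an effector protein and a nucleotide) on binding to the same macromolecule
is quantified by the cooperativity constant kappa = K_num / K_den, the ratio
of the association constants of one ligand with and without the other.  The
derived cycle energetics follow from

    dg = -RT ln kappa,    dh = dH_num - dH_den,    -T ds = dg - dh.

kappa > 1 means the two ligands stabilise each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import EnergeticConstants
from .thermo import BindingParameters

__all__ = ["CoopCycle", "ClosureReport", "heterotropic_cycle", "cycle_closure_check"]


@dataclass(frozen=True)
class CoopCycle:
    """One heterotropic cooperativity edge between two binding equilibria."""

    effect_label: str
    numerator_complex: str
    denominator_complex: str
    temperature_c: float
    kappa: float
    dg_kcal: float
    dh_kcal: float
    minus_Tds_kcal: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if abs(self.minus_Tds_kcal - (self.dg_kcal - self.dh_kcal)) > 1e-9:
            raise ValueError("-Tds = dg - dh violated")


def heterotropic_cycle(
    params_num: BindingParameters,
    params_den: BindingParameters,
    constants: EnergeticConstants,
    effect_label: str = "",
) -> CoopCycle:
    """Cooperativity parameters from two measured binding equilibria.

    Both parameter sets must refer to the same temperature; swapping
    numerator and denominator inverts kappa and flips the signs of all
    energetic terms.
    """
    if params_num.temperature_c != params_den.temperature_c:
        raise ValueError(
            f"temperature mismatch: {params_num.temperature_c} vs {params_den.temperature_c} C"
        )
    kappa = params_num.K_mM / params_den.K_mM
    dg = -constants.rt_kcal(params_num.temperature_c) * math.log(kappa)
    dh = params_num.dH_kcal - params_den.dH_kcal
    return CoopCycle(
        effect_label=effect_label or f"{params_num.complex_label}/{params_den.complex_label}",
        numerator_complex=params_num.complex_label,
        denominator_complex=params_den.complex_label,
        temperature_c=params_num.temperature_c,
        kappa=kappa,
        dg_kcal=dg,
        dh_kcal=dh,
        minus_Tds_kcal=dg - dh,
    )


@dataclass(frozen=True)
class ClosureReport:
    """Detailed-balance check of a thermodynamic square."""

    ln_k_discrepancy: float
    dh_discrepancy_kcal: float
    path_a_ln_k: float
    path_b_ln_k: float
    path_a_dh_kcal: float
    path_b_dh_kcal: float
    tolerance_ln: float
    consistent: bool


def cycle_closure_check(
    path_a: tuple[BindingParameters, BindingParameters],
    path_b: tuple[BindingParameters, BindingParameters],
    tolerance_ln: float = 0.2,
    tolerance_dh_kcal: float | None = None,
) -> ClosureReport:
    """Check detailed balance of a four-edge thermodynamic square.

    ``path_a`` and ``path_b`` are the two two-step routes connecting the same
    pair of end states (e.g. bind Sdo1 then the nucleotide, versus bind the
    nucleotide then Sdo1).  Detailed balance demands equal products of
    association constants and equal enthalpy sums along both routes; because
    kappa reciprocity is an algebraic identity, a violation beyond the
    experimental tolerance signals inconsistent measurements.  The default
    tolerance of 0.2 ln-units reflects typical 10-30 % errors on K.
    """
    temps = {p.temperature_c for p in (*path_a, *path_b)}
    if len(temps) != 1:
        raise ValueError("all four edges of the square must share a temperature")
    ln_a = sum(math.log(p.K_mM * 1e3) for p in path_a)
    ln_b = sum(math.log(p.K_mM * 1e3) for p in path_b)
    dh_a = sum(p.dH_kcal for p in path_a)
    dh_b = sum(p.dH_kcal for p in path_b)
    ln_disc = abs(ln_a - ln_b)
    dh_disc = abs(dh_a - dh_b)
    consistent = ln_disc <= tolerance_ln
    if tolerance_dh_kcal is not None:
        consistent = consistent and dh_disc <= tolerance_dh_kcal
    return ClosureReport(
        ln_k_discrepancy=ln_disc,
        dh_discrepancy_kcal=dh_disc,
        path_a_ln_k=ln_a,
        path_b_ln_k=ln_b,
        path_a_dh_kcal=dh_a,
        path_b_dh_kcal=dh_b,
        tolerance_ln=tolerance_ln,
        consistent=consistent,
    )
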