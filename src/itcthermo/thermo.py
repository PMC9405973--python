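"""Thermodynamic identities for binding equilibria and the van't Hoff heat-capacity fit.

Association constants cross the API boundary in mM^-1 (the working unit of
millimolar-scale titrations); free energies are referenced to the 1 M
standard state, so K is converted to M^-1 before taking logarithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

from .constants import EnergeticConstants, celsius_to_kelvin


@dataclass(frozen=True)
class BindingParameters:
    """Measured binding parameters of one complex at one temperature.

    ``K_mM`` is the association constant in mM^-1 and ``dH_kcal`` the binding
    enthalpy in kcal mol^-1, with their fitted standard errors; ``n`` is the
    binding stoichiometry (sites per macromolecule).
    """

    complex_label: str
    temperature_c: float
    K_mM: float
    dH_kcal: float
    n: float = 1.0
    K_err_mM: float = 0.0
    dH_err_kcal: float = 0.0

    def __post_init__(self) -> None:
        if self.K_mM <= 0:
            raise ValueError(f"association constant must be positive, got {self.K_mM}")
        if self.n <= 0:
            raise ValueError(f"stoichiometry must be positive, got {self.n}")
        if not 0.0 <= self.temperature_c <= 100.0:
            raise ValueError(f"temperature {self.temperature_c} C outside 0-100 C")


@dataclass(frozen=True)
class ThermoProfile:
    """Derived state functions of one binding equilibrium at one temperature."""

    temperature_c: float
    Kd_uM: float
    dG_kcal: float
    dH_kcal: float
    minus_TdS_kcal: float
    dS_cal: float

    def __post_init__(self) -> None:
        if abs(self.dG_kcal - (self.dH_kcal + self.minus_TdS_kcal)) > 1e-9:
            raise ValueError("dG = dH + (-TdS) violated")


@dataclass(frozen=True)
class CpFit:
    """Slope of dH_b versus temperature: the binding heat-capacity change."""

    dCp_cal: float
    dCp_err_cal: float
    dH_at_Tref_kcal: float
    Tref_c: float
    r_squared: float


def delta_g_from_k(K_mM: float, temperature_c: float, constants: EnergeticConstants) -> float:
    """Binding free energy -RT ln K (kcal mol^-1) from K in mM^-1."""
    if K_mM <= 0:
        raise ValueError("association constant must be positive")
    k_molar = K_mM * 1e3
    return -constants.rt_kcal(temperature_c) * math.log(k_molar)


def entropy_term(dG_kcal: float, dH_kcal: float) -> float:
    """The -TdS term of the Gibbs relation, dG - dH (kcal mol^-1)."""
    return dG_kcal - dH_kcal


def kd_from_kb(K_mM: float) -> float:
    """Dissociation constant in uM from an association constant in mM^-1."""
    if K_mM <= 0:
        raise ValueError("association constant must be positive")
    return 1000.0 / K_mM


def ds_b_from_entropy_term(minus_TdS_kcal: float, temperature_c: float) -> float:
    """Binding entropy (cal mol^-1 K^-1) from the -TdS term (kcal mol^-1)."""
    return -1000.0 * minus_TdS_kcal / celsius_to_kelvin(temperature_c)


def derive_profile(params: BindingParameters, constants: EnergeticConstants) -> ThermoProfile:
    """All derived state functions for one set of measured binding parameters."""
    dg = delta_g_from_k(params.K_mM, params.temperature_c, constants)
    mtds = entropy_term(dg, params.dH_kcal)
    return ThermoProfile(
        temperature_c=params.temperature_c,
        Kd_uM=kd_from_kb(params.K_mM),
        dG_kcal=dg,
        dH_kcal=params.dH_kcal,
        minus_TdS_kcal=mtds,
        dS_cal=ds_b_from_entropy_term(mtds, params.temperature_c),
    )


def fit_delta_cp(series: Sequence[tuple[float, float]]) -> CpFit:
    """Unweighted least-squares slope of dH_b (kcal mol^-1) against T (C).

    The slope, converted to cal mol^-1 K^-1, is the binding heat-capacity
    change under the usual assumption that dCp is constant over the narrow
    temperature span of the experiment.  At least two distinct temperatures
    are required.
    """
    temps = np.asarray([float(t) for t, _ in series])
    dhs = np.asarray([float(h) for _, h in series])
    if len(set(temps.tolist())) < 2:
        raise ValueError("heat-capacity fit needs >=2 distinct temperatures")
    n_pts = len(temps)
    sxx = float(np.sum((temps - temps.mean()) ** 2))
    slope = float(np.sum((temps - temps.mean()) * (dhs - dhs.mean())) / sxx)
    intercept = float(dhs.mean() - slope * temps.mean())
    resid = dhs - (intercept + slope * temps)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((dhs - dhs.mean()) ** 2))
    stderr = math.sqrt(ss_res / (n_pts - 2) / sxx) if n_pts > 2 else 0.0
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    tref = float(temps.min())
    return CpFit(
        dCp_cal=slope * 1000.0,
        dCp_err_cal=stderr * 1000.0,
        dH_at_Tref_kcal=intercept + slope * tref,
        Tref_c=tref,
        r_squared=max(0.0, min(1.0, r_squared)),
    )


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero, the convention of printed data tables."""
    quantum = Decimal(1).scaleb(-decimals)
    sign = -1 if value < 0 else 1
    rounded = Decimal(str(abs(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return sign * float(rounded)
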