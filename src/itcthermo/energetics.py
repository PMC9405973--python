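"""Structural-energetic deconvolution of dCp_b and dS_b.

The measured heat-capacity change of binding splits into a rigid-body part,
set by the polar/apolar surface buried at the interface,

    dCp_rb = alpha * dASA_ap + beta * dASA_p,

and a conformational part dCp_conf = dCp_b - dCp_rb attributable to
rearrangements outside the interface.  The conformational surface change is
recovered by weighting the coefficients with the average interface
hydrophobicity f_ap,

    dASA_conf = dCp_conf / (alpha * f_ap + beta * (1 - f_ap)),

(0.2228 cal K^-1 mol^-1 A^-2 with the default constants), and translated
into a residue count through the mean per-residue surface area.  The
binding entropy likewise splits into solvation, roto-translational and
conformational terms,

    dS_b = dS_solv + dS_rt + dS_conf,    dS_solv = dCp_b * ln(T / Ts),

with the conformational term expressed as a number of rotatable bonds that
stiffen (dS_conf < 0) or loosen (dS_conf > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

from .constants import EnergeticConstants, celsius_to_kelvin
from .thermo import ds_b_from_entropy_term, round_half_away

__all__ = [
    "AsaDecomposition",
    "EntropyDecomposition",
    "cp_rigid_body",
    "cp_conformational",
    "conf_coefficient",
    "asa_from_cp_conf",
    "n_residues_from_asa",
    "entropy_decomposition",
    "n_rotatable_bonds",
    "decompose",
]


@dataclass(frozen=True)
class AsaDecomposition:
    """Split of the binding heat capacity into rigid-body and conformational parts.

    ``dASA_conf`` is signed: negative values mean net exposure of surface by
    the conformational change; ``n_conf_residues`` counts the residues
    involved, as an absolute value.
    """

    dCp_cal: float
    dCp_rb_cal: float
    dCp_conf_cal: float
    dASA_conf_A2: float
    n_conf_residues: int
    dASA_ap_A2: float | None = None
    dASA_p_A2: float | None = None

    def __post_init__(self) -> None:
        if not math.isclose(
            self.dCp_cal, self.dCp_rb_cal + self.dCp_conf_cal, rel_tol=1e-12, abs_tol=1e-12
        ):
            raise ValueError("dCp_b = dCp_rb + dCp_conf violated")
        if self.n_conf_residues < 0:
            raise ValueError("residue count is an absolute value")


@dataclass(frozen=True)
class EntropyDecomposition:
    """Split of the binding entropy into its three canonical components."""

    dS_cal: float
    dS_solv_cal: float
    dS_rt_cal: float
    dS_conf_cal: float
    n_rot_bonds: int

    def __post_init__(self) -> None:
        if not math.isclose(
            self.dS_cal,
            self.dS_solv_cal + self.dS_rt_cal + self.dS_conf_cal,
            rel_tol=1e-12,
            abs_tol=1e-12,
        ):
            raise ValueError("dS_b = dS_solv + dS_rt + dS_conf violated")
        if self.n_rot_bonds < 0:
            raise ValueError("rotatable-bond count is an absolute value")


def cp_rigid_body(dASA_ap: float, dASA_p: float, constants: EnergeticConstants) -> float:
    """Rigid-body heat-capacity change from buried apolar/polar areas (A^2)."""
    return constants.alpha * dASA_ap + constants.beta * dASA_p


def cp_conformational(dCp_cal: float, dCp_rb_cal: float) -> float:
    """Conformational heat-capacity change, dCp_b - dCp_rb."""
    return dCp_cal - dCp_rb_cal


def conf_coefficient(constants: EnergeticConstants) -> float:
    """Hydrophobicity-weighted area-to-heat-capacity coefficient.

    alpha*f_ap + beta*(1-f_ap): the apolar and polar coefficients weighted
    by the average interface composition, so that a generic conformational
    surface change converts to heat capacity with a single number.
    """
    coeff = constants.alpha * constants.f_ap + constants.beta * (1.0 - constants.f_ap)
    if coeff <= 0:
        raise ValueError(
            f"alpha*f_ap + beta*(1-f_ap) = {coeff:.4g} <= 0: constants are unphysical"
        )
    return coeff


def asa_from_cp_conf(dCp_conf_cal: float, constants: EnergeticConstants) -> float:
    """Signed conformational surface-area change (A^2) from dCp_conf."""
    return dCp_conf_cal / conf_coefficient(constants)


def n_residues_from_asa(dASA_conf_A2: float, constants: EnergeticConstants) -> int:
    """Number of residues changing conformation (absolute value, rounded)."""
    return int(round_half_away(abs(dASA_conf_A2) / constants.asa_per_residue))


def entropy_decomposition(
    minus_TdS_kcal: float,
    dCp_cal: float,
    temperature_c: float,
    constants: EnergeticConstants,
) -> EntropyDecomposition:
    """Solvation / roto-translational / conformational split of dS_b."""
    t_kelvin = celsius_to_kelvin(temperature_c)
    ds_b = ds_b_from_entropy_term(minus_TdS_kcal, temperature_c)
    ds_solv = dCp_cal * math.log(t_kelvin / constants.Ts)
    ds_conf = ds_b - ds_solv - constants.dS_rt
    return EntropyDecomposition(
        dS_cal=ds_b,
        dS_solv_cal=ds_solv,
        dS_rt_cal=constants.dS_rt,
        dS_conf_cal=ds_conf,
        n_rot_bonds=n_rotatable_bonds(ds_conf, constants),
    )


def n_rotatable_bonds(dS_conf_cal: float, constants: EnergeticConstants) -> int:
    """Number of rotatable bonds changing conformation (absolute, rounded)."""
    return int(round_half_away(abs(dS_conf_cal) / constants.dS_per_rotor))


def decompose(
    dCp_cal: float,
    dCp_rb_cal: float,
    minus_TdS_kcal: float,
    temperature_c: float,
    constants: EnergeticConstants,
) -> tuple[AsaDecomposition, EntropyDecomposition]:
    """Full heat-capacity and entropy deconvolution of one complex."""
    dcp_conf = cp_conformational(dCp_cal, dCp_rb_cal)
    dasa_conf = asa_from_cp_conf(dcp_conf, constants)
    asa = AsaDecomposition(
        dCp_cal=dCp_cal,
        dCp_rb_cal=dCp_rb_cal,
        dCp_conf_cal=dcp_conf,
        dASA_conf_A2=dasa_conf,
        n_conf_residues=n_residues_from_asa(dasa_conf, constants),
    )
    entropy = entropy_decomposition(minus_TdS_kcal, dCp_cal, temperature_c, constants)
    return asa, entropy
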