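"""Synthetic titration experiments with known ground truth.

Stands in for the calorimeter: heats come from the forward model of
:mod:`itcthermo.itc`, Gaussian noise is added per injection on the raw
(microcalorie) scale where instrument noise lives, and an optional constant
blank offset emulates ligand dilution heat.  Every stream of randomness
derives from the single integer seed of the spec.

The default protocol mirrors a millimolar-ligand / tens-of-micromolar
protein titration: a 200 uL cell loaded with 40 uM protein titrated with
19 x 2 uL injections of 2.5 mM ligand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import GAS_CONSTANT_CAL, celsius_to_kelvin
from .itc import Isotherm, TitrationProtocol, predict_injection_heats
from .speciation import MgCouplingConstants
from .thermo import BindingParameters

__all__ = [
    "GeneratorSpec",
    "generate_isotherm",
    "generate_temperature_series",
    "generate_coupled_pair",
    "write_truth_json",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete recipe for one synthetic titration.

    ``truth`` holds the one-site (or intrinsic nucleotide-only) parameters;
    for coupled-equilibria experiments ``truth_mg`` adds the parameters of
    the protein / Mg-nucleotide equilibrium and ``mg_constants`` the metal
    speciation.  ``noise_sd_ucal`` is the per-injection Gaussian noise on
    the raw heat, ``blank_offset_ucal`` a constant dilution heat added to
    sample and blank alike.
    """

    truth: BindingParameters
    protocol: TitrationProtocol = field(default_factory=TitrationProtocol)
    noise_sd_ucal: float = 0.05
    blank_offset_ucal: float = 0.0
    seed: int = 0
    truth_mg: BindingParameters | None = None
    mg_constants: MgCouplingConstants | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_ucal < 0:
            raise ValueError("noise standard deviation must be >= 0")

    @property
    def mode(self) -> str:
        return "ternary" if self.truth_mg is not None else "one_site"


def _with_noise(raw_ucal: np.ndarray, spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    return raw_ucal + spec.blank_offset_ucal + rng.normal(0.0, spec.noise_sd_ucal, raw_ucal.shape)


def generate_isotherm(spec: GeneratorSpec) -> tuple[Isotherm, Isotherm]:
    """Sample and blank isotherms for one synthetic experiment.

    The sample is the forward-model prediction plus offset and noise; the
    blank is the protein-free prediction (zero for a one-site experiment,
    Mg-nucleotide dilution heats for a ternary one) plus the same offset and
    independent noise.  Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    model = predict_injection_heats(
        spec.protocol,
        spec.truth,
        mode=spec.mode,
        mg_constants=spec.mg_constants,
        params_mg=spec.truth_mg,
    )
    blank_protocol = replace(spec.protocol, cell_protein_uM=0.0)
    blank_model = predict_injection_heats(
        blank_protocol,
        spec.truth,
        mode=spec.mode,
        mg_constants=spec.mg_constants,
        params_mg=spec.truth_mg,
    )

    inj_moles = (
        np.asarray(spec.protocol.injection_volumes_uL)
        * 1e-6
        * spec.protocol.syringe_ligand_mM
        * 1e-3
    )

    def build(raw_model_ucal: np.ndarray, ratios: np.ndarray, subtracted: bool) -> Isotherm:
        raw = _with_noise(raw_model_ucal, spec, rng)
        ndh = np.where(inj_moles > 0, raw * 1e-9 / inj_moles, 0.0)
        return Isotherm(
            molar_ratio=ratios,
            ndh_kcal_per_mol=ndh,
            injection_volumes_uL=np.asarray(spec.protocol.injection_volumes_uL),
            raw_heat_ucal=raw,
            blank_subtracted=subtracted,
            meta={"seed": spec.seed, "mode": spec.mode},
        )

    sample = build(model.raw_heat_ucal, model.molar_ratio, False)
    blank = build(blank_model.raw_heat_ucal, model.molar_ratio, False)
    return sample, blank


def _vant_hoff_k(
    k25_mM: float, dh25_kcal: float, dcp_cal: float, t_from_c: float, t_to_c: float
) -> float:
    """Integrated van't Hoff extrapolation of K with constant dCp (mM^-1)."""
    r_kcal = GAS_CONSTANT_CAL / 1000.0
    t0 = celsius_to_kelvin(t_from_c)
    t1 = celsius_to_kelvin(t_to_c)
    dcp_kcal = dcp_cal / 1000.0
    ln_ratio = (
        (dh25_kcal - dcp_kcal * t0) * (1.0 / t0 - 1.0 / t1) + dcp_kcal * math.log(t1 / t0)
    ) / r_kcal
    return k25_mM * math.exp(ln_ratio)


def generate_temperature_series(
    truth_at_25: BindingParameters,
    dCp_true_cal: float,
    temperatures_c: Sequence[float],
    base_spec: GeneratorSpec,
) -> list[GeneratorSpec]:
    """Specs for a temperature series with a prescribed heat capacity.

    dH(T) is linear in T with slope dCp; K(T) follows the integrated van't
    Hoff relation with constant dCp.  Each member derives its own seed from
    the base seed so replicates are independent but reproducible.
    """
    if len(temperatures_c) < 2:
        raise ValueError("a temperature series needs at least 2 temperatures")
    specs = []
    for i, t in enumerate(temperatures_c):
        dh = truth_at_25.dH_kcal + dCp_true_cal / 1000.0 * (t - truth_at_25.temperature_c)
        k = _vant_hoff_k(
            truth_at_25.K_mM, truth_at_25.dH_kcal, dCp_true_cal, truth_at_25.temperature_c, t
        )
        truth = replace(truth_at_25, temperature_c=t, K_mM=k, dH_kcal=dh)
        specs.append(
            replace(
                base_spec,
                truth=truth,
                protocol=replace(base_spec.protocol, temperature_c=t),
                seed=(base_spec.seed + 10007 * (i + 1)) % 2**31,
            )
        )
    return specs


def generate_coupled_pair(
    truth_eg: BindingParameters,
    truth_emg: BindingParameters,
    mg_constants: MgCouplingConstants,
    base_spec: GeneratorSpec,
    mg_levels_mM: tuple[float, float] = (0.0, 5.0),
) -> tuple[GeneratorSpec, GeneratorSpec]:
    """Paired metal-free / metal-containing experiments sharing one truth.

    The first spec titrates in the absence of Mg(2+) (EDTA condition,
    modelled as zero total metal) and pins the intrinsic nucleotide-only
    equilibrium; the second adds the metal at the stated total concentration
    in both cell and syringe.
    """
    no_mg = replace(
        base_spec,
        truth=truth_eg,
        truth_mg=None,
        mg_constants=None,
        protocol=replace(base_spec.protocol, total_mg_mM=mg_levels_mM[0]),
        seed=base_spec.seed % 2**31,
    )
    with_mg = replace(
        base_spec,
        truth=truth_eg,
        truth_mg=truth_emg,
        mg_constants=mg_constants,
        protocol=replace(base_spec.protocol, total_mg_mM=mg_levels_mM[1]),
        seed=(base_spec.seed + 500009) % 2**31,
    )
    return no_mg, with_mg


def write_truth_json(spec: GeneratorSpec, path: str | Path) -> None:
    """Sidecar with the ground-truth parameters of a generated experiment."""
    payload = {
        "seed": spec.seed,
        "noise_sd_ucal": spec.noise_sd_ucal,
        "blank_offset_ucal": spec.blank_offset_ucal,
        "mode": spec.mode,
        "truth": {
            "complex_label": spec.truth.complex_label,
            "temperature_c": spec.truth.temperature_c,
            "n": spec.truth.n,
            "K_mM": spec.truth.K_mM,
            "dH_kcal": spec.truth.dH_kcal,
        },
    }
    if spec.truth_mg is not None:
        payload["truth_mg"] = {
            "K_mM": spec.truth_mg.K_mM,
            "dH_kcal": spec.truth_mg.dH_kcal,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
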