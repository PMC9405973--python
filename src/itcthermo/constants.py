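"""Energetic constants and the TOML constants file.

All thermodynamic bookkeeping in this package uses the calorie convention of
the binding-calorimetry literature: energies in kcal mol^-1, entropies and
heat capacities in cal mol^-1 K^-1, surface areas in A^2, temperatures in
degrees Celsius at the API boundary (converted to Kelvin internally).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

#: Gas constant, cal mol^-1 K^-1.
GAS_CONSTANT_CAL: float = 1.9872

#: Celsius -> Kelvin offset.
KELVIN_OFFSET: float = 273.15


def celsius_to_kelvin(temperature_c: float) -> float:
    return temperature_c + KELVIN_OFFSET


@dataclass(frozen=True)
class EnergeticConstants:
    """Constants of the surface-area/entropy parameterization of binding.

    Parameters
    ----------
    gas_constant : float
        Gas constant R, cal mol^-1 K^-1.
    Ts : float
        Reference temperature (K) at which solvation effects on the binding
        entropy vanish; 385.15 K (112 C) for protein systems.
    dS_rt : float
        Roto-translational entropy loss of a bimolecular association,
        cal mol^-1 K^-1 (negative).
    alpha : float
        Heat-capacity coefficient of buried apolar surface,
        cal K^-1 mol^-1 A^-2.
    beta : float
        Heat-capacity coefficient of buried polar surface,
        cal K^-1 mol^-1 A^-2 (negative).
    f_ap : float
        Average hydrophobicity (apolar fraction) of protein interfaces.
    asa_per_residue : float
        Mean accessible surface area per residue, A^2.
    dS_per_rotor : float
        Conformational entropy per rotatable bond, cal mol^-1 K^-1.
    """

    gas_constant: float = GAS_CONSTANT_CAL
    Ts: float = 385.15
    dS_rt: float = -8.0
    alpha: float = 0.45
    beta: float = -0.26
    f_ap: float = 0.68
    asa_per_residue: float = 47.0
    dS_per_rotor: float = 1.7

    def __post_init__(self) -> None:
        if self.gas_constant <= 0:
            raise ValueError("gas_constant must be positive")
        if self.Ts <= 273:
            raise ValueError("Ts must exceed 273 K")
        if not 0 < self.f_ap < 1:
            raise ValueError("f_ap must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta >= 0:
            raise ValueError("beta must be negative")
        if self.asa_per_residue <= 0:
            raise ValueError("asa_per_residue must be positive")
        if self.dS_per_rotor <= 0:
            raise ValueError("dS_per_rotor must be positive")

    def rt_kcal(self, temperature_c: float) -> float:
        """R*T in kcal mol^-1 at a Celsius temperature."""
        return self.gas_constant * celsius_to_kelvin(temperature_c) / 1000.0


@dataclass(frozen=True)
class ConstantsBundle:
    """Full contents of a constants file.

    ``dcp_rb`` maps a ``"LIGAND:mg_state"`` key (e.g. ``"GDP:+Mg"``) to the
    rigid-body heat-capacity change of that complex in cal mol^-1 K^-1;
    these values come from surface-area calculations on the complex
    structures and are inputs here, not recomputed.  ``mg_binding`` holds
    the Mg(2+)-nucleotide association constants (M^-1) and their stepwise
    enthalpies (kcal mol^-1); the shipped defaults are literature-style
    placeholder magnitudes and should be overridden when condition-specific
    values are available.
    """

    energetic: EnergeticConstants = field(default_factory=EnergeticConstants)
    dcp_rb: dict[str, float] = field(default_factory=dict)
    mg_binding: dict[str, float] = field(default_factory=dict)


def default_constants_path():
    """Path-like handle to the packaged default constants file."""
    return resources.files("itcthermo.data").joinpath("constants.toml")


def load_constants(path: str | Path | None = None) -> ConstantsBundle:
    """Read a TOML constants file; ``None`` loads the packaged defaults."""
    if path is None:
        raw = default_constants_path().read_bytes()
        data = tomllib.loads(raw.decode())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    energetic = EnergeticConstants(**data.get("energetic", {}))
    return ConstantsBundle(
        energetic=energetic,
        dcp_rb={str(k): float(v) for k, v in data.get("dcp_rb", {}).items()},
        mg_binding={str(k): float(v) for k, v in data.get("mg_binding", {}).items()},
    )


def dump_constants(bundle: ConstantsBundle, path: str | Path) -> None:
    """Write a constants bundle back to TOML text."""
    lines = ["[energetic]"]
    for key, value in asdict(bundle.energetic).items():
        lines.append(f"{key} = {value!r}")
    for section, table in (("dcp_rb", bundle.dcp_rb), ("mg_binding", bundle.mg_binding)):
        lines.append("")
        lines.append(f"[{section}]")
        for key, value in table.items():
            lines.append(f'"{key}" = {value!r}')
    Path(path).write_text("\n".join(lines) + "\n")
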