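"""Fitting machinery for auxiliary solution assays.

Two standard models: Michaelis-Menten steady-state kinetics (e.g. a
phosphate-release coupled GTP-hydrolysis assay) and a fluorescence binding
titration fitted with explicit ligand depletion (single-site quadratic),
with the hyperbolic no-depletion form as its limiting case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .speciation import solve_binary_speciation

__all__ = ["KineticsParams", "FluorBindingParams", "fit_michaelis_menten", "fit_fluorescence_kd"]


@dataclass(frozen=True)
class KineticsParams:
    """Michaelis-Menten parameters; kcat = Vmax / [E]."""

    Km_uM: float
    kcat_per_min: float
    Vmax_uM_per_min: float
    enzyme_conc_uM: float
    Km_err_uM: float = 0.0
    Vmax_err_uM_per_min: float = 0.0

    def __post_init__(self) -> None:
        if min(self.Km_uM, self.kcat_per_min, self.Vmax_uM_per_min, self.enzyme_conc_uM) <= 0:
            raise ValueError("kinetic parameters must be positive")


@dataclass(frozen=True)
class FluorBindingParams:
    """Single-site dissociation constant from a fluorescence titration."""

    Kd_uM: float
    F0: float
    Fmax: float
    receptor_conc_uM: float
    Kd_err_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.Kd_uM <= 0:
            raise ValueError("Kd must be positive")
        if self.Fmax == self.F0:
            raise ValueError("Fmax must differ from F0")


def fit_michaelis_menten(
    points: Sequence[tuple[float, float]], enzyme_conc_uM: float
) -> KineticsParams:
    """Least-squares fit of v = Vmax*S/(Km+S) to (substrate uM, rate uM/min)."""
    s = np.asarray([p[0] for p in points], dtype=float)
    v = np.asarray([p[1] for p in points], dtype=float)
    if len(set(s.tolist())) < 4:
        raise ValueError("need rates at >=4 substrate concentrations")

    vmax0 = float(v.max()) * 1.2
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))]) or float(np.median(s))
    popt, pcov = curve_fit(
        lambda x, vmax, km: vmax * x / (km + x),
        s,
        v,
        p0=[vmax0, km0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000,
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
    )
    vmax, km = popt
    if km < s.min() / 5.0 or km > s.max() * 5.0:
        warnings.warn(
            f"Km {km:.3g} uM lies outside the sampled substrate range: poorly identified",
            stacklevel=2,
        )
    errs = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return KineticsParams(
        Km_uM=km,
        kcat_per_min=vmax / enzyme_conc_uM,
        Vmax_uM_per_min=vmax,
        enzyme_conc_uM=enzyme_conc_uM,
        Km_err_uM=float(errs[1]),
        Vmax_err_uM_per_min=float(errs[0]),
    )


def _fraction_bound(l_total_uM: np.ndarray, kd_uM: float, receptor_uM: float) -> np.ndarray:
    """Receptor fraction bound with ligand depletion (single-site quadratic)."""
    if receptor_uM <= 0:
        return l_total_uM / (kd_uM + l_total_uM)
    out = np.empty_like(l_total_uM, dtype=float)
    for i, lt in enumerate(l_total_uM):
        _, _, c = solve_binary_speciation(receptor_uM * 1e-6, lt * 1e-6, 1.0 / (kd_uM * 1e-6))
        out[i] = c / (receptor_uM * 1e-6)
    return out


def fit_fluorescence_kd(
    points: Sequence[tuple[float, float]],
    receptor_conc_uM: float,
    deplete: bool = True,
) -> FluorBindingParams:
    """Fit F = F0 + (Fmax - F0) * fraction_bound to a titration curve.

    ``deplete=True`` uses the exact single-site quadratic for the bound
    fraction; ``deplete=False`` (or a vanishing receptor concentration)
    falls back to the hyperbolic approximation.
    """
    lt = np.asarray([p[0] for p in points], dtype=float)
    f = np.asarray([p[1] for p in points], dtype=float)
    if len(set(lt.tolist())) < 5:
        raise ValueError("need fluorescence at >=5 ligand concentrations")

    receptor = receptor_conc_uM if deplete else 0.0

    def model(x, kd, f0, fmax):
        return f0 + (fmax - f0) * _fraction_bound(x, kd, receptor)

    f0_0, fmax_0 = float(f[np.argmin(lt)]), float(f[np.argmax(lt)])
    span = fmax_0 - f0_0
    kd0 = float(lt[np.argmin(np.abs(f - (f0_0 + 0.5 * span)))]) or float(np.median(lt))
    popt, pcov = curve_fit(
        model,
        lt,
        f,
        p0=[kd0, f0_0, fmax_0],
        bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
    )
    kd, f0, fmax = popt
    frac_max = float(_fraction_bound(np.array([lt.max()]), kd, receptor)[0])
    if frac_max < 0.5:
        warnings.warn(
            f"titration reaches only {frac_max:.0%} saturation: Kd weakly constrained",
            stacklevel=2,
        )
    return FluorBindingParams(
        Kd_uM=kd,
        F0=f0,
        Fmax=fmax,
        receptor_conc_uM=receptor_conc_uM,
        Kd_err_uM=float(np.sqrt(max(pcov[0, 0], 0.0))),
    )
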