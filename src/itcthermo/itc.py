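"""Forward model of per-injection titration heats and nonlinear isotherm fitting.

The forward model reproduces the bookkeeping of a perfusion (overfill) cell:
each injection of volume ``dV`` displaces ``dV`` of cell solution carrying
the mean of the pre- and post-injection concentrations, so every total
concentration updates as::

    c_new = (c_old * (V0 - dV/2) + c_syringe * dV) / (V0 + dV/2)

and the measured heat of injection ``i`` is the enthalpy-weighted change in
complex content of the cell, corrected for complex formed in (or carried by)
the displaced half-volume and for pre-formed complexes entering from the
syringe.  Heats are normalised to kcal per mole of injectant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .speciation import (
    MgCouplingConstants,
    NO_MG,
    solve_binary_speciation,
    solve_mg_nucleotide,
    solve_ternary,
)
from .thermo import BindingParameters

__all__ = [
    "TitrationProtocol",
    "Isotherm",
    "TernaryFitResult",
    "predict_injection_heats",
    "subtract_dilution",
    "fit_one_site",
    "fit_ternary",
    "read_isotherm_csv",
    "write_isotherm_csv",
]

_SPECIES_HEAT_KEYS = ("EG", "EMG", "MgG", "Mg2G")


@dataclass(frozen=True)
class TitrationProtocol:
    """Geometry and concentrations of one titration experiment.

    Volumes in uL, syringe ligand in mM, cell protein in uM, Mg(2+) total
    (present at the same concentration in cell and syringe) in mM.
    """

    cell_volume_uL: float = 200.0
    injection_volumes_uL: tuple[float, ...] = (2.0,) * 19
    syringe_ligand_mM: float = 2.5
    cell_protein_uM: float = 40.0
    temperature_c: float = 30.0
    total_mg_mM: float = 0.0
    discard_first: bool = True

    def __post_init__(self) -> None:
        if self.cell_volume_uL <= 0:
            raise ValueError("cell volume must be positive")
        if not self.injection_volumes_uL or any(v <= 0 for v in self.injection_volumes_uL):
            raise ValueError("all injection volumes must be positive")
        if self.syringe_ligand_mM < 0 or self.cell_protein_uM < 0 or self.total_mg_mM < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_uL)

    def retained(self) -> np.ndarray:
        """Boolean mask of injections used for fitting."""
        mask = np.ones(self.n_injections, dtype=bool)
        if self.discard_first:
            mask[0] = False
        return mask


@dataclass
class Isotherm:
    """Integrated, normalised injection heats of one titration."""

    molar_ratio: np.ndarray
    ndh_kcal_per_mol: np.ndarray
    injection_volumes_uL: np.ndarray
    raw_heat_ucal: np.ndarray | None = None
    blank_subtracted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.ndh_kcal_per_mol = np.asarray(self.ndh_kcal_per_mol, dtype=float)
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        if not (
            len(self.molar_ratio) == len(self.ndh_kcal_per_mol) == len(self.injection_volumes_uL)
        ):
            raise ValueError("isotherm arrays must share one length")
        finite = self.molar_ratio[np.isfinite(self.molar_ratio)]
        if len(finite) > 1 and np.any(finite > 0) and np.any(np.diff(finite) <= 0):
            raise ValueError("molar ratio must be strictly increasing")

    def __len__(self) -> int:
        return len(self.molar_ratio)


@dataclass(frozen=True)
class TernaryFitResult:
    """Intrinsic constants of the coupled-equilibria fit (mM^-1, kcal mol^-1)."""

    K_EG_mM: float
    K_EMG_mM: float
    dH_EG_kcal: float
    dH_EMG_kcal: float
    K_EG_err_mM: float = 0.0
    K_EMG_err_mM: float = 0.0
    dH_EG_err_kcal: float = 0.0
    dH_EMG_err_kcal: float = 0.0

    @property
    def kappa(self) -> float:
        """Heterotropic cooperativity constant of Mg(2+) on nucleotide binding."""
        return self.K_EMG_mM / self.K_EG_mM


def _cell_totals(protocol: TitrationProtocol) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total concentrations (M) of protein, ligand and Mg after each injection."""
    v0 = protocol.cell_volume_uL
    e = protocol.cell_protein_uM * 1e-6
    g = 0.0
    mg = protocol.total_mg_mM * 1e-3
    g_syr = protocol.syringe_ligand_mM * 1e-3
    mg_syr = protocol.total_mg_mM * 1e-3
    e_tot, g_tot, mg_tot = [], [], []
    for dv in protocol.injection_volumes_uL:
        shrink, grow = v0 - dv / 2.0, v0 + dv / 2.0
        e = e * shrink / grow
        g = (g * shrink + g_syr * dv) / grow
        mg = (mg * shrink + mg_syr * dv) / grow
        e_tot.append(e)
        g_tot.append(g)
        mg_tot.append(mg)
    return np.array(e_tot), np.array(g_tot), np.array(mg_tot)


def _bound_species(
    e_tot: float,
    g_tot: float,
    mg_tot: float,
    params: BindingParameters,
    mode: str,
    mg_constants: MgCouplingConstants,
    params_mg: BindingParameters | None,
) -> dict[str, float]:
    """Concentrations of heat-carrying complexes at one cell composition."""
    sites = params.n * e_tot
    if mode == "one_site":
        _, _, c = solve_binary_speciation(sites, g_tot, params.K_mM * 1e3)
        return {"EG": c, "EMG": 0.0, "MgG": 0.0, "Mg2G": 0.0}
    state = solve_ternary(
        sites, g_tot, mg_tot, params.K_mM * 1e3, params_mg.K_mM * 1e3, mg_constants
    )
    return {"EG": state.EG, "EMG": state.EMG, "MgG": state.MgG, "Mg2G": state.Mg2G}


def _species_enthalpies(
    params: BindingParameters,
    mode: str,
    mg_constants: MgCouplingConstants,
    params_mg: BindingParameters | None,
) -> dict[str, float]:
    """Formation enthalpy of each complex from free E, G and Mg (kcal/mol)."""
    h = {"EG": params.dH_kcal, "EMG": 0.0, "MgG": 0.0, "Mg2G": 0.0}
    if mode == "ternary":
        h["MgG"] = mg_constants.dH_MgG
        h["Mg2G"] = mg_constants.dH_MgG + mg_constants.dH_Mg2G
        h["EMG"] = mg_constants.dH_MgG + params_mg.dH_kcal
    return h


def predict_injection_heats(
    protocol: TitrationProtocol,
    params: BindingParameters,
    mode: str = "one_site",
    mg_constants: MgCouplingConstants | None = None,
    params_mg: BindingParameters | None = None,
) -> Isotherm:
    """Noise-free isotherm predicted for a protocol and binding parameters.

    ``mode='one_site'`` treats ``params`` as the (apparent) single-site
    constants.  ``mode='ternary'`` requires ``mg_constants`` plus a second
    parameter set ``params_mg`` for the protein/Mg-nucleotide equilibrium;
    the heats then sum the enthalpy-weighted changes of all four complexes,
    with pre-formed Mg-nucleotide entering from the syringe credited so only
    re-equilibration inside the cell releases heat.
    """
    if mode not in ("one_site", "ternary"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ternary":
        if mg_constants is None or params_mg is None:
            raise ValueError("ternary mode needs mg_constants and params_mg")
    else:
        mg_constants = mg_constants or NO_MG
    if protocol.syringe_ligand_mM == 0:
        warnings.warn("zero ligand in syringe: all heats are zero", stacklevel=2)

    v0_L = protocol.cell_volume_uL * 1e-6
    e_tot, g_tot, mg_tot = _cell_totals(protocol)
    enthalpy = _species_enthalpies(params, mode, mg_constants, params_mg)

    # syringe pre-equilibrated Mg-nucleotide content
    b_syr = {k: 0.0 for k in _SPECIES_HEAT_KEYS}
    if mode == "ternary":
        g_s, mgg_s, mg2g_s, _ = solve_mg_nucleotide(
            protocol.syringe_ligand_mM * 1e-3, protocol.total_mg_mM * 1e-3, mg_constants
        )
        b_syr["MgG"], b_syr["Mg2G"] = mgg_s, mg2g_s

    # cell starts with protein (+ Mg) but no nucleotide: nothing bound yet
    prev = {k: 0.0 for k in _SPECIES_HEAT_KEYS}
    heats_kcal = np.zeros(protocol.n_injections)
    ratios = np.zeros(protocol.n_injections)
    for i, dv_uL in enumerate(protocol.injection_volumes_uL):
        dv_L = dv_uL * 1e-6
        cur = _bound_species(
            e_tot[i], g_tot[i], mg_tot[i], params, mode, mg_constants, params_mg
        )
        q = 0.0
        for sp in _SPECIES_HEAT_KEYS:
            d_moles = (
                v0_L * (cur[sp] - prev[sp])
                + dv_L * 0.5 * (cur[sp] + prev[sp])
                - dv_L * b_syr[sp]
            )
            q += enthalpy[sp] * d_moles
        heats_kcal[i] = q
        ratios[i] = g_tot[i] / e_tot[i] if e_tot[i] > 0 else np.inf
        prev = cur

    inj_moles = np.asarray(protocol.injection_volumes_uL) * 1e-6 * protocol.syringe_ligand_mM * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        ndh = np.where(inj_moles > 0, heats_kcal / inj_moles, 0.0)
    return Isotherm(
        molar_ratio=ratios,
        ndh_kcal_per_mol=ndh,
        injection_volumes_uL=np.asarray(protocol.injection_volumes_uL),
        raw_heat_ucal=heats_kcal * 1e9,
        blank_subtracted=True,
        meta={"mode": mode, "temperature_c": protocol.temperature_c},
    )


def subtract_dilution(sample: Isotherm, blank: Isotherm) -> Isotherm:
    """Point-wise blank (ligand-into-buffer) subtraction."""
    if len(sample) != len(blank) or not np.allclose(
        sample.injection_volumes_uL, blank.injection_volumes_uL
    ):
        raise ValueError("sample and blank injection schedules differ")
    raw = None
    if sample.raw_heat_ucal is not None and blank.raw_heat_ucal is not None:
        raw = sample.raw_heat_ucal - blank.raw_heat_ucal
    return Isotherm(
        molar_ratio=sample.molar_ratio.copy(),
        ndh_kcal_per_mol=sample.ndh_kcal_per_mol - blank.ndh_kcal_per_mol,
        injection_volumes_uL=sample.injection_volumes_uL.copy(),
        raw_heat_ucal=raw,
        blank_subtracted=True,
        meta=dict(sample.meta),
    )


def _c_value(n: float, K_mM: float, protocol: TitrationProtocol) -> float:
    return n * K_mM * 1e3 * protocol.cell_protein_uM * 1e-6


def _std_errors(res, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from a least_squares result."""
    jac = res.jac
    dof = max(n_obs - jac.shape[1], 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def fit_one_site(
    isotherm: Isotherm,
    protocol: TitrationProtocol,
    init: BindingParameters | None = None,
    fix_n: float | None = None,
) -> BindingParameters:
    """Least-squares fit of (n, K, dH) to a blank-subtracted isotherm.

    Trust-region least squares on the retained injections with three starts
    (c-value heuristic for K, half and double) taken in fixed order, so the
    result is deterministic.  ``fix_n`` freezes the stoichiometry instead of
    floating it.  Asymptotic standard errors for K and dH come from the
    Jacobian at the optimum.
    """
    mask = protocol.retained()
    y = isotherm.ndh_kcal_per_mol[mask]
    if np.count_nonzero(mask) < 5:
        raise ValueError("need at least 5 informative injections")

    if init is not None:
        n0, k0_mM, dh0 = init.n, init.K_mM, init.dH_kcal
    else:
        n0 = fix_n if fix_n is not None else 1.0
        k0_mM = 10.0 / (n0 * protocol.cell_protein_uM * 1e-6) / 1e3  # c = 10 heuristic
        lead = y[: max(3, len(y) // 4)]
        dh0 = float(np.mean(lead)) if np.any(lead) else 1.0
        if dh0 == 0.0:
            dh0 = 1.0

    float_n = fix_n is None

    def unpack(p):
        if float_n:
            n, logk, dh = p
        else:
            n = fix_n
            logk, dh = p
        return n, np.exp(logk), dh

    def residuals(p):
        n, k_M, dh = unpack(p)
        pars = BindingParameters(
            complex_label="fit", temperature_c=protocol.temperature_c,
            K_mM=k_M / 1e3, dH_kcal=dh, n=n,
        )
        model = predict_injection_heats(protocol, pars, mode="one_site")
        return model.ndh_kcal_per_mol[mask] - y

    best = None
    for k_start in (k0_mM, k0_mM / 2.0, k0_mM * 2.0):
        p0 = [np.log(k_start * 1e3), dh0]
        lo = [np.log(1e-3), -np.inf]
        hi = [np.log(1e12), np.inf]
        if float_n:
            p0 = [n0] + p0
            lo = [1e-3] + lo
            hi = [100.0] + hi
        try:
            res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15 * (1 + abs(best.cost)):
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("one-site fit failed from all starts")

    n_hat, k_M, dh_hat = unpack(best.x)
    errs = _std_errors(best, len(y))
    if float_n:
        _, logk_err, dh_err = errs
    else:
        logk_err, dh_err = errs
    k_mM = k_M / 1e3
    c_val = _c_value(n_hat, k_mM, protocol)
    if c_val < 0.1 or c_val > 1e5:
        warnings.warn(
            f"c-value {c_val:.3g} outside the identifiable window [0.1, 1e5]",
            stacklevel=2,
        )
    return BindingParameters(
        complex_label=str(isotherm.meta.get("label", "fit")),
        temperature_c=protocol.temperature_c,
        K_mM=k_mM,
        K_err_mM=k_mM * logk_err,  # delta method on log K
        dH_kcal=dh_hat,
        dH_err_kcal=dh_err,
        n=n_hat,
    )


def fit_ternary(
    isotherm_mg: Isotherm,
    isotherm_nomg: Isotherm,
    protocol_mg: TitrationProtocol,
    protocol_nomg: TitrationProtocol,
    mg_constants: MgCouplingConstants,
    n: float = 1.0,
) -> TernaryFitResult:
    """Joint fit of the intrinsic constants from a paired +/-Mg experiment.

    The metal-free isotherm pins (K_EG, dH_EG); the +Mg isotherm then
    determines (K_EMG, dH_EMG) through the coupled-equilibria model.  Both
    isotherms enter one least-squares problem.  If the Mg-nucleotide
    complexes carry heat, the model subtracts the protein-free prediction of
    the +Mg titration, mirroring the experimental blank subtraction.
    """
    if protocol_mg.temperature_c != protocol_nomg.temperature_c:
        raise ValueError("paired experiments must share a temperature")
    if protocol_mg.total_mg_mM == protocol_nomg.total_mg_mM:
        raise ValueError(
            "identical Mg totals make the pair rank-deficient: K_EMG is not identifiable"
        )
    t = protocol_mg.temperature_c

    mask_mg = protocol_mg.retained()
    mask_no = protocol_nomg.retained()
    y = np.concatenate(
        [isotherm_nomg.ndh_kcal_per_mol[mask_no], isotherm_mg.ndh_kcal_per_mol[mask_mg]]
    )

    blank_protocol = replace(protocol_mg, cell_protein_uM=0.0)
    has_mg_heat = mg_constants.dH_MgG != 0.0 or mg_constants.dH_Mg2G != 0.0

    def model(p):
        log_keg, log_kemg, dh_eg, dh_emg = p
        pars_eg = BindingParameters(
            complex_label="EG", temperature_c=t, K_mM=np.exp(log_keg) / 1e3,
            dH_kcal=dh_eg, n=n,
        )
        pars_emg = BindingParameters(
            complex_label="EMG", temperature_c=t, K_mM=np.exp(log_kemg) / 1e3,
            dH_kcal=dh_emg, n=n,
        )
        no_mg = predict_injection_heats(protocol_nomg, pars_eg, mode="one_site")
        with_mg = predict_injection_heats(
            protocol_mg, pars_eg, mode="ternary",
            mg_constants=mg_constants, params_mg=pars_emg,
        )
        pred_mg = with_mg.ndh_kcal_per_mol
        if has_mg_heat:
            blank = predict_injection_heats(
                blank_protocol, pars_eg, mode="ternary",
                mg_constants=mg_constants, params_mg=pars_emg,
            )
            pred_mg = pred_mg - blank.ndh_kcal_per_mol
        return np.concatenate([no_mg.ndh_kcal_per_mol[mask_no], pred_mg[mask_mg]])

    def residuals(p):
        return model(p) - y

    # start from independent one-site fits of the two isotherms
    eg0 = fit_one_site(isotherm_nomg, protocol_nomg, fix_n=n)
    mg0 = fit_one_site(isotherm_mg, protocol_mg, fix_n=n)
    p0 = [np.log(eg0.K_mM * 1e3), np.log(mg0.K_mM * 1e3), eg0.dH_kcal, mg0.dH_kcal]
    res = least_squares(residuals, p0, method="trf")
    if not res.success and np.max(np.abs(res.fun)) > 1e-6 * max(1.0, np.max(np.abs(y))):
        raise RuntimeError("ternary fit did not converge")
    errs = _std_errors(res, len(y))
    k_eg = float(np.exp(res.x[0])) / 1e3
    k_emg = float(np.exp(res.x[1])) / 1e3
    return TernaryFitResult(
        K_EG_mM=k_eg,
        K_EMG_mM=k_emg,
        dH_EG_kcal=float(res.x[2]),
        dH_EMG_kcal=float(res.x[3]),
        K_EG_err_mM=k_eg * errs[0],
        K_EMG_err_mM=k_emg * errs[1],
        dH_EG_err_kcal=errs[2],
        dH_EMG_err_kcal=errs[3],
    )


def read_isotherm_csv(path: str | Path) -> Isotherm:
    """Read an integrated-heats CSV (columns ``injection_index``,
    ``inj_volume_uL``, ``heat_ucal`` and/or ``normalized_heat_kcal_per_mol``,
    optional ``molar_ratio``); ``#`` comment lines are ignored."""
    df = pd.read_csv(path, comment="#")
    vols = df["inj_volume_uL"].to_numpy(dtype=float)
    ndh = (
        df["normalized_heat_kcal_per_mol"].to_numpy(dtype=float)
        if "normalized_heat_kcal_per_mol" in df
        else np.zeros(len(df))
    )
    raw = df["heat_ucal"].to_numpy(dtype=float) if "heat_ucal" in df else None
    ratio = (
        df["molar_ratio"].to_numpy(dtype=float)
        if "molar_ratio" in df
        else np.arange(1, len(df) + 1, dtype=float)
    )
    return Isotherm(
        molar_ratio=ratio,
        ndh_kcal_per_mol=ndh,
        injection_volumes_uL=vols,
        raw_heat_ucal=raw,
    )


def write_isotherm_csv(isotherm: Isotherm, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, len(isotherm) + 1),
            "inj_volume_uL": isotherm.injection_volumes_uL,
            "molar_ratio": isotherm.molar_ratio,
            "normalized_heat_kcal_per_mol": isotherm.ndh_kcal_per_mol,
        }
    )
    if isotherm.raw_heat_ucal is not None:
        df["heat_ucal"] = isotherm.raw_heat_ucal
    df.to_csv(path, index=False)
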