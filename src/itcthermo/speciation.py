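"""Equilibrium speciation of protein / nucleotide / Mg(2+) mixtures.

The ternary model couples three equilibria: the protein E binds either the
free nucleotide G (constant ``K_EG``) or its 1:1 magnesium complex MgG
(``K_EMG``); the nucleotide itself binds one Mg(2+) (``K_MgG``) and, for
triphosphates, a second one to give Mg2G (``K_Mg2G``), a species the protein
does not recognise.  All concentrations are molar and all constants are
association constants in M^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MgCouplingConstants",
    "SpeciationState",
    "solve_binary_speciation",
    "solve_mg_nucleotide",
    "solve_ternary",
    "apparent_constant",
]


@dataclass(frozen=True)
class MgCouplingConstants:
    """Stepwise Mg(2+)-nucleotide association constants and enthalpies.

    ``K_Mg2G = 0`` encodes a diphosphate, which binds a single Mg(2+).
    Enthalpies (kcal mol^-1) are stepwise: ``dH_Mg2G`` is the heat of adding
    the second ion to MgG.
    """

    K_MgG: float
    K_Mg2G: float = 0.0
    dH_MgG: float = 0.0
    dH_Mg2G: float = 0.0

    def __post_init__(self) -> None:
        if self.K_MgG < 0 or self.K_Mg2G < 0:
            raise ValueError("Mg-nucleotide association constants must be >= 0")


#: No metal coupling at all (metal-free buffer with EDTA).
NO_MG = MgCouplingConstants(K_MgG=0.0, K_Mg2G=0.0)


@dataclass(frozen=True)
class SpeciationState:
    """Free and complex concentrations (M) at equilibrium."""

    E: float
    G: float
    Mg: float
    MgG: float
    Mg2G: float
    EG: float
    EMG: float

    @property
    def bound_protein(self) -> float:
        return self.EG + self.EMG

    @property
    def total_protein(self) -> float:
        return self.E + self.EG + self.EMG

    @property
    def total_nucleotide(self) -> float:
        return self.G + self.MgG + self.Mg2G + self.EG + self.EMG

    @property
    def total_mg(self) -> float:
        return self.Mg + self.MgG + 2.0 * self.Mg2G + self.EMG


def solve_binary_speciation(
    total_protein: float, total_ligand: float, K: float
) -> tuple[float, float, float]:
    """Closed-form single-site equilibrium.

    Returns ``(free_protein, free_ligand, complex)`` from the physical root
    of the binding quadratic ``K*c^2 - (1 + K*(P+L))*c + K*P*L = 0``.
    """
    if total_protein < 0 or total_ligand < 0 or K < 0:
        raise ValueError("totals and K must be non-negative")
    if K == 0 or total_protein == 0 or total_ligand == 0:
        return total_protein, total_ligand, 0.0
    b = total_protein + total_ligand + 1.0 / K
    # numerically stable smaller root of c^2 - b*c + P*L = 0
    disc = math.sqrt(b * b - 4.0 * total_protein * total_ligand)
    c = 2.0 * total_protein * total_ligand / (b + disc)
    c = min(c, total_protein, total_ligand)
    return total_protein - c, total_ligand - c, c


def solve_mg_nucleotide(
    total_G: float, total_Mg: float, constants: MgCouplingConstants
) -> tuple[float, float, float, float]:
    """Speciation of a protein-free Mg(2+)/nucleotide mixture.

    Returns ``([G], [MgG], [Mg2G], [Mg])`` satisfying the stepwise equilibria
    ``[MgG] = K_MgG [Mg][G]`` and ``[Mg2G] = K_Mg2G [Mg][MgG]``.
    """
    state = solve_ternary(0.0, total_G, total_Mg, 0.0, 0.0, constants)
    return state.G, state.MgG, state.Mg2G, state.Mg


def _species(e: float, g: float, m: float, k_eg, k_emg, c: MgCouplingConstants):
    mgg = c.K_MgG * m * g
    mg2g = c.K_Mg2G * m * mgg
    eg = k_eg * e * g
    emg = k_emg * e * mgg
    return mgg, mg2g, eg, emg


def solve_ternary(
    total_E: float,
    total_G: float,
    total_Mg: float,
    K_EG: float,
    K_EMG: float,
    constants: MgCouplingConstants,
    *,
    tol: float = 1e-13,
    max_iter: int = 200,
) -> SpeciationState:
    """Simultaneous solution of the three coupled mass balances.

    Damped Newton iteration on the logarithms of the free concentrations
    (E, G, Mg), which keeps every species positive by construction.  The
    iteration starts from the uncoupled analytic solution and stops when
    every log mass-balance residual falls below ``tol``.
    """
    if min(total_E, total_G, total_Mg) < 0:
        raise ValueError("totals must be non-negative")
    if min(K_EG, K_EMG) < 0:
        raise ValueError("association constants must be non-negative")

    totals = np.array([total_E, total_G, total_Mg])
    active = totals > 0.0  # zero-total components carry no species

    def compute_totals(e: float, g: float, m: float):
        mgg, mg2g, eg, emg = _species(e, g, m, K_EG, K_EMG, constants)
        te = e + eg + emg
        tg = g + mgg + mg2g + eg + emg
        tm = m + mgg + 2.0 * mg2g + emg
        return np.array([te, tg, tm])

    # initial guess: solve E/G binding and Mg/G binding independently
    e0, g0, _ = solve_binary_speciation(total_E, total_G, K_EG)
    if total_Mg > 0 and constants.K_MgG > 0:
        m_free = solve_binary_speciation(total_Mg, total_G, constants.K_MgG)[0]
    else:
        m_free = total_Mg
    guess = np.array(
        [
            max(e0, total_E * 1e-12),
            max(g0, total_G * 1e-12),
            max(m_free, total_Mg * 1e-12),
        ]
    )
    x = np.log(np.where(active, guess, 1.0))

    def residual(x_log: np.ndarray) -> np.ndarray:
        free = np.where(active, np.exp(x_log), 0.0)
        computed = compute_totals(*free)
        r = np.zeros(3)
        r[active] = np.log(computed[active] / totals[active])
        return r

    r = residual(x)
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol:
            break
        free = np.where(active, np.exp(x), 0.0)
        e, g, m = free
        mgg, mg2g, eg, emg = _species(e, g, m, K_EG, K_EMG, constants)
        te = e + eg + emg
        tg = g + mgg + mg2g + eg + emg
        tm = m + mgg + 2.0 * mg2g + emg
        # J[i, j] = d ln(T_i) / d ln(x_j)
        jac = np.eye(3)
        if te > 0:
            jac[0] = [(e + eg + emg) / te, (eg + emg) / te, emg / te]
        if tg > 0:
            jac[1] = [
                (eg + emg) / tg,
                (g + mgg + mg2g + eg + emg) / tg,
                (mgg + 2.0 * mg2g + emg) / tg,
            ]
        if tm > 0:
            jac[2] = [emg / tm, (mgg + 2.0 * mg2g + emg) / tm, (m + mgg + 4.0 * mg2g + emg) / tm]
        # inactive components: species containing them vanish, so their
        # off-diagonal couplings are already zero; pin the diagonal
        for i in range(3):
            if not active[i]:
                jac[i] = 0.0
                jac[i, i] = 1.0
        try:
            step = np.linalg.solve(jac, r)
        except np.linalg.LinAlgError:
            step = r.copy()
        # damping: limit log-step, then backtrack until the residual shrinks
        norm = np.max(np.abs(step))
        if norm > 2.0:
            step *= 2.0 / norm
        lam, r_norm = 1.0, np.max(np.abs(r))
        for _ in range(40):
            x_new = x - lam * step
            r_new = residual(x_new)
            if np.max(np.abs(r_new)) < r_norm or lam < 1e-12:
                break
            lam *= 0.5
        x, r = x_new, r_new
    else:
        raise RuntimeError(
            f"ternary speciation did not converge: worst log-residual {np.max(np.abs(r)):.3e}"
        )

    e, g, m = np.where(active, np.exp(x), 0.0)
    mgg, mg2g, eg, emg = _species(e, g, m, K_EG, K_EMG, constants)
    return SpeciationState(E=e, G=g, Mg=m, MgG=mgg, Mg2G=mg2g, EG=eg, EMG=emg)


def apparent_constant(
    K_EG: float, K_EMG: float, free_Mg: float, constants: MgCouplingConstants
) -> float:
    """Mg-averaged association constant for the total uncomplexed nucleotide.

    At a fixed free Mg(2+) concentration the protein sees a nucleotide pool
    partitioned among G, MgG and (unrecognised) Mg2G, so the observable
    constant is the binding-weighted average::

        K_app = (K_EG + K_EMG K_MgG [Mg]) / (1 + K_MgG [Mg] + K_MgG K_Mg2G [Mg]^2)
    """
    if free_Mg < 0:
        raise ValueError("free Mg concentration must be non-negative")
    m = free_Mg
    num = K_EG + K_EMG * constants.K_MgG * m
    den = 1.0 + constants.K_MgG * m + constants.K_MgG * constants.K_Mg2G * m * m
    return num / den
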