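"""Independent brute-force oracles for the speciation solvers.

These deliberately avoid the package's Newton solver and closed-form
quadratic: everything is nested scalar bracketing on the mass balances.
"""

from scipy.optimize import brentq


def binary_oracle(e_tot, g_tot, k):
    """1-D bisection on the complex concentration."""
    if k == 0 or e_tot == 0 or g_tot == 0:
        return 0.0

    def resid(c):
        return k * (e_tot - c) * (g_tot - c) - c

    hi = min(e_tot, g_tot)
    return brentq(resid, 0.0, hi, xtol=1e-30, rtol=1e-15)


def ternary_oracle(e_tot, g_tot, mg_tot, k_eg, k_emg, mgc):
    """Nested bisection: outer on free Mg, inner on free nucleotide.

    For fixed free Mg and free G the free protein is explicit, so the G and
    Mg balances become monotone scalar equations solved by bracketing.
    """

    def g_balance(g, m):
        e = e_tot / (1.0 + k_eg * g + k_emg * mgc.K_MgG * m * g) if e_tot > 0 else 0.0
        mgg = mgc.K_MgG * m * g
        mg2g = mgc.K_Mg2G * m * mgg
        return g + mgg + mg2g + k_eg * e * g + k_emg * e * mgg - g_tot

    def solve_g(m):
        if g_tot == 0:
            return 0.0
        return brentq(lambda g: g_balance(g, m), 0.0, g_tot, xtol=1e-300, rtol=1e-15)

    def mg_balance(m):
        g = solve_g(m)
        e = e_tot / (1.0 + k_eg * g + k_emg * mgc.K_MgG * m * g) if e_tot > 0 else 0.0
        mgg = mgc.K_MgG * m * g
        mg2g = mgc.K_Mg2G * m * mgg
        return m + mgg + 2.0 * mg2g + k_emg * e * mgg - mg_tot

    m = 0.0 if mg_tot == 0 else brentq(mg_balance, 0.0, mg_tot, xtol=1e-300, rtol=1e-15)
    g = solve_g(m)
    e = e_tot / (1.0 + k_eg * g + k_emg * mgc.K_MgG * m * g) if e_tot > 0 else 0.0
    mgg = mgc.K_MgG * m * g
    return {
        "E": e,
        "G": g,
        "Mg": m,
        "MgG": mgg,
        "Mg2G": mgc.K_Mg2G * m * mgg,
        "EG": k_eg * e * g,
        "EMG": k_emg * e * mgg,
    }


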