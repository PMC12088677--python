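"""Independent oracles used by the test suite.

These are deliberately separate implementations — a numerical two-site
Bloch–McConnell CPMG propagator and a scalar textbook ¹⁵N relaxation-rate
calculator — coded directly from first principles so that the package's
closed forms can be checked against them rather than against themselves.
"""

import math

import numpy as np
from scipy.linalg import expm

# ¹⁵N/¹H frequency ratio from the gyromagnetic ratios, used to convert a
# ppm shift difference to rad/s at a given ¹H field
_GH = 2.6752218744e8
_GN = -2.7126e7
_HBAR = 1.054571817e-34


def _dw_rad_s(dw_ppm: float, field_mhz: float) -> float:
    return 2.0 * math.pi * field_mhz * 1e6 * abs(_GN) / _GH * dw_ppm * 1e-6


def bloch_mcconnell_r2eff(r20: float, pa: float, dw_ppm: float, kex: float,
                          nu_cpmg: float, field_mhz: float) -> float:
    """Asymptotic CPMG decay rate from the two-site Bloch–McConnell
    equations.

    One CPMG cycle is τ–180°–2τ–180°–τ with 4τ = 1/νCPMG.  Ideal 180°
    pulses conjugate the transverse magnetisation, and the pair of
    conjugations folds into an elementwise-conjugated middle propagator, so
    the cycle map U = E(τ)·conj(E(2τ))·E(τ) is linear.  R2eff is the decay
    rate of its dominant eigenvalue: R2eff = −νCPMG·ln|λ_max|.
    """
    dw = _dw_rad_s(dw_ppm, field_mhz)
    pb = 1.0 - pa
    kab, kba = pb * kex, pa * kex
    a_mat = np.array([[-r20 - kab, kba],
                      [kab, -r20 - kba + 1j * dw]], dtype=complex)
    tau = 1.0 / (4.0 * nu_cpmg)
    e1 = expm(a_mat * tau)
    e2 = expm(a_mat * 2.0 * tau)
    cycle = e1 @ np.conj(e2) @ e1
    lam = float(np.max(np.abs(np.linalg.eigvals(cycle))))
    return -math.log(lam) * nu_cpmg


def bloch_mcconnell_signal_r2eff(r20: float, pa: float, dw_ppm: float,
                                 kex: float, nu_cpmg: float, field_mhz: float,
                                 t_relax: float = 0.020) -> float:
    """Finite-duration variant: R2eff from the observed-state magnetisation
    after the full constant relaxation period (includes transients)."""
    dw = _dw_rad_s(dw_ppm, field_mhz)
    pb = 1.0 - pa
    kab, kba = pb * kex, pa * kex
    a_mat = np.array([[-r20 - kab, kba],
                      [kab, -r20 - kba + 1j * dw]], dtype=complex)
    n_cyc = max(int(round(t_relax * nu_cpmg)), 1)
    tau = t_relax / (4.0 * n_cyc)
    e1 = expm(a_mat * tau)
    e2 = expm(a_mat * 2.0 * tau)
    cycle = e1 @ np.conj(e2) @ e1
    mag = np.array([pa, pb], dtype=complex)
    for _ in range(n_cyc):
        mag = cycle @ mag
    return -math.log(abs(mag[0]) / pa) / t_relax


def textbook_n15_rates(s2: float, tau_m_s: float, tau_e_s: float,
                       field_mhz: float, rex: float = 0.0,
                       r_nh_m: float = 1.02e-10, csa_ppm: float = -160.0):
    """Scalar textbook ¹⁵N dipolar + CSA relaxation rates.

    Written without numpy, with the spectral density and the five
    frequencies spelled out inline.
    """
    d = 1e-7 * _HBAR * _GH * _GN / r_nh_m**3
    wh = 2.0 * math.pi * field_mhz * 1e6
    wn = wh * abs(_GN) / _GH
    c = wn * abs(csa_ppm) * 1e-6 / math.sqrt(3.0)

    def j(w):
        val = s2 * tau_m_s / (1.0 + (w * tau_m_s) ** 2)
        if tau_e_s > 0.0 and s2 < 1.0:
            tp = tau_m_s * tau_e_s / (tau_m_s + tau_e_s)
            val += (1.0 - s2) * tp / (1.0 + (w * tp) ** 2)
        return 0.4 * val

    j0 = j(0.0)
    jn = j(wn)
    jh_minus_n = j(wh - wn)
    jh = j(wh)
    jh_plus_n = j(wh + wn)

    r1 = d * d / 4.0 * (jh_minus_n + 3.0 * jn + 6.0 * jh_plus_n) + c * c * jn
    r2 = (d * d / 8.0 * (4.0 * j0 + jh_minus_n + 3.0 * jn + 6.0 * jh
                         + 6.0 * jh_plus_n)
          + c * c / 6.0 * (4.0 * j0 + 3.0 * jn) + rex)
    noe = 1.0 + (_GH / _GN) * (d * d / 4.0) * (6.0 * jh_plus_n
                                               - jh_minus_n) / r1
    return r1, r2, noe
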