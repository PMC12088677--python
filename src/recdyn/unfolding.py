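"""Two-state van't Hoff analysis of CD thermal melts.

Ellipticity between linear folded and unfolded baselines follows

    θ(T) = [ (m_f·T + b_f) + (m_u·T + b_u)·K(T) ] / (1 + K(T)),
    K(T) = exp[ (−ΔH_vH / R) · (1/T − 1/Tm) ],   T in kelvin inside K.

Baselines are parameterised against temperature in °C (slopes in mdeg/°C)
while the equilibrium constant uses absolute temperature with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹.  At T = Tm the signal sits exactly halfway
between the baselines, and θ is bounded by them at all temperatures.

Multi-domain proteins can unfold in separate events; ``multi_melt`` extends
the model to an amplitude-weighted sum of two transitions sharing the
baselines and compares against the single transition by AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_GAS_KCAL, T_KELVIN_0C
from .exceptions import FitError

__all__ = ["MeltCurve", "MeltFit", "two_state_theta", "multi_theta",
           "two_state_melt", "multi_melt"]


@dataclass
class MeltCurve:
    """Ellipticity versus temperature at one wavelength."""

    temperature_c: np.ndarray
    ellipticity_mdeg: np.ndarray
    wavelength_nm: int = 222

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        if len(self.temperature_c) < 20:
            raise ValueError("a melt needs at least 20 temperature points")
        if np.any(np.diff(self.temperature_c) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    """Fitted unfolding transitions between shared linear baselines."""

    transitions: list[dict]          # {'tm_c', 'dh_kcal_mol', 'amplitude'}
    folded_baseline: tuple[float, float]     # (slope mdeg/°C, intercept mdeg)
    unfolded_baseline: tuple[float, float]
    chi2: float
    aic: float
    n_points: int
    warnings: list[str] = field(default_factory=list)

    @property
    def tm_c(self) -> float:
        return self.transitions[0]["tm_c"]


def _equilibrium_k(t_c, tm_c: float, dh_kcal: float) -> np.ndarray:
    t_k = np.asarray(t_c, dtype=float) + T_KELVIN_0C
    tm_k = tm_c + T_KELVIN_0C
    arg = (-dh_kcal / R_GAS_KCAL) * (1.0 / t_k - 1.0 / tm_k)
    return np.exp(np.clip(arg, -700.0, 700.0))


def two_state_theta(t_c, tm_c: float, dh_kcal: float,
                    m_f: float, b_f: float, m_u: float, b_u: float):
    """Two-state melt signal; only the unfolded baseline is weighted by K."""
    t_c = np.asarray(t_c, dtype=float)
    k = _equilibrium_k(t_c, tm_c, dh_kcal)
    folded = m_f * t_c + b_f
    unfolded = m_u * t_c + b_u
    return (folded + unfolded * k) / (1.0 + k)


def multi_theta(t_c, transitions, m_f: float, b_f: float,
                m_u: float, b_u: float):
    """Amplitude-weighted sum of two-state transitions sharing baselines.

    ``transitions`` is a sequence of (tm_c, dh_kcal, amplitude); amplitudes
    must sum to 1.  The unfolded population is Σ aᵢ·Kᵢ/(1+Kᵢ).
    """
    t_c = np.asarray(t_c, dtype=float)
    folded = m_f * t_c + b_f
    unfolded = m_u * t_c + b_u
    f_u = np.zeros_like(t_c)
    for tm_c, dh, amp in transitions:
        k = _equilibrium_k(t_c, tm_c, dh)
        f_u = f_u + amp * k / (1.0 + k)
    return folded + (unfolded - folded) * f_u


def _initial_guesses(curve: MeltCurve):
    t, y = curve.temperature_c, curve.ellipticity_mdeg
    n_edge = max(len(t) // 10, 3)
    m_f, b_f = np.polyfit(t[:n_edge], y[:n_edge], 1)
    m_u, b_u = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    # inflection from the smoothed derivative
    kernel = np.ones(5) / 5.0
    ys = np.convolve(y, kernel, mode="same")
    dy = np.gradient(ys, t)
    interior = slice(n_edge, len(t) - n_edge)
    tm0 = float(t[interior][np.argmax(np.abs(dy[interior]))])
    return float(m_f), float(b_f), float(m_u), float(b_u), tm0


def _aic(rss: float, n: int, k: int, sigma: float | None) -> float:
    if sigma is not None:
        return rss / sigma**2 + 2 * k
    # unknown noise level: Gaussian profile-likelihood form
    return n * math.log(max(rss, 1e-300) / n) + 2 * k


def two_state_melt(curve: MeltCurve, sigma: float | None = None) -> MeltFit:
    """Fit a single two-state transition with linear baselines.

    Raises ``FitError("transition not bracketed")`` when the scanned range
    contains no resolvable inflection (flat data, or a midpoint at the edge
    of the grid).
    """
    return multi_melt(curve, n_transitions=1, sigma=sigma)


def multi_melt(curve: MeltCurve, n_transitions: int = 2,
               sigma: float | None = None) -> MeltFit:
    """Fit one or two unfolding events sharing folded/unfolded baselines.

    Midpoints fitted closer than 5 °C are poorly identifiable and trigger a
    warning.  When the per-point noise ``sigma`` is known the AIC is
    χ² + 2k; otherwise it uses the Gaussian profile-likelihood form.
    Either way it is comparable across transition counts for the same curve.
    """
    if n_transitions not in (1, 2):
        raise ValueError("n_transitions must be 1 or 2")
    t, y = curve.temperature_c, curve.ellipticity_mdeg
    m_f0, b_f0, m_u0, b_u0, tm0 = _initial_guesses(curve)
    t_lo, t_hi = float(t[0]), float(t[-1])
    dh0 = 50.0
    warns: list[str] = []

    if n_transitions == 1:
        def model(th):
            return two_state_theta(t, th[0], th[1], th[2], th[3], th[4], th[5])
        x0 = np.array([tm0, dh0, m_f0, b_f0, m_u0, b_u0])
        lb = [t_lo, 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
        ub = [t_hi, 500.0, np.inf, np.inf, np.inf, np.inf]
    else:
        # parameters: tm1, dh1, tm2, dh2, m_f, b_f, amp1, m_u, b_u
        def model(th):
            trans = [(th[0], th[1], th[6]), (th[2], th[3], 1.0 - th[6])]
            return multi_theta(t, trans, th[4], th[5], th[7], th[8])
        x0 = np.array([max(tm0 - 10.0, t_lo + 2.0), dh0,
                       min(tm0 + 10.0, t_hi - 2.0), dh0,
                       m_f0, b_f0, 0.5, m_u0, b_u0])
        lb = [t_lo, 1.0, t_lo, 1.0, -np.inf, -np.inf, 0.0, -np.inf, -np.inf]
        ub = [t_hi, 500.0, t_hi, 500.0, np.inf, np.inf, 1.0, np.inf, np.inf]

    best = None
    if n_transitions == 1:
        for tm_start in {tm0, 0.5 * (t_lo + t_hi)}:
            x0[0] = tm_start
            res = least_squares(lambda th: model(th) - y, x0,
                                bounds=(lb, ub), max_nfev=5000)
            if best is None or res.cost < best.cost:
                best = res
    else:
        span = t_hi - t_lo
        for f1, f2 in ((0.25, 0.65), (0.2, 0.8), (0.4, 0.7)):
            x0[0] = t_lo + f1 * span
            x0[2] = t_lo + f2 * span
            res = least_squares(lambda th: model(th) - y, x0,
                                bounds=(lb, ub), max_nfev=8000)
            if best is None or res.cost < best.cost:
                best = res

    th = best.x
    rss = float(2.0 * best.cost)
    n = len(y)

    if n_transitions == 1:
        tm_fit, dh_fit = float(th[0]), float(th[1])
        m_f, b_f, m_u, b_u = (float(v) for v in th[2:6])
        # an unresolvable transition: midpoint pinned at the grid edge or a
        # step smaller than the residual scatter
        edge = min(tm_fit - t_lo, t_hi - tm_fit) < 0.5
        step = abs((m_u * tm_fit + b_u) - (m_f * tm_fit + b_f))
        noise = math.sqrt(rss / max(n - len(th), 1))
        if edge or step < 3.0 * noise:
            raise FitError("transition not bracketed")
        transitions = [{"tm_c": tm_fit, "dh_kcal_mol": dh_fit,
                        "amplitude": 1.0}]
        k = len(th)
    else:
        pairs = sorted([(float(th[0]), float(th[1]), float(th[6])),
                        (float(th[2]), float(th[3]), 1.0 - float(th[6]))])
        if abs(pairs[0][0] - pairs[1][0]) < 5.0:
            warns.append("transitions closer than 5 °C: midpoints and "
                         "amplitudes are poorly identifiable")
        m_f, b_f = float(th[4]), float(th[5])
        m_u, b_u = float(th[7]), float(th[8])
        transitions = [{"tm_c": tm, "dh_kcal_mol": dh, "amplitude": amp}
                       for tm, dh, amp in pairs]
        k = len(th)

    return MeltFit(transitions, (m_f, b_f), (m_u, b_u), rss,
                   _aic(rss, n, k, sigma), n, warns)
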