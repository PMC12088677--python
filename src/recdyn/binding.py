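"""1:1 binding isotherms from MST-style dose–response data.

The labelled target is held at a fixed, low concentration (20 nM by
default) while the titrant is serially diluted (16-point two-fold series
from 200 µM by default).  The signal model is

    signal(L) = baseline + amplitude · f_bound(L)

with f_bound the exact ligand-depletion quadratic for the labelled target.
Because the target concentration is ~100-fold below the µM-range Kd values
involved here, the quadratic and the simple hyperbola are nearly identical,
but the quadratic costs nothing and stays exact when they are not.

Replicate affinities are compared with Welch's (unequal-variance) two-sided
t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .constants import MST_TARGET_CONC_NM
from .exceptions import FitError
from .perturbation import fraction_bound

__all__ = ["Isotherm", "BindingFit", "fit_isotherm", "compare_kd",
           "summarize_replicates"]


@dataclass
class Isotherm:
    """One MST dose–response trace."""

    titrant_conc_um: np.ndarray      # strictly descending dilution series
    signal: np.ndarray               # normalised signal, arbitrary units
    target_conc_nm: float = MST_TARGET_CONC_NM
    replicate: int = 0

    def __post_init__(self) -> None:
        self.titrant_conc_um = np.asarray(self.titrant_conc_um, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.titrant_conc_um) < 6:
            raise ValueError("an isotherm needs at least 6 points")
        if np.any(self.titrant_conc_um <= 0):
            raise ValueError("titrant concentrations must be positive")
        if np.any(np.diff(self.titrant_conc_um) >= 0):
            raise ValueError("titrant concentrations must be strictly "
                             "descending (dilution order)")
        if self.target_conc_nm <= 0:
            raise ValueError("target concentration must be positive")


@dataclass
class BindingFit:
    """Fitted 1:1 binding parameters for one isotherm."""

    kd_um: float | None              # None when no binding was detected
    kd_err: float | None
    baseline: float
    amplitude: float
    chi2: float
    n_points: int
    flags: list[str] = field(default_factory=list)

    @property
    def no_binding(self) -> bool:
        return self.kd_um is None


def fit_isotherm(iso: Isotherm, signal_sigma: float | None = None) -> BindingFit:
    """Weighted fit of baseline + amplitude·f_bound to one isotherm.

    ``signal_sigma`` (per-point noise) weights the fit and defines the
    no-binding criterion; when omitted it is estimated from the fit
    residuals.  An amplitude within 2σ of zero yields a "no binding
    detected" result with Kd undefined; a fitted Kd below the lowest
    titrant concentration is flagged ``kd_upper_bound`` (the series is
    saturated everywhere and only bounds Kd from above).
    """
    lig = iso.titrant_conc_um
    y = iso.signal
    target_um = iso.target_conc_nm * 1e-3
    sig = signal_sigma if signal_sigma is not None else 1.0

    def model(theta):
        kd = math.exp(theta[0])
        return theta[1] + theta[2] * fraction_bound(lig, target_um, kd)

    best = None
    span = float(y.max() - y.min())
    for kd0 in (lig.min(), math.sqrt(lig.min() * lig.max()), lig.max()):
        x0 = np.array([math.log(kd0), float(y[np.argmin(lig)]),
                       span if y[np.argmax(lig)] >= y[np.argmin(lig)]
                       else -span])
        res = least_squares(lambda th: (model(th) - y) / sig, x0,
                            max_nfev=2000)
        if best is None or res.cost < best.cost:
            best = res

    kd = math.exp(best.x[0])
    baseline, amplitude = float(best.x[1]), float(best.x[2])
    chi2 = float(2.0 * best.cost)
    dof = max(len(y) - 3, 1)
    noise = signal_sigma if signal_sigma is not None else float(
        np.std(model(best.x) - y, ddof=3)) if len(y) > 3 else sig

    # binding is detected through the fitted signal change across the
    # series, not the raw amplitude parameter (which is degenerate with Kd
    # when the curve is flat)
    f_span = (fraction_bound(lig.max(), target_um, kd)
              - fraction_bound(lig.min(), target_um, kd))
    if abs(amplitude) * f_span < 2.0 * noise:
        return BindingFit(None, None, baseline, amplitude, chi2, len(y),
                          flags=["no_binding"])

    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac)
        scale = 1.0 if signal_sigma is not None else 2.0 * best.cost / dof
        kd_err = kd * math.sqrt(max(cov[0, 0] * scale, 0.0))
    except np.linalg.LinAlgError:
        kd_err = float("nan")

    flags = []
    if kd < lig.min():
        flags.append("kd_upper_bound")
    if kd > lig.max():
        flags.append("kd_lower_bound")
    return BindingFit(float(kd), float(kd_err), baseline, amplitude, chi2,
                      len(y), flags)


def compare_kd(kds_a, kds_b):
    """Welch two-sample, two-sided t-test on replicate Kd values.

    Returns (t, dof, p).  Requires n ≥ 2 per group to define a variance
    (the experimental design uses n ≥ 3 technical replicates).
    """
    a = np.asarray(kds_a, dtype=float)
    b = np.asarray(kds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise FitError("need at least 2 replicates per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        # degenerate zero-variance groups: identical means are a perfect null
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf * np.sign(np.mean(a) - np.mean(b)), \
            float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summarize_replicates(fits: list[BindingFit]) -> dict:
    """Mean/SD/n of Kd over replicate fits (no-binding fits excluded)."""
    kds = [f.kd_um for f in fits if f.kd_um is not None]
    return {
        "n": len(kds),
        "kd_mean_um": float(np.mean(kds)) if kds else float("nan"),
        "kd_sd_um": float(np.std(kds, ddof=1)) if len(kds) > 1 else float("nan"),
    }
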