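"""Lipari–Szabo model-free analysis of ¹⁵N R1/R2/NOE relaxation data.

The amide bond-vector motion is parameterised by a generalised order
parameter S² (0 = fully flexible, 1 = rigid), an internal correlation time
τe, and the overall tumbling time τm.  The spectral density is

    J(ω) = (2/5)·[S²·τm/(1+(ωτm)²) + (1−S²)·τ′/(1+(ωτ′)²)],
    1/τ′ = 1/τm + 1/τe,

and R1, R2, NOE follow from the standard ¹⁵N dipolar + CSA linear
combinations of J at {0, ωN, ωH−ωN, ωH, ωH+ωN}.  Five per-residue models
are fit and selected by AIC:

    m1: S²            m2: S², τe          m3: S², Rex
    m4: S², τe, Rex   m5: S²f, S²s, τs   (extended model-free)

Rex is parameterised at the reference field and scaled by (B0/B0_ref)².
Diffusion is treated as a local τm or a shared isotropic sphere; anisotropic
tensors would require a structure and are out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares, minimize_scalar
from scipy.stats import trim_mean

from .constants import REF_FIELD_MHZ, PhysicalConstants
from .exceptions import FitError
from .io_tables import ResidueKey

__all__ = [
    "RelaxationRates", "ModelFreeParams",
    "spectral_density", "spectral_density_ext", "predict_rates",
    "estimate_tm", "fit_modelfree",
]

MF_MODELS = ("m1", "m2", "m3", "m4", "m5")


@dataclass
class RelaxationRates:
    """¹⁵N R1/R2/NOE (with 1σ uncertainties) at one static field."""

    residue: ResidueKey
    field_mhz: float
    r1: float
    r1_err: float
    r2: float
    r2_err: float
    noe: float
    noe_err: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("R1 and R2 must be positive")
        if min(self.r1_err, self.r2_err, self.noe_err) <= 0:
            raise ValueError("rate uncertainties must be positive")


@dataclass
class ModelFreeParams:
    """Parameters of one model-free form for one residue."""

    model: str                    # m1..m5
    s2: float                     # generalised order parameter (S²f·S²s for m5)
    tau_m_ns: float
    tau_e_ps: float = 0.0
    rex: float = 0.0              # s⁻¹ at the reference field
    s2f: float = 1.0
    s2s: float = 1.0
    tau_s_ps: float = 0.0
    chi2: float = float("nan")
    aic: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError("S² must lie in [0, 1]")
        if self.rex < 0:
            raise ValueError("Rex must be non-negative")
        if self.tau_e_ps >= self.tau_m_ns * 1e3:
            raise ValueError("tau_e must be shorter than tau_m")


def spectral_density(s2: float, tau_m_s: float, tau_e_s: float,
                     omega) -> np.ndarray:
    """Lipari–Szabo spectral density J(ω) in s/rad (τ in seconds)."""
    omega = np.abs(np.asarray(omega, dtype=float))
    j = s2 * tau_m_s / (1.0 + (omega * tau_m_s) ** 2)
    if tau_e_s > 0.0 and s2 < 1.0:
        tau_p = 1.0 / (1.0 / tau_m_s + 1.0 / tau_e_s)
        j = j + (1.0 - s2) * tau_p / (1.0 + (omega * tau_p) ** 2)
    return 0.4 * j


def spectral_density_ext(s2f: float, s2s: float, tau_m_s: float,
                         tau_s_s: float, omega) -> np.ndarray:
    """Extended (two-timescale) model-free J(ω): fast internal motion in the
    extreme-narrowing limit, slow internal motion with correlation time τs."""
    omega = np.abs(np.asarray(omega, dtype=float))
    j = s2f * s2s * tau_m_s / (1.0 + (omega * tau_m_s) ** 2)
    if tau_s_s > 0.0 and s2s < 1.0:
        tau_p = 1.0 / (1.0 / tau_m_s + 1.0 / tau_s_s)
        j = j + s2f * (1.0 - s2s) * tau_p / (1.0 + (omega * tau_p) ** 2)
    return 0.4 * j


def _j_five(params: ModelFreeParams, omega_h: float, omega_n: float):
    """J at the five frequencies entering the ¹⁵N rate expressions."""
    tau_m = params.tau_m_ns * 1e-9
    freqs = np.array([0.0, omega_n, omega_h - omega_n, omega_h,
                      omega_h + omega_n])
    if params.model == "m5":
        return spectral_density_ext(params.s2f, params.s2s, tau_m,
                                    params.tau_s_ps * 1e-12, freqs)
    return spectral_density(params.s2, tau_m, params.tau_e_ps * 1e-12, freqs)


def predict_rates(params: ModelFreeParams, field_mhz: float,
                  constants: PhysicalConstants = PhysicalConstants(),
                  ref_field: float = REF_FIELD_MHZ):
    """Forward-calculate (R1, R2, NOE) at one field from model-free
    parameters.

    Dipolar and CSA contributions use the standard linear combinations of
    J(0), J(ωN), J(ωH−ωN), J(ωH), J(ωH+ωN); an Rex term, when the model
    carries one, adds to R2 scaled by (B0/B0_ref)².
    """
    omega_h, omega_n = constants.larmor_rad_s(field_mhz)
    j0, jn, jhmn, jh, jhpn = _j_five(params, omega_h, omega_n)
    d2 = constants.dipolar_coupling ** 2
    c2 = constants.csa_coupling(field_mhz) ** 2

    r1 = d2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (d2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
          + c2 / 6.0 * (4.0 * j0 + 3.0 * jn))
    gamma_ratio = constants.gamma_h / constants.gamma_n
    noe = 1.0 + gamma_ratio * (d2 / 4.0) * (6.0 * jhpn - jhmn) / r1
    rex = params.rex * (field_mhz / ref_field) ** 2
    return float(r1), float(r2 + rex), float(noe)


# ---------------------------------------------------------------------------
# overall tumbling time from R2/R1

def _rigid_ratio(tau_m_ns: float, field_mhz: float,
                 constants: PhysicalConstants) -> float:
    p = ModelFreeParams("m1", s2=1.0, tau_m_ns=tau_m_ns)
    r1, r2, _ = predict_rates(p, field_mhz, constants)
    return r2 / r1


def estimate_tm(rates: list[RelaxationRates],
                noe_cutoff: float = 0.65,
                exclude: set[int] | None = None,
                trim: float = 0.1,
                constants: PhysicalConstants = PhysicalConstants(),
                tm_bracket_ns: tuple[float, float] = (1.0, 50.0)) -> float:
    """Estimate the overall tumbling time from rigid-residue R2/R1 ratios.

    Residues with NOE below ``noe_cutoff`` or listed in ``exclude`` (e.g.
    sites with an individually selected exchange term) are removed, the
    rigid-limit R2/R1(τm) relation is inverted per residue, and the trimmed
    mean over residues is returned in ns.  Requires at least five rigid
    residues; data in the extreme-narrowing regime (ratio below the
    bracket's lower end) are rejected as uninformative.
    """
    exclude = exclude or set()
    rigid = [r for r in rates
             if r.noe >= noe_cutoff and r.residue.number not in exclude]
    if len(rigid) < 5:
        raise FitError(f"only {len(rigid)} rigid residues; need >= 5 for "
                       "the diffusion estimate")
    lo, hi = tm_bracket_ns
    tms = []
    for r in rigid:
        ratio = r.r2 / r.r1
        f_lo = _rigid_ratio(lo, r.field_mhz, constants) - ratio
        f_hi = _rigid_ratio(hi, r.field_mhz, constants) - ratio
        if f_lo * f_hi > 0:
            if f_lo > 0:
                raise FitError(
                    f"residue {r.residue}: R2/R1 = {ratio:.3f} below the "
                    "rigid-limit bracket (extreme narrowing, uninformative)")
            continue  # beyond the upper bracket: aggregation, skip
        tms.append(brentq(lambda tm: _rigid_ratio(tm, r.field_mhz, constants)
                          - ratio, lo, hi))
    if len(tms) < 5:
        raise FitError("fewer than 5 residues yielded a tumbling time")
    return float(trim_mean(tms, trim))


# ---------------------------------------------------------------------------
# per-residue model fitting

def _mf_param_spec(model: str, tau_m_ns: float):
    tau_e_max = min(0.5 * tau_m_ns * 1e3, 5000.0)
    spec = {
        "m1": (["s2"], [0.9], [0.0], [1.0]),
        "m2": (["s2", "tau_e_ps"], [0.9, 50.0], [0.0, 0.0],
               [1.0, tau_e_max]),
        "m3": (["s2", "rex"], [0.9, 1.0], [0.0, 0.0], [1.0, 50.0]),
        "m4": (["s2", "tau_e_ps", "rex"], [0.9, 50.0, 1.0],
               [0.0, 0.0, 0.0], [1.0, tau_e_max, 50.0]),
        "m5": (["s2f", "s2s", "tau_s_ps"], [0.95, 0.9, 500.0],
               [0.0, 0.0, 0.0], [1.0, 1.0, tau_e_max]),
    }
    return spec[model]


def _params_from_theta(model: str, theta, tau_m_ns: float) -> ModelFreeParams:
    names, *_ = _mf_param_spec(model, tau_m_ns)
    kw = dict(zip(names, (float(v) for v in theta)))
    if model == "m5":
        s2 = kw["s2f"] * kw["s2s"]
        return ModelFreeParams("m5", s2=s2, tau_m_ns=tau_m_ns,
                               tau_s_ps=kw["tau_s_ps"], s2f=kw["s2f"],
                               s2s=kw["s2s"])
    return ModelFreeParams(model, tau_m_ns=tau_m_ns, **kw)


def _fit_residue_models(rates: list[RelaxationRates], tau_m_ns: float,
                        constants: PhysicalConstants,
                        models=MF_MODELS) -> ModelFreeParams | None:
    """Fit m1–m5 for one residue at fixed τm; AIC selection, ties to the
    simpler model.  Returns None when nothing converges."""
    obs = np.array([[r.r1, r.r2, r.noe] for r in rates]).ravel()
    sig = np.array([[r.r1_err, r.r2_err, r.noe_err] for r in rates]).ravel()
    fields = [r.field_mhz for r in rates]

    def residuals(theta, model):
        p = _params_from_theta(model, theta, tau_m_ns)
        pred = np.array([predict_rates(p, f, constants) for f in fields])
        return (pred.ravel() - obs) / sig

    candidates: list[ModelFreeParams] = []
    for model in models:
        names, x0, lb, ub = _mf_param_spec(model, tau_m_ns)
        try:
            res = least_squares(residuals, x0, args=(model,),
                                bounds=(lb, ub), max_nfev=500)
        except Exception:                                    # noqa: BLE001
            continue
        if not res.success:
            continue
        p = _params_from_theta(model, res.x, tau_m_ns)
        p.chi2 = float(2.0 * res.cost)
        p.aic = p.chi2 + 2.0 * len(names)
        candidates.append(p)
    if not candidates:
        return None
    aic_min = min(p.aic for p in candidates)
    tied = [p for p in candidates if p.aic - aic_min < 2.0]
    n_par = {m: len(_mf_param_spec(m, tau_m_ns)[0]) for m in MF_MODELS}
    return min(tied, key=lambda p: (n_par[p.model], p.aic))


def fit_modelfree(rates_by_residue: dict[int, list[RelaxationRates]],
                  tau_m_ns: float | None = None,
                  diffusion: str = "shared",
                  constants: PhysicalConstants = PhysicalConstants(),
                  noe_cutoff: float = 0.65,
                  max_rounds: int = 10,
                  tm_rtol: float = 0.005):
    """Model-free analysis of a residue set.

    With ``diffusion='shared'`` a single isotropic τm is iterated against
    the per-residue model fits: τm is re-optimised over all fit residues by
    minimising the total χ², models are refit, and iteration stops when τm
    changes by less than ``tm_rtol`` (0.5%) between rounds.  With
    ``diffusion='local'`` each residue instead carries its own τm fit
    jointly with its internal parameters.

    Returns (results, tau_m_ns) where results maps residue number to the
    selected :class:`ModelFreeParams` (residues where no model converges are
    reported as None and excluded from τm refinement).
    """
    if diffusion not in ("shared", "local"):
        raise ValueError("diffusion must be 'shared' or 'local'")

    flat = [r for rs in rates_by_residue.values() for r in rs]
    if tau_m_ns is None:
        tau_m_ns = estimate_tm(flat, noe_cutoff=noe_cutoff,
                               constants=constants)

    if diffusion == "local":
        results = {res: _fit_local_tm(rs, tau_m_ns, constants)
                   for res, rs in rates_by_residue.items()}
        return results, tau_m_ns

    tau_m = tau_m_ns
    results: dict[int, ModelFreeParams | None] = {}
    for _ in range(max_rounds):
        results = {res: _fit_residue_models(rs, tau_m, constants)
                   for res, rs in rates_by_residue.items()}
        fit_set = {res: p for res, p in results.items() if p is not None}
        if not fit_set:
            raise FitError("no residue converged in model-free fitting")

        def total_chi2(tm: float) -> float:
            tot = 0.0
            for res, p in fit_set.items():
                refit = _fit_residue_models(rates_by_residue[res], tm,
                                            constants, models=(p.model,))
                tot += refit.chi2 if refit is not None else 1e6
            return tot

        opt = minimize_scalar(total_chi2,
                              bounds=(max(0.5 * tau_m, 0.5),
                                      min(2.0 * tau_m, 60.0)),
                              method="bounded",
                              options={"xatol": tau_m * 1e-3})
        new_tm = float(opt.x)
        if abs(new_tm - tau_m) / tau_m < tm_rtol:
            tau_m = new_tm
            break
        tau_m = new_tm
    results = {res: _fit_residue_models(rs, tau_m, constants)
               for res, rs in rates_by_residue.items()}
    return results, tau_m


def _fit_local_tm(rates: list[RelaxationRates], tm0: float,
                  constants: PhysicalConstants) -> ModelFreeParams | None:
    """Local-τm variant: scan τm for the residue, keep the best AIC."""
    best: ModelFreeParams | None = None
    for tm in np.linspace(max(tm0 * 0.5, 1.0), tm0 * 1.5, 21):
        p = _fit_residue_models(rates, float(tm), constants)
        if p is not None and (best is None or p.chi2 < best.chi2):
            best = p
    return best
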