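"""CPMG relaxation dispersion: R2eff conversion, two-state exchange models,
per-residue and global fitting with AIC model selection.

The dispersion experiment measures the effective transverse relaxation rate
R2eff as a function of the CPMG refocusing frequency νCPMG during a constant
relaxation period (20 ms by default).  Curvature of R2eff(νCPMG) reports
µs–ms conformational exchange.  Three models are fit per residue:

``norex``
    R2eff = R20 — a flat profile, no exchange.

``meiboom``
    Two-state fast exchange,
    R2eff = R20 + (φ/kex)·[1 − (4νCPMG/kex)·tanh(kex/(4νCPMG))],
    with φ = pA·pB·Δω² parameterised at a reference field (600 MHz) and
    scaled by (B0/B0_ref)² at other fields, since Δω ∝ B0.

``cr72``
    The Carver–Richards closed form for two-site exchange, valid from fast
    to intermediate regimes, parameterised by (pA, Δω in ppm, kex).

Model selection uses AIC = χ² + 2k with known per-point σ; ties within
ΔAIC < 2 resolve to the fewer-parameter model.  Residues whose individual
selection chose an exchange model are eligible for a global fit sharing a
single kex, the signature of a concerted exchange process.

Dual-field data are always fit jointly per residue: R20 is per-field while
the exchange parameters are shared across fields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import least_squares

from .constants import REF_FIELD_MHZ, T_RELAX_CPMG, dw_ppm_to_rad_s
from .exceptions import FitError
from .io_tables import IntensitySeries, ResidueKey

__all__ = [
    "DispersionProfile", "ExchangeFit", "ResidueFitResult", "GlobalFit",
    "compute_r2eff", "model_norex", "model_meiboom", "model_cr72",
    "estimate_errors", "profile_from_series", "fit_residue", "fit_global",
    "fit_decay", "compute_hetnoe", "global_fit_frame",
    "profiles_to_frame", "profiles_from_frame",
]

MODELS = ("norex", "meiboom", "cr72")
#: multi-start grid for kex (s⁻¹); exchange-rate landscapes are multimodal
KEX_STARTS = tuple(np.logspace(1, 4, 5))
KEX_BOUNDS = (1.0, 1e6)


# ---------------------------------------------------------------------------
# data containers

@dataclass
class DispersionProfile:
    """R2eff(νCPMG) for one residue at one static field.

    νCPMG values are strictly positive: the νCPMG = 0 plane is the intensity
    reference consumed by :func:`compute_r2eff`, never an R2eff point.
    """

    residue: ResidueKey
    field_mhz: float
    nu_cpmg_hz: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.nu_cpmg_hz = np.asarray(self.nu_cpmg_hz, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.nu_cpmg_hz <= 0):
            raise ValueError("nu_cpmg values must be strictly positive "
                             "(the 0 plane is the reference)")
        if np.any(self.sigma <= 0):
            raise ValueError("every R2eff point needs sigma > 0")

    def __len__(self) -> int:
        return len(self.nu_cpmg_hz)


@dataclass
class ExchangeFit:
    """One fitted dispersion model for one residue (all fields jointly)."""

    model: str
    r20: dict[float, float]              # per-field R20, s⁻¹
    params: dict[str, float]             # phi/kex or pa/dw_ppm/kex
    stderr: dict[str, float]
    chi2: float
    aic: float
    n_points: int
    n_params: int
    converged: bool = True
    message: str = ""


@dataclass
class ResidueFitResult:
    residue: ResidueKey
    fits: dict[str, ExchangeFit]
    selected: str

    @property
    def has_exchange(self) -> bool:
        return self.selected != "norex"


@dataclass
class GlobalFit:
    """Joint fit of several residues sharing a single exchange rate."""

    model: str
    kex: float
    kex_err: float
    members: list[ResidueKey]
    per_residue: pd.DataFrame            # residue, R20_<field>..., phi/dw,pa
    chi2: float
    aic: float
    aic_individual_sum: float | None
    n_points: int
    n_params: int
    warnings: list[str] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# R2eff conversion and error estimation

def compute_r2eff(intensity, reference_intensity, t_relax: float = T_RELAX_CPMG,
                  sigma_i=None, sigma_i0=None):
    """Convert a constant-time CPMG intensity to R2eff = −ln(I/I0)/T.

    Uncertainties, when given, propagate to first order:
    σ_R = sqrt((σI/I)² + (σI0/I0)²)/T.  Returns (r2eff, sigma); sigma is
    None when no intensity uncertainties were supplied.  I ≥ I0 is allowed
    (R2eff ≤ 0) and left to the caller to flag; non-positive intensities
    are errors.
    """
    intensity = np.asarray(intensity, dtype=float)
    i0 = np.asarray(reference_intensity, dtype=float)
    if t_relax <= 0:
        raise ValueError("t_relax must be positive")
    if np.any(intensity <= 0) or np.any(i0 <= 0):
        raise ValueError("intensities must be positive")
    r2eff = -np.log(intensity / i0) / t_relax
    if sigma_i is None and sigma_i0 is None:
        return r2eff, None
    var = np.zeros_like(r2eff)
    if sigma_i is not None:
        var = var + (np.asarray(sigma_i, dtype=float) / intensity) ** 2
    if sigma_i0 is not None:
        var = var + (np.asarray(sigma_i0, dtype=float) / i0) ** 2
    return r2eff, np.sqrt(var) / t_relax


def estimate_errors(axis_values, values, floor_frac: float = 0.01,
                    default_sigma: float = 0.3) -> float:
    """Pooled standard deviation over duplicate axis points.

    Uncertainty is estimated from replicate spectra recorded at duplicated
    axis values: for each duplicated value the squared deviations from the
    group mean are pooled, σ² = ΣSS / Σ(m−1).  The result applies to every
    point of the series and is floored at ``floor_frac`` of the median
    |value| so a lucky pair of identical replicates cannot zero the weights.
    With no duplicates the configured ``default_sigma`` is returned with a
    warning.
    """
    axis_values = np.asarray(axis_values, dtype=float)
    values = np.asarray(values, dtype=float)
    ss = 0.0
    dof = 0
    for v in np.unique(axis_values):
        group = values[axis_values == v]
        if len(group) > 1:
            ss += float(np.sum((group - group.mean()) ** 2))
            dof += len(group) - 1
    floor = floor_frac * float(np.median(np.abs(values))) if len(values) else 0.0
    if dof == 0:
        warnings.warn("no duplicate points; falling back to default sigma",
                      stacklevel=2)
        return max(default_sigma, floor)
    return max(math.sqrt(ss / dof), floor)


def profile_from_series(series: IntensitySeries,
                        t_relax: float = T_RELAX_CPMG,
                        floor_frac: float = 0.01,
                        default_sigma: float = 0.3) -> DispersionProfile:
    """Convert a CPMG intensity series into a DispersionProfile.

    The νCPMG = 0 rows are averaged into the reference intensity I0; every
    other row becomes one R2eff point.  Per-point σ comes from the pooled
    duplicate spread on the R2eff scale.
    """
    if series.axis_kind != "cpmg":
        raise ValueError("profile_from_series expects a cpmg series")
    pts = series.points
    ref = pts.loc[pts["axis_value"] == 0.0, "intensity"]
    if ref.empty:
        raise FitError(f"residue {series.residue}: no reference plane")
    i0 = float(ref.mean())
    rest = pts[pts["axis_value"] > 0.0]
    nu = rest["axis_value"].to_numpy(dtype=float)
    r2eff, _ = compute_r2eff(rest["intensity"].to_numpy(dtype=float), i0,
                             t_relax)
    sigma = estimate_errors(nu, r2eff, floor_frac=floor_frac,
                            default_sigma=default_sigma)
    return DispersionProfile(series.residue, series.field_mhz, nu, r2eff,
                             np.full_like(r2eff, sigma))


# ---------------------------------------------------------------------------
# forward models

def model_norex(r20: float, nu_cpmg_hz) -> np.ndarray:
    """No exchange: a flat profile, R2eff = R20."""
    if r20 <= 0:
        raise ValueError("R20 must be positive")
    return np.full_like(np.asarray(nu_cpmg_hz, dtype=float), r20)


def model_meiboom(r20: float, phi: float, kex: float, nu_cpmg_hz) -> np.ndarray:
    """Two-state fast-exchange dispersion (Meiboom).

    R2eff = R20 + (φ/kex)·[1 − (4νCPMG/kex)·tanh(kex/(4νCPMG))].
    At νCPMG = 0 the analytic limit R20 + φ/kex is used.
    """
    if kex <= 0:
        raise ValueError("kex must be positive")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    nu = np.asarray(nu_cpmg_hz, dtype=float)
    out = np.full_like(nu, r20 + phi / kex)
    pos = nu > 0
    x = kex / (4.0 * nu[pos])
    out[pos] = r20 + (phi / kex) * (1.0 - np.tanh(x) / x)
    return out


def model_cr72(r20: float, pa: float, dw_ppm: float, kex: float,
               nu_cpmg_hz, field_mhz: float) -> np.ndarray:
    """Carver–Richards closed form for two-site exchange (equal intrinsic
    R20 in both states).

    Δω is given in ¹⁵N ppm and converted to rad/s at the stated ¹H field.
    The cosh⁻¹ is evaluated through a log-sum-exp branch when its argument
    would overflow, so the return value is always finite.
    """
    if not 0.5 < pa < 1.0:
        raise ValueError("pa must be in (0.5, 1)")
    if kex <= 0:
        raise ValueError("kex must be positive")
    nu = np.asarray(nu_cpmg_hz, dtype=float)
    if dw_ppm == 0.0:
        return np.full_like(nu, r20)
    dw = dw_ppm_to_rad_s(dw_ppm, field_mhz)
    pb = 1.0 - pa
    psi = kex * kex - dw * dw
    zeta = -2.0 * dw * kex * (pa - pb)
    root = math.hypot(psi, zeta)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)
    eta_plus = np.sqrt(max(psi + root, 0.0) / 2.0) / (2.0 * nu)
    eta_minus = np.sqrt(max(root - psi, 0.0) / 2.0) / (2.0 * nu)

    cos_m = np.cos(eta_minus)
    small = eta_plus < 30.0
    acosh_term = np.empty_like(nu)
    arg = d_plus * np.cosh(eta_plus[small]) - d_minus * cos_m[small]
    acosh_term[small] = np.arccosh(np.maximum(arg, 1.0))
    if np.any(~small):
        ep = eta_plus[~small]
        # arccosh(x) ≈ ln(2x); ln(2x) expanded around the dominant e^{η+}
        inner = (d_plus * (1.0 + np.exp(-2.0 * ep))
                 - 2.0 * d_minus * cos_m[~small] * np.exp(-ep))
        acosh_term[~small] = ep + np.log(np.maximum(inner, 1e-300))
    return r20 + 0.5 * kex - nu * acosh_term


# ---------------------------------------------------------------------------
# per-residue fitting

def _phi_scale(field_mhz: float, ref_field: float) -> float:
    return (field_mhz / ref_field) ** 2


def _stack(profiles: list[DispersionProfile]):
    nu = np.concatenate([p.nu_cpmg_hz for p in profiles])
    y = np.concatenate([p.r2eff for p in profiles])
    s = np.concatenate([p.sigma for p in profiles])
    fid = np.concatenate([np.full(len(p), i) for i, p in enumerate(profiles)])
    return nu, y, s, fid.astype(int)


def _residue_model_eval(model: str, theta: np.ndarray,
                        profiles: list[DispersionProfile], nu, fid,
                        ref_field: float) -> np.ndarray:
    nf = len(profiles)
    pred = np.empty_like(nu)
    for i, p in enumerate(profiles):
        m = fid == i
        if model == "norex":
            pred[m] = theta[i]
        elif model == "meiboom":
            phi = theta[nf] * _phi_scale(p.field_mhz, ref_field)
            pred[m] = model_meiboom(theta[i], phi, theta[nf + 1], nu[m])
        else:
            pred[m] = model_cr72(theta[i], theta[nf], theta[nf + 1],
                                 theta[nf + 2], nu[m], p.field_mhz)
    return pred


def _fit_one_model(model: str, profiles: list[DispersionProfile],
                   ref_field: float) -> ExchangeFit:
    nu, y, s, fid = _stack(profiles)
    nf = len(profiles)
    fields = [p.field_mhz for p in profiles]
    r20_init = [max(float(np.min(p.r2eff)), 0.1) for p in profiles]

    if model == "norex":
        # weighted mean per field is the exact WLS solution
        r20 = {}
        chi2 = 0.0
        stderr = {}
        for i, p in enumerate(profiles):
            w = 1.0 / p.sigma**2
            mu = float(np.sum(w * p.r2eff) / np.sum(w))
            r20[p.field_mhz] = mu
            chi2 += float(np.sum(w * (p.r2eff - mu) ** 2))
            stderr[f"r20_{p.field_mhz:g}"] = float(1.0 / math.sqrt(np.sum(w)))
        k = nf
        return ExchangeFit("norex", r20, {}, stderr, chi2, chi2 + 2 * k,
                           len(y), k)

    amp = max(float(np.max(y) - np.min(y)), 1e-3)

    def residuals(theta):
        return (_residue_model_eval(model, theta, profiles, nu, fid,
                                    ref_field) - y) / s

    best = None
    for kex0 in KEX_STARTS:
        if model == "meiboom":
            x0 = np.array(r20_init + [amp * kex0, kex0])
            lb = [1e-6] * nf + [0.0, KEX_BOUNDS[0]]
            ub = [np.inf] * nf + [np.inf, KEX_BOUNDS[1]]
        else:
            pa0 = 0.95
            dw0 = math.sqrt(max(amp * kex0, 1.0) / (pa0 * (1 - pa0)))
            dw0_ppm = min(max(dw0 / dw_ppm_to_rad_s(1.0, ref_field), 0.05), 20.0)
            x0 = np.array(r20_init + [pa0, dw0_ppm, kex0])
            lb = [1e-6] * nf + [0.5 + 1e-6, 1e-4, KEX_BOUNDS[0]]
            ub = [np.inf] * nf + [1.0 - 1e-6, 50.0, KEX_BOUNDS[1]]
        try:
            res = least_squares(residuals, x0, bounds=(lb, ub),
                                method="trf", max_nfev=2000)
        except Exception:                                   # noqa: BLE001
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"{model} fit did not converge")

    theta = best.x
    chi2 = float(2.0 * best.cost)
    k = len(theta)
    stderr_vec = _covariance_stderr(best.jac)
    r20 = {fields[i]: float(theta[i]) for i in range(nf)}
    if model == "meiboom":
        names = [f"r20_{f:g}" for f in fields] + ["phi", "kex"]
        params = {"phi": float(theta[nf]), "kex": float(theta[nf + 1])}
    else:
        names = [f"r20_{f:g}" for f in fields] + ["pa", "dw_ppm", "kex"]
        params = {"pa": float(theta[nf]), "dw_ppm": float(theta[nf + 1]),
                  "kex": float(theta[nf + 2])}
    stderr = dict(zip(names, stderr_vec))
    return ExchangeFit(model, r20, params, stderr, chi2, chi2 + 2 * k,
                       len(y), k, converged=best.success,
                       message=best.message)


def _covariance_stderr(jac: np.ndarray) -> list[float]:
    try:
        cov = np.linalg.pinv(jac.T @ jac)
        return [float(math.sqrt(max(v, 0.0))) for v in np.diag(cov)]
    except np.linalg.LinAlgError:
        return [float("nan")] * jac.shape[1]


def fit_residue(profiles: list[DispersionProfile],
                models: tuple[str, ...] = MODELS,
                ref_field: float = REF_FIELD_MHZ,
                delta_aic_tie: float = 2.0) -> ResidueFitResult:
    """Fit each candidate model to one residue's profiles (all fields
    jointly) and select by AIC.

    AIC = χ² + 2k with known per-point σ.  Fits whose AIC lies within
    ``delta_aic_tie`` of the minimum are treated as ties and the
    fewest-parameter model wins, so exchange is only claimed when the data
    demand it.  A model that fails to converge is excluded with a
    diagnostic and selection proceeds over the remainder.
    """
    if not profiles:
        raise ValueError("no profiles given")
    if any(len(p) < 8 for p in profiles):
        raise FitError(f"residue {profiles[0].residue}: need >= 8 points "
                       "per field")
    residue = profiles[0].residue
    fits: dict[str, ExchangeFit] = {}
    for model in models:
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        try:
            fits[model] = _fit_one_model(model, profiles, ref_field)
        except FitError as exc:
            warnings.warn(f"residue {residue}: {exc}", stacklevel=2)
    if not fits:
        raise FitError(f"residue {residue}: no model converged")
    aic_min = min(f.aic for f in fits.values())
    tied = [f for f in fits.values() if f.aic - aic_min < delta_aic_tie]
    selected = min(tied, key=lambda f: (f.n_params, f.aic)).model
    return ResidueFitResult(residue, fits, selected)


# ---------------------------------------------------------------------------
# global fitting

def _global_pack(model: str, n_res: int, n_fields: int):
    per_res = n_fields + (1 if model == "meiboom" else 2)
    n_params = 1 + n_res * per_res
    return per_res, n_params


def _global_eval(model: str, theta: np.ndarray,
                 member_profiles: list[list[DispersionProfile]],
                 ref_field: float) -> np.ndarray:
    kex = theta[0]
    chunks = []
    per_res = None
    pos = 1
    for profiles in member_profiles:
        nf = len(profiles)
        per_res = nf + (1 if model == "meiboom" else 2)
        block = theta[pos:pos + per_res]
        pos += per_res
        for i, p in enumerate(profiles):
            if model == "meiboom":
                phi = block[nf] * _phi_scale(p.field_mhz, ref_field)
                chunks.append(model_meiboom(block[i], phi, kex, p.nu_cpmg_hz))
            else:
                chunks.append(model_cr72(block[i], block[nf], block[nf + 1],
                                         kex, p.nu_cpmg_hz, p.field_mhz))
    return np.concatenate(chunks)


def fit_global(member_profiles: list[list[DispersionProfile]],
               model: str = "meiboom",
               individual: list[ResidueFitResult] | None = None,
               mc_draws: int = 200,
               seed: int | None = None,
               ref_field: float = REF_FIELD_MHZ) -> GlobalFit:
    """Fit a set of residues jointly with one shared exchange rate.

    Each member keeps its own per-field R20 and dispersion amplitude (φ at
    the reference field for ``meiboom``; pA and Δω for ``cr72``); only kex
    is shared.  Parameter uncertainties come from seeded Monte-Carlo
    resampling of the data within its σ (``mc_draws`` refits; 0 falls back
    to the covariance estimate).  The returned AIC can be compared with the
    sum of the members' individual exchange-fit AICs to decide whether one
    concerted process explains the data.
    """
    if model not in ("meiboom", "cr72"):
        raise ValueError("global fit supports the meiboom and cr72 models")
    if len(member_profiles) < 1:
        raise FitError("global fit needs at least one member residue")
    n_res = len(member_profiles)
    y = np.concatenate([p.r2eff for profs in member_profiles for p in profs])
    s = np.concatenate([p.sigma for profs in member_profiles for p in profs])

    def residuals(theta):
        return (_global_eval(model, theta, member_profiles, ref_field) - y) / s

    # starting points: individual fits when available, else per-residue
    # heuristics plus a kex grid
    kex_starts: list[float]
    if individual is not None:
        kexs = [r.fits[model].params["kex"] for r in individual
                if model in r.fits]
        kex_starts = [float(np.median(kexs))] if kexs else list(KEX_STARTS)
    else:
        kex_starts = list(KEX_STARTS)

    best = None
    for kex0 in kex_starts:
        x0 = [kex0]
        lb = [KEX_BOUNDS[0]]
        ub = [KEX_BOUNDS[1]]
        for profs in member_profiles:
            amp = max(float(np.max(np.concatenate([p.r2eff for p in profs]))
                            - np.min(np.concatenate([p.r2eff for p in profs]))),
                      1e-3)
            for p in profs:
                x0.append(max(float(np.min(p.r2eff)), 0.1))
                lb.append(1e-6)
                ub.append(np.inf)
            if model == "meiboom":
                x0.append(amp * kex0)
                lb.append(0.0)
                ub.append(np.inf)
            else:
                dw0 = math.sqrt(max(amp * kex0, 1.0) / 0.0475)
                x0.append(0.95)
                lb.append(0.5 + 1e-6)
                ub.append(1.0 - 1e-6)
                x0.append(min(max(dw0 / dw_ppm_to_rad_s(1.0, ref_field),
                                  0.05), 20.0))
                lb.append(1e-4)
                ub.append(50.0)
        spar = _global_sparsity(model, member_profiles)
        res = least_squares(residuals, np.asarray(x0), bounds=(lb, ub),
                            method="trf", jac_sparsity=spar, max_nfev=3000)
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    theta = best.x
    chi2 = float(2.0 * best.cost)
    n_points = len(y)
    n_params = len(theta)
    aic = chi2 + 2 * n_params

    warn_list: list[str] = []
    rng = np.random.default_rng(seed)
    if mc_draws > 0:
        kex_draws = []
        failures = 0
        for _ in range(mc_draws):
            y_mc = y + rng.normal(0.0, s)

            def res_mc(th, _y=y_mc):
                return (_global_eval(model, th, member_profiles, ref_field)
                        - _y) / s

            try:
                r = least_squares(res_mc, theta, bounds=(lb, ub),
                                  method="trf",
                                  jac_sparsity=_global_sparsity(
                                      model, member_profiles),
                                  max_nfev=1000)
                if r.success:
                    kex_draws.append(r.x[0])
                else:
                    failures += 1
            except Exception:                               # noqa: BLE001
                failures += 1
        if failures > 0.1 * mc_draws:
            warn_list.append(
                f"Monte-Carlo non-convergence rate {failures}/{mc_draws}")
        kex_err = float(np.std(kex_draws, ddof=1)) if len(kex_draws) > 1 \
            else float("nan")
    else:
        kex_err = _covariance_stderr(
            best.jac.toarray() if sparse.issparse(best.jac) else best.jac)[0]

    rows = []
    pos = 1
    members = []
    for profs in member_profiles:
        nf = len(profs)
        per_res = nf + (1 if model == "meiboom" else 2)
        block = theta[pos:pos + per_res]
        pos += per_res
        members.append(profs[0].residue)
        row: dict = {"residue": profs[0].residue.number}
        for i, p in enumerate(profs):
            row[f"R20_{p.field_mhz:g}"] = float(block[i])
        if model == "meiboom":
            row["phi_ref"] = float(block[nf])
        else:
            row["pa"] = float(block[nf])
            row["dw_ppm"] = float(block[nf + 1])
        rows.append(row)

    aic_ind = None
    if individual is not None:
        fits = [r.fits[model] for r in individual if model in r.fits]
        if len(fits) == len(member_profiles):
            aic_ind = float(sum(f.aic for f in fits))

    return GlobalFit(model, float(theta[0]), kex_err, members,
                     pd.DataFrame(rows), chi2, aic, aic_ind,
                     n_points, n_params, warn_list)


def _global_sparsity(model: str,
                     member_profiles: list[list[DispersionProfile]]):
    n_rows = sum(len(p) for profs in member_profiles for p in profs)
    per_res_list = [len(profs) + (1 if model == "meiboom" else 2)
                    for profs in member_profiles]
    n_cols = 1 + sum(per_res_list)
    spar = sparse.lil_matrix((n_rows, n_cols), dtype=np.uint8)
    spar[:, 0] = 1
    row = 0
    col = 1
    for profs, per_res in zip(member_profiles, per_res_list):
        nf = len(profs)
        shared_cols = list(range(col + nf, col + per_res))
        for i, p in enumerate(profs):
            spar[row:row + len(p), col + i] = 1
            for c in shared_cols:
                spar[row:row + len(p), c] = 1
            row += len(p)
        col += per_res
    return spar


# ---------------------------------------------------------------------------
# T1/T2 decays and hetNOE

def fit_decay(series: IntensitySeries, kind: str | None = None,
              mc_draws: int = 100, seed: int | None = None):
    """Fit a two-parameter exponential I(t) = I0·exp(−R·t) to a T1/T2 series.

    Returns (rate, sigma, warnings).  σ comes from Monte-Carlo resampling
    with the duplicate-delay intensity spread; without duplicates the
    covariance estimate is used.  A decay that rises beyond its noise level
    triggers a non-monotonicity warning.
    """
    if kind is None:
        kind = series.axis_kind
    if kind not in ("t1", "t2"):
        raise ValueError("fit_decay handles t1/t2 series")
    t = series.points["axis_value"].to_numpy(dtype=float)
    i = series.points["intensity"].to_numpy(dtype=float)
    if len(np.unique(t)) < 5 or 0.0 not in t:
        raise FitError(f"residue {series.residue}: need >= 5 delays incl. 0")
    warns: list[str] = []

    def fit_one(y):
        # log-linear start, then nonlinear refinement
        slope, intercept = np.polyfit(t, np.log(np.maximum(y, 1e-12)), 1)
        x0 = np.array([math.exp(intercept), max(-slope, 0.0)])
        res = least_squares(
            lambda th: th[0] * np.exp(-th[1] * t) - y, x0,
            bounds=([0.0, 0.0], [np.inf, np.inf]))
        return res.x

    i0_hat, rate = fit_one(i)

    # noise on the intensity scale: the replicate (duplicate-delay) scatter
    # is part of the residual scatter about the fitted decay, which carries
    # more degrees of freedom (n - 2) than the duplicate pairs alone
    dup_dof = sum(len(i[t == v]) - 1 for v in np.unique(t)
                  if len(i[t == v]) > 1)
    sigma_i = None
    if dup_dof > 0 and len(t) > 2:
        resid = i0_hat * np.exp(-rate * t) - i
        sigma_i = float(np.sqrt(np.sum(resid**2) / (len(t) - 2)))

    order = np.argsort(t)
    tol = 3.0 * (sigma_i or 0.0)
    if np.any(np.diff(i[order]) > tol) and rate > 0:
        warns.append("non-monotonic decay beyond noise")

    if sigma_i is not None and mc_draws > 0:
        rng = np.random.default_rng(seed)
        draws = [fit_one(i + rng.normal(0.0, sigma_i, size=i.shape))[1]
                 for _ in range(mc_draws)]
        sigma_r = float(np.std(draws, ddof=1))
    else:
        res = least_squares(
            lambda th: th[0] * np.exp(-th[1] * t) - i,
            np.array([i0_hat, rate]), bounds=([0.0, 0.0], [np.inf, np.inf]))
        sigma_r = _covariance_stderr(res.jac)[1]
        est = sigma_i if sigma_i is not None else float(
            np.std(res.fun, ddof=2)) if len(t) > 2 else 0.0
        sigma_r *= est if est > 0 else 1.0
    return float(rate), float(sigma_r), warns


def compute_hetnoe(i_sat: float, i_ref: float,
                   sigma_sat: float | None = None,
                   sigma_ref: float | None = None):
    """Steady-state ¹H-[¹⁵N] NOE = I_sat/I_ref with propagated σ.

    Negative saturated intensities pass through (negative NOE marks a
    highly flexible site); a non-positive reference is an error.
    """
    if i_ref <= 0:
        raise ValueError("reference intensity must be positive")
    noe = i_sat / i_ref
    if sigma_sat is None and sigma_ref is None:
        return noe, None
    var = 0.0
    if sigma_sat is not None:
        var += (sigma_sat / i_ref) ** 2
    if sigma_ref is not None:
        var += (i_sat * sigma_ref / i_ref**2) ** 2
    return noe, math.sqrt(var)


# ---------------------------------------------------------------------------
# result tables

R2EFF_COLUMNS = ["residue", "field_MHz", "nu_cpmg_hz", "r2eff", "sigma"]


def profiles_to_frame(profiles_by_residue: dict[int, list[DispersionProfile]]
                      ) -> pd.DataFrame:
    """Flatten dispersion profiles into the R2eff table schema
    (residue, field_MHz, nu_cpmg_hz, r2eff, sigma)."""
    rows = []
    for res, profiles in profiles_by_residue.items():
        for p in profiles:
            for nu, r2, s in zip(p.nu_cpmg_hz, p.r2eff, p.sigma):
                rows.append((res, p.field_mhz, nu, r2, s))
    return pd.DataFrame(rows, columns=R2EFF_COLUMNS)


def profiles_from_frame(df: pd.DataFrame) -> dict[int, list[DispersionProfile]]:
    """Inverse of :func:`profiles_to_frame`."""
    out: dict[int, list[DispersionProfile]] = {}
    for (res, field_mhz), grp in df.groupby(["residue", "field_MHz"],
                                            sort=True):
        out.setdefault(int(res), []).append(DispersionProfile(
            ResidueKey(int(res)), float(field_mhz),
            grp["nu_cpmg_hz"].to_numpy(dtype=float),
            grp["r2eff"].to_numpy(dtype=float),
            grp["sigma"].to_numpy(dtype=float)))
    return out


def global_fit_frame(fit: GlobalFit) -> pd.DataFrame:
    """Flatten a GlobalFit into the documented result schema
    (residue, model, R20_<field>..., phi_ref/pa/dw, kex, kex_err, chi2, AIC).
    """
    df = fit.per_residue.copy()
    df.insert(1, "model", fit.model)
    df["kex"] = fit.kex
    df["kex_err"] = fit.kex_err
    df["chi2"] = fit.chi2
    df["AIC"] = fit.aic
    return df
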