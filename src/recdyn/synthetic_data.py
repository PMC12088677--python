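"""Seeded synthetic inputs with the statistical structure each analysis
stage assumes, so every stage is verifiable by parameter recovery.

Each generator evaluates the same forward model its fitting counterpart
assumes — Meiboom dispersion with φ ∝ B0², Lipari–Szabo relaxation decays,
fast-exchange 1:1 titrations, quadratic binding isotherms, van't Hoff
melts — adds Gaussian noise of configurable σ, and returns the ground
truth alongside the data.  Identical seed and parameters give identical
output.  Default acquisition designs (νCPMG schedule, T1/T2 delays,
16-point two-fold dilution, 20–90 °C at 1 °C) are the printed designs in
:mod:`recdyn.constants`.

Deliberate simplifications: noise is additive Gaussian on the generated
quantity (R2eff, shift, signal, ellipticity) with no intensity dependence,
and titration line broadening is a simple bound-fraction intensity decay
rather than an exchange-regime lineshape model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import Isotherm
from .constants import (DEFAULT_FIELDS_MHZ, MELT_T_MAX_C, MELT_T_MIN_C,
                        MELT_T_STEP_C, MST_N_POINTS, MST_TARGET_CONC_NM,
                        MST_TOP_CONC_UM, NU_CPMG_HZ, REF_FIELD_MHZ,
                        T1_DELAYS_S, T1_DUPLICATES_S, T2_DELAYS_S,
                        T2_DUPLICATES_S, PhysicalConstants)
from .dispersion import DispersionProfile, model_meiboom
from .io_tables import IntensitySeries, PeakTable, ResidueKey
from .modelfree import ModelFreeParams, predict_rates
from .perturbation import TitrationSeries, fraction_bound
from .unfolding import MeltCurve, multi_theta

__all__ = [
    "GeneratorConfig",
    "simulate_dispersion", "draw_dispersion_truth",
    "simulate_relaxation_suite", "simulate_titration", "simulate_isotherm",
    "simulate_melt", "simulate_peak_tables", "write_sparky_list",
]

#: νCPMG schedule without the reference plane
NU_CPMG_POSITIVE = tuple(v for v in NU_CPMG_HZ if v > 0)


@dataclass
class GeneratorConfig:
    """Noise levels and acquisition design shared by the generators."""

    seed: int = 0
    sigma_r2eff: float = 0.3          # s⁻¹
    sigma_shift_ppm: float = 0.005    # ppm, on each of ¹H and ¹⁵N/5 scale
    sigma_signal: float = 1.0         # MST signal units
    sigma_mdeg: float = 0.2           # CD ellipticity
    sigma_intensity_frac: float = 0.01  # relative, relaxation decays
    fields_mhz: tuple[float, ...] = DEFAULT_FIELDS_MHZ
    residues: tuple[int, ...] = tuple(range(250, 270))

    def __post_init__(self) -> None:
        for name in ("sigma_r2eff", "sigma_shift_ppm", "sigma_signal",
                     "sigma_mdeg", "sigma_intensity_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _check_sigma(sigma: float) -> None:
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")


# ---------------------------------------------------------------------------
# CPMG dispersion

def draw_dispersion_truth(n_residues: int, kex: float, seed: int,
                          r20_range=(8.0, 15.0), phi_range=(5e3, 5e4),
                          fields=DEFAULT_FIELDS_MHZ,
                          ref_field: float = REF_FIELD_MHZ,
                          first_residue: int = 250) -> dict:
    """Draw per-residue ground truth for a global-exchange dispersion set.

    R20 is uniform per residue and field in ``r20_range`` (s⁻¹); φ at the
    reference field is uniform in ``phi_range`` (s⁻²); kex is shared.
    """
    rng = np.random.default_rng(seed)
    residues = list(range(first_residue, first_residue + n_residues))
    truth = {"kex": float(kex), "ref_field": ref_field, "residues": {}}
    for res in residues:
        truth["residues"][res] = {
            "r20": {f: float(rng.uniform(*r20_range)) for f in fields},
            "phi": float(rng.uniform(*phi_range)),
        }
    return truth


def simulate_dispersion(truth: dict, sigma: float, seed: int,
                        nu_cpmg=NU_CPMG_POSITIVE):
    """Generate dual-field dispersion profiles from a shared-kex truth.

    R2eff follows the Meiboom model with φ scaled by (B0/B0_ref)² across
    fields, plus Gaussian noise of the given σ.  Returns profiles grouped
    per residue, ordered as in the truth.  The per-point σ attached to the
    profiles is the generating σ (floored at 1e-6 for noiseless data so
    that weighted fits stay defined).
    """
    _check_sigma(sigma)
    if truth["kex"] <= 0:
        raise ValueError("kex must be positive")
    rng = np.random.default_rng(seed)
    nu = np.asarray(nu_cpmg, dtype=float)
    ref = truth["ref_field"]
    sig_rep = max(sigma, 1e-6)
    out: dict[int, list[DispersionProfile]] = {}
    for res, p in truth["residues"].items():
        if p["phi"] < 0:
            raise ValueError("phi must be non-negative")
        profiles = []
        for field_mhz, r20 in p["r20"].items():
            phi_f = p["phi"] * (field_mhz / ref) ** 2
            r2 = model_meiboom(r20, phi_f, truth["kex"], nu)
            if sigma > 0:
                r2 = r2 + rng.normal(0.0, sigma, size=nu.shape)
            profiles.append(DispersionProfile(
                ResidueKey(int(res)), float(field_mhz), nu.copy(), r2,
                np.full_like(nu, sig_rep)))
        out[int(res)] = profiles
    return out


# ---------------------------------------------------------------------------
# R1/R2/NOE relaxation suite

def simulate_relaxation_suite(residue_params: dict[int, tuple[float, float]],
                              tau_m_ns: float,
                              fields=DEFAULT_FIELDS_MHZ,
                              t1_delays=T1_DELAYS_S,
                              t1_duplicates=T1_DUPLICATES_S,
                              t2_delays=T2_DELAYS_S,
                              t2_duplicates=T2_DUPLICATES_S,
                              noise_frac: float = 0.0,
                              seed: int = 0,
                              i0: float = 1e6,
                              constants: PhysicalConstants = PhysicalConstants()):
    """Generate T1/T2 decay tables and NOE pairs from model-free truths.

    ``residue_params`` maps residue number to (S², τe in ps); τm is shared.
    Decays are I(t) = I0·exp(−R·t) with R from the forward calculator; the
    NOE pair is (I_sat, I_ref) with I_sat/I_ref equal to the true NOE
    before noise.  Gaussian noise has σ = ``noise_frac``·I0.  Returns
    (series, truth) where ``series`` is a list of
    :class:`~recdyn.io_tables.IntensitySeries` and ``truth`` maps residue →
    field → (R1, R2, NOE).
    """
    _check_sigma(noise_frac)
    import warnings as _warnings
    rng = np.random.default_rng(seed)
    sigma = noise_frac * i0
    series: list[IntensitySeries] = []
    truth: dict[int, dict[float, tuple[float, float, float]]] = {}

    def delay_rows(delays, dups):
        rows = [(float(d), 0) for d in delays]
        rows += [(float(d), 1) for d in dups]
        return sorted(rows)

    for res, (s2, tau_e_ps) in residue_params.items():
        if not 0.0 <= s2 <= 1.0:
            raise ValueError("S² must lie in [0, 1]")
        if tau_e_ps >= tau_m_ns * 1e3:
            raise ValueError("tau_e must be shorter than tau_m")
        params = ModelFreeParams("m2", s2=s2, tau_m_ns=tau_m_ns,
                                 tau_e_ps=tau_e_ps)
        truth[res] = {}
        for field_mhz in fields:
            r1, r2, noe = predict_rates(params, field_mhz, constants)
            truth[res][field_mhz] = (r1, r2, noe)
            for kind, rate, delays, dups in (
                    ("t1", r1, t1_delays, t1_duplicates),
                    ("t2", r2, t2_delays, t2_duplicates)):
                if max(delays) * rate < np.log(10.0):
                    _warnings.warn(
                        f"{kind} delays cover less than one decade of decay "
                        f"at R = {rate:.2f} s⁻¹", stacklevel=2)
                rows = delay_rows(delays, dups)
                inten = [i0 * np.exp(-rate * d) for d, _ in rows]
                if sigma > 0:
                    inten = [v + rng.normal(0.0, sigma) for v in inten]
                pts = pd.DataFrame({
                    "axis_value": [d for d, _ in rows],
                    "intensity": inten,
                    "replicate": [r for _, r in rows]})
                series.append(IntensitySeries(ResidueKey(res), field_mhz,
                                              kind, pts))
            # NOE pair: axis 0 = reference, 1 = saturated
            i_ref = i0
            i_sat = noe * i0
            if sigma > 0:
                i_ref += rng.normal(0.0, sigma)
                i_sat += rng.normal(0.0, sigma)
            pts = pd.DataFrame({"axis_value": [0.0, 1.0],
                                "intensity": [i_ref, i_sat],
                                "replicate": [0, 0]})
            series.append(IntensitySeries(ResidueKey(res), field_mhz, "noe",
                                          pts))
    return series, truth


# ---------------------------------------------------------------------------
# titrations, isotherms, melts

def simulate_titration(kd_um: float, protein_conc_um: float,
                       ligand_conc_um, ddmax_ppm: dict[int, float],
                       broadened: set[int] | None = None,
                       noise_ppm: float = 0.0, seed: int = 0,
                       bound_intensity_ratio: float = 0.1):
    """Fast-exchange 1:1 titration: Δδ(L) = f_bound(L)·Δδmax per residue.

    Residues in ``broadened`` additionally lose intensity in proportion to
    the bound fraction, down to ``bound_intensity_ratio`` at saturation.
    Returns (:class:`TitrationSeries`, truth dict).
    """
    _check_sigma(noise_ppm)
    if protein_conc_um <= 0:
        raise ValueError("protein concentration must be positive")
    rng = np.random.default_rng(seed)
    lig = np.asarray(ligand_conc_um, dtype=float)
    broadened = broadened or set()
    f = fraction_bound(lig, protein_conc_um, kd_um)
    csp_rows, inten_rows = {}, {}
    for res, ddmax in ddmax_ppm.items():
        if not np.isfinite(ddmax):
            raise ValueError("ddmax must be finite")
        dd = ddmax * f
        if noise_ppm > 0:
            noise = rng.normal(0.0, noise_ppm, size=lig.shape)
            noise[lig == 0.0] = 0.0     # apo is the Δδ = 0 reference
            dd = dd + noise
        csp_rows[res] = dd
        ratio = (1.0 - f * (1.0 - bound_intensity_ratio)
                 if res in broadened else np.ones_like(f))
        inten_rows[res] = ratio
    csp = pd.DataFrame(csp_rows, index=lig).T
    inten = pd.DataFrame(inten_rows, index=lig).T
    truth = {"kd_um": float(kd_um), "ddmax_ppm": dict(ddmax_ppm),
             "broadened": sorted(broadened)}
    return TitrationSeries(protein_conc_um, lig, csp, inten), truth


def simulate_isotherm(kd_um: float, target_conc_nm: float = MST_TARGET_CONC_NM,
                      top_conc_um: float = MST_TOP_CONC_UM,
                      n_points: int = MST_N_POINTS,
                      baseline: float = 800.0, amplitude: float = 60.0,
                      sigma: float = 0.0, seed: int = 0,
                      replicate: int = 0):
    """16-point two-fold serial-dilution MST isotherm.

    signal = baseline + amplitude·f_bound with the labelled target fixed at
    ``target_conc_nm``.  Returns (:class:`Isotherm`, truth dict).
    """
    _check_sigma(sigma)
    if n_points < 6:
        raise ValueError("an isotherm needs at least 6 points")
    rng = np.random.default_rng(seed)
    lig = top_conc_um / 2.0 ** np.arange(n_points)
    f = fraction_bound(lig, target_conc_nm * 1e-3, kd_um)
    signal = baseline + amplitude * f
    if sigma > 0:
        signal = signal + rng.normal(0.0, sigma, size=signal.shape)
    truth = {"kd_um": float(kd_um), "baseline": baseline,
             "amplitude": amplitude}
    return Isotherm(lig, signal, target_conc_nm, replicate), truth


def simulate_melt(transitions, folded_baseline=(0.02, -20.0),
                  unfolded_baseline=(0.01, -5.0),
                  t_min_c: float = MELT_T_MIN_C, t_max_c: float = MELT_T_MAX_C,
                  t_step_c: float = MELT_T_STEP_C,
                  sigma: float = 0.0, seed: int = 0,
                  wavelength_nm: int = 222):
    """CD melt on a 20–90 °C grid (1 °C steps by default).

    ``transitions`` is a list of (Tm °C, ΔH_vH kcal/mol, amplitude); the
    amplitudes must sum to 1.  A single transition is the two-state van't
    Hoff curve; several combine as an amplitude-weighted sum between shared
    linear baselines.  Returns (:class:`MeltCurve`, truth dict).
    """
    _check_sigma(sigma)
    import warnings as _warnings
    amps = sum(a for _, _, a in transitions)
    if abs(amps - 1.0) > 1e-9:
        raise ValueError("transition amplitudes must sum to 1")
    for tm, _, _ in transitions:
        if not t_min_c <= tm <= t_max_c:
            _warnings.warn(f"Tm = {tm} °C lies outside the scanned range",
                           stacklevel=2)
    rng = np.random.default_rng(seed)
    t = np.arange(t_min_c, t_max_c + 0.5 * t_step_c, t_step_c)
    theta = multi_theta(t, transitions, *folded_baseline, *unfolded_baseline)
    if sigma > 0:
        theta = theta + rng.normal(0.0, sigma, size=theta.shape)
    truth = {"transitions": [{"tm_c": tm, "dh_kcal_mol": dh, "amplitude": a}
                             for tm, dh, a in transitions],
             "folded_baseline": tuple(folded_baseline),
             "unfolded_baseline": tuple(unfolded_baseline)}
    return MeltCurve(t, theta, wavelength_nm), truth


# ---------------------------------------------------------------------------
# peak tables (CSP inputs)

def simulate_peak_tables(true_csp: dict[int, tuple[float, float]],
                         broadened: set[int] | None = None,
                         noise_ppm: float = 0.0, seed: int = 0,
                         apo_label: str = "apo", bound_label: str = "bound"):
    """Apo/bound peak-table pair with planted per-residue shifts.

    ``true_csp`` maps residue → (ΔδH, ΔδN) in ppm applied between the apo
    and bound condition.  Residues in ``broadened`` are omitted from the
    bound table (their resonance has vanished).  Gaussian noise of
    ``noise_ppm`` is added to the ¹H shifts and 5·``noise_ppm`` to ¹⁵N in
    both conditions.  Returns (apo, bound, truth).
    """
    _check_sigma(noise_ppm)
    rng = np.random.default_rng(seed)
    broadened = broadened or set()
    aa_cycle = "ACDEFGHIKLMNPQRSTVWY"
    apo_rows, bound_rows = [], []
    for res, (ddh, ddn) in sorted(true_csp.items()):
        aa = aa_cycle[res % len(aa_cycle)]
        dh = float(rng.uniform(7.0, 9.5))
        dn = float(rng.uniform(105.0, 130.0))
        inten = float(rng.uniform(0.8e6, 1.2e6))
        eps = (rng.normal(0.0, noise_ppm, size=4) if noise_ppm > 0
               else np.zeros(4))
        apo_rows.append((res, aa, dh + eps[0], dn + 5 * eps[1], inten,
                         apo_label))
        if res not in broadened:
            bound_rows.append((res, aa, dh + ddh + eps[2],
                               dn + ddn + 5 * eps[3], inten, bound_label))
    cols = ["residue", "aa", "dH_ppm", "dN_ppm", "intensity", "condition"]
    truth = {"csp": dict(true_csp), "broadened": sorted(broadened)}
    return (PeakTable(pd.DataFrame(apo_rows, columns=cols)),
            PeakTable(pd.DataFrame(bound_rows, columns=cols)), truth)


def write_sparky_list(table: PeakTable, path: str | Path,
                      n_unassigned: int = 0, seed: int = 0) -> None:
    """Write a PeakTable as a Sparky-style list, optionally mixing in
    unassigned ``?-?`` rows (as real peak lists do)."""
    rng = np.random.default_rng(seed)
    lines = ["Assignment         w1         w2   Data Height"]
    for _, row in table.data.iterrows():
        lines.append(f"{row['aa']}{int(row['residue'])}N-H"
                     f" {row['dN_ppm']:10.3f} {row['dH_ppm']:10.3f}"
                     f" {row['intensity']:12.1f}")
    for _ in range(n_unassigned):
        lines.append(f"?-? {rng.uniform(100, 135):10.3f}"
                     f" {rng.uniform(6, 10):10.3f}"
                     f" {rng.uniform(1e5, 1e6):12.1f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def truth_sidecar(truth: dict, path: str | Path) -> None:
    """Write a ground-truth JSON sidecar next to a generated dataset."""
    Path(path).write_text(json.dumps(truth, indent=1, default=float),
                          encoding="utf-8")
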