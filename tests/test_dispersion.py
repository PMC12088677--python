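"""Dispersion models, R2eff conversion, error pooling, and exchange fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bloch_mcconnell_r2eff
from recdyn import dispersion as dsp
from recdyn.constants import NU_CPMG_HZ, dw_ppm_to_rad_s
from recdyn.exceptions import FitError
from recdyn.io_tables import IntensitySeries, ResidueKey
from recdyn.synthetic_data import draw_dispersion_truth, simulate_dispersion

NU_POS = np.array([v for v in NU_CPMG_HZ if v > 0])


# ---------------------------------------------------------------------------
# R2eff conversion

def test_r2eff_is_zero_when_intensity_equals_reference():
    r2, _ = dsp.compute_r2eff(5e5, 5e5, 0.020)
    assert r2 == pytest.approx(0.0, abs=1e-15)


def test_r2eff_closed_form_values():
    r2, _ = dsp.compute_r2eff(0.9, 1.0, 0.020)
    assert r2 == pytest.approx(-math.log(0.9) / 0.020, rel=1e-12)
    assert r2 == pytest.approx(5.268, abs=5e-4)
    r2, _ = dsp.compute_r2eff(math.exp(-1.0), 1.0, 0.020)
    assert r2 == pytest.approx(50.0, rel=1e-12)


def test_r2eff_error_propagation_and_validation():
    r2, sig = dsp.compute_r2eff(0.5, 1.0, 0.020, sigma_i=0.01, sigma_i0=0.01)
    expected = math.sqrt((0.01 / 0.5) ** 2 + 0.01**2) / 0.020
    assert sig == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        dsp.compute_r2eff(-1.0, 1.0)


# ---------------------------------------------------------------------------
# forward models

def test_norex_is_flat_and_nests_in_meiboom():
    nu = NU_POS
    np.testing.assert_allclose(dsp.model_norex(12.0, nu), 12.0)
    np.testing.assert_allclose(dsp.model_norex(12.0, nu),
                               dsp.model_meiboom(12.0, 0.0, 500.0, nu))


def test_meiboom_frozen_value_and_zero_frequency_limit():
    # independently evaluated: R20=10, phi=20000 s⁻², kex=147 s⁻¹, nu=25 Hz
    val = dsp.model_meiboom(10.0, 20000.0, 147.0, [25.0])[0]
    assert val == pytest.approx(62.79490456573956, rel=1e-12)
    # nu -> 0 plateau is R20 + phi/kex
    lim = dsp.model_meiboom(10.0, 20000.0, 147.0, [0.0])[0]
    assert lim == pytest.approx(10.0 + 20000.0 / 147.0, rel=1e-12)


def test_meiboom_refocusing_limit():
    val = dsp.model_meiboom(10.0, 50000.0, 1e4, [1e6])[0]
    assert abs(val - 10.0) < 1e-3


@settings(max_examples=50, deadline=None)
@given(r20=st.floats(1.0, 30.0), phi=st.floats(0.0, 1e5),
       kex=st.floats(10.0, 1e4))
def test_meiboom_monotone_non_increasing(r20, phi, kex):
    nu = np.linspace(10.0, 2000.0, 40)
    prof = dsp.model_meiboom(r20, phi, kex, nu)
    assert np.all(np.diff(prof) <= 1e-10)


def test_cr72_reduces_to_norex_when_dw_vanishes():
    np.testing.assert_allclose(
        dsp.model_cr72(10.0, 0.9, 0.0, 500.0, NU_POS, 600.0), 10.0)


def test_cr72_fast_exchange_matches_meiboom():
    pa, dw_ppm, kex, field = 0.95, 1.0, 5000.0, 600.0
    dw = dw_ppm_to_rad_s(dw_ppm, field)
    assert kex / dw >= 10
    phi = pa * (1 - pa) * dw**2
    cr = dsp.model_cr72(10.0, pa, dw_ppm, kex, NU_POS, field)
    mb = dsp.model_meiboom(10.0, phi, kex, NU_POS)
    np.testing.assert_allclose(cr, mb, rtol=1e-2)


def test_cr72_matches_bloch_mcconnell_propagator():
    # fast-to-intermediate grid; the oracle is the dominant eigenvalue of
    # the numerical one-cycle propagator
    for pa in (0.9, 0.95, 0.98):
        for dw_ppm in (1.0, 3.0):
            for kex in (300.0, 2000.0):
                for nu in (25.0, 100.0, 500.0):
                    ref = bloch_mcconnell_r2eff(10.0, pa, dw_ppm, kex, nu,
                                                600.0)
                    val = dsp.model_cr72(10.0, pa, dw_ppm, kex, [nu],
                                         600.0)[0]
                    assert val == pytest.approx(ref, rel=5e-3)


def test_cr72_stays_finite_in_stiff_corner():
    # large dw, slow pulsing: cosh would overflow without the stable branch
    vals = dsp.model_cr72(10.0, 0.99, 30.0, 50.0, [1.0, 5.0, 25.0], 850.0)
    assert np.all(np.isfinite(vals))


# ---------------------------------------------------------------------------
# duplicate-based error estimation

def test_pooled_sigma_from_one_duplicate_pair():
    # pair differing by 2d -> sigma = d*sqrt(2)
    d = 0.35
    axis = [25, 50, 50, 100]
    vals = [12.0, 11.0 - d, 11.0 + d, 10.0]
    sig = dsp.estimate_errors(axis, vals, floor_frac=0.0)
    assert sig == pytest.approx(d * math.sqrt(2), rel=1e-12)


def test_pooled_sigma_three_pairs_matches_hand_computation():
    axis = [50, 50, 500, 500, 800, 800, 100]
    vals = [10.1, 10.5, 9.0, 9.4, 12.0, 12.6, 11.0]
    # hand pooling: SS = 2*(0.2² + 0.2² + 0.3²), dof = 3
    expected = math.sqrt(2 * (0.2**2 + 0.2**2 + 0.3**2) / 3)
    sig = dsp.estimate_errors(axis, vals, floor_frac=0.0)
    assert sig == pytest.approx(expected, rel=1e-9)


def test_identical_duplicates_hit_floor():
    sig = dsp.estimate_errors([50, 50], [10.0, 10.0], floor_frac=0.01)
    assert sig == pytest.approx(0.1)


def test_no_duplicates_falls_back_with_warning():
    with pytest.warns(UserWarning, match="duplicate"):
        sig = dsp.estimate_errors([25, 50], [10.0, 11.0],
                                  default_sigma=0.3, floor_frac=0.0)
    assert sig == 0.3


def test_profile_from_series_consumes_reference_plane():
    nu = [0.0, 0.0, 25.0, 50.0, 50.0, 100.0, 250.0, 500.0, 1000.0]
    rep = [0, 1, 0, 0, 1, 0, 0, 0, 0]
    i0 = 1e6
    inten = [i0 * math.exp(-0.020 * dsp.model_meiboom(10, 2e4, 200, [v])[0])
             if v > 0 else i0 for v in nu]
    pts = pd.DataFrame({"axis_value": nu, "intensity": inten,
                        "replicate": rep})
    series = IntensitySeries(ResidueKey(267), 600.0, "cpmg", pts)
    prof = dsp.profile_from_series(series)
    assert np.all(prof.nu_cpmg_hz > 0)
    assert len(prof) == 7
    expected = dsp.model_meiboom(10, 2e4, 200, prof.nu_cpmg_hz)
    np.testing.assert_allclose(prof.r2eff, expected, rtol=1e-9)


# ---------------------------------------------------------------------------
# per-residue fitting and model selection

def _profiles(kex, phi, seed=0, sigma=0.0, n_res=1, fields=(600.0, 850.0)):
    truth = draw_dispersion_truth(n_res, kex, seed, fields=fields)
    for res in truth["residues"]:
        truth["residues"][res]["phi"] = phi
    return simulate_dispersion(truth, sigma, seed + 1), truth


def test_flat_profile_selects_norex_and_recovers_r20():
    profs, truth = _profiles(kex=500.0, phi=0.0, seed=4)
    res = next(iter(profs))
    result = dsp.fit_residue(profs[res])
    assert result.selected == "norex"
    for p in profs[res]:
        assert result.fits["norex"].r20[p.field_mhz] == pytest.approx(
            truth["residues"][res]["r20"][p.field_mhz], rel=1e-9)


def test_exchange_profile_recovers_kex_and_rejects_norex():
    profs, truth = _profiles(kex=400.0, phi=15000.0, seed=5)
    res = next(iter(profs))
    result = dsp.fit_residue(profs[res])
    assert result.selected in ("meiboom", "cr72")
    fit = result.fits[result.selected]
    assert fit.params["kex"] == pytest.approx(400.0, rel=1e-3)
    assert result.fits["norex"].aic > fit.aic


def test_norex_specificity_on_noisy_flat_profiles():
    wins = 0
    n_seeds = 100
    for seed in range(n_seeds):
        profs, _ = _profiles(kex=500.0, phi=0.0, seed=1000 + seed,
                             sigma=0.3, fields=(600.0,))
        result = dsp.fit_residue(profs[next(iter(profs))])
        wins += result.selected == "norex"
    assert wins >= 90


def test_fit_residue_requires_enough_points():
    profs, _ = _profiles(kex=400.0, phi=1e4, seed=6)
    res = next(iter(profs))
    short = [dsp.DispersionProfile(p.residue, p.field_mhz,
                                   p.nu_cpmg_hz[:5], p.r2eff[:5],
                                   p.sigma[:5]) for p in profs[res]]
    with pytest.raises(FitError, match="8 points"):
        dsp.fit_residue(short)


# ---------------------------------------------------------------------------
# global fitting

def test_single_member_global_fit_matches_individual():
    profs, _ = _profiles(kex=300.0, phi=2e4, seed=7)
    res = next(iter(profs))
    individual = dsp.fit_residue(profs[res])
    gfit = dsp.fit_global([profs[res]], mc_draws=0)
    assert gfit.kex == pytest.approx(
        individual.fits["meiboom"].params["kex"], rel=1e-6)


def test_global_fit_recovers_shared_kex_without_bias():
    # 100-seed recovery study at the working noise level
    errors = []
    for seed in range(100):
        truth = draw_dispersion_truth(5, 250.0, seed=2000 + seed)
        profs = simulate_dispersion(truth, 0.3, seed=7000 + seed)
        gfit = dsp.fit_global(list(profs.values()), mc_draws=0)
        errors.append(gfit.kex / 250.0 - 1.0)
    assert abs(float(np.mean(errors))) < 0.02


def test_global_fit_prefers_splitting_two_kex_groups():
    truth_a = draw_dispersion_truth(3, 150.0, seed=31, phi_range=(2e4, 5e4))
    truth_b = draw_dispersion_truth(3, 1500.0, seed=32, phi_range=(2e4, 5e4),
                                    first_residue=300)
    profs_a = simulate_dispersion(truth_a, 0.3, seed=33)
    profs_b = simulate_dispersion(truth_b, 0.3, seed=34)
    joint = dsp.fit_global(list(profs_a.values()) + list(profs_b.values()),
                           mc_draws=0)
    split_a = dsp.fit_global(list(profs_a.values()), mc_draws=0)
    split_b = dsp.fit_global(list(profs_b.values()), mc_draws=0)
    # splitting adds one kex parameter; AIC must still prefer it
    assert split_a.aic + split_b.aic + 2.0 < joint.aic


def test_global_fit_reports_monte_carlo_uncertainty():
    truth = draw_dispersion_truth(3, 200.0, seed=41)
    profs = simulate_dispersion(truth, 0.3, seed=42)
    gfit = dsp.fit_global(list(profs.values()), mc_draws=25, seed=5)
    assert gfit.kex_err > 0
    assert gfit.kex == pytest.approx(200.0, abs=5 * gfit.kex_err)
    frame = dsp.global_fit_frame(gfit)
    assert {"residue", "model", "kex", "kex_err", "chi2",
            "AIC"} <= set(frame.columns)


def test_profiles_frame_round_trip():
    truth = draw_dispersion_truth(2, 147.0, seed=9)
    profs = simulate_dispersion(truth, 0.3, seed=10)
    frame = dsp.profiles_to_frame(profs)
    back = dsp.profiles_from_frame(frame)
    assert set(back) == set(profs)
    for res in profs:
        for p, q in zip(profs[res], back[res]):
            np.testing.assert_allclose(p.r2eff, q.r2eff, atol=1e-12)


# ---------------------------------------------------------------------------
# decays and NOE

def _decay_series(rate, delays, noise=0.0, seed=0, kind="t1"):
    rng = np.random.default_rng(seed)
    rows = [(d, 1e6 * math.exp(-rate * d), r)
            for d, r in delays]
    pts = pd.DataFrame(rows, columns=["axis_value", "intensity", "replicate"])
    if noise > 0:
        pts["intensity"] += rng.normal(0, noise * 1e6, len(pts))
    return IntensitySeries(ResidueKey(100), 600.0, kind, pts)


T1_SCHEDULE = [(0.0, 0), (0.02, 0), (0.02, 1), (0.06, 0), (0.06, 1),
               (0.1, 0), (0.2, 0), (0.6, 0), (0.6, 1), (0.8, 0), (1.2, 0)]


def test_decay_fit_recovers_rate_exactly_without_noise():
    series = _decay_series(1.2, T1_SCHEDULE)
    rate, _, warns = dsp.fit_decay(series, mc_draws=0)
    assert rate == pytest.approx(1.2, abs=1e-9)
    assert warns == []


def test_flat_decay_gives_zero_rate():
    series = _decay_series(0.0, T1_SCHEDULE)
    rate, _, _ = dsp.fit_decay(series, mc_draws=0)
    assert rate == pytest.approx(0.0, abs=1e-9)


def test_decay_rate_uncertainty_covers_truth():
    # the noise estimate carries n-2 = 9 degrees of freedom, so the
    # 3-sigma interval behaves like a t(9) interval (~98.5% coverage)
    hits = 0
    for seed in range(100):
        series = _decay_series(1.2, T1_SCHEDULE, noise=0.01, seed=seed)
        rate, sig, _ = dsp.fit_decay(series, mc_draws=50, seed=seed)
        hits += abs(rate - 1.2) < 3 * sig
    assert hits >= 96


def test_hetnoe_ratio_and_sign_passthrough():
    assert dsp.compute_hetnoe(1.0, 1.0)[0] == pytest.approx(1.0)
    assert dsp.compute_hetnoe(0.78, 1.0)[0] == pytest.approx(0.78)
    noe, sig = dsp.compute_hetnoe(-0.3, 1.0, sigma_sat=0.01, sigma_ref=0.01)
    assert noe == pytest.approx(-0.3)
    assert sig > 0
    with pytest.raises(ValueError):
        dsp.compute_hetnoe(0.5, 0.0)
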