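"""CSP computation, thresholding, broadening, hotspot mapping, titrations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recdyn import perturbation as pert
from recdyn.exceptions import FitError
from recdyn.synthetic_data import simulate_peak_tables, simulate_titration

# residues reported as most sensitive to loss of tight RNA binding in the
# GeoRec variants; used as a planted ground-truth set
HOTSPOT_RESIDUES = [170, 192, 264, 269, 270, 279, 300, 301, 368, 376, 403,
                    405, 408, 429]


# ---------------------------------------------------------------------------
# combined CSP

def test_identical_tables_give_zero_csp():
    apo, bound, _ = simulate_peak_tables({r: (0.0, 0.0)
                                          for r in range(100, 110)}, seed=1)
    profile = pert.compute_csp(apo, bound)
    assert (profile.data["status"] == "ok").all()
    np.testing.assert_allclose(profile.data["csp_ppm"], 0.0, atol=1e-12)


def test_csp_hand_checked_values():
    # ΔδH = 0.1, ΔδN = 0.5 -> sqrt((0.01 + 0.25/25)/2) = 0.1 ppm
    assert pert.combined_csp(0.1, 0.5) == pytest.approx(0.1, rel=1e-12)
    # ΔδH = 0, ΔδN = 0.5 -> sqrt(0.005) ≈ 0.0707 ppm
    assert pert.combined_csp(0.0, 0.5) == pytest.approx(np.sqrt(0.005),
                                                        rel=1e-12)
    # the literal no-sqrt variant carries the squared scale
    assert pert.combined_csp(0.1, 0.5, sqrt_form=False) == pytest.approx(
        0.01, rel=1e-12)


def test_csp_symmetric_under_condition_swap():
    truth = {r: (0.02 * (r % 3), -0.1 * (r % 2)) for r in range(100, 112)}
    apo, bound, _ = simulate_peak_tables(truth, seed=2)
    forward = pert.compute_csp(apo, bound).finite_csp()
    backward = pert.compute_csp(bound, apo).finite_csp()
    pd.testing.assert_series_equal(forward, backward)


def test_vanished_peaks_are_flagged_broadened():
    truth = {r: (0.05, 0.1) for r in range(100, 112)}
    apo, bound, _ = simulate_peak_tables(truth, broadened={103, 107}, seed=3)
    profile = pert.compute_csp(apo, bound)
    by_res = profile.data.set_index("residue")
    assert by_res.loc[103, "status"] == "broadened"
    assert np.isnan(by_res.loc[103, "csp_ppm"])
    assert by_res.loc[104, "status"] == "ok"


def test_disjoint_tables_are_an_error():
    apo, _, _ = simulate_peak_tables({r: (0, 0) for r in range(100, 105)},
                                     seed=4)
    _, bound, _ = simulate_peak_tables({r: (0, 0) for r in range(300, 305)},
                                       seed=5)
    with pytest.raises(FitError, match="overlap"):
        pert.compute_csp(apo, bound)


# ---------------------------------------------------------------------------
# trimmed threshold

def test_threshold_matches_hand_computed_oracle():
    values = [0.01] * 18 + [0.2, 0.5]
    threshold, significant = pert.trimmed_threshold(values)
    # hand computation: 10% trim removes the two lowest and two highest,
    # trimmed mean = 0.01; untrimmed sample SD = 0.1154123...
    assert threshold == pytest.approx(0.1831184565550421, rel=1e-9)
    assert significant.sum() == 2
    assert set(np.asarray(values)[significant]) == {0.2, 0.5}


def test_constant_values_give_empty_significant_set():
    threshold, significant = pert.trimmed_threshold([0.05] * 15)
    assert threshold == pytest.approx(0.05)
    assert significant.sum() == 0


def test_missing_values_do_not_move_threshold():
    base = [0.01] * 18 + [0.2, 0.5]
    t1, _ = pert.trimmed_threshold(base)
    t2, sig2 = pert.trimmed_threshold(base + [np.nan, np.nan])
    assert t2 == pytest.approx(t1, rel=1e-12)
    assert not sig2[-1]


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(0.1, 100.0))
def test_threshold_scales_linearly(scale):
    base = np.array([0.01] * 12 + [0.05, 0.08, 0.3])
    t1, s1 = pert.trimmed_threshold(base)
    t2, s2 = pert.trimmed_threshold(base * scale)
    assert t2 == pytest.approx(t1 * scale, rel=1e-9)
    np.testing.assert_array_equal(s1, s2)


# ---------------------------------------------------------------------------
# broadening

def test_broadening_flags_trivial_cases():
    apo = pd.Series({1: 1e6, 2: 1e6, 3: 1e6, 4: -5.0})
    bound = pd.Series({1: 1e6, 2: 1e5, 4: 1e6})
    flags = pert.broadening_flags(apo, bound).set_index("residue")
    assert flags.loc[1, "flag"] == "ok"
    assert flags.loc[1, "ratio"] == pytest.approx(1.0)
    assert flags.loc[2, "flag"] == "broadened"       # ratio 0.1 < 0.2
    assert flags.loc[3, "flag"] == "broadened"       # peak vanished
    assert flags.loc[4, "flag"] == "excluded"        # bad apo intensity


def test_generator_broadening_subset_recovered_exactly():
    truth = {r: (0.03, 0.15) for r in range(100, 120)}
    broadened = {105, 111, 118}
    apo, bound, _ = simulate_peak_tables(truth, broadened=broadened, seed=6)
    profile = pert.compute_csp(apo, bound)
    found = set(profile.data.loc[profile.data["status"] == "broadened",
                                 "residue"])
    assert found == broadened


# ---------------------------------------------------------------------------
# residual CSP / hotspots

def _profile_from_csp(csp_by_residue):
    rows = [(res, np.nan, np.nan, csp, "ok", 1.0)
            for res, csp in csp_by_residue.items()]
    return pert.CspProfile(pd.DataFrame(
        rows, columns=["residue", "d_dH_ppm", "d_dN_ppm", "csp_ppm",
                       "status", "intensity_ratio"]))


def _planted_pair(noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    residues = list(range(95, 455, 5))
    wt = {}
    mut = {}
    for res in residues:
        base = 0.05 + 0.01 * (res % 4)
        wt[res] = base + (rng.normal(0, noise) if noise else 0.0)
        drop = 0.15 if res in HOTSPOT_RESIDUES else 0.0
        mut[res] = base - drop + (rng.normal(0, noise) if noise else 0.0)
    for res in HOTSPOT_RESIDUES:       # ensure every hotspot is on the grid
        base = 0.05 + 0.01 * (res % 4)
        wt[res] = base + (rng.normal(0, noise) if noise else 0.0)
        mut[res] = base - 0.15 + (rng.normal(0, noise) if noise else 0.0)
    return _profile_from_csp(wt), _profile_from_csp(mut)


def test_identical_profiles_have_no_hotspots():
    wt, _ = _planted_pair()
    result = pert.residual_csp(wt, wt)
    np.testing.assert_allclose(result.residuals, 0.0, atol=1e-15)
    assert result.hotspots == []
    assert result.anti_hotspots == []


def test_planted_hotspot_set_recovered_exactly():
    wt, mut = _planted_pair()
    result = pert.residual_csp(wt, mut)
    assert sorted(result.hotspots) == HOTSPOT_RESIDUES
    assert result.anti_hotspots == []


def test_hotspot_recall_and_precision_under_noise():
    wt, mut = _planted_pair(noise=0.005, seed=8)
    result = pert.residual_csp(wt, mut)
    found = set(result.hotspots)
    planted = set(HOTSPOT_RESIDUES)
    recall = len(found & planted) / len(planted)
    precision = len(found & planted) / max(len(found), 1)
    assert recall >= 0.9
    assert precision >= 0.9


def test_sign_flip_swaps_hotspots_and_anti_hotspots():
    wt, mut = _planted_pair()
    fwd = pert.residual_csp(wt, mut)
    rev = pert.residual_csp(mut, wt)
    assert sorted(rev.anti_hotspots) == sorted(fwd.hotspots)
    assert sorted(rev.hotspots) == sorted(fwd.anti_hotspots)


def test_broadened_residues_excluded_and_listed():
    wt, mut = _planted_pair()
    mut.data.loc[mut.data["residue"] == 170,
                 ["csp_ppm", "status"]] = [np.nan, "broadened"]
    result = pert.residual_csp(wt, mut)
    assert 170 in result.excluded
    assert 170 not in result.hotspots


# ---------------------------------------------------------------------------
# titration fits

def test_fraction_bound_limits_and_monotonicity():
    lig = np.linspace(0.0, 500.0, 200)
    f = pert.fraction_bound(lig, 100.0, 3.3)
    assert f[0] == pytest.approx(0.0)
    assert np.all(np.diff(f) > 0)
    assert np.all(f <= np.minimum(1.0, np.where(lig > 0, lig / 100.0, 0.0))
                  + 1e-12)
    # saturation: ligand far above both Kd and protein
    f_sat = pert.fraction_bound(1e5, 100.0, 3.3)
    assert f_sat == pytest.approx(1.0, abs=1e-2)


def test_titration_kd_round_trip_noiseless():
    ddmax = {res: 0.04 + 0.02 * (res % 3) for res in range(100, 108)}
    lig = np.array([0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0])
    series, _ = simulate_titration(3.3, 100.0, lig, ddmax)
    kd, kd_err, ddmax_fit, flags = pert.fit_titration_kd(series)
    assert kd == pytest.approx(3.3, rel=1e-4)
    assert flags == []
    for res, dd in ddmax.items():
        assert ddmax_fit[res] == pytest.approx(dd, rel=1e-4)


def test_titration_apo_point_is_zero_and_saturation_reaches_ddmax():
    lig = np.array([0.0, 50.0, 200.0, 1000.0, 5000.0])
    series, _ = simulate_titration(3.3, 10.0, lig, {100: 0.2})
    assert series.csp.loc[100].iloc[0] == 0.0
    assert series.csp.loc[100].iloc[-1] == pytest.approx(0.2, rel=1e-2)


def test_single_residue_fit_equals_global_fit():
    lig = np.array([0.0, 5.0, 15.0, 40.0, 120.0, 400.0])
    full, _ = simulate_titration(5.0, 50.0, lig, {100: 0.1, 101: 0.2})
    single, _ = simulate_titration(5.0, 50.0, lig, {100: 0.1})
    kd_full, *_ = pert.fit_titration_kd(full)
    kd_single, *_ = pert.fit_titration_kd(single)
    assert kd_single == pytest.approx(kd_full, rel=1e-6)


def test_titration_without_curvature_flags_lower_bound():
    # ligand range far below Kd: no curvature, Kd only bounded from below
    lig = np.array([0.0, 0.05, 0.1, 0.2, 0.4])
    series, _ = simulate_titration(500.0, 1.0, lig, {100: 0.5})
    kd, _, _, flags = pert.fit_titration_kd(series)
    assert "kd_lower_bound" in flags
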