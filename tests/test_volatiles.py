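"""Calibration, peak matching, quantification and compositional statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glandkit import datasets
from glandkit.volatiles import (ALKENE_COMPONENTS, DEFAULT_REGISTRY,
                                MAIN_COMPONENTS, CalibrationCurve,
                                alkene_fractions, compare_groups,
                                compare_sexes, compositional_stats,
                                fit_calibration, fit_standard_series,
                                match_peak, mbq_ebq_molar_ratio, molar_totals,
                                quantify, quantify_peaks, sum_quinones)


# -------------------------------------------------------------- calibration

def test_fit_exact_line():
    pts = [(1, 3.0), (2, 6.0), (5, 15.0), (10, 30.0), (20, 60.0)]
    curve = fit_calibration(pts)
    assert curve.slope == pytest.approx(3.0)
    assert curve.intercept == pytest.approx(0.0, abs=1e-9)
    assert curve.r_squared == pytest.approx(1.0)
    assert curve.n_points == 5


def test_fit_degenerate_design_errors():
    with pytest.raises(ValueError):
        fit_calibration([(5, 1.0)] * 5)


def test_fit_needs_two_points():
    with pytest.raises(ValueError):
        fit_calibration([(5, 1.0)])


def test_curve_rejects_nonpositive_slope():
    with pytest.raises(ValueError):
        CalibrationCurve("x", 0.0, 0.0, 1.0, 5)


# ------------------------------------------------------------ peak matching

def test_match_pentadecene():
    assert match_peak(1492, DEFAULT_REGISTRY) == "15ene"


def test_match_nothing_nearby():
    assert match_peak(1200, DEFAULT_REGISTRY, tolerance=5) is None


def test_match_dual_alias():
    # 1015 sits between the two listed MBQ retention indices
    assert match_peak(1015, DEFAULT_REGISTRY) == "MBQ"


def test_match_all_registry_indices_roundtrip():
    for comp in DEFAULT_REGISTRY.values():
        for ri in comp.retention_indices:
            assert match_peak(ri, DEFAULT_REGISTRY, tolerance=0) == comp.name


# ---------------------------------------------------------- quantification

def _curve(slope, intercept):
    return CalibrationCurve("c", slope, intercept, 1.0, 5)


def test_quantify_area_equals_intercept():
    assert quantify(5.0, _curve(2.0, 5.0)) == 0.0


def test_quantify_simple():
    assert quantify(20.0, _curve(2.0, 0.0)) == pytest.approx(10.0)


def test_quantify_clips_negative():
    assert quantify(1.0, _curve(2.0, 5.0)) == 0.0


@given(m=st.floats(0, 1e4), slope=st.floats(0.1, 100),
       intercept=st.floats(-50, 50))
def test_quantify_roundtrip(m, slope, intercept):
    curve = _curve(slope, intercept)
    assert quantify(slope * m + intercept, curve) == pytest.approx(m, abs=1e-6)


def test_ebq_quantified_through_ehq_curve():
    peaks = pd.DataFrame([{"sample_id": "a", "compound": "EBQ",
                           "area": 2.0 * 10 + 1.0}])
    curves = {"EHQ": CalibrationCurve("EHQ", 2.0, 1.0, 1.0, 5)}
    out = quantify_peaks(peaks, curves)
    assert out.loc[0, "mass_ng"] == pytest.approx(10.0)


def test_missing_surrogate_curve_errors():
    peaks = pd.DataFrame([{"sample_id": "a", "compound": "EBQ", "area": 5.0}])
    with pytest.raises(KeyError):
        quantify_peaks(peaks, {"MBQ": _curve(1.0, 0.0)})


def test_quantify_peaks_by_retention_index():
    peaks = pd.DataFrame([
        {"sample_id": "a", "retention_index": 1492, "area": 30.0},
        {"sample_id": "a", "retention_index": 1200, "area": 99.0},  # unmatched
        {"sample_id": "a", "retention_index": 1477, "area": 10.0},  # excluded
    ])
    curves = {"15ene": _curve(3.0, 0.0)}
    out = quantify_peaks(peaks, curves)
    assert len(out) == 1
    assert out.loc[0, "compound"] == "15ene"
    assert out.loc[0, "mass_ng"] == pytest.approx(10.0)


def test_sum_quinones():
    masses = {"MBQ": 1.0, "MHQ": 0.5, "EBQ": 2.0, "EHQ": 0.25,
              "15ene": 3.0, "17diene": 1.0, "17ene": 0.5}
    out = sum_quinones(masses)
    assert out["MBQ_sum"] == pytest.approx(1.5)
    assert out["EBQ_sum"] == pytest.approx(2.25)
    assert out["15ene"] == pytest.approx(3.0)


# ------------------------------------------------------------- molar totals

def test_molar_totals_male_thoracic():
    q, a = molar_totals({"MBQ_sum": 5.39, "EBQ_sum": 7.08,
                         "15ene": 4.71, "17diene": 2.39, "17ene": 1.08})
    assert round(q, 2) == 96.21


def test_molar_totals_male_abdominal_alkenes():
    q, a = molar_totals({"MBQ_sum": 8.43, "EBQ_sum": 10.63,
                         "15ene": 9.91, "17diene": 0.51, "17ene": 1.06})
    assert round(a, 2) == 53.74


def test_molar_totals_all_zero():
    zeros = {c: 0.0 for c in MAIN_COMPONENTS}
    assert molar_totals(zeros) == (0.0, 0.0)


def test_molar_totals_missing_component_errors():
    with pytest.raises(KeyError):
        molar_totals({"MBQ_sum": 1.0})


def test_all_published_nmol_cells_within_tolerance():
    printed = {("male", "thoracic"): (96.21, 37.06),
               ("female", "thoracic"): (100.81, 38.84),
               ("male", "abdominal"): (147.18, 53.74),
               ("female", "abdominal"): (141.24, 52.32),
               ("male", "whole"): (243.39, 90.80),
               ("female", "whole"): (242.34, 90.58)}
    table = datasets.gland_volatile_means(include_whole_rows=True)
    for _, row in table.iterrows():
        q, a = molar_totals(row[list(MAIN_COMPONENTS)])
        exp_q, exp_a = printed[(row["sex"], row["gland"])]
        assert q == pytest.approx(exp_q, abs=0.05)
        assert a == pytest.approx(exp_a, abs=0.05)


# ----------------------------------------------------- compositional stats

@pytest.fixture(scope="module")
def compo():
    return compositional_stats(datasets.gland_volatile_means()) \
        .set_index(["sex", "gland"])


def test_mbq_ebq_ratio_published_rows():
    whole = datasets.gland_volatile_means(include_whole_rows=True)
    whole = whole[whole["gland"] == "whole"].set_index("sex")
    assert round(mbq_ebq_molar_ratio(whole.loc["male", "MBQ_sum"],
                                     whole.loc["male", "EBQ_sum"]), 2) == 0.87
    assert round(mbq_ebq_molar_ratio(whole.loc["female", "MBQ_sum"],
                                     whole.loc["female", "EBQ_sum"]), 2) == 0.81


def test_quinone_alkene_ratio_thoracic(compo):
    assert round(compo.loc[("male", "thoracic"),
                           "quinone_alkene_molar_ratio"], 2) == 2.60


def test_quinone_alkene_ratio_abdominal_range(compo):
    for sex in ("male", "female"):
        r = compo.loc[(sex, "abdominal"), "quinone_alkene_molar_ratio"]
        assert 2.70 <= round(r, 2) <= 2.74


def test_gland_share_about_40_60(compo):
    for sex in ("male", "female"):
        assert compo.loc[(sex, "thoracic"), "quinone_share_of_beetle"] \
            == pytest.approx(0.4, abs=0.03)
        assert compo.loc[(sex, "abdominal"), "quinone_share_of_beetle"] \
            == pytest.approx(0.6, abs=0.03)


def test_alkene_fraction_pattern(compo):
    thr = compo.loc[("male", "thoracic")]
    abd = compo.loc[("male", "abdominal")]
    assert thr["frac_15ene"] == pytest.approx(0.60, abs=0.03)
    assert abd["frac_15ene"] == pytest.approx(0.88, abs=0.02)


def test_quinone_weight_fraction_whole(compo):
    # published whole-beetle quinone weight share ~61.5%
    assert 100 * compo.loc[("male", "whole"), "quinone_weight_fraction"] \
        == pytest.approx(61.5, abs=1.0)


@given(masses=st.lists(st.floats(0.01, 100), min_size=3, max_size=3))
def test_alkene_fractions_sum_to_one(masses):
    d = dict(zip(ALKENE_COMPONENTS, masses))
    fr = alkene_fractions(d)
    assert sum(fr.values()) == pytest.approx(1.0)


def test_alkene_fractions_flag_quinone_only_profile():
    fr = alkene_fractions({c: 0.0 for c in ALKENE_COMPONENTS})
    assert all(np.isnan(v) for v in fr.values())


def test_compositional_stats_empty_errors():
    with pytest.raises(ValueError):
        compositional_stats(pd.DataFrame(columns=["sex", "gland",
                                                  *MAIN_COMPONENTS]))


# --------------------------------------------------------- group comparisons

def _profiles(rng, n, shift=0.0, sex="male"):
    rows = []
    for i in range(n):
        rows.append({"sex": sex, "gland": "thoracic",
                     **{c: max(0.0, rng.normal(5 + shift, 0.5))
                        for c in MAIN_COMPONENTS}})
    return pd.DataFrame(rows)


def test_compare_groups_identical(rng):
    wt = _profiles(rng, 5)
    res = compare_groups(wt, wt).set_index("component")
    assert (res["pvalue"] == 1.0).all()


def test_compare_groups_planted_knockdown(rng):
    wt = _profiles(rng, 15)
    kd = wt.copy()
    kd["MBQ_sum"] = 0.0  # quinone-less knock-down
    res = compare_groups(wt, kd).set_index("component")
    assert res.loc["MBQ_sum", "pvalue"] < 0.001
    assert res.loc["15ene", "pvalue"] > 0.05


def test_compare_sexes_welch(rng):
    males = _profiles(rng, 10, sex="male")
    females = _profiles(rng, 10, shift=10.0, sex="female")
    res = compare_sexes(pd.concat([males, females])).set_index("component")
    assert (res["pvalue"] < 0.001).all()


# -------------------------------------------------- generator round trips

def test_fit_standard_series_recovers_params(rng):
    from glandkit.synthetic import generate_gcms_run
    params = {"MBQ": (3.0, 2.0), "EHQ": (1.5, -1.0)}
    _, standards = generate_gcms_run({}, params, noise_sd=0.0, seed=1)
    curves = fit_standard_series(standards)
    for comp, (slope, intercept) in params.items():
        assert curves[comp].slope == pytest.approx(slope)
        assert curves[comp].intercept == pytest.approx(intercept, abs=1e-9)


def test_noiseless_gcms_roundtrip():
    from glandkit.synthetic import generate_gcms_run
    params = {"MBQ": (3.0, 2.0), "MHQ": (2.5, 0.0), "EHQ": (1.5, -1.0),
              "15ene": (4.0, 1.0), "17ene": (2.0, 0.5)}
    true = {"MBQ": 7.0, "MHQ": 1.5, "EBQ": 9.0, "EHQ": 2.0,
            "15ene": 12.0, "17diene": 3.0, "17ene": 4.0}
    peaks, standards = generate_gcms_run(true, params, noise_sd=0.0, seed=2)
    curves = fit_standard_series(standards)
    out = quantify_peaks(peaks, curves).set_index("compound")["mass_ng"]
    for comp, mass in true.items():
        assert out[comp] == pytest.approx(mass, abs=1e-9)


def test_calibration_recovery_converges_with_noise():
    from glandkit.synthetic import generate_gcms_run
    params = {"MBQ": (3.0, 2.0)}
    slopes = []
    for noise in (0.05, 0.005, 0.0005):
        _, standards = generate_gcms_run({}, params, noise_sd=noise, seed=7)
        slopes.append(fit_standard_series(standards)["MBQ"].slope)
    errors = [abs(s - 3.0) for s in slopes]
    assert errors[2] < errors[0]
    assert errors[2] < 0.01
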