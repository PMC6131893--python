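"""Tracer-dilution core: dose arithmetic, apparent volume, elimination fit."""

import math

import numpy as np
import pytest

from ferrovol import (
    DilutionModel,
    DoseRecord,
    SubjectRecord,
    T1Series,
    apparent_volume,
    blood_volume,
    blood_volume_per_kg,
    fit_elimination,
    iron_amount,
    sensitivity,
)


def test_iron_amount_default_formulation():
    assert iron_amount(DoseRecord(1.0)) == pytest.approx(30.0 / 55.845, rel=1e-12)
    # 0.7 mg/kg for a 40 kg subject at 30 mg/ml
    assert iron_amount(DoseRecord(28.0 / 30.0)) == pytest.approx(28.0 / 55.845,
                                                                 rel=1e-12)


def test_iron_amount_is_linear_in_volume():
    one = iron_amount(DoseRecord(1.0))
    assert iron_amount(DoseRecord(3.5)) == pytest.approx(3.5 * one, rel=1e-12)


def test_apparent_volume_reference_point():
    n_fe = iron_amount(DoseRecord(1.0))
    v = apparent_volume(n_fe, 18.0, 230.0, 1600.0)
    assert v == pytest.approx(18.0 * (30.0 / 55.845) / (1000 / 230 - 0.625),
                              rel=1e-12)
    assert v == pytest.approx(2.5974, abs=2e-4)


def test_apparent_volume_requires_enhancement_and_is_linear_in_dose():
    with pytest.raises(ValueError):
        apparent_volume(0.5, 18.0, 1600.0, 1600.0)
    v1 = apparent_volume(0.5, 18.0, 230.0, 1600.0)
    assert apparent_volume(1.0, 18.0, 230.0, 1600.0) == pytest.approx(2 * v1,
                                                                      rel=1e-12)


def test_apparent_volume_matches_concentration_oracle():
    """V' equals dose divided by the concentration implied by dR1 = r1*[CA]."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n_fe = rng.uniform(0.05, 2.0)
        r1 = rng.uniform(5.0, 25.0)
        base = rng.uniform(1200.0, 2000.0)
        t1 = rng.uniform(150.0, 0.9 * base)
        conc_mm = (1000.0 / t1 - 1000.0 / base) / r1   # mM, via the relaxivity law
        assert apparent_volume(n_fe, r1, t1, base) == pytest.approx(
            n_fe / conc_mm, rel=1e-12)


def test_sensitivity_factors_at_study_operating_point():
    s_post, s_base = sensitivity(230.0, 1600.0)
    assert 4.0 * s_post == pytest.approx(4.67, abs=0.005)
    assert 1.0 * s_base == pytest.approx(0.168, abs=0.001)


def test_sensitivity_limit_infinite_baseline():
    s_post, s_base = sensitivity(230.0, 1e9)
    assert s_post == pytest.approx(1.0, abs=1e-5)
    assert s_base == pytest.approx(0.0, abs=1e-5)


def test_blood_volume_hematocrit_correction():
    assert blood_volume(2.5, SubjectRecord(40.0, 0.40)) == pytest.approx(2.5 / 0.6,
                                                                         rel=1e-12)
    assert blood_volume(2.5, SubjectRecord(40.0, 0.0)) == 2.5
    subj = SubjectRecord(40.0, 0.295)
    # per-kg form: 61.9 ml/kg plasma at Hct 0.295 -> 87.8 ml/kg blood
    v_plasma_l = 61.9 * 40.0 / 1000.0
    assert blood_volume_per_kg(v_plasma_l, subj) == pytest.approx(87.80, abs=0.01)


def test_blood_volume_monotone_in_hematocrit():
    volumes = [blood_volume(2.5, SubjectRecord(40.0, h))
               for h in np.linspace(0.0, 0.6, 13)]
    assert all(b > a for a, b in zip(volumes, volumes[1:]))


def test_subject_record_validation():
    with pytest.raises(ValueError):
        SubjectRecord(40.0, 1.0)
    with pytest.raises(ValueError):
        SubjectRecord(-1.0, 0.3)


def _noiseless_series(v_plasma_l, t_half_h, times_min, dose,
                      baseline=1600.0, compartment="LV"):
    tau_min = t_half_h * 60.0 / math.log(2)
    n_fe = iron_amount(dose)
    dr1 = dose.agent.r1 * n_fe / (v_plasma_l * np.exp(times_min / tau_min))
    t1 = 1000.0 / (1000.0 / baseline + dr1)
    return T1Series(times_min=times_min, t1_ms={compartment: t1},
                    baseline_ms={compartment: baseline})


@pytest.mark.parametrize("t_half_h", [0.5, 1.7, 3.4, 8.0, 14.0])
@pytest.mark.parametrize("times", [np.arange(20.0, 61.0, 2.0),
                                   np.array([20.0, 35.0, 60.0])])
def test_elimination_fit_recovers_noiseless_truth(t_half_h, times):
    dose = DoseRecord(1.0)
    series = _noiseless_series(2.5, t_half_h, times, dose)
    res = fit_elimination(series, dose)
    assert res.positive_elimination
    assert res.v_plasma_l == pytest.approx(2.5, rel=1e-8)
    assert res.t_half_h == pytest.approx(t_half_h, rel=1e-8)
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)


def test_model_results_carry_blood_volume_and_summary():
    dose = DoseRecord(1.0)
    subject = SubjectRecord(40.0, 0.30)
    series = _noiseless_series(2.5, 3.4, np.arange(20.0, 61.0, 2.0), dose)
    res = DilutionModel(series, dose, subject=subject).fit()
    assert res.v_blood_l == pytest.approx(2.5 / 0.7, rel=1e-8)
    assert res.v_blood_ml_per_kg == pytest.approx(2.5 / 0.7 / 40 * 1000, rel=1e-8)
    text = res.summary()
    assert "V_plasma" in text and "half-life" in text
    assert 0.0 <= res.r_squared <= 1.0


def test_fit_window_excludes_early_points():
    dose = DoseRecord(1.0)
    times = np.arange(4.0, 61.0, 2.0)
    series = _noiseless_series(2.5, 3.4, times, dose)
    res = fit_elimination(series, dose, window=(20.0, 60.0))
    assert res.n_points == int(((times >= 20) & (times <= 60)).sum())


def test_single_point_window_raises():
    dose = DoseRecord(1.0)
    series = _noiseless_series(2.5, 3.4, np.arange(20.0, 61.0, 2.0), dose)
    with pytest.raises(ValueError):
        fit_elimination(series, dose, window=(20.0, 21.0))


def test_negative_slope_flagged_not_raised():
    dose = DoseRecord(1.0)
    tau_min = -3.4 * 60.0 / math.log(2)  # shrinking apparent volume
    times = np.arange(20.0, 61.0, 2.0)
    n_fe = iron_amount(dose)
    dr1 = dose.agent.r1 * n_fe / (2.5 * np.exp(times / tau_min))
    t1 = 1000.0 / (1000.0 / 1600.0 + dr1)
    series = T1Series(times, {"LV": t1}, {"LV": 1600.0})
    res = fit_elimination(series, dose)
    assert not res.positive_elimination


def test_t1_series_csv_round_trip(tmp_path):
    dose = DoseRecord(1.0)
    series = _noiseless_series(2.5, 3.4, np.arange(20.0, 61.0, 2.0), dose)
    path = tmp_path / "series.csv"
    series.to_dataframe().to_csv(path, index=False)
    back = T1Series.from_csv(path)
    np.testing.assert_allclose(back.times_min, series.times_min)
    np.testing.assert_allclose(back.t1_ms["LV"], series.t1_ms["LV"])
    assert back.baseline_ms["LV"] == pytest.approx(series.baseline_ms["LV"])


def test_t1_series_validation():
    with pytest.raises(ValueError):  # blood T1 above baseline
        T1Series(np.array([20.0, 22.0]), {"LV": np.array([1700.0, 1800.0])},
                 {"LV": 1600.0})
    with pytest.raises(ValueError):  # non-increasing times
        T1Series(np.array([20.0, 20.0]), {"LV": np.array([230.0, 231.0])},
                 {"LV": 1600.0})
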