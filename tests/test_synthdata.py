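"""Synthetic study generator, T1 maps, ROI extraction, end-to-end recovery."""

import dataclasses

import numpy as np
import pytest

from ferrovol import (
    DoseRecord,
    StudyDesign,
    fit_elimination,
    generate_study,
    generate_t1_map,
    reference_change_summary,
    reference_t1_table,
    roi_extract,
)
from ferrovol.relaxometry import ContrastAgentSpec


def _degenerate_design(**overrides):
    base = dict(
        n_subjects=2,
        weight_range_kg=(40.0, 40.0),
        hematocrit_range=(0.295, 0.295),
        v_plasma_per_kg_range_ml=(61.9, 61.9),
        half_life_range_h=(3.4, 3.4),
        noise_cv=0.0,
        seed=1,
    )
    base.update(overrides)
    return StudyDesign(**base)


def _fit_subject(study, subj, sess=1):
    row = study.truths.set_index("subject").loc[subj]
    dose = DoseRecord(float(row["dose_ml"]), study.design.agent)
    return fit_elimination(study.series[subj, sess], dose), row


def test_degenerate_design_recovers_truth_exactly():
    study = generate_study(_degenerate_design())
    assert study.truths["v_plasma_l"].nunique() == 1
    for subj in (1, 2):
        res, row = _fit_subject(study, subj)
        assert res.v_plasma_l == pytest.approx(row["v_plasma_l"], rel=1e-10)
        assert res.t_half_h == pytest.approx(row["t_half_h"], rel=1e-10)


def test_fixed_seed_reproduces_bit_identical_study():
    design = StudyDesign(n_subjects=3, seed=42)
    a, b = generate_study(design), generate_study(design)
    assert a.truths.equals(b.truths)
    for key in a.series:
        np.testing.assert_array_equal(a.series[key].t1_ms["LV"],
                                      b.series[key].t1_ms["LV"])
        assert a.series[key].baseline_ms == b.series[key].baseline_ms


def test_end_to_end_recovery_bias_consistent_with_zero():
    """Over 200 seeded replicate studies, the pipeline's mean relative
    error on V_plasma stays within 3 Monte-Carlo standard errors of zero."""
    rel_errors = []
    for seed in range(200):
        study = generate_study(StudyDesign(n_subjects=1, seed=seed))
        res, row = _fit_subject(study, 1)
        rel_errors.append(res.v_plasma_l / row["v_plasma_l"] - 1.0)
    rel_errors = np.asarray(rel_errors)
    se = rel_errors.std(ddof=1) / np.sqrt(rel_errors.size)
    assert abs(rel_errors.mean()) < 3 * se + 1e-4


def test_early_transient_biases_unwindowed_fit_only():
    """The optional early washout transient perturbs the first ~20 min;
    the default 20-60 min window keeps the fit nearly unbiased."""
    design = _degenerate_design(n_subjects=1, early_transient_amplitude=0.3,
                                early_transient_tau_min=6.0)
    study = generate_study(design)
    row = study.truths.iloc[0]
    dose = DoseRecord(float(row["dose_ml"]), design.agent)
    windowed = fit_elimination(study.series[1, 1], dose, window=(20.0, 60.0))
    naive = fit_elimination(study.series[1, 1], dose, window=(4.0, 60.0))
    err_windowed = abs(windowed.v_plasma_l / row["v_plasma_l"] - 1.0)
    err_naive = abs(naive.v_plasma_l / row["v_plasma_l"] - 1.0)
    assert err_windowed < 0.01
    assert err_naive > err_windowed


def test_reference_table_change_percentages():
    tbl = reference_t1_table()
    summary = reference_change_summary()
    assert summary["lv_post_over_baseline_pct"] == pytest.approx(
        100 * tbl.loc["LV", 4] / tbl.loc["LV", "baseline"], rel=1e-12)
    assert round(summary["lv_post_over_baseline_pct"], 1) == 14.5
    assert round(summary["lv_rise_60_over_4_pct"], 1) == 21.3
    assert round(summary["myo_recovery_60_over_4_pct"], 1) == 2.7


def test_generated_lv_enhancement_matches_observed_ratio():
    """With the study-mean truths and no noise, the generated LV T1 at
    4 min lands near the observed post/baseline ratio (~14.5%)."""
    study = generate_study(_degenerate_design(n_subjects=1))
    s = study.series[1, 1]
    idx = int(np.where(s.times_min == 4.0)[0][0])
    ratio_pct = 100.0 * s.t1_ms["LV"][idx] / s.baseline_ms["LV"]
    assert ratio_pct == pytest.approx(14.5, abs=1.0)


def test_two_session_noise_only_cv_below_in_vivo():
    """Test-retest CV from measurement noise alone stays far below the
    in vivo 6.9%, which includes physiological variation."""
    diffs_cv = []
    for seed in range(40):
        study = generate_study(StudyDesign(n_subjects=1, n_sessions=2,
                                           noise_cv=0.006, seed=seed))
        v = [_fit_subject(study, 1, sess)[0].v_plasma_l for sess in (1, 2)]
        diffs_cv.append(100.0 * np.std(v, ddof=1) / np.mean(v))
    assert np.mean(diffs_cv) < 2.0


def test_t1_map_noiseless_roi_means_exact():
    values = {"LV": 1604.2, "RV": 1807.9, "myo": 1135.0}
    img, masks = generate_t1_map((64, 64), values, noise_cv=0.0)
    for comp, val in values.items():
        assert img[masks[comp]].mean() == pytest.approx(val, rel=1e-12)


def test_t1_map_mask_sizes_exact_and_disjoint():
    img, masks = generate_t1_map((64, 64), {"LV": 1600.0, "RV": 1800.0},
                                 region_pixels={"LV": 150, "RV": 60})
    assert masks["LV"].sum() == 150
    assert masks["RV"].sum() == 60
    assert not (masks["LV"] & masks["RV"]).any()


def test_t1_map_overlapping_regions_raise():
    with pytest.raises(ValueError):
        generate_t1_map((16, 16), {"LV": 1600.0, "RV": 1800.0},
                        region_pixels={"LV": 200, "RV": 200},
                        region_centers={"LV": (0.5, 0.5), "RV": (0.5, 0.5)})


def test_t1_map_intra_roi_noise_statistics():
    """0.6% multiplicative noise over a 150-pixel ROI: intra-ROI CV near
    0.6% and SEM of the ROI mean near 0.6%/sqrt(150) ~ 0.049%."""
    means = []
    for seed in range(300):
        img, masks = generate_t1_map((64, 64), {"LV": 1600.0}, noise_cv=0.006,
                                     seed=seed, region_pixels={"LV": 150})
        roi = img[masks["LV"]]
        means.append(roi.mean())
    cv = np.std(roi, ddof=1) / np.mean(roi)
    assert cv == pytest.approx(0.006, rel=0.2)
    sem_pct = 100.0 * np.std(means, ddof=1) / np.mean(means)
    assert sem_pct == pytest.approx(100 * 0.006 / np.sqrt(150), rel=0.2)


def test_roi_extract_recovers_generated_series():
    design = _degenerate_design(n_subjects=1)
    study = generate_study(design)
    s = study.series[1, 1]
    values_per_frame = (
        [{c: s.baseline_ms[c] for c in s.compartments}] * 5
        + [{c: s.t1_ms[c][i] for c in s.compartments}
           for i in range(s.times_min.size)]
    )
    frames, masks = [], None
    for vals in values_per_frame:
        img, masks = generate_t1_map((64, 64), vals, noise_cv=0.0)
        frames.append(img)
    extracted = roi_extract(np.stack(frames), masks, s.times_min, n_baseline=5)
    np.testing.assert_allclose(extracted.t1_ms["LV"], s.t1_ms["LV"], rtol=1e-12)
    assert extracted.baseline_ms["LV"] == pytest.approx(s.baseline_ms["LV"])
    assert np.all(extracted.sd_ms["LV"] < 1e-9)  # uniform ROI up to rounding


def test_roi_extract_validation():
    maps = np.ones((6, 8, 8))
    good = np.zeros((8, 8), dtype=bool)
    good[2:4, 2:4] = True
    with pytest.raises(ValueError):  # empty mask
        roi_extract(maps, {"LV": np.zeros((8, 8), dtype=bool)}, [10.0])
    with pytest.raises(ValueError):  # mask shape mismatch
        roi_extract(maps, {"LV": np.ones((4, 4), dtype=bool)}, [10.0])
    with pytest.raises(ValueError):  # frame count mismatch
        roi_extract(maps, {"LV": good}, [10.0, 20.0])


def test_study_to_dir_round_trip(tmp_path):
    from ferrovol import T1Series

    study = generate_study(StudyDesign(n_subjects=2, seed=9))
    study.to_dir(tmp_path / "study")
    assert (tmp_path / "study" / "manifest.json").exists()
    frame = __import__("pandas").read_csv(tmp_path / "study" / "series.csv")
    one = frame[(frame.subject == 1) & (frame.session == 1)].drop(
        columns=["subject", "session"])
    back = T1Series.from_dataframe(one)
    np.testing.assert_allclose(back.t1_ms["LV"], study.series[1, 1].t1_ms["LV"])
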