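"""Synthetic cohort generator: determinism, design margins, ground truth."""

import numpy as np
import pandas as pd
import pytest

from subgrowth.cohort import (
    CohortConfig,
    STRUCTURES,
    default_truth,
    flat_truth,
    generate_cohort,
    generate_mullen,
    volume_column,
)


def test_same_seed_identical_tables():
    a, _ = generate_cohort(CohortConfig(n_subjects=40, seed=9))
    b, _ = generate_cohort(CohortConfig(n_subjects=40, seed=9))
    pd.testing.assert_frame_equal(a, b)


def test_zero_noise_records_lie_on_truth():
    cfg = CohortConfig(n_subjects=25, seed=1, noise_sd=0.0,
                       random_intercept_sd=0.0)
    rec, truth = generate_cohort(cfg)
    for s in ("thalamus", "amygdala"):
        # recompute row-wise with each record's sex and site
        expect = np.array(
            [
                truth.expected_volume(s, "L", r.age_days, r.sex, r.site, r.icv)
                for r in rec.itertuples()
            ]
        )
        np.testing.assert_allclose(rec[volume_column(s, "L")], expect,
                                   rtol=1e-12)


def test_repeat_scan_fraction_matches_design():
    rec, _ = generate_cohort(CohortConfig(n_subjects=231, seed=5))
    per = rec.groupby("subject_id").size()
    frac2 = (per >= 2).mean()
    se = np.sqrt(0.45 * 0.55 / 231)
    assert abs(frac2 - 0.45) < 3 * se


def test_sex_site_proportions_within_3se():
    cfg = CohortConfig(n_subjects=500, seed=3)
    rec, _ = generate_cohort(cfg)
    subj = rec.groupby("subject_id").first()
    for col, probs in (("sex", cfg.sex_probabilities),
                       ("site", cfg.site_probabilities)):
        for level, p in probs.items():
            obs = (subj[col] == level).mean()
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / 500)


def test_ages_within_range_and_distinct():
    rec, _ = generate_cohort(CohortConfig(n_subjects=100, seed=8))
    assert rec.age_days.between(0, 810).all()
    assert not rec.duplicated(["subject_id", "age_days"]).any()


@pytest.mark.parametrize(
    "kw,msg",
    [
        ({"n_subjects": 0}, "n_subjects"),
        ({"noise_sd": -1.0}, "noise_sd"),
        ({"age_range": (0, 900)}, "age_range"),
        ({"sex_probabilities": {"male": 0.7, "female": 0.7}},
         "sex_probabilities"),
    ],
)
def test_invalid_config_rejected_naming_parameter(kw, msg):
    with pytest.raises(ValueError, match=msg):
        generate_cohort(CohortConfig(seed=0, **kw))


def test_flat_truth_curves_are_constant():
    truth = flat_truth()
    t = np.linspace(0, 810, 20)
    for curve in truth.curves.values():
        np.testing.assert_allclose(curve.value(t), curve.value(0.0))
        np.testing.assert_allclose(curve.derivative(t), 0.0)


def test_truth_curves_positive_and_growing():
    truth = default_truth()
    t = np.linspace(0, 810, 50)
    for (s, h), curve in truth.curves.items():
        v = curve.value(t)
        assert (v > 0).all()
        assert v[-1] > v[0]


class TestMullen:
    def test_null_effect_gives_near_zero_correlation(self):
        cfg = CohortConfig(n_subjects=400, seed=11)
        truth = flat_truth()  # no behavior effects planted
        rec, truth = generate_cohort(cfg, truth=truth)
        rec = generate_mullen(rec, truth, seed=2)
        ratio = np.log(
            (rec[volume_column("thalamus", "L")]
             + rec[volume_column("thalamus", "R")]) / rec.icv
        )
        r = np.corrcoef(ratio, rec.mullen_RL)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(rec))

    def test_planted_effect_detectable(self):
        cfg = CohortConfig(n_subjects=400, seed=12)
        rec, truth = generate_cohort(cfg)
        rec = generate_mullen(rec, truth, seed=3)
        ratio = np.log(
            (rec[volume_column("thalamus", "L")]
             + rec[volume_column("thalamus", "R")]) / rec.icv
        )
        z = (ratio - ratio.mean()) / ratio.std()
        r = np.corrcoef(z, rec.mullen_RL)[0, 1]
        assert r > 0.1  # planted +3.5 score units per SD

    def test_zero_noise_reproduces_generating_formula(self):
        cfg = CohortConfig(n_subjects=60, seed=13)
        rec, truth = generate_cohort(cfg)
        truth.behavior_noise_sd = 0.0
        truth.behavior_subject_sd = 0.0
        truth.behavior_effects = {("thalamus", "RL"): 2.0}
        rec = generate_mullen(rec, truth, seed=4)
        vol = (rec[volume_column("thalamus", "L")]
               + rec[volume_column("thalamus", "R")]).to_numpy()
        ratio = np.log(vol / rec.icv.to_numpy())
        age = rec.age_days.to_numpy(float)
        A = np.column_stack([np.ones(len(rec)), age])
        resid = ratio - A @ np.linalg.lstsq(A, ratio, rcond=None)[0]
        z = (resid - resid.mean()) / resid.std()
        inc = rec.income.to_numpy(float)
        edu = rec.maternal_education.to_numpy(float)
        z_inc = (inc - inc.mean()) / inc.std()
        z_edu = (edu - edu.mean()) / edu.std()
        np.testing.assert_allclose(
            rec.mullen_RL, 50.0 + z_inc + z_edu + 2.0 * z, rtol=1e-10
        )

    def test_missing_rate_respected(self):
        cfg = CohortConfig(n_subjects=200, seed=14)
        rec, truth = generate_cohort(cfg)
        rec = generate_mullen(rec, truth, seed=5, missing_rate=0.3)
        frac = rec.mullen_GM.isna().mean()
        assert 0.2 < frac < 0.4
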