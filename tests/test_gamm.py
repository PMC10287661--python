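"""Growth-trajectory GAMM: recovery, limits, prediction algebra."""

import numpy as np
import pandas as pd
import pytest

from subgrowth.cohort import CohortConfig, generate_cohort
from subgrowth.gamm import (
    TrajectoryModel,
    derivative_curve,
    fit_gamm,
    normalized_curve,
    predict_curve,
)


def _plain_frame(t, y, one_scan=True):
    n = len(t)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)] if one_scan
            else [f"s{i % 20}" for i in range(n)],
            "age_days": t,
            "sex": "female",
            "site": "siteA",
            "icv": 8e5,
            "vol_x_L": y,
        }
    )


@pytest.fixture(scope="module")
def noiseless_spline_fit():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 810, 150))
    y = 1000 + 0.9 * t - 6e-4 * t**2 + 2e-7 * t**3
    rec = _plain_frame(t, y)
    model = fit_gamm(rec, "vol_x_L", with_sex=False, include_icv=False,
                     include_site=False, k=10)
    return model, t, y


def test_zero_noise_recovery(noiseless_spline_fit):
    model, t, y = noiseless_spline_fit
    pred = predict_curve(model, t).estimate
    assert np.max(np.abs(pred - y) / np.abs(y)) < 1e-6


def test_lambda_infinity_equals_ols_on_linear(noiseless_spline_fit):
    _, t, _ = noiseless_spline_fit
    rng = np.random.default_rng(1)
    y = 500 + 0.4 * t + rng.normal(0, 20, t.size)
    rec = _plain_frame(t, y)
    model = fit_gamm(rec, "vol_x_L", with_sex=False, include_icv=False,
                     include_site=False, k=10,
                     fixed_lambdas=[1e16], fixed_ratio=np.inf)
    X = np.column_stack([np.ones(t.size), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = predict_curve(model, t).estimate
    np.testing.assert_allclose(pred, X @ coef, atol=1e-6)


def test_prediction_at_observed_design_equals_fitted(thalamus_model,
                                                     cohort_small):
    records, _, _ = cohort_small
    fitted = thalamus_model.fitted_values(include_random=False)
    # rebuild the population design row-by-row from the observed covariates
    W = thalamus_model.engine.W
    np.testing.assert_allclose(W @ thalamus_model.fit.beta, fitted, rtol=1e-12)


def test_sex_curves_differ_by_fitted_sex_terms(thalamus_model, month_grid):
    m = thalamus_model
    male = predict_curve(m, month_grid, "male").estimate
    female = predict_curve(m, month_grid, "female").estimate
    Cm = m.design(month_grid, "male")
    Cf = m.design(month_grid, "female")
    np.testing.assert_allclose(male - female, (Cm - Cf) @ m.fit.beta,
                               atol=1e-10)


def test_derivative_of_constant_response_is_zero():
    rng = np.random.default_rng(2)
    t = np.sort(rng.uniform(0, 810, 120))
    rec = _plain_frame(t, np.full(t.size, 700.0))
    m = fit_gamm(rec, "vol_x_L", with_sex=False, include_icv=False,
                 include_site=False, span=(0, 810))
    d = derivative_curve(m, np.linspace(0, 810, 30)).estimate
    assert np.max(np.abs(d)) < 1e-8 * 700.0


def test_derivative_of_linear_response_is_30b():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0, 810, 120))
    b = 0.8
    rec = _plain_frame(t, 100 + b * t)
    m = fit_gamm(rec, "vol_x_L", with_sex=False, include_icv=False,
                 include_site=False, span=(0, 810))
    d = derivative_curve(m, np.linspace(0, 810, 30)).estimate
    np.testing.assert_allclose(d, 30 * b, rtol=1e-6)


def test_derivative_matches_finite_difference(thalamus_model):
    grid = np.linspace(10, 800, 25)
    h = 0.05
    up = predict_curve(thalamus_model, grid + h, "male").estimate
    dn = predict_curve(thalamus_model, grid - h, "male").estimate
    fd = (up - dn) / (2 * h) * 30.0
    an = derivative_curve(thalamus_model, grid, "male").estimate
    scale = np.maximum(np.abs(an), 1e-3 * np.abs(an).max())
    assert np.max(np.abs(fd - an) / scale) < 1e-4


def test_normalized_curve_properties(thalamus_model, month_grid):
    nc = normalized_curve(thalamus_model, month_grid, "pooled")
    assert nc.estimate[0] == pytest.approx(1.0)
    fitted = predict_curve(thalamus_model, month_grid, "pooled").estimate
    if np.all(np.diff(fitted) > 0):
        assert (nc.estimate[1:] >= 1.0).all()


def test_band_width_shrinks_with_sample_size(month_grid):
    widths = {}
    for n in (50, 200):
        rec, _ = generate_cohort(CohortConfig(n_subjects=n, seed=21))
        m = fit_gamm(rec, ("thalamus", "L"), with_sex=False, span=(0, 810))
        c = predict_curve(m, month_grid)
        widths[n] = np.mean(c.upper - c.lower)
    assert widths[200] < widths[50]


def test_band_contains_estimate(thalamus_model, month_grid):
    c = predict_curve(thalamus_model, month_grid, "pooled")
    assert (c.lower <= c.estimate).all() and (c.estimate <= c.upper).all()


def test_extrapolation_raises(thalamus_model):
    with pytest.raises(ValueError, match="span"):
        predict_curve(thalamus_model, [900.0])


def test_single_site_dropped_gracefully():
    rng = np.random.default_rng(4)
    t = np.sort(rng.uniform(0, 810, 100))
    rec = _plain_frame(t, 500 + t * 0.3 + rng.normal(0, 5, t.size))
    m = fit_gamm(rec, "vol_x_L", with_sex=False, include_icv=False)
    assert len(m.site_levels) == 1  # no dummy columns added


def test_serialization_roundtrip_preserves_predictions(thalamus_model,
                                                       month_grid):
    d = thalamus_model.to_dict()
    clone = TrajectoryModel.from_dict(d)
    for stratum in ("male", "female", "pooled"):
        a = predict_curve(thalamus_model, month_grid, stratum)
        b = predict_curve(clone, month_grid, stratum)
        np.testing.assert_allclose(a.estimate, b.estimate, rtol=1e-12)
        np.testing.assert_allclose(a.lower, b.lower, rtol=1e-9)
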