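"""Discrimination, likelihood R-squareds, AIC/BIC, calibration hierarchy."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from pedfl.fp import FPTerm, fit_final, fit_logistic
from pedfl.metrics import (aic_bic, c_statistic, calibration_assess,
                           calibration_plot, cox_snell_to_nagelkerke,
                           null_loglik, performance_report, r2_family)


# ---------------------------------------------------------------------------
# c-statistic


def test_c_statistic_examples():
    assert c_statistic([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75
    assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert c_statistic([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0]) == 0.5


def test_c_statistic_single_class_error():
    with pytest.raises(ValueError):
        c_statistic([0.2, 0.4], [1, 1])


def test_c_statistic_equals_brute_force_pair_count(rng):
    for _ in range(20):
        n = int(rng.integers(10, 120))
        pred = rng.random(n).round(2)  # rounding forces ties
        y = (rng.random(n) < 0.4).astype(int)
        if y.min() == y.max():
            continue
        cases, controls = pred[y == 1], pred[y == 0]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
        assert c_statistic(pred, y) == pytest.approx(
            wins / (len(cases) * len(controls)), abs=1e-12)


def test_c_statistic_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    pred = rng.random(300)
    y = (rng.random(300) < 0.35).astype(int)
    assert c_statistic(pred, y) == pytest.approx(roc_auc_score(y, pred),
                                                 abs=1e-12)


# ---------------------------------------------------------------------------
# likelihood R-squareds and information criteria


def test_r2_family_null_model_gives_zero():
    ll0 = null_loglik(500, 0.3)
    cs, mx, nag = r2_family(ll0, ll0, 500)
    assert cs == 0.0 and nag == 0.0
    assert mx == pytest.approx(1 - math.exp(2 * ll0 / 500))


def test_r2_family_reproduces_published_nagelkerke():
    phi = 642 / 1672
    assert cox_snell_to_nagelkerke(0.26, phi) == pytest.approx(0.35,
                                                               abs=0.005)
    assert cox_snell_to_nagelkerke(0.25, phi) == pytest.approx(0.34,
                                                               abs=0.005)


def test_r2_family_rejects_worse_than_null():
    ll0 = null_loglik(100, 0.4)
    with pytest.raises(ValueError):
        r2_family(ll0, ll0 - 5.0, 100)


def test_r2_family_invariant_to_design_scaling(rng):
    X = np.column_stack([np.ones(400), rng.normal(size=(400, 2))])
    y = (rng.random(400) < expit(X @ np.array([-0.5, 1.0, -0.7]))
         ).astype(float)
    lls = []
    for s in (1.0, 100.0):
        Xs = X.copy()
        Xs[:, 1:] *= s
        lls.append(fit_logistic(Xs, y).loglik)
    r = [r2_family(None, ll, 400, event_fraction=y.mean()) for ll in lls]
    assert r[0][2] == pytest.approx(r[1][2], abs=1e-8)


def test_aic_bic_closed_forms():
    assert aic_bic(0.0, 1, 1) == (2.0, 0.0)  # ln 1 = 0, so BIC = 0
    aic, bic = aic_bic(-850.0, 9, 1672)
    assert bic - aic == pytest.approx(9 * (math.log(1672) - 2))
    # the published AIC/BIC gap of 48 pins k = 9 parameters at n = 1672
    assert 9 * (math.log(1672) - 2) == pytest.approx(48, abs=1)


# ---------------------------------------------------------------------------
# calibration


def _fitted_model_predictions(cohort):
    terms = [FPTerm("age"), FPTerm("bmi"), FPTerm("alt", (-2.0, -1.0), 100.0),
             FPTerm("homa", (1.0, 2.0), 10.0), FPTerm("tg"), FPTerm("ur")]
    fit = fit_final(cohort.data, terms, B_ci=0, seed=0)
    return fit.predict(cohort.data), cohort.data["fl"].to_numpy(float), fit


def test_apparent_calibration_identity(cohort_1672):
    """An MLE scored on its training data has slope 1 and intercept 0."""
    pred, y, _ = _fitted_model_predictions(cohort_1672)
    rep = calibration_assess(pred, y, B_ci=50, seed=1)
    assert rep.slope == pytest.approx(1.0, abs=1e-6)
    assert rep.intercept == pytest.approx(0.0, abs=1e-6)
    assert rep.slope_ci[0] <= 1.0 <= rep.slope_ci[1]


def test_overconfident_predictions_halve_the_slope(rng):
    n = 4000
    lp_true = rng.normal(-0.5, 1.2, n)
    y = (rng.random(n) < expit(lp_true)).astype(float)
    over = expit(2.0 * lp_true)
    rep = calibration_assess(over, y, B_ci=50, seed=2)
    assert rep.slope == pytest.approx(0.5, abs=0.08)


def test_constant_predictions_are_rejected():
    y = np.array([0, 1, 0, 1, 1, 0], dtype=float)
    with pytest.raises(ValueError, match="constant|inestimable"):
        calibration_assess(np.full(6, 0.5), y, B_ci=10)
    with pytest.raises(ValueError):
        calibration_assess(np.array([0.0, 0.5, 1.0, 0.5, 0.4, 0.2]), y,
                           B_ci=10)


def test_mean_calibration_fields(cohort_1672):
    pred, y, _ = _fitted_model_predictions(cohort_1672)
    rep = calibration_assess(pred, y, B_ci=100, seed=3)
    assert rep.observed_rate == pytest.approx(y.mean())
    assert rep.observed_rate_ci[0] < y.mean() < rep.observed_rate_ci[1]
    assert rep.mean_predicted == pytest.approx(pred.mean())
    assert ((rep.curve["smoothed_observed"] >= 0)
            & (rep.curve["smoothed_observed"] <= 1)).all()


def test_moderate_calibration_hugs_the_diagonal(cohort_1672):
    pred, y, _ = _fitted_model_predictions(cohort_1672)
    rep = calibration_assess(pred, y, B_ci=10, seed=4)
    mid = rep.curve[(rep.curve.grid_risk >= 0.10)
                    & (rep.curve.grid_risk <= 0.70)]
    gap = (mid["smoothed_observed"] - mid["grid_risk"]).abs().max()
    assert gap < 0.1


def test_calibration_plot_round_trips_curve_csv(tmp_path, cohort_1672):
    pred, y, _ = _fitted_model_predictions(cohort_1672)
    rep = calibration_assess(pred, y, B_ci=10, seed=5)
    png = tmp_path / "cal.png"
    csv = tmp_path / "cal.csv"
    calibration_plot(rep, png, csv)
    assert png.stat().st_size > 0
    back = pd.read_csv(csv)
    pd.testing.assert_frame_equal(back, rep.curve, check_exact=False,
                                  rtol=1e-12)


def test_performance_report_bundle(cohort_1672):
    pred, y, fit = _fitted_model_predictions(cohort_1672)
    rep = performance_report(pred, y, fit.loglik, fit.k, B_ci=100, seed=6)
    assert 0.75 < rep.c_statistic < 0.90
    assert rep.c_ci[0] < rep.c_statistic < rep.c_ci[1]
    assert 0 < rep.cox_snell_r2 < rep.max_cox_snell < 1
    assert rep.nagelkerke_r2 == pytest.approx(
        rep.cox_snell_r2 / rep.max_cox_snell)
    assert rep.bic > rep.aic
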