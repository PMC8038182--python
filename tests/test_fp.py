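"""Fractional-polynomial engine: transforms, fits, closed test, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from pedfl.fp import (FP_POWERS, FPTerm, RankDeficiencyError, SeparationError,
                      _candidate_fp_columns, bootstrap_bif, design_matrix,
                      fit_final, fit_logistic, fp_transform, fsp_select,
                      mfp_cycle)
from pedfl.synth import GeneratorConfig, sample_cohort


# ---------------------------------------------------------------------------
# fp_transform


@pytest.mark.parametrize("x, scale, powers, expected", [
    (100.0, 100.0, (-2.0, -1.0), (1.0, 1.0)),
    (23.0, 100.0, (-2.0, -1.0), ((100 / 23) ** 2, 100 / 23)),
    (2.4, 10.0, (1.0, 2.0), (0.24, 0.0576)),
])
def test_fp_transform_examples(x, scale, powers, expected):
    out = fp_transform(x, FPTerm("v", powers, scale))
    assert out.shape == (1, 2)
    np.testing.assert_allclose(out[0], expected, rtol=1e-9)


def test_fp_transform_log_and_repeated_powers():
    t0 = fp_transform(np.e, FPTerm("v", (0.0,)))
    assert t0[0, 0] == pytest.approx(1.0)
    rep = fp_transform(4.0, FPTerm("v", (2.0, 2.0)))
    np.testing.assert_allclose(rep[0], [16.0, 16.0 * np.log(4.0)])


def test_fp_transform_nonpositive_base_names_row():
    with pytest.raises(ValueError, match="row 1"):
        fp_transform(np.array([2.0, 0.0]), FPTerm("alt", (-1.0,)))


# ---------------------------------------------------------------------------
# fit_logistic


def test_intercept_only_fit_is_logit_of_rate(rng):
    y = np.array([1.0] * 30 + [0.0] * 70)
    fit = fit_logistic(np.ones((100, 1)), y)
    assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-8)


def test_binary_covariate_equals_log_odds_ratio():
    # 2x2 table: exposed 40/60 events, unexposed 10/90
    x = np.array([1.0] * 100 + [0.0] * 100)
    y = np.array([1.0] * 40 + [0.0] * 60 + [1.0] * 10 + [0.0] * 90)
    fit = fit_logistic(np.column_stack([np.ones(200), x]), y)
    log_or = np.log((40 * 90) / (60 * 10))
    assert fit.coef[1] == pytest.approx(log_or, abs=1e-8)


def test_fit_matches_statsmodels(rng):
    import statsmodels.api as sm
    X = np.column_stack([np.ones(500), rng.normal(size=(500, 3))])
    y = (rng.random(500) < expit(X @ np.array([-0.3, 0.8, -0.5, 0.2]))
         ).astype(float)
    ours = fit_logistic(X, y)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.coef, ref.params, atol=1e-6)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)


def test_separation_is_detected():
    x = np.linspace(-2, 2, 80)
    y = (x > 0).astype(float)
    with pytest.raises(SeparationError):
        fit_logistic(np.column_stack([np.ones(80), x]), y)


def test_rank_deficiency_is_reported(rng):
    x = rng.normal(size=60)
    y = (rng.random(60) < 0.5).astype(float)
    X = np.column_stack([np.ones(60), x, 2 * x])
    with pytest.raises(RankDeficiencyError):
        fit_logistic(X, y)


def test_single_class_outcome_is_an_error():
    with pytest.raises(ValueError, match="single-class"):
        fit_logistic(np.ones((10, 1)), np.ones(10))


# ---------------------------------------------------------------------------
# closed test (function-selection procedure)


def _brute_best(x, y, adjust, scale):
    ones = np.ones((len(y), 1))
    A = ones if adjust is None else np.column_stack([ones, adjust])
    blocks = _candidate_fp_columns(x / scale)
    dev = {pw: fit_logistic(np.column_stack([A, c]), y).deviance
           for pw, c in blocks.items()}
    b1 = min((p for p in dev if len(p) == 1), key=lambda p: (dev[p], p))
    b2 = min((p for p in dev if len(p) == 2), key=lambda p: (dev[p], p))
    return dev, b1, b2


def test_fsp_matches_exhaustive_search(rng):
    """Engine best-FP deviances equal a brute-force scan of all 8/36 forms."""
    for trial in range(3):
        n = 300
        x = rng.lognormal(1.0, 0.6, n)
        lp = -0.5 + 0.8 * np.log(x) - 0.2 * x
        y = (rng.random(n) < expit(lp)).astype(float)
        adjust = rng.normal(size=(n, 2))
        d = fsp_select(x, y, adjust, name="x")
        dev, b1, b2 = _brute_best(x, y, adjust, 1.0)
        assert d.deviances["fp1"] == pytest.approx(dev[b1], abs=1e-5)
        assert d.deviances["fp2"] == pytest.approx(dev[b2], abs=1e-5)
        assert d.deviances["linear"] == pytest.approx(dev[(1.0,)], abs=1e-5)


def test_fsp_deviance_monotonicity(rng):
    n = 500
    x = rng.lognormal(0.5, 0.5, n)
    y = (rng.random(n) < expit(-1 + 0.5 * np.log(x))).astype(float)
    d = fsp_select(x, y, name="x")
    dv = d.deviances
    tol = 1e-6
    assert dv["null"] >= dv["linear"] - tol
    assert dv["linear"] >= dv["fp1"] - tol
    assert dv["fp1"] >= dv["fp2"] - tol


def test_fsp_recovers_linear_truth(rng):
    n = 5000
    x = rng.lognormal(3, 0.5, n)
    y = (rng.random(n) < expit(-2 + 0.05 * x)).astype(float)
    d = fsp_select(x, y, name="x")
    assert d.outcome == "linear"


def test_fsp_recovers_generating_fp2_powers():
    n = 20000
    c = sample_cohort(GeneratorConfig(n=n, seed=1))
    alt = c.data["alt"].to_numpy()
    z = alt / 100.0
    lp = 0.2 + 0.036 * z ** -2 - 0.767 * z ** -1
    y = (np.random.default_rng(501).random(n) < expit(lp)).astype(float)
    d = fsp_select(alt, y, scale=100.0, name="alt")
    assert d.outcome == "fp2"
    assert d.powers == (-2.0, -1.0)


def test_fsp_omits_pure_noise_most_of_the_time():
    omitted = 0
    reps = 40
    for r in range(reps):
        rr = np.random.default_rng(100 + r)
        x = rr.lognormal(0, 1, 500)
        y = (rr.random(500) < 0.4).astype(float)
        omitted += fsp_select(x, y, name="noise").outcome == "omitted"
    assert omitted / reps > 0.85   # ~1 - alpha with alpha = 0.05


def test_fsp_binary_branch_is_one_df():
    rr = np.random.default_rng(7)
    x = rr.integers(0, 2, 800).astype(float)
    y = (rr.random(800) < expit(-1 + 1.2 * x)).astype(float)
    d = fsp_select(x, y, name="male", binary=True)
    assert d.outcome == "linear"
    assert d.powers == (1.0,)
    assert "linear_vs_null" in d.p_values


# ---------------------------------------------------------------------------
# mfp cycling


def test_single_candidate_cycle_reduces_to_fsp(small_cohort):
    df = small_cohort.data
    res = mfp_cycle(df, ["alt"], scales={"alt": 100.0})
    direct = fsp_select(df["alt"].to_numpy(float),
                        df["fl"].to_numpy(float), scale=100.0, name="alt")
    assert res.decisions["alt"].outcome == direct.outcome
    assert res.decisions["alt"].powers == direct.powers


def test_empty_candidate_list_gives_intercept_only(small_cohort):
    res = mfp_cycle(small_cohort.data, [])
    assert res.terms == []
    assert res.stable


def test_mfp_recovers_published_predictor_set(cohort_1672):
    res = mfp_cycle(cohort_1672.data,
                    ["male", "age", "alt", "homa", "hdlc", "ldlc", "tg",
                     "map", "ur", "crp", "bmi"],
                    scales={"alt": 100.0, "homa": 10.0})
    dec = res.decisions
    assert dec["alt"].outcome == "fp2"
    assert dec["alt"].powers[0] == -2.0
    for v in ("age", "bmi", "ur"):
        assert dec[v].retained, f"{v} should be retained"
    assert not dec["male"].retained


# ---------------------------------------------------------------------------
# bootstrap inclusion fractions and the final fit


def test_bif_single_resample_percentages_are_degenerate(small_cohort):
    bif = bootstrap_bif(small_cohort.data, ["alt", "tg"], B=1, seed=9,
                        scales={"alt": 100.0})
    assert set(bif.table["bif1"]).issubset({0.0, 100.0})
    assert set(bif.table["bif2"]).issubset({0.0, 100.0})


def test_bif_is_reproducible_and_ordered(small_cohort):
    kw = dict(B=5, seed=4, scales={"alt": 100.0})
    a = bootstrap_bif(small_cohort.data, ["alt", "age", "tg"], **kw)
    b = bootstrap_bif(small_cohort.data, ["alt", "age", "tg"], **kw)
    pd.testing.assert_frame_equal(a.table, b.table, check_exact=True)
    t = a.table
    assert ((0 <= t["bif2"]) & (t["bif2"] <= t["bif1"])
            & (t["bif1"] <= 100)).all()


def test_fit_final_cis_bracket_estimates(small_cohort):
    terms = [FPTerm("alt", (-2.0, -1.0), 100.0), FPTerm("age"), FPTerm("ur")]
    fit = fit_final(small_cohort.data, terms, B_ci=60, seed=2)
    assert np.all(fit.ci_low <= fit.coef)
    assert np.all(fit.coef <= fit.ci_high)
    assert fit.loglik <= 0
    assert fit.n_ci_converged > 0


def test_fit_final_rejects_overparametrized_design():
    c = sample_cohort(GeneratorConfig(n=4, seed=8, outcome_model="none"))
    terms = [FPTerm("alt", (-2.0, -1.0), 100.0), FPTerm("age"),
             FPTerm("ur"), FPTerm("tg")]
    with pytest.raises(ValueError, match="identify"):
        fit_final(c.data, terms, B_ci=0)


def test_design_matrix_names_align_with_columns(small_cohort):
    terms = [FPTerm("alt", (-2.0, -1.0), 100.0), FPTerm("homa", (1.0, 2.0),
                                                        10.0), FPTerm("age")]
    X, names = design_matrix(small_cohort.data, terms)
    assert X.shape[1] == len(names) == 6
    assert names[0] == "intercept"
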