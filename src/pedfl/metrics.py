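"""Internal-validation metrics: discrimination, likelihood fit, calibration hierarchy.

Calibration follows the three-level hierarchy of Van Calster et al.:

1. **mean** — the average predicted risk against the observed event rate
   (Wilson interval for the observed rate, percentile bootstrap for the mean
   prediction);
2. **weak** — the calibration slope (coefficient of ``logit(pred)`` in a
   logistic refit of the outcome) and the calibration intercept (intercept of
   a logistic fit with ``logit(pred)`` as a fixed offset, i.e. slope pinned
   at 1), both with percentile bootstrap CIs;
3. **moderate** — a locally weighted (lowess) smooth of the outcome on the
   predicted risk, evaluated on an equally spaced risk grid, plus a histogram
   of the predictions.

For a logistic model evaluated on its own training data the apparent slope is
exactly 1 and the apparent intercept exactly 0 (score equations of the MLE);
that identity is the deterministic anchor the tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.proportion import proportion_confint

from .fp import fit_logistic

__all__ = [
    "PerformanceReport",
    "CalibrationReport",
    "c_statistic",
    "r2_family",
    "null_loglik",
    "aic_bic",
    "performance_report",
    "calibration_assess",
    "calibration_plot",
]


def c_statistic(pred, outcome) -> float:
    """Concordance (Harrell's c / AUROC) by the rank-sum identity.

    The proportion of case/non-case pairs in which the case has the higher
    predicted risk, ties counted one half.  Both classes must be present.
    """
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome)
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic undefined: outcome has a single class")
    ranks = stats.rankdata(pred)
    return float((ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def null_loglik(n: int, event_fraction: float) -> float:
    """Log-likelihood of the intercept-only (prevalence) logistic model."""
    phi = event_fraction
    if not 0 < phi < 1:
        raise ValueError("event fraction must lie strictly inside (0, 1)")
    return n * (phi * math.log(phi) + (1 - phi) * math.log(1 - phi))


def r2_family(loglik_null: float | None, loglik_model: float, n: int,
              event_fraction: float | None = None
              ) -> tuple[float, float, float]:
    """(Cox-Snell R², its maximum, Nagelkerke R²) from log-likelihoods.

    ``loglik_null`` may be omitted when ``event_fraction`` is given, in which
    case the intercept-only likelihood is computed in closed form.  Nagelkerke
    rescales Cox-Snell by the prevalence-dependent maximum
    ``1 - exp(2 * loglik_null / n)``.
    """
    if loglik_null is None:
        if event_fraction is None:
            raise ValueError("need loglik_null or event_fraction")
        loglik_null = null_loglik(n, event_fraction)
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood is below the null model's")
    cox_snell = 1.0 - math.exp(2.0 * (loglik_null - loglik_model) / n)
    max_cs = 1.0 - math.exp(2.0 * loglik_null / n)
    return cox_snell, max_cs, cox_snell / max_cs


def cox_snell_to_nagelkerke(cox_snell: float, event_fraction: float) -> float:
    """Nagelkerke R² implied by a Cox-Snell R² at a given prevalence."""
    max_cs = 1.0 - math.exp(2.0 * null_loglik(1, event_fraction))
    return cox_snell / max_cs


def aic_bic(loglik: float, k: int, n: int) -> tuple[float, float]:
    """Akaike and Bayesian information criteria (-2*loglik + penalty)."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be positive")
    return -2.0 * loglik + 2.0 * k, -2.0 * loglik + k * math.log(n)


@dataclass
class PerformanceReport:
    """Discrimination and global-fit summary of one model on one dataset."""

    c_statistic: float
    c_ci: tuple[float, float]
    cox_snell_r2: float
    max_cox_snell: float
    nagelkerke_r2: float
    aic: float
    bic: float
    n: int
    k: int

    def to_dict(self) -> dict:
        return {
            "c_statistic": self.c_statistic, "c_ci": list(self.c_ci),
            "cox_snell_r2": self.cox_snell_r2,
            "max_cox_snell": self.max_cox_snell,
            "nagelkerke_r2": self.nagelkerke_r2,
            "aic": self.aic, "bic": self.bic, "n": self.n, "k": self.k,
        }


def performance_report(pred, outcome, loglik: float, k: int, *,
                       B_ci: int = 1000, seed: int = 0) -> PerformanceReport:
    """Bundle c-statistic (with bootstrap CI), R² family and AIC/BIC."""
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n = len(outcome)
    c = c_statistic(pred, outcome)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(B_ci):
        idx = rng.integers(0, n, size=n)
        if 0 < outcome[idx].sum() < n:
            draws.append(c_statistic(pred[idx], outcome[idx]))
    c_lo, c_hi = np.percentile(draws, [2.5, 97.5]) if draws else (np.nan,) * 2
    cs, max_cs, nag = r2_family(None, loglik, n,
                                event_fraction=float(outcome.mean()))
    aic, bic = aic_bic(loglik, k, n)
    return PerformanceReport(c, (float(c_lo), float(c_hi)), cs, max_cs, nag,
                             aic, bic, n, k)


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationReport:
    """Three-level calibration assessment of predicted risks."""

    observed_rate: float
    observed_rate_ci: tuple[float, float]      # Wilson
    mean_predicted: float
    mean_predicted_ci: tuple[float, float]     # percentile bootstrap
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    curve: pd.DataFrame = field(repr=False)    # grid_risk, smoothed_observed, n_in_bin
    B: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_calibration": {
                "observed_rate": self.observed_rate,
                "observed_rate_ci": list(self.observed_rate_ci),
                "mean_predicted": self.mean_predicted,
                "mean_predicted_ci": list(self.mean_predicted_ci),
            },
            "weak_calibration": {
                "slope": self.slope, "slope_ci": list(self.slope_ci),
                "intercept": self.intercept,
                "intercept_ci": list(self.intercept_ci),
            },
            "moderate_calibration": self.curve.to_dict(orient="list"),
            "B": self.B, "seed": self.seed,
        }


def _weak_calibration(lp: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept): slope from refit on logit(pred); intercept with
    slope fixed at 1 via an offset fit."""
    X = np.column_stack([np.ones(len(y)), lp])
    slope = float(fit_logistic(X, y).coef[1])
    icpt = float(fit_logistic(np.ones((len(y), 1)), y, offset=lp).coef[0])
    return slope, icpt


def calibration_assess(pred, outcome, *, B_ci: int = 2000, seed: int = 0,
                       grid_size: int = 100,
                       lowess_frac: float = 0.75) -> CalibrationReport:
    """Mean / weak / moderate calibration of predicted risks against outcomes."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.any((pred <= 0) | (pred >= 1)):
        raise ValueError("predicted risks must lie strictly inside (0, 1)")
    if y.min() == y.max():
        raise ValueError("calibration undefined: outcome has a single class")
    if np.ptp(pred) == 0:
        raise ValueError(
            "predictions are constant: the calibration slope is inestimable")
    n = len(y)
    lp = logit(pred)

    events = int(y.sum())
    obs_lo, obs_hi = proportion_confint(events, n, alpha=0.05,
                                        method="wilson")
    slope, icpt = _weak_calibration(lp, y)

    rng = np.random.default_rng(seed)
    slopes, icpts, means = [], [], []
    for _ in range(B_ci):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        means.append(pred[idx].mean())
        if yb.min() == yb.max() or np.ptp(lp[idx]) == 0:
            continue
        try:
            s, i = _weak_calibration(lp[idx], yb)
        except Exception:
            continue
        slopes.append(s)
        icpts.append(i)
    def pct(v):
        return (tuple(np.percentile(v, [2.5, 97.5])) if v
                else (float("nan"), float("nan")))

    # it=0: the robustness iterations treat binary outcomes as outliers
    smooth = lowess(y, pred, frac=lowess_frac, it=0, return_sorted=True)
    grid = np.linspace(pred.min(), pred.max(), grid_size)
    curve_vals = np.interp(grid, smooth[:, 0], smooth[:, 1])
    curve_vals = np.clip(curve_vals, 0.0, 1.0)
    edges = np.linspace(pred.min(), pred.max(), grid_size + 1)
    counts, _ = np.histogram(pred, bins=edges)
    curve = pd.DataFrame({
        "grid_risk": grid,
        "smoothed_observed": curve_vals,
        "n_in_bin": counts,
    })
    return CalibrationReport(
        observed_rate=float(y.mean()),
        observed_rate_ci=(float(obs_lo), float(obs_hi)),
        mean_predicted=float(pred.mean()),
        mean_predicted_ci=pct(means),
        slope=slope, slope_ci=pct(slopes),
        intercept=icpt, intercept_ci=pct(icpts),
        curve=curve, B=B_ci, seed=seed,
    )


def calibration_plot(report: CalibrationReport, path,
                     csv_path=None) -> None:
    """Calibration plot (identity line, lowess curve, risk histogram) + curve CSV."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1, label="ideal")
    ax.plot(report.curve["grid_risk"], report.curve["smoothed_observed"],
            color="C0", lw=2, label="lowess")
    counts = report.curve["n_in_bin"].to_numpy(dtype=float)
    if counts.max() > 0:
        heights = 0.12 * counts / counts.max()
        width = np.diff(report.curve["grid_risk"]).mean() if len(counts) > 1 else 0.01
        ax.bar(report.curve["grid_risk"], heights, width=width,
               color="lightgrey", align="center", label="risk distribution")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed event rate")
    ax.set_title(
        f"slope {report.slope:.2f}, intercept {report.intercept:+.2f}, "
        f"observed {100 * report.observed_rate:.0f}%")
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    if csv_path is not None:
        report.curve.to_csv(csv_path, index=False)
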