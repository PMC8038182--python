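#!/usr/bin/env python
"""Internal validation of the fitted models: discrimination, fit, calibration.

For each arm's final model (from 04_select_models.py) this computes the
c-statistic with a bootstrap CI, the Cox-Snell and Nagelkerke R², AIC/BIC,
and the three-level calibration assessment (mean rates, logistic slope and
intercept with bootstrap CIs, lowess calibration curve), writing a
calibration plot per arm.  Because the models are maximum-likelihood fits
evaluated on their training data, the apparent calibration slope is 1 and
the intercept 0 — the same identity the original internal validation
reports; the interesting outputs are the discrimination and the curve.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pedfl.cohort import read_cohort
from pedfl.fp import FPTerm, ModelFit
from pedfl.metrics import (calibration_assess, calibration_plot,
                           performance_report)

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def load_fit(path: Path) -> ModelFit:
    raw = json.loads(path.read_text())
    terms = [FPTerm(t["variable"], tuple(t["powers"]), t["scale"],
                    t["shift"]) for t in raw["terms"]]
    return ModelFit(terms, raw["names"], np.array(raw["coef"]),
                    np.array(raw["ci_low"]), np.array(raw["ci_high"]),
                    raw["loglik"], raw["loglik_null"], raw["n"])


def main() -> None:
    cohort = read_cohort(SCRATCH / "synthetic_cohort.csv")
    y = cohort.data["fl"].to_numpy(float)
    rows = {}
    for arm in ("bmi", "wc"):
        fit = load_fit(OUT / f"model_{arm}.json")
        pred = fit.predict(cohort.data)
        perf = performance_report(pred, y, fit.loglik, fit.k, B_ci=500,
                                  seed=3)
        cal = calibration_assess(pred, y, B_ci=500, seed=3)
        calibration_plot(cal, OUT / f"calibration_{arm}.png",
                         OUT / f"calibration_{arm}.csv")
        rows[arm] = {
            "c_statistic": round(perf.c_statistic, 3),
            "c_ci": [round(v, 3) for v in perf.c_ci],
            "cox_snell_r2": round(perf.cox_snell_r2, 3),
            "nagelkerke_r2": round(perf.nagelkerke_r2, 3),
            "aic": round(perf.aic, 1),
            "bic": round(perf.bic, 1),
            "observed_rate_pct": round(100 * cal.observed_rate, 1),
            "mean_predicted_pct": round(100 * cal.mean_predicted, 1),
            "calibration_slope": round(cal.slope, 4),
            "calibration_intercept": round(cal.intercept, 4),
        }
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "validation.csv")
    print(table.to_string())
    print("\ncalibration plots: results/calibration_{bmi,wc}.png")


if __name__ == "__main__":
    main()
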