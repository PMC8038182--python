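"""The two published fatty-liver scoring equations as immutable functions.

Both models predict the probability of any-degree fatty liver on liver
ultrasonography in obese children and adolescents from a logistic linear
predictor over fractional-polynomial terms:

* **BMI model**: age, BMI, (ALT/100)^-2, (ALT/100)^-1, (HOMA-IR/10),
  (HOMA-IR/10)^2, triglycerides, uric acid; intercept -0.533.
* **WC model**: age, (ALT/100)^-2, (ALT/100)^-1, (HOMA-IR/10),
  (HOMA-IR/10)^2, triglycerides, uric acid, waist circumference;
  intercept -0.925.

Coefficients are shipped bit-exact to the published tables as JSON model
cards under ``pedfl/data``.  The published regression-equation appendix is
not reproduced in the available full text; the equations here are
reconstructed as intercept plus the sum of the printed coefficient-times-term
products, which the table structure forces.  A few printed confidence bounds
of the WC model appear to have dropped minus signs (a negative *** point
estimate with a positive upper bound); they are stored exactly as printed
with a ``ci_suspect`` flag rather than silently corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .fp import FPTerm, fp_transform

__all__ = ["PublishedModel", "load_model", "linear_predictor", "predict_risk"]


@dataclass(frozen=True)
class PublishedModel:
    """An immutable published scoring equation (logistic scale)."""

    id: str
    intercept: float
    terms: tuple[FPTerm, ...]
    coefficients: tuple[tuple[float, ...], ...]   # per term, matching powers
    ci_as_printed: tuple[tuple[tuple[float, float], ...], ...]
    ci_suspect: tuple[tuple[bool, ...], ...]
    n: int
    fit: Mapping[str, object]

    @property
    def required_fields(self) -> tuple[str, ...]:
        return tuple(t.variable for t in self.terms)

    @property
    def k(self) -> int:
        """Parameter count including the intercept."""
        return 1 + sum(len(c) for c in self.coefficients)


def load_model(model_id: str) -> PublishedModel:
    """Load the ``"bmi"`` or ``"wc"`` model card shipped with the package."""
    if model_id not in ("bmi", "wc"):
        raise ValueError(f"unknown model id {model_id!r}; expected 'bmi' or 'wc'")
    text = resources.files("pedfl.data").joinpath(
        f"model_{model_id}.json").read_text(encoding="utf-8")
    card = json.loads(text)
    terms, coefs, cis, flags = [], [], [], []
    for t in card["terms"]:
        terms.append(FPTerm(t["variable"], tuple(float(p) for p in t["powers"]),
                            float(t["scale"])))
        coefs.append(tuple(float(c) for c in t["coef"]))
        cis.append(tuple((float(lo), float(hi)) for lo, hi in t["ci"]))
        flags.append(tuple(bool(f) for f in t["ci_suspect"]))
    return PublishedModel(card["id"], float(card["intercept"]), tuple(terms),
                          tuple(coefs), tuple(cis), tuple(flags),
                          int(card["n"]), card["fit"])


def _columns(model: PublishedModel, data) -> np.ndarray:
    """Stacked transformed columns in model-card order; validates inputs."""
    if isinstance(data, pd.DataFrame):
        getter = lambda v: data[v].to_numpy(dtype=float)  # noqa: E731
        missing = [v for v in model.required_fields if v not in data.columns]
    else:
        getter = lambda v: np.atleast_1d(np.asarray(data[v], dtype=float))  # noqa: E731
        missing = [v for v in model.required_fields if v not in data]
    if missing:
        raise ValueError(
            f"{model.id} model requires field(s) {missing} which are absent")
    blocks = []
    for term in model.terms:
        blocks.append(fp_transform(getter(term.variable), term))
    return np.column_stack(blocks)


def linear_predictor(model: PublishedModel, data) -> float | np.ndarray:
    """Logit-scale score: intercept + sum of coefficient x transformed term.

    ``data`` may be a single subject (mapping / Series) or a cohort
    DataFrame; returns a scalar or an order-preserving array accordingly.
    """
    cols = _columns(model, data)
    beta = np.concatenate([np.asarray(c, dtype=float)
                           for c in model.coefficients])
    lp = model.intercept + cols @ beta
    return float(lp[0]) if lp.shape[0] == 1 and not isinstance(
        data, pd.DataFrame) else lp


def predict_risk(model: PublishedModel, data) -> float | np.ndarray:
    """Predicted fatty-liver probability, ``expit`` of the linear predictor."""
    lp = linear_predictor(model, data)
    out = expit(lp)
    return float(out) if np.ndim(out) == 0 else out
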