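"""Degree-2 fractional-polynomial (FP) logistic regression with bootstrap selection.

The modelling strategy implemented here is the multivariable fractional
polynomial (MFP) approach of Royston & Sauerbrei wrapped in a nonparametric
bootstrap:

* an :class:`FPTerm` transforms a positive predictor ``x`` as
  ``z = (x + shift)/scale`` raised to one or two powers from
  ``P = {-2, -1, -0.5, 0, 0.5, 1, 2, 3}``, with power 0 meaning ``ln z`` and a
  repeated pair ``(p, p)`` meaning ``(z^p, z^p ln z)``;
* :func:`fsp_select` runs the function-selection closed test for one
  predictor (omit vs linear vs best FP1 vs best FP2, chi-square deviance
  tests on 4/3/2 df);
* :func:`mfp_cycle` cycles the closed test over all candidates, each test
  adjusting for the current functional forms of the others, until the joint
  model is stable;
* :func:`bootstrap_bif` repeats the whole cycle on bootstrap resamples and
  tallies per-predictor bootstrap inclusion fractions (BIF-1: retained in any
  form; BIF-2: retained with a second FP term) and modal powers;
* :func:`fit_final` fits a fixed functional form by maximum likelihood and
  attaches percentile bootstrap confidence intervals.

The logistic fits use a hand-written Newton/IRLS solver: the bootstrap
selection loop performs on the order of 10^5 small fits and needs explicit
separation and rank diagnostics, which a bare-metal solver provides cheaply.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "FP_POWERS",
    "FPTerm",
    "LogisticFit",
    "SelectionDecision",
    "MFPResult",
    "BootstrapSelectionSummary",
    "ModelFit",
    "SeparationError",
    "RankDeficiencyError",
    "fp_transform",
    "fp_column_names",
    "design_matrix",
    "fit_logistic",
    "fsp_select",
    "mfp_cycle",
    "bootstrap_bif",
    "fit_final",
]

#: The standard degree-2 FP power set; 0 denotes the natural logarithm.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class SeparationError(RuntimeError):
    """The outcome is perfectly separated by the design; the MLE diverges."""


class RankDeficiencyError(RuntimeError):
    """The design matrix is rank-deficient (collinear columns)."""


@dataclass(frozen=True)
class FPTerm:
    """One predictor's fractional-polynomial transform.

    ``powers`` holds 1 (FP1 or linear) or 2 (FP2) exponents in ascending
    order; a repeated pair ``(p, p)`` expands to ``(z^p, z^p ln z)``.
    ``scale`` is a fixed positive divisor applied before powering (used to
    keep published coefficients on their printed scale, e.g. ALT/100),
    ``shift`` a non-negative origin shift to enforce positivity.
    """

    variable: str
    powers: tuple[float, ...] = (1.0,)
    scale: float = 1.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be strictly positive")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        if len(self.powers) not in (1, 2):
            raise ValueError("an FP term has one or two powers")

    @property
    def n_columns(self) -> int:
        return len(self.powers)


def fp_transform(x, term: FPTerm) -> np.ndarray:
    """Transformed column(s) for one FP term, shape ``(n, n_columns)``.

    Raises ``ValueError`` naming the first offending row when
    ``(x + shift)/scale`` is not strictly positive.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = (x + term.shift) / term.scale
    if term.powers == (1.0,):  # identity term: no positivity requirement
        return z[:, None]
    if np.any(z <= 0):
        row = int(np.argmax(z <= 0))
        raise ValueError(
            f"non-positive base for FP transform of '{term.variable}' at row "
            f"{row} (value {x[row]!r}, shift {term.shift}, scale {term.scale})"
        )
    logz = np.log(z)

    def one(p: float) -> np.ndarray:
        return logz if p == 0 else z ** p

    cols = [one(term.powers[0])]
    if len(term.powers) == 2:
        p1, p2 = term.powers
        cols.append(one(p1) * logz if p1 == p2 else one(p2))
    return np.column_stack(cols)


def fp_column_names(term: FPTerm) -> list[str]:
    """Human-readable names for the transformed columns of one term."""
    def pow_name(p: float) -> str:
        if p == 0:
            return f"ln({term.variable})"
        if p == 1:
            return term.variable
        return f"{term.variable}^{p:g}"

    names = [pow_name(term.powers[0])]
    if len(term.powers) == 2:
        p1, p2 = term.powers
        names.append(f"{pow_name(p1)}*ln" if p1 == p2 else pow_name(p2))
    return names


def design_matrix(data: pd.DataFrame | Mapping[str, np.ndarray],
                  terms: Sequence[FPTerm]) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix for a list of FP terms."""
    cols, names = [], ["intercept"]
    n = len(next(iter(data[t.variable] for t in terms))) if terms else None
    if terms:
        for t in terms:
            cols.append(fp_transform(np.asarray(data[t.variable], float), t))
            names.extend(fp_column_names(t))
        X = np.column_stack([np.ones(len(cols[0]))] + cols)
    else:
        raise ValueError("design_matrix needs at least one term; "
                         "use an explicit intercept-only fit instead")
    return X, names


# ---------------------------------------------------------------------------
# Newton/IRLS logistic fit


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(X: np.ndarray, y: np.ndarray,
                 offset: np.ndarray | None = None,
                 start: np.ndarray | None = None,
                 tol: float = 1e-8, maxiter: int = 60) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton's method with step halving.

    ``X`` must include its own intercept column.  Converges when the maximum
    absolute score component falls below ``tol``.  Perfect separation raises
    :class:`SeparationError`; a singular information matrix raises
    :class:`RankDeficiencyError` naming the dependent columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, k) with one row per outcome")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is single-class; logistic MLE undefined")
    n, k = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    beta = np.zeros(k) if start is None else np.array(start, dtype=float)

    eta = X @ beta + off
    ll = _loglik(eta, y)
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        p = expit(eta)
        g = X.T @ (y - p)
        if np.max(np.abs(g)) < tol:
            break
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            _raise_rank(X)
            raise
        # step-halve if the likelihood fails to improve
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand + off
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta, eta, ll = cand, eta_c, ll_c
        if np.max(np.abs(eta - off)) > 30.0 and -ll < 1e-6 * n:
            raise SeparationError(
                "perfect separation: fitted log-odds diverge while the "
                "deviance approaches zero"
            )
    else:
        p = expit(eta)
        if np.max(np.abs(y - p)) < 1e-6 or np.max(np.abs(eta - off)) > 30.0:
            raise SeparationError(
                "logistic fit failed to converge with diverging log-odds; "
                "the data are (quasi-)separated"
            )

    p = expit(eta)
    converged = np.max(np.abs(X.T @ (y - p))) < max(tol, 1e-6)
    w = np.maximum(p * (1.0 - p), 1e-12)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        _raise_rank(X)
        raise
    return LogisticFit(beta, cov, ll, converged, n_iter)


def _raise_rank(X: np.ndarray) -> None:
    """Diagnose and report collinear columns of a rank-deficient design."""
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X)
        dep = np.where(np.abs(np.diag(R)) < 1e-8 * np.abs(R).max())[0]
        raise RankDeficiencyError(
            f"design matrix rank {r} < {X.shape[1]} columns; dependent "
            f"column indices {dep.tolist()}"
        )


# ---------------------------------------------------------------------------
# Function-selection procedure (closed test) for one predictor


@dataclass
class SelectionDecision:
    """Outcome of the closed test for one predictor."""

    variable: str
    outcome: str                      # 'omitted' | 'linear' | 'fp1' | 'fp2'
    powers: tuple[float, ...] | None  # None when omitted; (1.0,) when linear
    deviances: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def retained(self) -> bool:
        return self.outcome != "omitted"

    @property
    def two_terms(self) -> bool:
        return self.outcome == "fp2"


def _candidate_fp_columns(z: np.ndarray) -> dict[tuple[float, ...], np.ndarray]:
    """All FP1/FP2 column blocks for a positive, pre-scaled predictor."""
    logz = np.log(z)
    base = {p: (logz if p == 0 else z ** p) for p in FP_POWERS}
    out: dict[tuple[float, ...], np.ndarray] = {}
    for p in FP_POWERS:
        out[(p,)] = base[p][:, None]
    for i, p in enumerate(FP_POWERS):
        for q in FP_POWERS[i:]:
            if p == q:
                out[(p, p)] = np.column_stack([base[p], base[p] * logz])
            else:
                out[(p, q)] = np.column_stack([base[p], base[q]])
    return out


def _batched_deviances(A: np.ndarray, C: np.ndarray, y: np.ndarray,
                       start: np.ndarray, tol: float = 1e-6,
                       maxiter: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Newton logistic deviances for many designs sharing the columns ``A``.

    ``C`` has shape (B, n, m): B candidate column blocks appended to ``A``.
    Candidate columns are standardized internally (an affine, hence
    deviance-invariant, reparametrization) for conditioning.  All fits
    iterate in lock-step, vectorized over the batch, with elementwise step
    halving; converged members drop out of the active batch.  Returns
    (deviance, ok) arrays of length B; ``ok`` is False for members that
    failed to converge or separated.
    """
    B, n, m = C.shape
    k = A.shape[1]
    mu = C.mean(axis=1, keepdims=True)
    sd = C.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    X = np.empty((B, n, k + m))
    X[:, :, :k] = A[None]
    X[:, :, k:] = (C - mu) / sd
    beta = np.tile(np.concatenate([start, np.zeros(m)]), (B, 1))
    eta = np.matmul(X, beta[:, :, None])[:, :, 0]
    ll = np.sum(y[None] * eta - np.logaddexp(0.0, eta), axis=1)

    dev_out = -2.0 * ll.copy()
    ok_out = np.zeros(B, dtype=bool)
    active = np.arange(B)
    eye = np.eye(k + m)
    for _ in range(maxiter):
        p = expit(eta)
        g = np.matmul(X.transpose(0, 2, 1), (y[None] - p)[:, :, None])[:, :, 0]
        conv = np.max(np.abs(g), axis=1) < tol
        # diverging log-odds with near-zero deviance: perfect separation
        sep = ~conv & (np.max(np.abs(eta), axis=1) > 30.0) & (-ll < 1e-6 * n)
        done = conv | sep
        if done.any():
            dev_out[active[done]] = -2.0 * ll[done]
            ok_out[active[conv]] = True
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            X, beta, eta, ll, p, g = (X[keep], beta[keep], eta[keep],
                                      ll[keep], p[keep], g[keep])
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = np.matmul(X.transpose(0, 2, 1), X * w[:, :, None])
        try:
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * eye[None], g[:, :, None])[:, :, 0]
        new_beta = beta + step
        new_eta = np.matmul(X, new_beta[:, :, None])[:, :, 0]
        new_ll = np.sum(y[None] * new_eta - np.logaddexp(0.0, new_eta), axis=1)
        for _ in range(30):
            bad = new_ll < ll - 1e-12
            if not bad.any():
                break
            new_beta[bad] = beta[bad] + 0.5 * (new_beta[bad] - beta[bad])
            new_eta[bad] = np.matmul(X[bad], new_beta[bad][:, :, None])[:, :, 0]
            new_ll[bad] = np.sum(y[None] * new_eta[bad]
                                 - np.logaddexp(0.0, new_eta[bad]), axis=1)
        beta, eta, ll = new_beta, new_eta, new_ll
    else:
        if active.size:
            dev_out[active] = -2.0 * ll
    return dev_out, ok_out


def fsp_select(x: np.ndarray, y: np.ndarray,
               adjust: np.ndarray | None = None, *,
               alpha: float = 0.05, scale: float = 1.0, shift: float = 0.0,
               name: str = "x", binary: bool = False) -> SelectionDecision:
    """Closed-test choice among omitted / linear / best FP1 / best FP2.

    ``adjust`` holds the already-transformed columns of the other model terms
    (no intercept column; one is added internally).  Best FP1/FP2 are found
    by exhaustive search over the 8 powers and 36 power pairs.  The closed
    test compares, at level ``alpha``: FP2 vs omitted (4 df), FP2 vs linear
    (3 df), FP2 vs best FP1 (2 df), stopping at the first non-significant
    step.  Binary predictors skip the FP family and are tested linear vs
    omitted on 1 df.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    if adjust is None:
        A = ones
    else:
        adjust = np.asarray(adjust, dtype=float)
        sd = adjust.std(axis=0)
        sd[sd < 1e-12] = 1.0
        # standardized adjustment (affine, deviance-invariant) for conditioning
        A = np.column_stack([ones, (adjust - adjust.mean(axis=0)) / sd])

    try:
        fit_null = fit_logistic(A, y)
        d_null = fit_null.deviance
        if binary:
            fit_lin = fit_logistic(np.column_stack([A, x]), y)
            d_lin = fit_lin.deviance
            p_lin = float(stats.chi2.sf(d_null - d_lin, 1))
            keep = p_lin < alpha
            return SelectionDecision(
                name, "linear" if keep else "omitted",
                (1.0,) if keep else None,
                {"null": d_null, "linear": d_lin},
                {"linear_vs_null": p_lin},
            )

        z = (x + shift) / scale
        if np.any(z <= 0):
            raise ValueError(
                f"predictor '{name}' has non-positive values after shift/scale"
            )
        blocks = _candidate_fp_columns(z)
        keys1 = [pw for pw in blocks if len(pw) == 1]
        keys2 = [pw for pw in blocks if len(pw) == 2]
        dev1, ok1 = _batched_deviances(
            A, np.stack([blocks[pw] for pw in keys1]), y, fit_null.coef)
        dev2, ok2 = _batched_deviances(
            A, np.stack([blocks[pw] for pw in keys2]), y, fit_null.coef)
        if not (ok1.any() and ok2.any() and ok1[keys1.index((1.0,))]):
            return SelectionDecision(name, "omitted", None, converged=False)
        dev: dict[tuple[float, ...], float] = {}
        dev.update({pw: float(d) for pw, d, o in zip(keys1, dev1, ok1) if o})
        dev.update({pw: float(d) for pw, d, o in zip(keys2, dev2, ok2) if o})
        d_lin = dev[(1.0,)]
        best1 = min((pw for pw in dev if len(pw) == 1), key=lambda pw: (dev[pw], pw))
        best2 = min((pw for pw in dev if len(pw) == 2), key=lambda pw: (dev[pw], pw))
        d_fp1, d_fp2 = dev[best1], dev[best2]
    except SeparationError:
        return SelectionDecision(name, "omitted", None, converged=False)

    p_any = float(stats.chi2.sf(max(d_null - d_fp2, 0.0), 4))
    p_nonlin = float(stats.chi2.sf(max(d_lin - d_fp2, 0.0), 3))
    p_fp2 = float(stats.chi2.sf(max(d_fp1 - d_fp2, 0.0), 2))
    devs = {"null": d_null, "linear": d_lin, "fp1": d_fp1, "fp2": d_fp2}
    pvals = {"fp2_vs_null": p_any, "fp2_vs_linear": p_nonlin,
             "fp2_vs_fp1": p_fp2}

    if p_any >= alpha:
        return SelectionDecision(name, "omitted", None, devs, pvals)
    if p_nonlin >= alpha:
        return SelectionDecision(name, "linear", (1.0,), devs, pvals)
    if p_fp2 >= alpha:
        return SelectionDecision(name, "fp1", best1, devs, pvals)
    return SelectionDecision(name, "fp2", best2, devs, pvals)


# ---------------------------------------------------------------------------
# Multivariable cycling


@dataclass
class MFPResult:
    decisions: dict[str, SelectionDecision]
    terms: list[FPTerm]
    cycles: int
    stable: bool

    @property
    def converged(self) -> bool:
        return all(d.converged for d in self.decisions.values())


def _decision_terms(decisions: Mapping[str, SelectionDecision],
                    scales: Mapping[str, float],
                    shifts: Mapping[str, float],
                    order: Sequence[str]) -> list[FPTerm]:
    return [
        FPTerm(v, decisions[v].powers, scales.get(v, 1.0), shifts.get(v, 0.0))
        for v in order if decisions[v].retained
    ]


def mfp_cycle(data: pd.DataFrame, candidates: Sequence[str], *,
              alpha: float = 0.05, max_cycles: int = 5,
              scales: Mapping[str, float] | None = None,
              shifts: Mapping[str, float] | None = None,
              binary_vars: Sequence[str] = ("male",),
              outcome: str = "fl") -> MFPResult:
    """Cycle the closed test over all candidates until the joint model is stable.

    Candidates are visited in order of increasing p-value in the initial
    all-linear model (most significant first); each predictor's test adjusts
    for the current functional forms of every other retained predictor.
    Stops when a full cycle changes no decision, or flags the result unstable
    after ``max_cycles``.
    """
    scales = dict(scales or {})
    shifts = dict(shifts or {})
    candidates = list(candidates)
    y = data[outcome].to_numpy(dtype=float)
    if not candidates:
        fit0 = fit_logistic(np.ones((len(y), 1)), y)
        return MFPResult({}, [], 0, True)

    # initial visiting order: Wald p-values from the all-linear model
    X_lin = np.column_stack(
        [np.ones(len(y))] + [data[v].to_numpy(float) for v in candidates])
    try:
        lin = fit_logistic(X_lin, y)
        pvals = 2 * stats.norm.sf(np.abs(lin.coef[1:] / lin.se[1:]))
        order = [candidates[i] for i in np.argsort(pvals, kind="stable")]
    except (SeparationError, RankDeficiencyError):
        order = candidates

    decisions: dict[str, SelectionDecision] = {
        v: SelectionDecision(v, "linear", (1.0,)) for v in order}

    cycles, stable = 0, False
    for cycles in range(1, max_cycles + 1):
        changed = False
        for v in order:
            others = _decision_terms(decisions, scales, shifts,
                                     [w for w in order if w != v])
            adjust = None
            if others:
                adjust = np.column_stack(
                    [fp_transform(data[t.variable].to_numpy(float), t)
                     for t in others])
            d = fsp_select(
                data[v].to_numpy(float), y, adjust, alpha=alpha,
                scale=scales.get(v, 1.0), shift=shifts.get(v, 0.0),
                name=v, binary=v in binary_vars)
            prev = decisions[v]
            if (d.outcome, d.powers) != (prev.outcome, prev.powers):
                changed = True
            decisions[v] = d
        if not changed:
            stable = True
            break

    terms = _decision_terms(decisions, scales, shifts, order)
    return MFPResult(decisions, terms, cycles, stable)


# ---------------------------------------------------------------------------
# Bootstrap inclusion fractions


@dataclass
class BootstrapSelectionSummary:
    """Per-predictor inclusion fractions and modal powers over resamples.

    ``table`` columns: ``bif1`` / ``bif2`` (percent of converged resamples
    retaining the predictor at all / with a second FP term) and ``exp1`` /
    ``exp2`` (modal first/second exponent among retaining resamples; modal
    ties broken toward the lowest power).
    """

    table: pd.DataFrame
    B: int
    converged: int
    seed: int
    inclusion_threshold: float = 66.0

    @property
    def included(self) -> list[str]:
        return list(self.table.index[
            self.table["bif1"] >= self.inclusion_threshold])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _modal_power(values: list[float]) -> float | None:
    if not values:
        return None
    vals, counts = np.unique(values, return_counts=True)
    return float(vals[np.argmax(counts)])  # ties: lowest power (unique sorts)


def bootstrap_bif(data: pd.DataFrame, candidates: Sequence[str], *,
                  B: int = 1000, alpha: float = 0.05, seed: int = 0,
                  scales: Mapping[str, float] | None = None,
                  shifts: Mapping[str, float] | None = None,
                  binary_vars: Sequence[str] = ("male",),
                  outcome: str = "fl",
                  max_cycles: int = 5) -> BootstrapSelectionSummary:
    """Bootstrap inclusion fractions: run the MFP cycle on ``B`` row resamples.

    Resampling is a plain nonparametric bootstrap of rows (size n, with
    replacement).  Percentages are computed over converged resamples; more
    than 5% non-converged resamples triggers a warning, 100% an error.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(data)
    rows = data.reset_index(drop=True)

    retained: dict[str, list[tuple[float, ...]]] = {v: [] for v in candidates}
    converged = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = rows.iloc[idx].reset_index(drop=True)
        try:
            res = mfp_cycle(sample, candidates, alpha=alpha,
                            max_cycles=max_cycles, scales=scales,
                            shifts=shifts, binary_vars=binary_vars,
                            outcome=outcome)
        except (SeparationError, RankDeficiencyError, ValueError):
            continue
        if not res.converged:
            continue
        converged += 1
        for v in candidates:
            d = res.decisions[v]
            if d.retained:
                retained[v].append(d.powers)

    if converged == 0:
        raise RuntimeError("no bootstrap resample converged")
    if converged < 0.95 * B:
        warnings.warn(
            f"{B - converged} of {B} bootstrap resamples failed to converge",
            RuntimeWarning, stacklevel=2)

    records = {}
    for v in candidates:
        forms = retained[v]
        two = [pw for pw in forms if len(pw) == 2]
        records[v] = {
            "bif1": 100.0 * len(forms) / converged,
            "exp1": _modal_power([pw[0] for pw in forms]),
            "bif2": 100.0 * len(two) / converged,
            "exp2": _modal_power([pw[1] for pw in two]),
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    return BootstrapSelectionSummary(table, B, converged, seed)


# ---------------------------------------------------------------------------
# Final model fit with bootstrap confidence intervals


@dataclass
class ModelFit:
    """A fitted FP logistic model with percentile-bootstrap 95% CIs."""

    terms: list[FPTerm]
    names: list[str]
    coef: np.ndarray               # intercept first, matching ``names``
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    seed: int | None = None
    B_ci: int = 0
    n_ci_converged: int = 0

    @property
    def k(self) -> int:
        return len(self.coef)

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X, _ = design_matrix(data, self.terms)
        return X @ self.coef

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))

    def to_json(self, path) -> None:
        payload = {
            "terms": [
                {"variable": t.variable, "powers": list(t.powers),
                 "scale": t.scale, "shift": t.shift} for t in self.terms],
            "names": self.names,
            "coef": self.coef.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n": self.n, "seed": self.seed, "B_ci": self.B_ci,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def fit_final(data: pd.DataFrame, terms: Sequence[FPTerm], *,
              B_ci: int = 1000, seed: int = 0,
              outcome: str = "fl") -> ModelFit:
    """Full-data MLE of a fixed functional form plus percentile bootstrap CIs.

    The functional form (powers, scales) is held fixed across resamples; only
    coefficients are re-estimated.  Non-convergent resamples are dropped from
    the percentile computation with a warning when they exceed 5%.
    """
    terms = list(terms)
    y = data[outcome].to_numpy(dtype=float)
    X, names = design_matrix(data, terms)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"n = {X.shape[0]} rows cannot identify {X.shape[1]} parameters")
    fit = fit_logistic(X, y)
    fit0 = fit_logistic(np.ones((len(y), 1)), y)

    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(B_ci):
        idx = rng.integers(0, len(y), size=len(y))
        try:
            bfit = fit_logistic(X[idx], y[idx], start=fit.coef)
        except (SeparationError, RankDeficiencyError):
            continue
        draws.append(bfit.coef)
    if B_ci and not draws:
        raise RuntimeError("no bootstrap resample converged for the CIs")
    if B_ci and len(draws) < 0.95 * B_ci:
        warnings.warn(
            f"{B_ci - len(draws)} of {B_ci} CI resamples failed to converge",
            RuntimeWarning, stacklevel=2)
    if draws:
        arr = np.vstack(draws)
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    else:
        lo = hi = np.full_like(fit.coef, np.nan)
    return ModelFit(terms, names, fit.coef, lo, hi, fit.loglik, fit0.loglik,
                    len(y), seed, B_ci, len(draws))
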