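"""Cohort data model: derived variables, descriptives, collinearity screening, CSV I/O.

A cohort is one row per child.  Continuous fields are stored in clinical
units (see :mod:`pedfl.reference`); sex is coded 0 = female / 1 = male; the
fatty-liver outcome ``fl`` is 0 = normal liver, 1 = any degree of steatosis
on ultrasonography, with the optional 4-level grade in ``fl_grade``
(0 none / 1 mild / 2 moderate / 3 severe).

HOMA-IR and mean arterial pressure are *derived* variables:

    HOMA-IR = insulin (uU/mL) * glucose (mg/dL) / 405
    MAP     = SBP/3 + 2*DBP/3   (mm Hg)

and the cohort validator enforces that stored values agree with these
formulas to 1e-9 whenever the parent columns are present.  Complete data are
assumed throughout (the development study had none missing); any missing cell
is an error, not an NA to be imputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HOMA_DENOMINATOR",
    "CohortTable",
    "ScreeningResult",
    "derive_homa_ir",
    "derive_map",
    "describe",
    "spearman_screen",
    "read_cohort",
    "write_cohort",
]

HOMA_DENOMINATOR = 405.0

#: Canonical column order for CSV round trips.  Only ``fl`` plus at least one
#: predictor are strictly required; validators check whichever are present.
CANONICAL_COLUMNS = [
    "fl", "fl_grade", "male", "age", "pub", "weight", "height", "bmi", "wc",
    "alt", "ast", "ggt", "glu", "ins", "homa", "chol", "hdlc", "ldlc", "tg",
    "sbp", "dbp", "map", "ur", "crp",
]

#: Columns that must be strictly positive when present.
_POSITIVE_COLUMNS = [
    "age", "weight", "height", "bmi", "wc", "alt", "ast", "ggt", "glu",
    "ins", "homa", "chol", "hdlc", "ldlc", "tg", "sbp", "dbp", "map", "ur",
    "crp",
]

_BINARY_COLUMNS = ["fl", "male"]


def derive_homa_ir(insulin, glucose):
    """HOMA-IR from fasting insulin (uU/mL) and glucose (mg/dL).

    Vectorized; accepts scalars or arrays.  Zero insulin is allowed (gives
    HOMA-IR 0); negative inputs and non-positive glucose are domain errors.
    """
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if np.any(insulin < 0):
        raise ValueError("insulin must be non-negative")
    if np.any(glucose <= 0):
        raise ValueError("glucose must be strictly positive")
    out = insulin * glucose / HOMA_DENOMINATOR
    return out.item() if out.ndim == 0 else out


def derive_map(sbp, dbp):
    """Mean arterial pressure SBP/3 + 2*DBP/3 (mm Hg).

    Requires 0 < DBP <= SBP elementwise.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(dbp <= 0):
        raise ValueError("diastolic pressure must be strictly positive")
    if np.any(dbp > sbp):
        raise ValueError("diastolic pressure exceeds systolic pressure")
    out = sbp / 3.0 + 2.0 * dbp / 3.0
    return out.item() if out.ndim == 0 else out


@dataclass
class CohortTable:
    """An ordered cohort of subject records backed by a DataFrame.

    Parameters
    ----------
    data
        One row per child, columns a subset of :data:`CANONICAL_COLUMNS`.
    provenance
        ``"real"`` or ``"synthetic"``.
    seed
        Generator seed when synthetic, else ``None``.
    """

    data: pd.DataFrame
    provenance: str = "real"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        validate_cohort(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def prevalence(self) -> float:
        return float(self.data["fl"].mean())


def validate_cohort(df: pd.DataFrame, *, atol: float = 1e-9) -> None:
    """Raise ``ValueError`` on any violated cohort invariant."""
    if len(df) < 1:
        raise ValueError("cohort is empty")
    if "fl" not in df.columns:
        raise ValueError("cohort must contain the outcome column 'fl'")
    na = df.isna()
    if na.to_numpy().any():
        col = na.any()[na.any()].index[0]
        row = int(na[col].idxmax())
        raise ValueError(
            f"missing value at row {row}, column '{col}': the model assumes "
            "complete data (no imputation is performed)"
        )
    unknown = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns: {unknown}")
    for col in _BINARY_COLUMNS:
        if col in df.columns and not df[col].isin([0, 1]).all():
            raise ValueError(f"column '{col}' must be binary 0/1")
    if "pub" in df.columns and not df["pub"].isin([1, 2, 3, 4, 5]).all():
        raise ValueError("pubertal stage must be an integer in 1..5")
    if "fl_grade" in df.columns:
        if not df["fl_grade"].isin([0, 1, 2, 3]).all():
            raise ValueError("fl_grade must be in 0..3")
        if not (df["fl"] == (df["fl_grade"] >= 1).astype(int)).all():
            raise ValueError("fl must equal 1 exactly when fl_grade >= 1")
    for col in _POSITIVE_COLUMNS:
        if col in df.columns and not (df[col] > 0).all():
            raise ValueError(f"column '{col}' must be strictly positive")
    if {"homa", "ins", "glu"}.issubset(df.columns):
        expected = derive_homa_ir(df["ins"].to_numpy(), df["glu"].to_numpy())
        if not np.allclose(df["homa"].to_numpy(), expected, atol=atol, rtol=0):
            raise ValueError("homa does not equal ins*glu/405 to 1e-9")
    if {"map", "sbp", "dbp"}.issubset(df.columns):
        expected = derive_map(df["sbp"].to_numpy(), df["dbp"].to_numpy())
        if not np.allclose(df["map"].to_numpy(), expected, atol=atol, rtol=0):
            raise ValueError("map does not equal sbp/3 + 2*dbp/3 to 1e-9")


# ---------------------------------------------------------------------------
# Descriptive summaries

_DISCRETE = ("fl", "male", "pub", "fl_grade")


def describe(cohort: CohortTable | pd.DataFrame,
             group_by: str | None = None) -> pd.DataFrame:
    """Median (p25-p75) for continuous fields, count (%) for discrete ones.

    Quantiles use linear interpolation of order statistics (the numpy/R
    type-7 default).  With ``group_by`` (a binary column, e.g. ``male``) the
    groups are reported side by side next to the total column.
    """
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    if len(df) == 0:
        raise ValueError("cannot describe an empty cohort")

    def one_group(sub: pd.DataFrame, label: str) -> pd.Series:
        rows: dict[str, str] = {}
        rows["n"] = str(len(sub))
        for col in sub.columns:
            if col == group_by:
                continue
            if col in _DISCRETE:
                for level, cnt in sub[col].value_counts().sort_index().items():
                    rows[f"{col}={level}"] = (
                        f"{cnt} ({100 * cnt / len(sub):.1f}%)"
                    )
            else:
                q25, q50, q75 = np.quantile(sub[col].to_numpy(),
                                            [0.25, 0.50, 0.75])
                rows[col] = f"{q50:g} ({q25:g}-{q75:g})"
        return pd.Series(rows, name=label)

    parts = [one_group(df, "total")]
    if group_by is not None:
        if group_by not in df.columns:
            raise ValueError(f"group_by column '{group_by}' not in cohort")
        for level in sorted(df[group_by].unique()):
            parts.append(one_group(df[df[group_by] == level],
                                   f"{group_by}={level}"))
    return pd.concat(parts, axis=1)


def quantile_summary(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric p25/p50/p75 per column (type-7 quantiles), for calibration checks."""
    out = {}
    for col in columns:
        out[col] = np.quantile(df[col].to_numpy(), [0.25, 0.50, 0.75])
    return pd.DataFrame(out, index=["p25", "p50", "p75"]).T


# ---------------------------------------------------------------------------
# Spearman collinearity screening


@dataclass
class ScreeningResult:
    """Rank-correlation screen: matrix, collinear clusters, kept representatives."""

    spearman_matrix: pd.DataFrame
    clusters: list[set[str]]
    kept: dict[frozenset, str] = field(default_factory=dict)
    threshold: float = 0.60

    @property
    def dropped(self) -> set[str]:
        out: set[str] = set()
        for cluster in self.clusters:
            keep = self.kept.get(frozenset(cluster))
            out |= {v for v in cluster if v != keep}
        return out

    def flagged_pairs(self) -> list[tuple[str, str, float]]:
        m = self.spearman_matrix
        pairs = []
        for i, a in enumerate(m.index):
            for b in m.columns[i + 1:]:
                if abs(m.loc[a, b]) > self.threshold:
                    pairs.append((a, b, float(m.loc[a, b])))
        return pairs


def spearman_screen(cohort: CohortTable | pd.DataFrame,
                    variables: Sequence[str],
                    threshold: float = 0.60,
                    priority: Sequence[str] | None = None) -> ScreeningResult:
    """Screen predictors for collinear clusters by Spearman rank correlation.

    Clusters are the connected components of the graph whose edges are the
    pairs with ``|rho| > threshold`` — so e.g. ALT-AST and ALT-GGT both above
    threshold merge AST, GGT and ALT into one cluster even though AST-GGT may
    fall below it.  The representative kept for each cluster is the first
    cluster member appearing in ``priority`` (a clinical-availability ranking
    supplied by the analyst); with no priority list covering a cluster the
    cluster is reported with no ``kept`` entry.

    Ties in ranks use mid-ranks (``scipy.stats.spearmanr`` default).
    """
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least two variables to screen")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    for v in variables:
        if df[v].nunique() <= 1:
            raise ValueError(
                f"column '{v}' is constant; its rank correlations are undefined"
            )
    sub = df[variables].to_numpy(dtype=float)
    rho = stats.spearmanr(sub).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-variable case
        r = float(stats.spearmanr(sub[:, 0], sub[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    matrix = pd.DataFrame(rho, index=variables, columns=variables)

    # Union-find over the |rho| > threshold graph.
    parent = {v: v for v in variables}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            if abs(matrix.loc[a, b]) > threshold:
                parent[find(a)] = find(b)

    comps: dict[str, set[str]] = {}
    for v in variables:
        comps.setdefault(find(v), set()).add(v)
    clusters = [c for c in comps.values() if len(c) > 1]
    clusters.sort(key=lambda c: sorted(c)[0])

    kept: dict[frozenset, str] = {}
    if priority is not None:
        rank = {v: i for i, v in enumerate(priority)}
        for cluster in clusters:
            ranked = sorted((v for v in cluster if v in rank),
                            key=rank.__getitem__)
            if ranked:
                kept[frozenset(cluster)] = ranked[0]
    return ScreeningResult(matrix, clusters, kept, threshold)


# ---------------------------------------------------------------------------
# CSV I/O


def read_cohort(path, required: Iterable[str] | None = None) -> CohortTable:
    """Read a cohort CSV (header of canonical names, ``#``-comment provenance line).

    Raises ``ValueError`` naming the row/column for any missing or
    non-numeric cell — the models assume complete data.
    """
    provenance, seed = "real", None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(
                kv.split("=", 1) for kv in first[1:].strip().split()
                if "=" in kv
            )
            provenance = meta.get("provenance", "real")
            seed = int(meta["seed"]) if "seed" in meta else None
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"cohort file {path} lacks required columns {missing}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {df[col][row]!r} at row {row}, column '{col}'"
            )
        df[col] = coerced
    for col in df.columns:
        df[col] = (df[col].astype(int) if col in ("fl", "fl_grade", "male",
                                                  "pub")
                   else df[col].astype(float))
    return CohortTable(df, provenance=provenance, seed=seed)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV with a provenance/seed comment header line."""
    header = f"# provenance={cohort.provenance}"
    if cohort.seed is not None:
        header += f" seed={cohort.seed}"
    cols = [c for c in CANONICAL_COLUMNS if c in cohort.data.columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        # %.17g is lossless for IEEE doubles, so read(write(c)) is bit-exact
        cohort.data[cols].to_csv(fh, index=False, float_format="%.17g")
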