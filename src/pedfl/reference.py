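"""Published summary statistics of the development cohort.

The development cohort (n = 1672 obese children and adolescents, 980 girls /
692 boys, fatty-liver prevalence 642/1672) was never deposited; what is public
is its descriptive table (medians and quartiles per variable), its Spearman
rank-correlation matrix among outcome and candidate predictors, and the two
final scoring equations.  This module freezes those published summaries so the
synthetic-cohort generator can be calibrated to them and so tests can refer to
a single source.

Variable abbreviations follow the published correlation table: ``fl`` fatty
liver (binary), ``male`` sex, ``age`` years, ``pub`` Tanner pubertal stage
(1-5), ``bmi`` kg/m^2, ``wc`` waist circumference cm, ``alt``/``ast``/``ggt``
liver enzymes U/L, ``glu`` fasting glucose mg/dL, ``ins`` fasting insulin
uU/mL, ``homa`` HOMA-IR, ``hdlc``/``ldlc`` cholesterol fractions mg/dL,
``tg`` triglycerides mg/dL, ``map`` mean arterial pressure mm Hg, ``ur`` uric
acid mg/dL, ``crp`` C-reactive protein mg/L.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Total cohort size and composition of the development study.
N_COHORT = 1672
N_GIRLS = 980
N_BOYS = 692
MALE_PROPORTION = N_BOYS / N_COHORT

#: Fatty-liver cases and prevalence in the development cohort.
N_FL = 642
FL_PREVALENCE = N_FL / N_COHORT

#: Pubertal (Tanner) stage frequencies, stages 1..5.
STAGE_COUNTS = (194, 144, 213, 373, 748)
STAGE_FREQUENCIES = tuple(c / N_COHORT for c in STAGE_COUNTS)

#: Fatty-liver grade frequencies among cases (mild, moderate, severe).
FL_GRADE_COUNTS = (250, 300, 92)

#: Published pooled quartiles (p25, median, p75) per continuous variable, in
#: the units listed in the module docstring.  Blood pressures are recorded to
#: the nearest 5 mm Hg, hence the tied printed quartiles.
QUANTILE_ANCHORS: dict[str, tuple[float, float, float]] = {
    "age": (13, 15, 16),
    "weight": (83, 96, 112),
    "height": (1.56, 1.63, 1.69),
    "bmi": (32, 36, 40),
    "wc": (101, 111, 122),
    "alt": (16, 23, 35),
    "ast": (17, 21, 26),
    "ggt": (12, 16, 22),
    "glu": (74, 79, 83),
    "ins": (9, 13, 18),
    "homa": (1.6, 2.4, 3.5),
    "chol": (142, 162, 182),
    "hdlc": (37, 43, 51),
    "ldlc": (85, 102, 122),
    "tg": (66, 87, 114),
    "ur": (5.2, 6.0, 6.9),
    "crp": (0.2, 0.4, 0.7),
    "sbp": (120, 120, 130),
    "dbp": (70, 80, 80),
    "map": (87, 93, 97),
}

# Lower-triangle entries of the published Spearman matrix, keyed (row, col)
# with row listed after col in _SPEARMAN_ORDER.  The outcome row (fl) is kept
# for screening checks; derived variables (homa, map) have rows too, but the
# generator treats those as emergent checks, never as copula targets.
_SPEARMAN_ORDER = [
    "fl", "male", "age", "pub", "bmi", "wc", "alt", "ast", "ggt", "glu",
    "ins", "homa", "hdlc", "ldlc", "tg", "map", "ur", "crp",
]

_SPEARMAN_LOWER: dict[tuple[str, str], float] = {
    ("male", "fl"): 0.25,
    ("age", "fl"): -0.02, ("age", "male"): -0.09,
    ("pub", "fl"): -0.10, ("pub", "male"): -0.30, ("pub", "age"): 0.82,
    ("bmi", "fl"): 0.23, ("bmi", "male"): 0.01, ("bmi", "age"): 0.36,
    ("bmi", "pub"): 0.31,
    ("wc", "fl"): 0.25, ("wc", "male"): 0.23, ("wc", "age"): 0.38,
    ("wc", "pub"): 0.28, ("wc", "bmi"): 0.77,
    ("alt", "fl"): 0.45, ("alt", "male"): 0.39, ("alt", "age"): 0.05,
    ("alt", "pub"): -0.09, ("alt", "bmi"): 0.21, ("alt", "wc"): 0.29,
    ("ast", "fl"): 0.37, ("ast", "male"): 0.41, ("ast", "age"): -0.12,
    ("ast", "pub"): -0.24, ("ast", "bmi"): 0.03, ("ast", "wc"): 0.12,
    ("ast", "alt"): 0.81,
    ("ggt", "fl"): 0.35, ("ggt", "male"): 0.35, ("ggt", "age"): 0.13,
    ("ggt", "pub"): 0.01, ("ggt", "bmi"): 0.30, ("ggt", "wc"): 0.34,
    ("ggt", "alt"): 0.61, ("ggt", "ast"): 0.46,
    ("glu", "fl"): 0.12, ("glu", "male"): 0.13, ("glu", "age"): -0.13,
    ("glu", "pub"): -0.16, ("glu", "bmi"): 0.09, ("glu", "wc"): 0.13,
    ("glu", "alt"): 0.07, ("glu", "ast"): 0.03, ("glu", "ggt"): 0.05,
    ("ins", "fl"): 0.29, ("ins", "male"): 0.05, ("ins", "age"): 0.03,
    ("ins", "pub"): 0.03, ("ins", "bmi"): 0.40, ("ins", "wc"): 0.37,
    ("ins", "alt"): 0.27, ("ins", "ast"): 0.13, ("ins", "ggt"): 0.34,
    ("ins", "glu"): 0.14,
    ("homa", "fl"): 0.30, ("homa", "male"): 0.07, ("homa", "age"): 0.01,
    ("homa", "pub"): 0.01, ("homa", "bmi"): 0.41, ("homa", "wc"): 0.38,
    ("homa", "alt"): 0.27, ("homa", "ast"): 0.13, ("homa", "ggt"): 0.34,
    ("homa", "glu"): 0.29, ("homa", "ins"): 0.98,
    ("hdlc", "fl"): -0.16, ("hdlc", "male"): -0.17, ("hdlc", "age"): -0.06,
    ("hdlc", "pub"): -0.02, ("hdlc", "bmi"): -0.22, ("hdlc", "wc"): -0.27,
    ("hdlc", "alt"): -0.17, ("hdlc", "ast"): -0.09, ("hdlc", "ggt"): -0.20,
    ("hdlc", "glu"): -0.07, ("hdlc", "ins"): -0.25, ("hdlc", "homa"): -0.26,
    ("ldlc", "fl"): 0.11, ("ldlc", "male"): 0.06, ("ldlc", "age"): -0.03,
    ("ldlc", "pub"): -0.05, ("ldlc", "bmi"): 0.07, ("ldlc", "wc"): 0.08,
    ("ldlc", "alt"): 0.16, ("ldlc", "ast"): 0.15, ("ldlc", "ggt"): 0.27,
    ("ldlc", "glu"): 0.04, ("ldlc", "ins"): 0.10, ("ldlc", "homa"): 0.10,
    ("ldlc", "hdlc"): -0.05,
    ("tg", "fl"): 0.21, ("tg", "male"): 0.10, ("tg", "age"): 0.07,
    ("tg", "pub"): 0.02, ("tg", "bmi"): 0.19, ("tg", "wc"): 0.21,
    ("tg", "alt"): 0.25, ("tg", "ast"): 0.17, ("tg", "ggt"): 0.31,
    ("tg", "glu"): 0.00, ("tg", "ins"): 0.34, ("tg", "homa"): 0.32,
    ("tg", "hdlc"): -0.38, ("tg", "ldlc"): 0.43,
    ("map", "fl"): 0.11, ("map", "male"): 0.14, ("map", "age"): 0.30,
    ("map", "pub"): 0.22, ("map", "bmi"): 0.41, ("map", "wc"): 0.42,
    ("map", "alt"): 0.19, ("map", "ast"): 0.06, ("map", "ggt"): 0.23,
    ("map", "glu"): 0.06, ("map", "ins"): 0.25, ("map", "homa"): 0.25,
    ("map", "hdlc"): -0.10, ("map", "ldlc"): 0.04, ("map", "tg"): 0.13,
    ("ur", "fl"): 0.29, ("ur", "male"): 0.36, ("ur", "age"): 0.13,
    ("ur", "pub"): 0.05, ("ur", "bmi"): 0.37, ("ur", "wc"): 0.42,
    ("ur", "alt"): 0.37, ("ur", "ast"): 0.28, ("ur", "ggt"): 0.38,
    ("ur", "glu"): 0.09, ("ur", "ins"): 0.28, ("ur", "homa"): 0.29,
    ("ur", "hdlc"): -0.26, ("ur", "ldlc"): 0.09, ("ur", "tg"): 0.25,
    ("ur", "map"): 0.26,
    ("crp", "fl"): 0.10, ("crp", "male"): -0.02, ("crp", "age"): 0.04,
    ("crp", "pub"): 0.00, ("crp", "bmi"): 0.34, ("crp", "wc"): 0.22,
    ("crp", "alt"): 0.02, ("crp", "ast"): -0.04, ("crp", "ggt"): 0.16,
    ("crp", "glu"): 0.04, ("crp", "ins"): 0.14, ("crp", "homa"): 0.14,
    ("crp", "hdlc"): -0.10, ("crp", "ldlc"): 0.04, ("crp", "tg"): 0.00,
    ("crp", "map"): 0.09, ("crp", "ur"): 0.09,
}


def spearman_targets() -> pd.DataFrame:
    """Published Spearman matrix as a symmetric DataFrame with unit diagonal."""
    k = len(_SPEARMAN_ORDER)
    m = np.eye(k)
    idx = {v: i for i, v in enumerate(_SPEARMAN_ORDER)}
    for (a, b), rho in _SPEARMAN_LOWER.items():
        i, j = idx[a], idx[b]
        m[i, j] = m[j, i] = rho
    return pd.DataFrame(m, index=_SPEARMAN_ORDER, columns=_SPEARMAN_ORDER)


#: Pairs the published screening flagged as collinear (|rho| > 0.60).
FLAGGED_PAIRS = (
    ("age", "pub", 0.82),
    ("bmi", "wc", 0.77),
    ("alt", "ast", 0.81),
    ("alt", "ggt", 0.61),
    ("ins", "homa", 0.98),
)
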