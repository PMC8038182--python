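"""Riley minimum-sample-size criteria for developing a binary-outcome model.

Three criteria, each giving a minimum n; the requirement is their maximum:

1. **shrinkage** — expected uniform shrinkage of predictor effects at least
   ``S`` (default 0.9, i.e. < 10% shrinkage):
   ``n1 = p / ((S - 1) * ln(1 - R2_CS / S))``;
2. **optimism** — apparent-minus-adjusted Nagelkerke R² at most ``delta``
   (default 0.05), which corresponds to a shrinkage target
   ``S2 = R2_CS / (R2_CS + delta * max_R2_CS)`` applied to the same formula;
3. **precision** — estimating the outcome prevalence to within ``+/- d``
   (default 0.05) with 95% confidence:
   ``n3 = (1.96 / d)^2 * phi * (1 - phi)``.

``R2_CS`` is the anticipated Cox-Snell R², ``p`` the number of candidate
parameters (indicator coding counts each dummy, e.g. a 5-level ordinal
contributes 4), ``phi`` the anticipated outcome prevalence, and
``max_R2_CS = 1 - exp(2*(phi ln phi + (1-phi) ln(1-phi)))`` the largest
Cox-Snell R² attainable at that prevalence.  Each criterion is rounded up to
the next whole subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SampleSizeInputs", "SampleSizeResult", "max_cox_snell",
           "riley_n", "effective_parameters"]

Z_95 = 1.96  # two-sided 95% normal quantile for the precision criterion


def max_cox_snell(prevalence: float) -> float:
    """Largest attainable Cox-Snell R² for a binary outcome at a prevalence."""
    phi = prevalence
    if not 0 < phi < 1:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    ll0 = phi * math.log(phi) + (1 - phi) * math.log(1 - phi)
    return 1.0 - math.exp(2.0 * ll0)


def effective_parameters(n_continuous: int, ordinal_levels: tuple[int, ...] = (),
                         n_binary: int = 0) -> int:
    """Candidate-parameter count under indicator coding.

    Each continuous or binary candidate contributes one parameter; an ordinal
    candidate with L levels contributes L - 1 indicators.
    """
    return n_continuous + n_binary + sum(lv - 1 for lv in ordinal_levels)


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the three minimum-sample-size criteria."""

    p: int                       # candidate parameters
    r2_cs: float                 # anticipated Cox-Snell R-squared
    prevalence: float            # anticipated outcome prevalence
    shrinkage: float = 0.9       # target expected shrinkage factor S
    delta_nagelkerke: float = 0.05   # allowed apparent-vs-adjusted difference
    delta_prevalence: float = 0.05   # absolute precision of the risk estimate

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be a positive integer")
        for name in ("r2_cs", "prevalence", "shrinkage",
                     "delta_nagelkerke", "delta_prevalence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if self.r2_cs >= self.shrinkage:
            raise ValueError("r2_cs must be below the shrinkage target S")
        if self.r2_cs >= max_cox_snell(self.prevalence):
            raise ValueError(
                "anticipated r2_cs exceeds its maximum at this prevalence")


@dataclass(frozen=True)
class SampleSizeResult:
    n_shrinkage: int
    n_optimism: int
    n_precision: int
    max_cox_snell: float
    inputs: SampleSizeInputs

    @property
    def n_required(self) -> int:
        return max(self.n_shrinkage, self.n_optimism, self.n_precision)

    @property
    def events_per_parameter(self) -> float:
        return self.n_required * self.inputs.prevalence / self.inputs.p


def _n_shrinkage(p: int, r2: float, s: float) -> int:
    return math.ceil(p / ((s - 1.0) * math.log(1.0 - r2 / s)))


def riley_n(inputs: SampleSizeInputs) -> SampleSizeResult:
    """Minimum development sample size: the maximum of the three criteria."""
    max_r2 = max_cox_snell(inputs.prevalence)
    n1 = _n_shrinkage(inputs.p, inputs.r2_cs, inputs.shrinkage)
    s2 = inputs.r2_cs / (inputs.r2_cs + inputs.delta_nagelkerke * max_r2)
    n2 = _n_shrinkage(inputs.p, inputs.r2_cs, s2)
    phi = inputs.prevalence
    n3 = math.ceil((Z_95 / inputs.delta_prevalence) ** 2 * phi * (1 - phi))
    return SampleSizeResult(n1, n2, n3, max_r2, inputs)
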