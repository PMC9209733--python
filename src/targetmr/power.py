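"""Instrument R-squared and analytic power for MR with a binary outcome.

Power follows the non-centrality-parameter approach for summary-data MR
with a case-control outcome: the observable log-odds association between
the instrumented exposure and disease is attenuated through the disease
prevalence K, its sampling variance shrinks with the outcome sample size
and the exposure variance explained by the instrument (R-squared), and the
test statistic is noncentral chi-square with one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import stats

from .types import ValidationError

__all__ = ["PowerScenario", "instrument_r2", "binary_mr_power"]


@dataclass(frozen=True)
class PowerScenario:
    """Inputs to a binary-outcome MR power calculation.

    n: outcome-study sample size (cases + controls).
    case_fraction: K, the proportion of cases in (0,1).
    or_per_sd: hypothesized causal odds ratio per SD of exposure.
    r2: exposure variance explained by the instrument(s), in (0,1).
    alpha: two-sided significance level.
    """

    n: int
    case_fraction: float
    or_per_sd: float
    r2: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if not (0 < self.case_fraction < 1):
            raise ValidationError("case_fraction must lie in (0,1)")
        if not (0 < self.r2 < 1):
            raise ValidationError("r2 must lie in (0,1)")
        if self.or_per_sd <= 0:
            raise ValidationError("or_per_sd must be positive")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0,1)")


def instrument_r2(
    eaf: Union[float, Sequence[float]],
    beta: Union[float, Sequence[float]],
) -> float:
    """Variance of a unit-variance exposure explained by instrument(s).

    Per variant ``2 p (1-p) beta^2`` under Hardy-Weinberg; several variants
    are summed assuming independence. Symmetric in ``p`` vs ``1-p``.
    """
    eafs = np.atleast_1d(np.asarray(eaf, dtype=float))
    betas = np.atleast_1d(np.asarray(beta, dtype=float))
    if eafs.shape != betas.shape:
        raise ValidationError("eaf and beta must have matching shapes")
    if np.any((eafs <= 0) | (eafs >= 1)):
        raise ValidationError("eaf values must lie strictly in (0,1)")
    r2 = float(np.sum(2.0 * eafs * (1.0 - eafs) * betas**2))
    if r2 >= 1.0:
        raise ValidationError(
            f"instrument r2 {r2:.3g} >= 1 implies a non-standardized exposure"
        )
    return r2


def binary_mr_power(scenario: PowerScenario) -> float:
    """Analytic power of the MR test for a binary outcome.

    With K the case fraction and OR the causal odds ratio per SD, the
    attenuated observable effect is ``b = K (OR / (1 + K (OR - 1)) - 1)``,
    its variance ``v = (K (1-K) - b^2) / (n r2)``, and power is the upper
    tail of a noncentral chi-square(1, b^2/v) beyond the central
    chi-square(1) critical value at ``alpha``. Returns a fraction in (0,1);
    equals ``alpha`` when OR = 1.
    """
    k, orr = scenario.case_fraction, scenario.or_per_sd
    b = k * (orr / (1.0 + k * (orr - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b * b) / (scenario.n * scenario.r2)
    if v <= 0:
        raise ValidationError("non-positive effect variance; inputs out of range")
    ncp = b * b / v
    if not math.isfinite(ncp):
        raise ValidationError("non-finite non-centrality parameter")
    crit = stats.chi2.ppf(1.0 - scenario.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))
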