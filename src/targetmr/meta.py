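"""Fixed- and random-effects meta-analysis of MR estimates.

Per-cohort causal estimates (log scale) are pooled with inverse-variance
weights. Heterogeneity is quantified by Cochran's Q and I-squared; the
random-effects model uses the DerSimonian-Laird moment estimator of the
between-study variance tau-squared. The model-selection rule used in the
pipeline is: fixed effects unless the Q test rejects homogeneity.
"""

from __future__ import annotations

import math
from typing import Sequence, Union

from scipy import stats

from .types import MetaResult, MREstimate, ValidationError

__all__ = ["pool_fixed", "pool_random", "decide_model", "estimate_from_or_ci"]

Estimate = Union[MREstimate, MetaResult]


def _validate(estimates: Sequence[Estimate]) -> bool:
    if not estimates:
        raise ValidationError("meta-analysis requires at least one estimate")
    binary = estimates[0].odds_ratio is not None
    if any((e.odds_ratio is not None) != binary for e in estimates):
        raise ValidationError("cannot pool estimates on mixed outcome scales")
    return binary


def _build(model: str, beta: float, se: float, q: float, df: int, tau2: float,
           estimates: Sequence[Estimate], binary: bool, ci_level: float) -> MetaResult:
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci_low, ci_high = beta - z * se, beta + z * se
    pvalue = 2.0 * stats.norm.sf(abs(beta) / se)
    q_pvalue = float(stats.chi2.sf(q, df)) if df >= 1 else 1.0
    i2 = 0.0 if q <= 0 or df < 1 else max(0.0, (q - df) / q) * 100.0
    kwargs = {}
    if binary:
        kwargs = dict(
            odds_ratio=math.exp(beta),
            or_ci_low=math.exp(ci_low),
            or_ci_high=math.exp(ci_high),
        )
    first = estimates[0]
    return MetaResult(
        model=model,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        pvalue=pvalue,
        q=q,
        df=df,
        q_pvalue=q_pvalue,
        i2=i2,
        tau2=tau2,
        k=len(estimates),
        exposure=first.exposure,
        outcome=first.outcome,
        **kwargs,
    )


def pool_fixed(estimates: Sequence[Estimate], ci_level: float = 0.95) -> MetaResult:
    """Fixed-effects (inverse-variance) pooling with heterogeneity statistics.

    ``k = 1`` yields a degenerate but well-formed result: the input estimate
    with Q = 0, I-squared = 0 and Q p-value 1.
    """
    binary = _validate(estimates)
    w = [1.0 / e.se**2 for e in estimates]
    sw = sum(w)
    beta = sum(wi * e.beta for wi, e in zip(w, estimates)) / sw
    se = 1.0 / math.sqrt(sw)
    q = sum(wi * (e.beta - beta) ** 2 for wi, e in zip(w, estimates))
    return _build("fixed", beta, se, q, len(estimates) - 1, 0.0, estimates, binary, ci_level)


def pool_random(estimates: Sequence[Estimate], ci_level: float = 0.95) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau-squared is the truncated moment estimator computed from the
    fixed-effect Q; with homogeneous inputs (Q <= df) it is zero and the
    result coincides with ``pool_fixed``.
    """
    if len(estimates) < 2:
        raise ValidationError("random-effects pooling requires at least two estimates")
    binary = _validate(estimates)
    w = [1.0 / e.se**2 for e in estimates]
    sw = sum(w)
    beta_fe = sum(wi * e.beta for wi, e in zip(w, estimates)) / sw
    q = sum(wi * (e.beta - beta_fe) ** 2 for wi, e in zip(w, estimates))
    df = len(estimates) - 1
    c = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - df) / c)
    ws = [1.0 / (e.se**2 + tau2) for e in estimates]
    sws = sum(ws)
    beta = sum(wi * e.beta for wi, e in zip(ws, estimates)) / sws
    se = 1.0 / math.sqrt(sws)
    return _build("random", beta, se, q, df, tau2, estimates, binary, ci_level)


def decide_model(estimates: Sequence[Estimate], q_alpha: float = 0.05) -> str:
    """Choose ``fixed`` unless Cochran's Q rejects homogeneity at ``q_alpha``."""
    if len(estimates) < 2:
        return "fixed"
    return "fixed" if pool_fixed(estimates).q_pvalue > q_alpha else "random"


def estimate_from_or_ci(
    odds_ratio: float,
    ci_low: float,
    ci_high: float,
    method: str = "wald_ratio",
    n_snps: int = 1,
    ci_level: float = 0.95,
    exposure: str = "",
    outcome: str = "",
) -> MREstimate:
    """Reconstruct a log-scale estimate from a published OR and CI.

    The SE is back-derived as ``ln(ci_high/ci_low) / (2 z)`` with ``z`` the
    normal quantile of the interval; the p-value is recomputed from the
    reconstructed z-score. Useful for pooling cohort results reported only
    at odds-ratio precision.
    """
    if not (0 < ci_low < odds_ratio < ci_high):
        raise ValidationError("require ci_low < odds_ratio < ci_high, all positive")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    beta = math.log(odds_ratio)
    se = math.log(ci_high / ci_low) / (2.0 * z)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pvalue=2.0 * stats.norm.sf(abs(beta) / se),
        n_snps=n_snps,
        exposure=exposure,
        outcome=outcome,
        odds_ratio=math.exp(beta),
        or_ci_low=math.exp(beta - z * se),
        or_ci_high=math.exp(beta + z * se),
    )
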