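"""Wald-ratio and inverse-variance-weighted causal estimation.

For a single instrument the causal effect of a standardized exposure on an
outcome is the Wald ratio ``beta_Y / beta_X``. Its first-order standard
error ``se_Y / |beta_X|`` ignores uncertainty in the exposure association;
the second-order (delta-method) form adds the exposure-side term and is
never smaller. With several independent instruments the IVW estimate is the
precision-weighted mean of per-variant Wald ratios, equivalent to
fixed-effects pooling of the individual ratio estimates.

Instrument strength is summarized by the F statistic, which for a single
variant with summary data equals the squared association z-score.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from scipy import stats

from .types import (
    AssociationRecord,
    HarmonizedPair,
    MREstimate,
    ValidationError,
)

__all__ = ["wald_ratio", "ivw", "f_statistic", "scaled_biomarker_effect"]


def _finish(
    method: str,
    beta: float,
    se: float,
    ci_level: float,
    n_snps: int,
    exposure: str,
    outcome: str,
    binary: bool,
) -> MREstimate:
    if not (0 < ci_level < 1):
        raise ValidationError(f"ci_level must lie in (0,1), got {ci_level}")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci_low, ci_high = beta - z * se, beta + z * se
    pvalue = 2.0 * stats.norm.sf(abs(beta) / se)
    kwargs = {}
    if binary:
        # exp() can overflow for extreme ratios; saturate to inf
        _exp = lambda v: math.exp(v) if v < 709 else math.inf  # noqa: E731
        kwargs = dict(
            odds_ratio=_exp(beta),
            or_ci_low=_exp(ci_low),
            or_ci_high=_exp(ci_high),
        )
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        pvalue=pvalue,
        n_snps=n_snps,
        exposure=exposure,
        outcome=outcome,
        **kwargs,
    )


def wald_ratio(
    pair: HarmonizedPair,
    se_method: str = "first_order",
    ci_level: float = 0.95,
) -> MREstimate:
    """Single-instrument causal estimate ``outcome_beta / exposure_beta``.

    ``se_method`` selects the first-order SE (outcome uncertainty only,
    the conventional default) or the second-order delta-method SE which
    also propagates exposure-side uncertainty.
    """
    if pair.exposure_beta == 0:
        raise ValidationError(f"{pair.rsid}: Wald ratio undefined for exposure beta 0")
    beta = pair.outcome_beta / pair.exposure_beta
    if se_method == "first_order":
        se = pair.outcome_se / abs(pair.exposure_beta)
    elif se_method == "second_order":
        bx2 = pair.exposure_beta**2
        se = math.sqrt(
            pair.outcome_se**2 / bx2
            + pair.outcome_beta**2 * pair.exposure_se**2 / bx2**2
        )
    else:
        raise ValidationError(f"unknown se_method {se_method!r}")
    return _finish(
        "wald_ratio",
        beta,
        se,
        ci_level,
        1,
        pair.exposure,
        pair.outcome,
        pair.outcome_trait_type == "binary",
    )


def ivw(pairs: Sequence[HarmonizedPair], ci_level: float = 0.95) -> MREstimate:
    """Inverse-variance-weighted estimate over independent instruments.

    Weights are ``beta_X^2 / se_Y^2`` (the inverse first-order ratio
    variances); a single pair reduces exactly to ``wald_ratio`` with the
    first-order SE. Fixed-effect weighting without multiplicative residual
    scaling; correlation between instruments is not modelled.
    """
    if not pairs:
        raise ValidationError("ivw requires at least one harmonized pair")
    num = den = 0.0
    for p in pairs:
        if p.exposure_beta == 0:
            raise ValidationError(f"{p.rsid}: Wald ratio undefined for exposure beta 0")
        w = p.exposure_beta**2 / p.outcome_se**2
        num += w * (p.outcome_beta / p.exposure_beta)
        den += w
    beta = num / den
    se = 1.0 / math.sqrt(den)
    first = pairs[0]
    method = "ivw" if len(pairs) > 1 else "wald_ratio"
    return _finish(
        method,
        beta,
        se,
        ci_level,
        len(pairs),
        first.exposure,
        first.outcome,
        first.outcome_trait_type == "binary",
    )


def f_statistic(record: AssociationRecord) -> float:
    """Instrument-strength F statistic, ``(beta/se)^2``.

    Equals the squared association z-score; values above 10 are
    conventionally taken to indicate negligible weak-instrument bias.
    """
    return (record.beta / record.se) ** 2


def scaled_biomarker_effect(
    exposure_rec: AssociationRecord,
    biomarker_rec: AssociationRecord,
    ci_level: float = 0.95,
) -> MREstimate:
    """Change in a downstream quantitative biomarker per SD of exposure.

    A Wald ratio between two quantitative associations at the same variant:
    biomarker SD change per SD increase in the exposure, first-order SE,
    normal confidence interval, no odds-scale fields.
    """
    if exposure_rec.rsid != biomarker_rec.rsid:
        raise ValidationError(
            f"rsid mismatch: {exposure_rec.rsid!r} vs {biomarker_rec.rsid!r}"
        )
    if exposure_rec.trait_type != "quantitative" or biomarker_rec.trait_type != "quantitative":
        raise ValidationError("scaled biomarker effects require two quantitative traits")
    if exposure_rec.beta == 0:
        raise ValidationError(f"{exposure_rec.rsid}: Wald ratio undefined for exposure beta 0")
    beta = biomarker_rec.beta / exposure_rec.beta
    se = biomarker_rec.se / abs(exposure_rec.beta)
    return _finish(
        "wald_ratio",
        beta,
        se,
        ci_level,
        1,
        exposure_rec.trait,
        biomarker_rec.trait,
        binary=False,
    )
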