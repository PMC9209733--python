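"""Instrument selection and exposure/outcome harmonization.

Selection applies three filters to exposure associations -- genome-wide
significance, a minor-allele-frequency floor, and removal of palindromic
(A/T, C/G) variants -- followed by greedy LD pruning at an r-squared
threshold. Harmonization places the outcome association on the exposure's
effect allele, resolving allele swaps and strand flips, and a final
alignment step orients every pair to the exposure-increasing allele.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import List, Sequence

import numpy as np

from .types import (
    COMPLEMENT,
    AssociationRecord,
    ConfigurationError,
    HarmonizationError,
    HarmonizedPair,
    InstrumentSet,
    LDMatrix,
    SelectionCriteria,
    ValidationError,
    _check_allele,
)

logger = logging.getLogger(__name__)

#: half-width of the EAF band around 0.5 inside which palindromic variants
#: cannot be oriented by frequency
EAF_AMBIGUITY_BAND = 0.08


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    a = _check_allele(effect_allele, "effect_allele")
    b = _check_allele(other_allele, "other_allele")
    return COMPLEMENT[a] == b


def select_instruments(
    exposure_assocs: Sequence[AssociationRecord],
    criteria: SelectionCriteria = SelectionCriteria(),
    ld: LDMatrix = None,
) -> InstrumentSet:
    """Filter exposure associations into an instrument set.

    Filters are applied per candidate (significance, MAF, palindromy); the
    survivors are then greedily LD-pruned: sort by ascending p-value (ties
    by rsid), keep the best, and drop any later candidate whose r-squared
    with an already-kept variant reaches ``criteria.ld_r2_max``. Every
    decision is recorded in the selection log.
    """
    log: List[tuple] = []
    survivors: List[AssociationRecord] = []
    decided = {}
    for rec in exposure_assocs:
        if rec.pvalue is None:
            decided[rec.rsid] = (False, "missing p-value")
        elif rec.pvalue >= criteria.p_max:
            decided[rec.rsid] = (False, f"p-value {rec.pvalue:.3g} >= {criteria.p_max:.3g}")
        elif rec.maf is None:
            decided[rec.rsid] = (False, "missing EAF")
        elif rec.maf <= criteria.maf_min:
            decided[rec.rsid] = (False, f"MAF {rec.maf:.4g} <= {criteria.maf_min:.4g}")
        elif criteria.drop_palindromic and is_palindromic(rec.effect_allele, rec.other_allele):
            decided[rec.rsid] = (False, "palindromic allele pair")
        else:
            survivors.append(rec)

    if survivors and ld is None:
        raise ConfigurationError("an LD matrix is required when candidates survive filtering")
    for rec in survivors:
        if rec.rsid not in ld:
            raise ConfigurationError(f"candidate {rec.rsid!r} missing from LD matrix")

    kept: List[AssociationRecord] = []
    for rec in sorted(survivors, key=lambda r: (r.pvalue, r.rsid)):
        clash = next(
            (k.rsid for k in kept if ld.r2_between(rec.rsid, k.rsid) >= criteria.ld_r2_max),
            None,
        )
        if clash is None:
            kept.append(rec)
            decided[rec.rsid] = (True, "retained")
        else:
            r2 = ld.r2_between(rec.rsid, clash)
            decided[rec.rsid] = (False, f"LD r2 {r2:.3g} with {clash} >= {criteria.ld_r2_max:.3g}")

    kept_ids = {r.rsid for r in kept}
    records = tuple(r for r in exposure_assocs if r.rsid in kept_ids)
    for rec in exposure_assocs:
        retained, reason = decided[rec.rsid]
        log.append((rec.rsid, retained, reason))
        logger.info("selection: %s %s (%s)", rec.rsid, "retained" if retained else "dropped", reason)
    sub_ld = ld.subset([r.rsid for r in records]) if records else LDMatrix([], np.empty((0, 0)))
    return InstrumentSet(records=records, ld=sub_ld, selection_log=tuple(log))


def _pair_from(exposure: AssociationRecord, outcome: AssociationRecord, action: str,
               outcome_beta: float, outcome_eaf, palindromic: bool) -> HarmonizedPair:
    return HarmonizedPair(
        rsid=exposure.rsid,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        exposure_beta=exposure.beta,
        exposure_se=exposure.se,
        outcome_beta=outcome_beta,
        outcome_se=outcome.se,
        exposure_eaf=exposure.eaf,
        outcome_eaf=outcome_eaf,
        palindromic=palindromic,
        orientation_action=action,
        exposure=exposure.trait,
        outcome=outcome.trait,
        outcome_trait_type=outcome.trait_type,
    )


def harmonize_pair(
    exposure_rec: AssociationRecord,
    outcome_rec: AssociationRecord,
    palindromic_policy: str = "drop",
) -> HarmonizedPair:
    """Orient the outcome association onto the exposure's effect allele.

    Identical allele pairs need no action; reversed pairs negate the outcome
    beta and complement its EAF; pairs matching only after base
    complementation are treated as strand flips. Palindromic variants are
    strand-unresolvable from alleles alone: policy ``drop`` refuses them,
    ``infer_by_eaf`` orients by comparing allele frequencies and refuses when
    both EAFs fall within ``EAF_AMBIGUITY_BAND`` of 0.5.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValidationError(f"unknown palindromic_policy {palindromic_policy!r}")
    if exposure_rec.rsid != outcome_rec.rsid:
        raise HarmonizationError(
            f"rsid mismatch: {exposure_rec.rsid!r} vs {outcome_rec.rsid!r}"
        )
    ea, oa = exposure_rec.effect_allele, exposure_rec.other_allele
    out_ea, out_oa = outcome_rec.effect_allele, outcome_rec.other_allele
    palindromic = is_palindromic(ea, oa)

    if palindromic:
        if {out_ea, out_oa} != {ea, oa}:
            raise HarmonizationError(f"{exposure_rec.rsid}: incompatible allele sets")
        if palindromic_policy == "drop":
            raise HarmonizationError(
                f"{exposure_rec.rsid}: palindromic variant is strand-ambiguous (policy=drop)"
            )
        if exposure_rec.eaf is None or outcome_rec.eaf is None:
            raise HarmonizationError(
                f"{exposure_rec.rsid}: infer_by_eaf requires both EAFs"
            )
        if (
            abs(exposure_rec.eaf - 0.5) <= EAF_AMBIGUITY_BAND
            or abs(outcome_rec.eaf - 0.5) <= EAF_AMBIGUITY_BAND
        ):
            raise HarmonizationError(
                f"{exposure_rec.rsid}: EAFs too close to 0.5 to resolve strand"
            )
        # frequencies on the same side of 0.5 => labels already concordant
        same_side = (exposure_rec.eaf - 0.5) * (outcome_rec.eaf - 0.5) > 0
        if (out_ea == ea) == same_side:
            return _pair_from(exposure_rec, outcome_rec, "none",
                              outcome_rec.beta, outcome_rec.eaf, True)
        eaf = None if outcome_rec.eaf is None else 1.0 - outcome_rec.eaf
        return _pair_from(exposure_rec, outcome_rec, "allele_swap",
                          -outcome_rec.beta, eaf, True)

    comp_ea, comp_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
    out_eaf = outcome_rec.eaf
    if (out_ea, out_oa) == (ea, oa):
        return _pair_from(exposure_rec, outcome_rec, "none", outcome_rec.beta, out_eaf, False)
    if (out_ea, out_oa) == (oa, ea):
        eaf = None if out_eaf is None else 1.0 - out_eaf
        return _pair_from(exposure_rec, outcome_rec, "allele_swap", -outcome_rec.beta, eaf, False)
    if (comp_ea, comp_oa) == (ea, oa):
        return _pair_from(exposure_rec, outcome_rec, "strand_flip", outcome_rec.beta, out_eaf, False)
    if (comp_ea, comp_oa) == (oa, ea):
        eaf = None if out_eaf is None else 1.0 - out_eaf
        return _pair_from(exposure_rec, outcome_rec, "strand_flip_and_swap",
                          -outcome_rec.beta, eaf, False)
    raise HarmonizationError(
        f"{exposure_rec.rsid}: allele sets incompatible even after complementation "
        f"({ea}/{oa} vs {out_ea}/{out_oa})"
    )


def align_to_increasing(pair: HarmonizedPair) -> HarmonizedPair:
    """Orient a harmonized pair to the exposure-increasing allele.

    When the exposure beta is negative both betas are negated, the allele
    labels are swapped and both EAFs complemented. Idempotent; the Wald
    ratio is invariant.
    """
    if pair.exposure_beta >= 0:
        return pair
    return replace(
        pair,
        effect_allele=pair.other_allele,
        other_allele=pair.effect_allele,
        exposure_beta=-pair.exposure_beta,
        outcome_beta=-pair.outcome_beta,
        exposure_eaf=None if pair.exposure_eaf is None else 1.0 - pair.exposure_eaf,
        outcome_eaf=None if pair.outcome_eaf is None else 1.0 - pair.outcome_eaf,
    )
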