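"""Published summary-data inputs for the IL-6 receptor cis-MR analysis.

These tables carry the per-variant associations used in a target-based MR
of IL-6 signaling: two IL-6R-region variants (rs2228145, the Asp358Ala
missense variant, and the intronic rs12048091) against circulating IL-6
level (the exposure, standardized), the downstream biomarkers C-reactive
protein and fibrinogen, the positive-control outcomes rheumatoid arthritis
and coronary heart disease, and the per-cohort NAFLD odds ratios from two
independent case-control GWASs. Values are as published (betas to two
decimals, SEs to three), which bounds how precisely derived quantities can
be reproduced.

The palindromic variant rs10752641 is included among the exposure
candidates with SYNTHETIC placeholder alleles (A/T), EAF and beta/SE --
its published record states only that it passed significance and was then
removed for strand ambiguity; the placeholders exist so the selection
filter can be exercised end to end. Its LD with the retained variants is
likewise a synthetic placeholder; the published value is only the
rs2228145-rs12048091 r-squared of 0.11.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .types import AssociationRecord, LDMatrix, StudyMeta

__all__ = [
    "IL6_STUDY",
    "NAFLD_COHORTS",
    "il6_exposure_associations",
    "outcome_associations",
    "il6r_ld_matrix",
    "nafld_cohort_ors",
]

IL6_STUDY = StudyMeta(label="IL-6 GWAS meta-analysis", trait="IL-6", n=30000)

#: outcome / biomarker cohort metadata keyed by trait name
_OUTCOME_META: Dict[str, StudyMeta] = {
    "CRP": StudyMeta(label="UK Biobank", trait="CRP", n=361194),
    "fibrinogen": StudyMeta(label="UK Biobank", trait="fibrinogen", n=361194),
    "rheumatoid_arthritis": StudyMeta(
        label="RA GWAS", trait="rheumatoid_arthritis", trait_type="binary",
        n_cases=14361, n_controls=43923,
    ),
    "coronary_heart_disease": StudyMeta(
        label="CHD GWAS", trait="coronary_heart_disease", trait_type="binary",
        n_cases=60801, n_controls=123504,
    ),
}

NAFLD_COHORTS = {
    "non-FinnGen": StudyMeta(
        label="non-FinnGen", trait="NAFLD", trait_type="binary",
        n_cases=1483, n_controls=17781,
    ),
    "FinnGen": StudyMeta(
        label="FinnGen", trait="NAFLD", trait_type="binary",
        n_cases=894, n_controls=217898,
    ),
}


def il6_exposure_associations(include_palindromic: bool = False) -> List[AssociationRecord]:
    """Per-variant associations with standardized circulating IL-6 level.

    With ``include_palindromic`` the synthetic rs10752641 placeholder row
    is appended so that selection filters see a palindromic candidate.
    """
    records = [
        AssociationRecord(
            rsid="rs2228145", effect_allele="C", other_allele="A",
            eaf=0.38, beta=0.17, se=0.012, pvalue=3.34e-45,
            n=IL6_STUDY.n, trait="IL-6",
        ),
        AssociationRecord(
            rsid="rs12048091", effect_allele="A", other_allele="G",
            eaf=0.82, beta=0.09, se=0.016, pvalue=3.95e-8,
            n=IL6_STUDY.n, trait="IL-6",
        ),
    ]
    if include_palindromic:
        # synthetic placeholder: only the variant's significance and its
        # palindromic allele pair are on record
        records.append(
            AssociationRecord(
                rsid="rs10752641", effect_allele="A", other_allele="T",
                eaf=0.45, beta=0.06, se=0.010, pvalue=1.0e-9,
                n=IL6_STUDY.n, trait="IL-6",
            )
        )
    return records


#: (beta, se, p) per outcome trait, keyed by rsid; effect allele as in the
#: exposure table (C for rs2228145, A for rs12048091)
_OUTCOME_ROWS: Dict[str, Dict[str, tuple]] = {
    "CRP": {
        "rs2228145": (-0.09, 0.002, 1.00e-200),
        "rs12048091": (-0.06, 0.003, 4.36e-65),
    },
    "fibrinogen": {
        "rs2228145": (-0.01, 0.003, 0.001),
        "rs12048091": (-0.01, 0.004, 0.013),
    },
    "rheumatoid_arthritis": {
        "rs2228145": (-0.07, 0.015, 4.50e-6),
        "rs12048091": (-0.09, 0.021, 1.30e-5),
    },
    "coronary_heart_disease": {
        "rs2228145": (-0.05, 0.010, 1.86e-7),
        "rs12048091": (0.02, 0.013, 0.243),
    },
}

_ALLELES = {"rs2228145": ("C", "A"), "rs12048091": ("A", "G")}
_EAFS = {"rs2228145": 0.38, "rs12048091": 0.82}


def outcome_associations(trait: str) -> List[AssociationRecord]:
    """Associations of the two instruments with a biomarker or outcome.

    ``trait`` is one of CRP, fibrinogen, rheumatoid_arthritis,
    coronary_heart_disease. Betas are on the SD scale for the biomarkers
    and the log-odds scale for the disease outcomes, oriented to the same
    effect alleles as the exposure table.
    """
    if trait not in _OUTCOME_ROWS:
        raise KeyError(f"unknown trait {trait!r}; options: {sorted(_OUTCOME_ROWS)}")
    meta = _OUTCOME_META[trait]
    records = []
    for rsid, (beta, se, p) in _OUTCOME_ROWS[trait].items():
        ea, oa = _ALLELES[rsid]
        records.append(
            AssociationRecord(
                rsid=rsid, effect_allele=ea, other_allele=oa,
                eaf=_EAFS[rsid], beta=beta, se=se, pvalue=p,
                n=meta.n, n_cases=meta.n_cases, n_controls=meta.n_controls,
                trait=meta.trait, trait_type=meta.trait_type,
            )
        )
    return records


def il6r_ld_matrix(include_palindromic: bool = False) -> LDMatrix:
    """Pairwise LD (r-squared) between the IL-6R-region candidates.

    The rs2228145-rs12048091 value 0.11 is published; entries involving the
    placeholder rs10752641 are synthetic.
    """
    if include_palindromic:
        rsids = ["rs2228145", "rs12048091", "rs10752641"]
        r2 = np.array(
            [
                [1.00, 0.11, 0.05],
                [0.11, 1.00, 0.02],
                [0.05, 0.02, 1.00],
            ]
        )
    else:
        rsids = ["rs2228145", "rs12048091"]
        r2 = np.array([[1.00, 0.11], [0.11, 1.00]])
    return LDMatrix(rsids, r2)


def nafld_cohort_ors() -> Dict[str, tuple]:
    """Published per-cohort single-instrument NAFLD odds ratios.

    Each value is (OR, 95% CI low, 95% CI high) for the rs2228145 Wald
    estimate; log-scale SEs can be back-derived from the interval widths
    with :func:`targetmr.meta.estimate_from_or_ci` for pooling.
    """
    return {"non-FinnGen": (1.99, 1.27, 3.13), "FinnGen": (1.51, 0.84, 2.72)}
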