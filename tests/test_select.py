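"""Instrument selection, harmonization and effect-allele alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr.select import (
    align_to_increasing,
    harmonize_pair,
    is_palindromic,
    select_instruments,
)
from targetmr.types import (
    AssociationRecord,
    ConfigurationError,
    HarmonizationError,
    LDMatrix,
    SelectionCriteria,
    ValidationError,
)


def _rec(rsid, ea, oa, p, eaf=0.3, beta=0.1, se=0.01):
    return AssociationRecord(
        rsid=rsid, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pvalue=p, trait="exposure",
    )


class TestPalindromic:
    @pytest.mark.parametrize(
        "ea, oa, expected",
        [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
         ("C", "A", False), ("A", "G", False), ("G", "T", False)],
    )
    def test_definition(self, ea, oa, expected):
        assert is_palindromic(ea, oa) is expected

    def test_non_acgt_allele_rejected(self):
        with pytest.raises(ValidationError):
            is_palindromic("A", "N")


class TestSelectInstruments:
    def test_published_candidates_keep_two_drop_palindromic(self, il6_candidates, ld_full):
        result = select_instruments(il6_candidates, SelectionCriteria(), ld_full)
        assert result.rsids == ("rs2228145", "rs12048091")
        log = {rsid: (kept, reason) for rsid, kept, reason in result.selection_log}
        assert log["rs10752641"][0] is False
        assert "palindromic" in log["rs10752641"][1]
        assert len(result.selection_log) == len(il6_candidates)

    def test_empty_candidate_list(self):
        result = select_instruments([], SelectionCriteria(), None)
        assert result.records == ()
        assert result.selection_log == ()

    def test_high_ld_pair_keeps_lower_p_only(self):
        a = _rec("rsA", "C", "A", 1e-20)
        b = _rec("rsB", "A", "G", 1e-10)
        ld = LDMatrix(["rsA", "rsB"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        result = select_instruments([a, b], SelectionCriteria(), ld)
        assert result.rsids == ("rsA",)
        log = dict((r, why) for r, _, why in result.selection_log)
        assert "LD" in log["rsB"]

    def test_pruning_is_input_order_invariant(self):
        a = _rec("rsA", "C", "A", 1e-20)
        b = _rec("rsB", "A", "G", 1e-10)
        c = _rec("rsC", "G", "T", 1e-15)
        r2 = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        ld = LDMatrix(["rsA", "rsB", "rsC"], r2)
        kept_fwd = select_instruments([a, b, c], SelectionCriteria(), ld).rsids
        kept_rev = select_instruments([c, b, a], SelectionCriteria(), ld).rsids
        assert set(kept_fwd) == set(kept_rev) == {"rsA", "rsC"}

    def test_p_and_maf_filters(self):
        weak = _rec("rsW", "C", "A", 1e-6)
        rare = _rec("rsR", "A", "G", 1e-20, eaf=0.005)
        boundary = _rec("rsM", "G", "T", 1e-20, eaf=0.01)  # MAF not strictly > floor
        ld = LDMatrix(["rsW", "rsR", "rsM"], np.eye(3))
        result = select_instruments([weak, rare, boundary], SelectionCriteria(), ld)
        assert result.rsids == ()

    def test_missing_ld_entry_is_configuration_error(self):
        a = _rec("rsA", "C", "A", 1e-20)
        ld = LDMatrix(["rsOther"], np.array([[1.0]]))
        with pytest.raises(ConfigurationError, match="rsA"):
            select_instruments([a], SelectionCriteria(), ld)


class TestHarmonize:
    exposure = _rec("rs2228145", "C", "A", 3.34e-45, eaf=0.38, beta=0.17, se=0.012)

    def _outcome(self, ea, oa, beta, eaf=0.40):
        return AssociationRecord(
            rsid="rs2228145", effect_allele=ea, other_allele=oa,
            eaf=eaf, beta=beta, se=0.010, pvalue=1.9e-7,
            n_cases=100, n_controls=900, trait="CHD", trait_type="binary",
        )

    def test_identical_alleles_no_action(self):
        pair = harmonize_pair(self.exposure, self._outcome("C", "A", -0.05))
        assert pair.orientation_action == "none"
        assert pair.outcome_beta == -0.05

    def test_swapped_alleles_negate_beta_and_complement_eaf(self):
        pair = harmonize_pair(self.exposure, self._outcome("A", "C", 0.05, eaf=0.60))
        assert pair.orientation_action == "allele_swap"
        assert pair.outcome_beta == -0.05
        assert pair.outcome_eaf == pytest.approx(0.40)

    def test_strand_flip_detected(self):
        pair = harmonize_pair(self.exposure, self._outcome("G", "T", -0.05))
        assert pair.orientation_action == "strand_flip"
        assert pair.outcome_beta == -0.05

    def test_strand_flip_and_swap(self):
        pair = harmonize_pair(self.exposure, self._outcome("T", "G", 0.05))
        assert pair.orientation_action == "strand_flip_and_swap"
        assert pair.outcome_beta == -0.05

    def test_palindromic_drop_policy_errors(self):
        exp = _rec("rs1", "A", "T", 1e-9, eaf=0.3)
        out = AssociationRecord(
            rsid="rs1", effect_allele="A", other_allele="T",
            eaf=0.3, beta=0.05, se=0.01, pvalue=0.01,
        )
        with pytest.raises(HarmonizationError, match="ambiguous"):
            harmonize_pair(exp, out, palindromic_policy="drop")

    def test_palindromic_infer_by_eaf_orients_or_refuses(self):
        exp = _rec("rs1", "A", "T", 1e-9, eaf=0.2)
        concordant = AssociationRecord(
            rsid="rs1", effect_allele="A", other_allele="T",
            eaf=0.22, beta=0.05, se=0.01, pvalue=0.01,
        )
        pair = harmonize_pair(exp, concordant, palindromic_policy="infer_by_eaf")
        assert pair.orientation_action == "none" and pair.outcome_beta == 0.05

        flipped = AssociationRecord(
            rsid="rs1", effect_allele="A", other_allele="T",
            eaf=0.78, beta=0.05, se=0.01, pvalue=0.01,
        )
        pair = harmonize_pair(exp, flipped, palindromic_policy="infer_by_eaf")
        assert pair.orientation_action == "allele_swap" and pair.outcome_beta == -0.05

        ambiguous = AssociationRecord(
            rsid="rs1", effect_allele="A", other_allele="T",
            eaf=0.52, beta=0.05, se=0.01, pvalue=0.01,
        )
        with pytest.raises(HarmonizationError, match="0.5"):
            harmonize_pair(exp, ambiguous, palindromic_policy="infer_by_eaf")

    def test_rsid_mismatch_and_incompatible_alleles(self):
        other = AssociationRecord(
            rsid="rs999", effect_allele="C", other_allele="A",
            eaf=0.4, beta=0.1, se=0.01, pvalue=0.01,
        )
        with pytest.raises(HarmonizationError, match="mismatch"):
            harmonize_pair(self.exposure, other)
        incompatible = self._outcome("A", "G", 0.05)
        with pytest.raises(HarmonizationError, match="incompatible"):
            harmonize_pair(self.exposure, incompatible)


class TestAlignToIncreasing:
    def test_positive_exposure_unchanged(self):
        pair = harmonize_pair(
            TestHarmonize.exposure, TestHarmonize()._outcome("C", "A", -0.05)
        )
        assert align_to_increasing(pair) == pair

    def test_negative_exposure_flips_both_betas_and_alleles(self):
        exp = _rec("rs1", "C", "A", 1e-9, eaf=0.38, beta=-0.17)
        out = AssociationRecord(
            rsid="rs1", effect_allele="C", other_allele="A",
            eaf=0.38, beta=0.05, se=0.01, pvalue=0.01,
        )
        pair = align_to_increasing(harmonize_pair(exp, out))
        assert pair.exposure_beta == pytest.approx(0.17)
        assert pair.outcome_beta == pytest.approx(-0.05)
        assert (pair.effect_allele, pair.other_allele) == ("A", "C")
        assert pair.exposure_eaf == pytest.approx(0.62)

    def test_idempotent(self):
        exp = _rec("rs1", "C", "A", 1e-9, beta=-0.17)
        out = AssociationRecord(
            rsid="rs1", effect_allele="C", other_allele="A",
            eaf=0.3, beta=0.05, se=0.01, pvalue=0.01,
        )
        once = align_to_increasing(harmonize_pair(exp, out))
        assert align_to_increasing(once) == once


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    exp_beta=st.floats(-1, 1).filter(lambda b: abs(b) > 1e-3),
    out_beta=st.floats(-1, 1),
    swap=st.booleans(),
    flip=st.booleans(),
)
def test_wald_ratio_invariant_under_harmonization_and_alignment(
    exp_beta, out_beta, swap, flip
):
    """Orientation bookkeeping never changes the causal ratio's value."""
    exp = AssociationRecord(
        rsid="rs1", effect_allele="C", other_allele="A",
        eaf=0.38, beta=exp_beta, se=0.01, pvalue=1e-9,
    )
    ea, oa = ("A", "C") if swap else ("C", "A")
    if flip:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ea, oa = comp[ea], comp[oa]
    out = AssociationRecord(
        rsid="rs1", effect_allele=ea, other_allele=oa,
        eaf=0.40, beta=out_beta if not swap else -out_beta,
        se=0.02, pvalue=0.5,
    )
    pair = align_to_increasing(harmonize_pair(exp, out))
    assert pair.exposure_beta >= 0
    assert pair.outcome_beta / pair.exposure_beta == pytest.approx(
        out_beta / exp_beta, rel=1e-12
    )
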