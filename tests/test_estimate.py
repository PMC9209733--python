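"""Wald-ratio and IVW estimation, F statistics, biomarker scaling."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from targetmr.estimate import f_statistic, ivw, scaled_biomarker_effect, wald_ratio
from targetmr.meta import pool_fixed
from targetmr.types import AssociationRecord, HarmonizedPair, ValidationError


def _pair(bx, sx, by, sy, rsid="rs1", outcome_type="binary"):
    return HarmonizedPair(
        rsid=rsid, effect_allele="C", other_allele="A",
        exposure_beta=bx, exposure_se=sx, outcome_beta=by, outcome_se=sy,
        outcome_trait_type=outcome_type,
    )


CHD_PAIR = _pair(0.17, 0.012, -0.05, 0.010, rsid="rs2228145")


class TestWaldRatio:
    def test_chd_positive_control_point_and_interval(self):
        """rs2228145 CHD over IL-6: OR 0.745, matching the published 0.75."""
        res = wald_ratio(CHD_PAIR)
        assert res.beta == pytest.approx(-0.05 / 0.17, rel=1e-12)
        assert res.se == pytest.approx(0.010 / 0.17, rel=1e-12)
        assert res.odds_ratio == pytest.approx(0.7452, abs=5e-4)
        assert res.or_ci_low == pytest.approx(0.664, abs=5e-3)
        assert res.or_ci_high == pytest.approx(0.836, abs=5e-3)
        assert res.method == "wald_ratio" and res.n_snps == 1

    def test_null_outcome_gives_null_effect(self):
        res = wald_ratio(_pair(0.17, 0.012, 0.0, 0.010))
        assert res.beta == 0.0
        assert res.odds_ratio == 1.0
        assert res.pvalue == pytest.approx(1.0)

    def test_second_order_se_matches_delta_method_value(self):
        # sqrt(0.010^2/0.17^2 + 0.05^2 * 0.012^2 / 0.17^4) = 0.06238
        res = wald_ratio(CHD_PAIR, se_method="second_order")
        assert res.se == pytest.approx(0.06238, abs=5e-5)

    def test_zero_exposure_beta_is_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            wald_ratio(_pair(0.0, 0.01, 0.05, 0.01))

    def test_quantitative_outcome_has_no_odds_fields(self):
        res = wald_ratio(_pair(0.17, 0.012, -0.09, 0.002, outcome_type="quantitative"))
        assert res.odds_ratio is None

    def test_pvalue_matches_chi2_tail_of_squared_z(self):
        res = wald_ratio(CHD_PAIR)
        z2 = (res.beta / res.se) ** 2
        assert res.pvalue == pytest.approx(stats.chi2.sf(z2, 1), abs=1e-12)


class TestIVW:
    def test_single_pair_reduces_to_wald_first_order(self):
        res_ivw = ivw([CHD_PAIR])
        res_w = wald_ratio(CHD_PAIR)
        assert res_ivw.beta == pytest.approx(res_w.beta, rel=1e-14)
        assert res_ivw.se == pytest.approx(res_w.se, rel=1e-14)
        assert res_ivw.method == "wald_ratio"

    def test_two_instrument_chd_estimate_matches_weighted_mean_oracle(self):
        """Explicit weighted-sum arithmetic: pooled beta -0.2207, se 0.0545."""
        pair2 = _pair(0.09, 0.016, 0.02, 0.013, rsid="rs12048091")
        res = ivw([CHD_PAIR, pair2])
        w1, w2 = 0.17**2 / 0.010**2, 0.09**2 / 0.013**2
        expected = (w1 * (-0.05 / 0.17) + w2 * (0.02 / 0.09)) / (w1 + w2)
        assert res.beta == pytest.approx(expected, rel=1e-14)
        assert res.beta == pytest.approx(-0.2207, abs=5e-4)
        assert res.se == pytest.approx(0.0545, abs=5e-4)
        assert res.n_snps == 2 and res.method == "ivw"

    def test_duplicated_pair_shrinks_se_by_sqrt2(self):
        one = ivw([CHD_PAIR])
        two = ivw([CHD_PAIR, CHD_PAIR])
        assert two.beta == pytest.approx(one.beta, rel=1e-14)
        assert two.se == pytest.approx(one.se / math.sqrt(2), rel=1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            ivw([])

    def test_equals_fixed_effects_pooling_of_wald_estimates(self):
        """Cross-module identity: IVW == inverse-variance pooling of ratios."""
        pairs = [CHD_PAIR, _pair(0.09, 0.016, 0.02, 0.013, rsid="rs12048091")]
        direct = ivw(pairs)
        pooled = pool_fixed([wald_ratio(p) for p in pairs])
        assert direct.beta == pytest.approx(pooled.beta, abs=1e-12)
        assert direct.se == pytest.approx(pooled.se, abs=1e-12)


class TestFStatistic:
    def test_primary_instrument_value(self):
        rec = AssociationRecord(
            rsid="rs2228145", effect_allele="C", other_allele="A",
            eaf=0.38, beta=0.17, se=0.012, pvalue=3.34e-45,
        )
        assert f_statistic(rec) == pytest.approx((0.17 / 0.012) ** 2, rel=1e-14)
        assert f_statistic(rec) == pytest.approx(200.7, abs=0.1)

    def test_secondary_instrument_value(self):
        rec = AssociationRecord(
            rsid="rs12048091", effect_allele="A", other_allele="G",
            eaf=0.82, beta=0.09, se=0.016, pvalue=3.95e-8,
        )
        assert f_statistic(rec) == pytest.approx(31.64, abs=0.01)

    def test_null_beta_gives_zero(self):
        rec = AssociationRecord(
            rsid="rs0", effect_allele="C", other_allele="A", beta=0.0, se=0.01
        )
        assert f_statistic(rec) == 0.0


class TestScaledBiomarkerEffect:
    il6 = AssociationRecord(
        rsid="rs2228145", effect_allele="C", other_allele="A",
        eaf=0.38, beta=0.17, se=0.012, pvalue=3.34e-45, trait="IL-6",
    )

    def test_crp_scaling_for_primary_instrument(self):
        crp = AssociationRecord(
            rsid="rs2228145", effect_allele="C", other_allele="A",
            eaf=0.38, beta=-0.09, se=0.002, pvalue=1e-200, trait="CRP",
        )
        res = scaled_biomarker_effect(self.il6, crp)
        assert res.beta == pytest.approx(-0.529, abs=5e-4)
        assert res.ci_low == pytest.approx(-0.55, abs=5e-3)
        assert res.ci_high == pytest.approx(-0.51, abs=5e-3)
        assert res.odds_ratio is None

    def test_fibrinogen_scaling_for_primary_instrument(self):
        fib = AssociationRecord(
            rsid="rs2228145", effect_allele="C", other_allele="A",
            eaf=0.38, beta=-0.01, se=0.003, pvalue=0.001, trait="fibrinogen",
        )
        res = scaled_biomarker_effect(self.il6, fib)
        assert res.beta == pytest.approx(-0.0588, abs=5e-4)

    def test_null_biomarker_beta(self):
        flat = AssociationRecord(
            rsid="rs2228145", effect_allele="C", other_allele="A",
            eaf=0.38, beta=0.0, se=0.003, pvalue=0.9, trait="flat",
        )
        assert scaled_biomarker_effect(self.il6, flat).beta == 0.0

    def test_binary_trait_rejected(self):
        binary = AssociationRecord(
            rsid="rs2228145", effect_allele="C", other_allele="A",
            beta=-0.05, se=0.01, trait_type="binary", n_cases=10, n_controls=90,
        )
        with pytest.raises(ValidationError, match="quantitative"):
            scaled_biomarker_effect(self.il6, binary)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    bx=st.floats(0.01, 2.0),
    sx=st.floats(0.001, 0.5),
    by=st.floats(-1.0, 1.0),
    sy=st.floats(0.001, 0.5),
    c=st.floats(0.1, 10.0),
)
def test_wald_scale_invariance_and_se_ordering(bx, sx, by, sy, c):
    """Rescaling the exposure rescales the ratio but not its z-score, and
    the delta-method SE always dominates the first-order SE."""
    base = _pair(bx, sx, by, sy)
    scaled = _pair(c * bx, c * sx, by, sy)
    r1, r2 = wald_ratio(base), wald_ratio(scaled)
    assert r2.beta == pytest.approx(r1.beta / c, rel=1e-9)
    assert r2.beta / r2.se == pytest.approx(r1.beta / r1.se, rel=1e-9)

    second = wald_ratio(base, se_method="second_order")
    assert second.se >= r1.se * (1 - 1e-12)  # equality up to rounding when by == 0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    bx=st.floats(0.01, 2.0), by=st.floats(0.001, 1.0),
)
def test_wald_sign_flips_with_either_input_sign(bx, by):
    plus = wald_ratio(_pair(bx, 0.01, by, 0.01)).beta
    assert wald_ratio(_pair(-bx, 0.01, by, 0.01)).beta == pytest.approx(-plus, rel=1e-9)
    assert wald_ratio(_pair(bx, 0.01, -by, 0.01)).beta == pytest.approx(-plus, rel=1e-9)
    assert wald_ratio(_pair(-bx, 0.01, -by, 0.01)).beta == pytest.approx(plus, rel=1e-9)
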