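"""Lin's CCC, Bland-Altman, and the composite concordance verdict."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cieagree.agreement import (
    AgreementCriteria,
    PairedMeasurements,
    bland_altman,
    bland_altman_from_summary,
    ccc_confidence_interval,
    concordance_verdict,
    lin_ccc,
)
from cieagree.errors import (
    DegenerateCIError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from conftest import ccc_bruteforce


def pairs(x, y, label=""):
    return PairedMeasurements(np.asarray(x, float), np.asarray(y, float), label)


class TestLinCCC:
    def test_perfect_concordance(self):
        assert lin_ccc(pairs([1, 2, 3, 4], [1, 2, 3, 4])).estimate == 1.0

    def test_shifted_line_toy(self):
        # x=(1,2,3), y=x+1: 1/n moments give rho_c = 2*(2/3)/(2/3+2/3+1)
        assert lin_ccc(pairs([1, 2, 3], [2, 3, 4])).estimate == pytest.approx(
            4 / 7, abs=1e-15
        )

    def test_perfect_negative_concordance(self):
        assert lin_ccc(pairs([1, 2, 3], [3, 2, 1])).estimate == pytest.approx(
            -1.0, abs=1e-15
        )

    def test_symmetry_in_x_and_y(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert lin_ccc(pairs(x, y)).estimate == pytest.approx(
            lin_ccc(pairs(y, x)).estimate, abs=1e-14
        )

    def test_never_exceeds_pearson_in_magnitude(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(2, 1, size=25)
            y = 0.8 * x + rng.normal(0, 0.5, size=25)
            res = lin_ccc(pairs(x, y))
            assert abs(res.estimate) <= abs(res.pearson_r) + 1e-12

    def test_equals_pearson_iff_moments_match(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = lin_ccc(pairs(x, x[::-1]))  # same mean, same SD
        assert res.estimate == pytest.approx(res.pearson_r, abs=1e-14)
        res2 = lin_ccc(pairs(x, x + 1))  # shifted mean
        assert abs(res2.estimate) < abs(res2.pearson_r)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=3,
            max_size=40,
        )
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_bruteforce_raw_sum_implementation(self, data):
        x = [a for a, _ in data]
        y = [b for _, b in data]
        sx2 = np.var(x)
        sy2 = np.var(y)
        if sx2 + sy2 + (np.mean(x) - np.mean(y)) ** 2 < 1e-6:
            return  # degenerate: both constant and (near) equal
        got = lin_ccc(pairs(x, y)).estimate
        assert got == pytest.approx(ccc_bruteforce(x, y), abs=1e-12)

    def test_constant_identical_sets_are_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            lin_ccc(pairs([2, 2, 2], [2, 2, 2]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length mismatch"):
            pairs([1, 2, 3], [1, 2])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            pairs([1, 2], [1, 2])

    def test_pairwise_deletion_of_missing_values(self):
        p = pairs([1, 2, np.nan, 4, 5], [1, np.nan, 3, 4, 5])
        assert p.n == 3


class TestCCCConfidenceInterval:
    @staticmethod
    def _sample(n=50, seed=5):
        rng = np.random.default_rng(seed)
        x = rng.normal(5, 2, size=n)
        y = 0.9 * x + rng.normal(0.3, 0.8, size=n)
        return x, y

    def test_interval_brackets_estimate_within_unit_bounds(self):
        res = lin_ccc(pairs(*self._sample()))
        assert -1 < res.ci_low <= res.estimate <= res.ci_high < 1

    def test_higher_level_gives_wider_nested_interval(self):
        res = lin_ccc(pairs(*self._sample()))
        ci95 = ccc_confidence_interval(res, 0.95)
        ci90 = ccc_confidence_interval(res, 0.90)
        assert ci95.ci_low < ci90.ci_low < ci90.ci_high < ci95.ci_high

    def test_interval_collapses_for_large_n(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20_000)
        y = 0.9 * x + rng.normal(0, 0.45, size=20_000)
        res = lin_ccc(pairs(x, y))
        assert res.ci_high - res.ci_low < 0.02
        small = lin_ccc(pairs(x[:40], y[:40]))
        assert res.ci_high - res.ci_low < small.ci_high - small.ci_low

    def test_analytic_ci_close_to_bootstrap_percentiles(self):
        """Fisher-z analytic interval vs a 2,000-replicate percentile
        bootstrap on n=50 bivariate data (independent oracle)."""
        x, y = self._sample()
        res = lin_ccc(pairs(x, y))
        rng = np.random.default_rng(99)
        n = len(x)
        boots = np.empty(2000)
        for b in range(2000):
            idx = rng.integers(0, n, size=n)
            boots[b] = ccc_bruteforce(list(x[idx]), list(y[idx]))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo, abs=0.03)
        assert res.ci_high == pytest.approx(hi, abs=0.03)

    def test_degenerate_estimate_raises_with_guidance(self):
        res = lin_ccc(pairs([1, 2, 3], [1, 2, 3]))
        with pytest.raises(DegenerateCIError, match="bootstrap"):
            ccc_confidence_interval(res, 0.95)


class TestBlandAltman:
    def test_identical_readings(self):
        res = bland_altman(pairs([1, 2, 3, 4], [1, 2, 3, 4]))
        assert res.bias == 0 and res.loa_lower == 0 and res.loa_upper == 0

    def test_hand_computed_differences(self):
        # x=(1,3,5), y=(1,1,5) -> d=(0,2,0): bias 2/3, sample SD 2/sqrt(3)
        res = bland_altman(pairs([1, 3, 5], [1, 1, 5]))
        assert res.bias == pytest.approx(2 / 3)
        assert res.sd_diff == pytest.approx(2 / math.sqrt(3))

    def test_hand_computed_bias_one_sd_sqrt_two(self):
        # differences with mean 1 and sample SD sqrt(2):
        # LoA = 1 +/- 1.96*sqrt(2) = (-1.772, 3.772)
        res = bland_altman_from_summary(n=10, bias=1.0, sd_diff=math.sqrt(2))
        assert res.loa_lower == pytest.approx(1 - 1.96 * math.sqrt(2))
        assert res.loa_upper == pytest.approx(1 + 1.96 * math.sqrt(2))
        assert res.loa_upper == pytest.approx(3.7718, abs=5e-4)

    def test_loa_symmetry_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=15)
            y = x + rng.normal(0.2, 0.7, size=15)
            res = bland_altman(pairs(x, y))
            assert res.loa_lower == pytest.approx(2 * res.bias - res.loa_upper, abs=1e-12)
            assert res.loa_lower <= res.bias <= res.loa_upper

    def test_swapping_sides_negates_bias_and_mirrors_loa(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = x + rng.normal(0.5, 1.0, size=20)
        a, b = bland_altman(pairs(x, y)), bland_altman(pairs(y, x))
        assert a.bias == pytest.approx(-b.bias, abs=1e-12)
        assert a.loa_lower == pytest.approx(-b.loa_upper, abs=1e-12)
        assert a.loa_upper == pytest.approx(-b.loa_lower, abs=1e-12)

    def test_published_pilot_bias_interval_reconstruction(self):
        # n=41, bias 0.17, upper LoA 2.83 -> t-based CI upper bound 0.60
        res = bland_altman_from_summary(41, 0.17, (2.83 - 0.17) / 1.96)
        assert round(res.bias_ci_high, 2) == 0.60

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman_from_summary(2, 0.0, 1.0)


class TestConcordanceVerdict:
    def test_pilot_total_row_fails_on_loa_only(self):
        # published pilot inter-observer CIBDAI: CCC 0.88, bias 0.17,
        # LoA (-2.49, 2.83), total limits -> only the LoA criterion fails
        ba = bland_altman_from_summary(41, 0.17, (2.83 - 0.17) / 1.96)
        v = concordance_verdict(
            None, ba, AgreementCriteria(), is_total=True, ccc_estimate=0.88
        )
        assert not v.concordant
        assert v.failure_reasons == ("loa_exceeds",)

    def test_item_row_with_loa_just_outside_unit(self):
        # CCC 0.87, bias 0.05, LoA (-1.02, 1.12), item limits +/-1
        ba = bland_altman_from_summary(41, 0.05, (1.12 - 0.05) / 1.96)
        v = concordance_verdict(
            None, ba, AgreementCriteria(), is_total=False, ccc_estimate=0.87
        )
        assert not v.concordant and "loa_exceeds" in v.failure_reasons

    def test_ccc_threshold_is_strict(self):
        ba = bland_altman_from_summary(50, 0.0, 0.0)
        v = concordance_verdict(
            None, ba, AgreementCriteria(), is_total=False, ccc_estimate=0.81
        )
        assert not v.concordant and v.failure_reasons == ("ccc_below",)

    def test_perfect_agreement_is_concordant(self):
        ba = bland_altman_from_summary(50, 0.0, 0.0)
        v = concordance_verdict(
            None, ba, AgreementCriteria(), is_total=True, ccc_estimate=1.0
        )
        assert v.concordant and v.failure_reasons == ()

    def test_relaxed_presets(self):
        assert AgreementCriteria.preset("relaxed_1").loa_limit_item == 1.5
        assert AgreementCriteria.preset("relaxed_1").loa_limit_total == 2.5
        assert AgreementCriteria.preset("relaxed_2").loa_limit_item == 2.0
        assert AgreementCriteria.preset("relaxed_2").loa_limit_total == 3.0
        with pytest.raises(ValidationError):
            AgreementCriteria.preset("nope")

    def test_verdict_monotone_in_bias_and_loa_width(self):
        """Shrinking |bias| and narrowing LoA (CCC fixed) never flips a
        concordant verdict to non-concordant."""
        criteria = AgreementCriteria()
        for bias in np.linspace(1.4, 0, 8):
            prev = None
            for sd in np.linspace(1.2, 0, 8):
                ba = bland_altman_from_summary(40, bias, sd)
                v = concordance_verdict(
                    None, ba, criteria, is_total=True, ccc_estimate=0.95
                )
                if prev is not None and prev.concordant:
                    assert v.concordant
                prev = v

    def test_mismatched_n_rejected(self):
        x = np.arange(10.0)
        ccc = lin_ccc(pairs(x, x + np.linspace(0, 1, 10)))
        ba = bland_altman_from_summary(12, 0.0, 1.0)
        with pytest.raises(ValidationError, match="inconsistent n"):
            concordance_verdict(ccc, ba, AgreementCriteria())

    def test_loa_coverage_of_simulated_normal_differences(self):
        """95% LoA contain about 95% of simulated normal differences."""
        rng = np.random.default_rng(12)
        d = rng.normal(0.3, 1.7, size=100_000)
        res = bland_altman(pairs(d, np.zeros_like(d)))
        inside = np.mean((d >= res.loa_lower) & (d <= res.loa_upper))
        assert inside == pytest.approx(0.95, abs=0.005)
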