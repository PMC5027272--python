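"""Unit and property tests for the binomial mixture exclusion model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryomix.mixture import (
    MixtureQuery,
    NotExcludable,
    combined_probability,
    concordance_evidence,
    estimate_rate,
    min_excludable_n,
    rho_profile,
    term_origin_pmf,
    term_origin_tail,
    worst_case,
)


class TestRateEstimate:
    @pytest.mark.parametrize(
        "developed, transferred, shown",
        [(24, 232, 0.103), (107, 237, 0.451), (0, 100, 0.0)],
    )
    def test_printed_rates(self, developed, transferred, shown):
        est = estimate_rate(developed, transferred)
        assert est.rate == developed / transferred  # exact, no rounding
        assert est.display(3) == shown

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_rate(1, 0)
        with pytest.raises(ValueError):
            estimate_rate(5, 4)


class TestConcordanceEvidence:
    def test_closed_form_and_limits(self):
        assert concordance_evidence(0, 0.7) == 1.0
        assert concordance_evidence(20, 0.0) == 1.0
        assert concordance_evidence(20, 1.0) == 0.0
        assert concordance_evidence(20, 0.1) == pytest.approx(0.9**20, rel=1e-12)

    def test_large_k_stays_finite(self):
        assert concordance_evidence(10_000, 0.5) == pytest.approx(
            math.exp(10_000 * math.log(0.5)), rel=1e-9
        )

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError):
            concordance_evidence(3, 1.5)


class TestTermOriginDistribution:
    def test_rho_zero_means_no_phenotype2_offspring(self, base_query):
        for n in range(1, base_query.T + 1):
            assert term_origin_pmf(base_query, 0.0, n) == 0.0
        assert term_origin_tail(replace(base_query, n=1), 0.0) == 0.0

    def test_pmf_normalizes(self, base_query):
        total = sum(
            term_origin_pmf(base_query, 0.3, n) for n in range(base_query.T + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_rho_one_puts_all_mass_at_T(self, base_query):
        assert term_origin_pmf(base_query, 1.0, base_query.T) == pytest.approx(1.0)

    def test_tail_consistent_with_pmf(self, base_query):
        rho = 0.17
        for n0 in (0, 1, 5, 12, 24):
            q = replace(base_query, n=n0)
            direct = sum(term_origin_pmf(q, rho, n) for n in range(n0, q.T + 1))
            assert term_origin_tail(q, rho) == pytest.approx(direct, abs=1e-12)

    def test_tail_from_zero_is_one(self, base_query):
        assert term_origin_tail(replace(base_query, n=0), 0.2) == pytest.approx(1.0)

    def test_conditional_binomial_closed_form(self, base_query):
        """The marginalization over m collapses to Binomial(T, r(rho)).

        Conditional on T term offspring, each derives from phenotype-II
        independently with probability rho*q2 / (rho*q2 + (1-rho)*q1) — an
        independent closed form the m-sum must reproduce.
        """
        from scipy.stats import binom

        q1, q2 = base_query.q1.rate, base_query.q2.rate
        for rho in (0.02, 0.1, 0.45, 0.9):
            r = rho * q2 / (rho * q2 + (1 - rho) * q1)
            expected = binom.pmf(np.arange(25), 24, r)
            got = [term_origin_pmf(base_query, rho, n) for n in range(25)]
            np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-300)

    def test_invalid_inputs(self, base_query):
        with pytest.raises(ValueError):
            term_origin_pmf(base_query, -0.1, 3)
        with pytest.raises(ValueError):
            term_origin_pmf(base_query, 0.5, base_query.T + 1)


class TestCombinedProbability:
    def test_no_evidence_equals_tail(self, base_query):
        q = replace(base_query, k_list=())
        assert combined_probability(q, 0.3) == pytest.approx(
            term_origin_tail(q, 0.3), rel=1e-12
        )

    def test_rho_one_with_evidence_is_zero(self, base_query):
        assert combined_probability(base_query, 1.0) == 0.0

    def test_multiple_evidences_multiply(self, base_query):
        q = replace(base_query, k_list=(9, 20))
        expected = term_origin_tail(q, 0.1) * 0.9**29
        assert combined_probability(q, 0.1) == pytest.approx(expected, rel=1e-10)

    def test_no_evidence_n_zero_is_one_everywhere(self, base_query):
        q = replace(base_query, k_list=(), n=0)
        for rho in (0.0, 0.25, 0.8, 1.0):
            assert combined_probability(q, rho) == pytest.approx(1.0)


class TestWorstCase:
    def test_profile_endpoints_vanish(self, base_query):
        prof = rho_profile(base_query, grid_size=101)
        assert prof.p_values[0] == 0.0  # no phenotype-II at rho = 0
        assert prof.p_values[-1] == 0.0  # evidence factor kills rho = 1

    def test_profile_max_matches_worst_case(self, base_query):
        prof = rho_profile(base_query, grid_size=2001)
        res = worst_case(base_query)
        assert res.p_max >= prof.p_values.max()
        assert res.p_max == pytest.approx(prof.p_values.max(), rel=1e-4)

    def test_profile_dominance_in_n(self, base_query):
        p9 = rho_profile(replace(base_query, n=9), grid_size=201).p_values
        p10 = rho_profile(replace(base_query, n=10), grid_size=201).p_values
        assert np.all(p9 >= p10)

    def test_exclusion_verdict_tracks_alpha(self, base_query):
        res = worst_case(base_query)
        assert res.excluded == (res.p_max <= base_query.alpha)
        looser = worst_case(replace(base_query, alpha=0.2))
        assert looser.excluded

    def test_strategy_recorded(self, base_query):
        assert worst_case(base_query).strategy == "total-conditioned"
        lit = worst_case(replace(base_query, strategy="literal-prose"))
        assert lit.strategy == "literal-prose"

    def test_grid_size_validation(self, base_query):
        with pytest.raises(ValueError):
            rho_profile(base_query, grid_size=1)

    def test_worst_case_monotone_in_n_and_k(self, base_query):
        p = [worst_case(replace(base_query, n=n)).p_max for n in (5, 9, 14, 20)]
        assert all(a >= b for a, b in zip(p, p[1:]))
        pk = [
            worst_case(replace(base_query, k_list=(k,))).p_max for k in (5, 9, 20, 40)
        ]
        assert all(a >= b for a, b in zip(pk, pk[1:]))

    def test_deep_tail_without_underflow(self, base_query):
        """Bounds at the 1e-17 scale stay finite and positive in log space."""
        res = worst_case(replace(base_query, n=24, k_list=(9, 20)))
        assert 0.0 < res.p_max < 1e-8

    def test_scales_to_large_cohorts(self, cohort_rates):
        q1, q2 = cohort_rates
        q = MixtureQuery(N=10_000, T=24, q1=q1, q2=q2, k_list=(20,), n=9)
        res = worst_case(q, grid_size=201)
        assert 0.0 < res.p_max < 1.0


class TestMinExcludableN:
    @pytest.mark.parametrize("k_list, expected", [((20,), 9), ((9,), 14), ((9, 20), 7)])
    def test_printed_thresholds(self, cohort_rates, k_list, expected):
        q1, q2 = cohort_rates
        q = MixtureQuery(N=232, T=24, q1=q1, q2=q2, k_list=k_list, n=0)
        assert min_excludable_n(q) == expected

    def test_monotone_in_alpha(self, cohort_rates):
        q1, q2 = cohort_rates
        thresholds = [
            min_excludable_n(
                MixtureQuery(232, 24, q1, q2, (20,), 0, alpha=a), grid_size=401
            )
            for a in (0.01, 0.05, 0.2)
        ]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_not_excludable_signalled(self, cohort_rates):
        q1, q2 = cohort_rates
        # overwhelming evidence floor: alpha far below any attainable bound
        q = MixtureQuery(232, 24, q1, q2, (), 0, alpha=0.05)
        with pytest.raises(NotExcludable):
            min_excludable_n(q, grid_size=201)


class TestQueryValidation:
    def test_rejects_bad_orderings(self, cohort_rates):
        q1, q2 = cohort_rates
        with pytest.raises(ValueError):
            MixtureQuery(232, 300, q1, q2)
        with pytest.raises(ValueError):
            MixtureQuery(232, 24, q1, q2, n=30)
        with pytest.raises(ValueError):
            MixtureQuery(232, 24, q1, q2, k_list=(0,))
        with pytest.raises(ValueError):
            MixtureQuery(232, 24, q1, q2, alpha=1.5)
        with pytest.raises(ValueError):
            MixtureQuery(232, 24, q1, q2, strategy="bogus")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    rho=st.floats(0.0, 1.0),
    n=st.integers(0, 24),
    k=st.integers(1, 40),
)
def test_combined_probability_is_a_probability(rho, n, k):
    q = MixtureQuery(232, 24, estimate_rate(24, 232), estimate_rate(107, 237),
                     k_list=(k,), n=n)
    p = combined_probability(q, rho)
    assert 0.0 <= p <= 1.0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(rho=st.floats(0.01, 0.99), n=st.integers(1, 23))
def test_tail_non_increasing_in_n(rho, n):
    q1, q2 = estimate_rate(24, 232), estimate_rate(107, 237)
    lo = MixtureQuery(232, 24, q1, q2, n=n)
    hi = MixtureQuery(232, 24, q1, q2, n=n + 1)
    assert term_origin_tail(lo, rho) >= term_origin_tail(hi, rho)
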