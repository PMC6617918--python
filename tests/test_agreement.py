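"""Agreement statistics: Bland-Altman, Wilcoxon signed-rank, summaries, Likert."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hs

from oculogas import (
    DomainError,
    InsufficientDataError,
    PairedJudgments,
    bland_altman,
    summarize,
    tabulate_likert,
    wilcoxon_signed_rank,
)


class TestPairedJudgments:
    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            PairedJudgments([1, 2, 3], [1, 2])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            PairedJudgments([50], [50])

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(DomainError):
            PairedJudgments([50, 110], [50, 50])


class TestBlandAltman:
    def test_fundus_photograph_pairs(self, fundus_pairs):
        """Hand oracle on the four photograph pairs: differences
        (surgeon - patient) are (-1, +1, 0, +2), so bias = +0.5 and
        sd = sqrt(5/3) ~ 1.291."""
        report = bland_altman(fundus_pairs)
        assert report.bias == pytest.approx(0.5, abs=1e-12)
        assert report.sd_diff == pytest.approx(np.sqrt(5.0 / 3.0), abs=1e-12)
        assert report.loa_low == pytest.approx(0.5 - 1.96 * np.sqrt(5 / 3), abs=1e-9)
        assert report.loa_high == pytest.approx(0.5 + 1.96 * np.sqrt(5 / 3), abs=1e-9)
        assert report.n == 4

    def test_identical_series_degenerate(self):
        report = bland_altman(PairedJudgments([40, 50, 60], [40, 50, 60]))
        assert report.bias == 0.0
        assert report.sd_diff == 0.0
        assert (report.loa_low, report.loa_high) == (0.0, 0.0)

    def test_matches_independent_computation_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = rng.uniform(5, 95, size=40)
            p = np.clip(s + rng.normal(0, 3, size=40), 0, 100)
            report = bland_altman(PairedJudgments(s, p))
            d = s - p
            assert report.bias == pytest.approx(d.mean(), abs=1e-12)
            assert report.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-12)
            assert report.loa_high - report.bias == pytest.approx(
                report.bias - report.loa_low, abs=1e-9
            )

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(20, 80, size=30)
        p = rng.uniform(20, 80, size=30)
        base = bland_altman(PairedJudgments(s, p))
        shifted = bland_altman(PairedJudgments(s, p + 5.0))
        assert shifted.bias == pytest.approx(base.bias - 5.0, abs=1e-9)
        assert shifted.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)

    def test_custom_multiplier(self, fundus_pairs):
        report = bland_altman(fundus_pairs, multiplier=2.0)
        assert report.loa_high == pytest.approx(0.5 + 2.0 * report.sd_diff)


class TestWilcoxon:
    def test_identical_series_degenerate(self):
        r = wilcoxon_signed_rank(PairedJudgments([40, 50], [40, 50]))
        assert r.degenerate
        assert r.p_value == 1.0

    def test_all_positive_n6_exact(self):
        """All six differences positive: two-sided exact p = 2/2^6."""
        r = wilcoxon_signed_rank(
            PairedJudgments([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
        )
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 / 64)

    def test_role_swap_symmetry(self):
        a = wilcoxon_signed_rank(PairedJudgments([1, 3, 6], [2, 5, 9]))
        b = wilcoxon_signed_rank(PairedJudgments([2, 5, 9], [1, 3, 6]))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(10, 90, size=12)
        p = np.clip(s + rng.normal(0, 4, size=12), 0, 100)
        pairs = PairedJudgments(s, p)
        d = pairs.differences()  # continuous draws: no ties or zeros a.s.
        ours = wilcoxon_signed_rank(pairs, method="exact")
        ref = st.wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_approx_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = rng.uniform(10, 90, size=40)
        p = np.clip(s + rng.normal(1, 5, size=40), 0, 100)
        pairs = PairedJudgments(s, p)
        ours = wilcoxon_signed_rank(pairs, method="approx")
        ref = st.wilcoxon(pairs.differences(), method="approx", correction=True)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_vs_approx_close_at_n15(self):
        rng = np.random.default_rng(77)
        s = rng.uniform(10, 90, size=15)
        p = np.clip(s + rng.normal(0.5, 4, size=15), 0, 100)
        pairs = PairedJudgments(s, p)
        exact = wilcoxon_signed_rank(pairs, method="exact")
        approx = wilcoxon_signed_rank(pairs, method="approx")
        assert abs(exact.p_value - approx.p_value) < 0.02

    def test_handles_ties_and_zeros(self):
        pairs = PairedJudgments([50, 52, 54, 56, 58], [50, 50, 52, 58, 56])
        r = wilcoxon_signed_rank(pairs)
        assert r.n_nonzero == 4  # one zero difference dropped
        assert 0.0 <= r.p_value <= 1.0

    @settings(deadline=None, max_examples=50)
    @given(hs.integers(min_value=0, max_value=2**31 - 1))
    def test_p_value_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        s = rng.uniform(0, 100, size=n)
        p = np.clip(s + rng.normal(0, 5, size=n), 0, 100)
        r = wilcoxon_signed_rank(PairedJudgments(s, p))
        assert 0.0 <= r.p_value <= 1.0


class TestSummarize:
    def test_photograph_heights(self):
        assert summarize([75, 45, 35, 20]) == {"median": 40.0, "min": 20.0, "max": 75.0}

    @pytest.mark.parametrize(
        "values, median", [([5], 5.0), ([1, 2, 3], 2.0), ([1, 2, 3, 10], 2.5)]
    )
    def test_median_conventions(self, values, median):
        assert summarize(values)["median"] == median

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize([])


class TestLikert:
    def test_counts_and_proportions(self):
        t = tabulate_likert([5, 5, 4])
        assert t.counts == {1: 0, 2: 0, 3: 0, 4: 1, 5: 2}
        assert t.proportions[4] == pytest.approx(1 / 3)
        assert t.proportions[5] == pytest.approx(2 / 3)
        assert sum(t.counts.values()) == t.n == 3

    def test_empty_gives_zero_counts(self):
        t = tabulate_likert([])
        assert all(c == 0 for c in t.counts.values())

    def test_seeded_draws_match_brute_force_recount(self):
        rng = np.random.default_rng(3)
        draws = rng.choice([1, 2, 3, 4, 5], size=50, p=[0.05, 0.05, 0.1, 0.4, 0.4])
        t = tabulate_likert(draws)
        for level in range(1, 6):
            assert t.counts[level] == int(np.sum(draws == level))
        assert sum(t.proportions.values()) == pytest.approx(1.0)

    def test_out_of_range_reports_index(self):
        with pytest.raises(DomainError, match="index 2"):
            tabulate_likert([4, 5, 6])
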