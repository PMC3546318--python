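"""The k-of-n exceedance statistic and its binomial null."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen import value_counting as vc
from poolscreen.io import AnnotationMap


def enumeration_tail(k: int, n: int, p: float) -> float:
    """Brute-force P(X >= k): sum over all 2^n replicate outcome vectors."""
    total = 0.0
    for bits in product((0, 1), repeat=n):
        successes = sum(bits)
        if successes >= k:
            total += p**successes * (1 - p) ** (n - successes)
    return total


def matrix(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"S{i}" for i in range(values.shape[0])]
    return pd.DataFrame(
        values, index=pd.Index(ids, name="id"),
        columns=[f"rep_{j + 1}" for j in range(values.shape[1])],
    )


class TestThresholds:
    def test_closed_form_column(self):
        ratios = matrix(np.array([[-1.0], [0.0], [1.0]]))
        thr = vc.replicate_thresholds(ratios)
        assert thr.mean[0] == pytest.approx(0.0)
        assert thr.sd[0] == pytest.approx(1.0)  # sample SD
        assert thr.upper[0] == pytest.approx(1.0)
        assert thr.lower[0] == pytest.approx(-1.0)

    def test_constant_column_warns_and_collapses_to_mean(self):
        ratios = matrix(np.full((5, 1), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            thr = vc.replicate_thresholds(ratios)
        assert thr.upper[0] == thr.lower[0] == pytest.approx(3.0)

    def test_standard_normal_fraction_above_upper(self):
        """Monte-Carlo check against Phi(-1) ~ 0.159."""
        rng = np.random.default_rng(42)
        ratios = matrix(rng.standard_normal((100_000, 1)))
        thr = vc.replicate_thresholds(ratios)
        p_over, p_under = vc.exceedance_rates(ratios, thr)
        assert p_over == pytest.approx(0.1587, abs=0.004)
        assert p_under == pytest.approx(0.1587, abs=0.004)


class TestExceedances:
    def test_all_above_in_six_replicates(self):
        base = matrix(np.vstack([np.zeros((10, 6)), np.full((1, 6), 50.0)]))
        thr = vc.replicate_thresholds(base)
        counts = vc.count_exceedances(base, thr)
        assert counts.iloc[-1]["k_over"] == 6
        assert counts.iloc[-1]["k_under"] == 0

    def test_value_exactly_at_threshold_does_not_count(self):
        ratios = matrix(np.array([[-1.0], [0.0], [1.0]]))  # upper = 1.0 exactly
        thr = vc.replicate_thresholds(ratios)
        counts = vc.count_exceedances(ratios, thr)
        assert counts.loc["S2", "k_over"] == 0

    def test_mixed_row(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (50, 6)) * 0.01
        vals[0] = [5, 5, 5, 5, 5, -5]
        ratios = matrix(vals)
        thr = vc.replicate_thresholds(ratios)
        counts = vc.count_exceedances(ratios, thr)
        assert counts.iloc[0]["k_over"] == 5
        assert counts.iloc[0]["k_under"] == 1

    def test_dimension_mismatch_is_error(self):
        a = matrix(np.zeros((5, 6)) + np.arange(5)[:, None])
        thr = vc.replicate_thresholds(a)
        with pytest.raises(ValueError, match="replicate count"):
            vc.count_exceedances(a.iloc[:, :3], thr)


class TestBinomialTail:
    def test_k_zero_is_total_probability(self):
        assert vc.binomial_tail(0, 6, 0.37) == 1.0

    def test_six_of_six_fair_coin(self):
        assert vc.binomial_tail(6, 6, 0.5) == pytest.approx(1 / 64)

    @pytest.mark.parametrize("k,n,p", [(5, 6, 0.13), (4, 6, 0.14), (3, 8, 0.25)])
    def test_matches_exhaustive_enumeration(self, k, n, p):
        assert vc.binomial_tail(k, n, p) == pytest.approx(
            enumeration_tail(k, n, p), abs=1e-12
        )

    @pytest.mark.parametrize("k,n,p", [(7, 6, 0.5), (-1, 6, 0.5), (3, 6, 1.5)])
    def test_invalid_inputs_raise(self, k, n, p):
        with pytest.raises(ValueError):
            vc.binomial_tail(k, n, p)

    @given(n=st.integers(1, 12), p=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_nonincreasing_in_k(self, n, p):
        tails = [vc.binomial_tail(k, n, p) for k in range(n + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    @given(k=st.integers(0, 6), ps=st.tuples(st.floats(0, 1), st.floats(0, 1)))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_nondecreasing_in_p(self, k, ps):
        lo, hi = sorted(ps)
        assert vc.binomial_tail(k, 6, lo) <= vc.binomial_tail(k, 6, hi) + 1e-15


class TestRates:
    def test_constructed_thirteen_percent(self):
        """87 values at 0 and 13 at a high value: exactly 13% exceed mean+SD."""
        vals = np.concatenate([np.zeros(87), np.full(13, 10.0)])[:, None]
        ratios = matrix(vals)
        thr = vc.replicate_thresholds(ratios)
        p_over, _ = vc.exceedance_rates(ratios, thr)
        assert p_over == pytest.approx(0.13)

    def test_constant_matrix_has_zero_rates(self):
        ratios = matrix(np.ones((10, 6)))
        with pytest.warns(UserWarning):
            thr = vc.replicate_thresholds(ratios)
        assert vc.exceedance_rates(ratios, thr) == (0.0, 0.0)


class TestCandidates:
    def _counts(self):
        return pd.DataFrame(
            {"k_over": [5, 6, 2], "k_under": [0, 0, 5], "n": 6},
            index=pd.Index(["S1", "S2", "S3"], name="id"),
        )

    def test_membership_at_criterion(self):
        cs = vc.call_candidates(self._counts(), 5, "over")
        assert set(cs.shrnas) == {"S1", "S2"}
        assert cs.criterion == "5of6"

    def test_five_hits_misses_six_of_six(self):
        cs = vc.call_candidates(self._counts(), 6, "over")
        assert set(cs.shrnas) == {"S2"}

    def test_gene_multiplicity_counts_distinct_shrnas(self):
        ann = AnnotationMap(
            {"P1": {"S1"}, "P2": {"S2"}}, {"S1": "G1", "S2": "G1", "S3": "G2"}
        )
        cs = vc.call_candidates(self._counts(), 5, "over", ann)
        assert cs.gene_multiplicity == {"G1": 2}

    def test_criteria_are_nested(self, default_screen):
        from poolscreen import preprocess as pre

        table, ann, _ = default_screen
        ratios, _ = pre.preprocess_screen(table, ann)
        thr = vc.replicate_thresholds(ratios)
        counts = vc.count_exceedances(ratios, thr)
        for direction in ("over", "under"):
            sets = [
                set(vc.call_candidates(counts, k, direction).shrnas) for k in (4, 5, 6)
            ]
            assert sets[2] <= sets[1] <= sets[0]


class TestFdrTable:
    def test_arithmetic(self):
        cs = vc.CandidateSet("over", 5, 6, [f"S{i}" for i in range(10)])
        # choose p so the tail gives expected = 1.0 for N=1000
        # p solved implicitly: use the computed tail instead of a magic p
        table = vc.fdr_table([cs], p_over=0.1, p_under=0.1, n_tested=1000)
        row = table.iloc[0]
        assert row["expected"] == pytest.approx(1000 * vc.binomial_tail(5, 6, 0.1))
        assert row["fdr"] == pytest.approx(row["expected"] / 10)

    def test_found_equals_expected_gives_fdr_one(self):
        p = 0.2
        tail = vc.binomial_tail(4, 6, p)
        n_tested = 500
        found = int(round(n_tested * tail))
        cs = vc.CandidateSet("under", 4, 6, [f"S{i}" for i in range(found)])
        table = vc.fdr_table([cs], p, p, n_tested)
        assert table.iloc[0]["fdr"] == pytest.approx(
            n_tested * tail / found, rel=1e-12
        )

    def test_found_zero_reports_nan(self):
        cs = vc.CandidateSet("over", 6, 6, [])
        table = vc.fdr_table([cs], 0.1, 0.1, 100)
        assert np.isnan(table.iloc[0]["fdr"])

    def test_nonpositive_n_is_error(self):
        with pytest.raises(ValueError):
            vc.fdr_table([], 0.1, 0.1, 0)
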