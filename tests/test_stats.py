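"""Brunner–Munzel test: oracle exactness, symmetries, comparisons table."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from samquant import SamQuantError, brunner_munzel, pairwise_timepoints, type1_power_sim


def pair_counting_p_hat(x, y):
    """Independent oracle: (#{x<y} + 1/2 #{x=y}) / (n1 n2)."""
    wins = sum(1.0 for xi in x for yi in y if xi < yi)
    ties = sum(1.0 for xi in x for yi in y if xi == yi)
    return (wins + 0.5 * ties) / (len(x) * len(y))


class TestPHat:
    def test_worked_example(self):
        assert brunner_munzel([1, 2, 4], [3, 5]).p_hat == pytest.approx(5 / 6)

    def test_identical_samples_are_symmetric(self):
        res = brunner_munzel([1, 2, 3], [1, 2, 3])
        assert res.p_hat == 0.5
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_p_hat_equals_pair_counting_oracle_exhaustive(self, rng):
        """Exact agreement with the pair-counting oracle on >= 1000 random
        small integer samples (heavy ties included)."""
        for _ in range(1000):
            n1, n2 = rng.integers(2, 7, 2)
            x = rng.integers(0, 5, n1)
            y = rng.integers(0, 5, n2)
            res = brunner_munzel(x, y)
            assert res.p_hat == pytest.approx(pair_counting_p_hat(x, y), abs=1e-12)

    @given(
        x=st.lists(st.integers(0, 8), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 8), min_size=2, max_size=6),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_swap_antisymmetry(self, x, y):
        """Swapping samples maps p_hat -> 1 - p_hat, negates the statistic
        and preserves the p-value."""
        a = brunner_munzel(x, y)
        b = brunner_munzel(y, x)
        assert a.p_hat == pytest.approx(1 - b.p_hat, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        if not a.degenerate:
            assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)

    @given(
        y=st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=6),
        c=st.floats(0.0, 3.0, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_shift_never_decreases_p_hat(self, y, c):
        x = [-1.0, 0.0, 0.5, 1.0]
        before = brunner_munzel(x, y).p_hat
        after = brunner_munzel(x, [v + c for v in y]).p_hat
        assert after >= before - 1e-12

    def test_tie_scaling_invariance(self, rng):
        """Duplicating every observation leaves p_hat unchanged (midranks)."""
        for _ in range(50):
            x = rng.integers(0, 4, 4)
            y = rng.integers(0, 4, 4)
            a = brunner_munzel(x, y).p_hat
            b = brunner_munzel(np.repeat(x, 2), np.repeat(y, 2)).p_hat
            assert a == pytest.approx(b, abs=1e-12)


class TestDegenerateFallback:
    def test_complete_separation_exact_permutation(self):
        """Fully separated samples: p_hat = 1 and the exact permutation
        p-value is 2 / C(6,3) = 0.1."""
        res = brunner_munzel([1, 2, 3], [10, 11, 12])
        assert res.degenerate
        assert res.method == "exact-permutation"
        assert res.p_hat == 1.0
        assert res.p_value == pytest.approx(2 / math.comb(6, 3))

    def test_exact_p_matches_full_enumeration_oracle(self):
        """Exact permutation p-value equals brute-force enumeration of all
        group assignments of the pooled sample."""
        x, y = [1.0, 2.0], [5.0, 6.0, 7.0]
        res = brunner_munzel(x, y)
        pooled = np.array(x + y)
        obs = abs(pair_counting_p_hat(x, y) - 0.5)
        count = total = 0
        for g1 in itertools.combinations(range(5), 2):
            g2 = [i for i in range(5) if i not in g1]
            ph = pair_counting_p_hat(pooled[list(g1)], pooled[g2])
            count += abs(ph - 0.5) >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total)

    def test_all_ties_is_degenerate_with_p_one(self):
        res = brunner_munzel([2, 2, 2], [2, 2, 2])
        assert res.degenerate and res.p_hat == 0.5 and res.p_value == 1.0

    def test_matches_scipy_on_nondegenerate_samples(self, rng):
        """Statistic and p-value agree with the reference implementation
        in scipy on random continuous samples."""
        from scipy.stats import brunnermunzel as scipy_bm

        for _ in range(200):
            x = rng.normal(size=rng.integers(4, 12))
            y = rng.normal(loc=0.3, size=rng.integers(4, 12))
            mine = brunner_munzel(x, y)
            ref = scipy_bm(x, y)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_small_samples_rejected(self):
        with pytest.raises(SamQuantError, match="at least 2"):
            brunner_munzel([1.0], [2.0, 3.0])


class TestPairwiseTimepoints:
    def summaries(self, medians_by_tp, channel="FT", region="RM"):
        rows = []
        for tp, meds in medians_by_tp.items():
            for i, m in enumerate(meds):
                rows.append(
                    {
                        "meristem_id": f"{tp}_m{i}",
                        "time_point": tp,
                        "channel": channel,
                        "region": region,
                        "n_nuclei": 10,
                        "median": m,
                        "q1": m,
                        "q3": m,
                    }
                )
        return pd.DataFrame(rows)

    def test_three_comparisons_per_channel_region(self):
        summ = self.summaries(
            {
                "10LD": [0.2, 0.3, 0.25],
                "11LD": [0.3, 0.4, 0.35, 0.3],
                "12LD": [0.5, 0.6, 0.55, 0.5],
                "13LD": [0.7, 0.8, 0.75, 0.7],
            }
        )
        table = pairwise_timepoints(summ, baseline="10LD", alpha=0.1)
        assert len(table) == 3
        assert table["comparison"].tolist() == ["11LD", "12LD", "13LD"]
        assert (table["n1"] == 3).all() and (table["n2"] == 4).all()

    def test_strong_separation_all_significant(self):
        summ = self.summaries(
            {
                "10LD": [0.1, 0.12, 0.11],
                "11LD": [0.5, 0.52, 0.51, 0.53],
                "12LD": [0.6, 0.62, 0.61, 0.63],
                "13LD": [0.7, 0.72, 0.71, 0.73],
            }
        )
        table = pairwise_timepoints(summ, baseline="10LD", alpha=0.1)
        assert table["significant"].all()

    def test_small_group_skipped_with_reason(self):
        summ = self.summaries({"10LD": [0.2], "11LD": [0.3, 0.4, 0.35]})
        table = pairwise_timepoints(summ, baseline="10LD")
        assert len(table) == 1
        assert table.iloc[0]["method"] == "skipped"
        assert "fewer than 2" in table.iloc[0]["reason"]
        assert not table.iloc[0]["significant"]

    def test_missing_baseline_rejected(self):
        summ = self.summaries({"11LD": [0.1, 0.2]})
        with pytest.raises(SamQuantError, match="baseline"):
            pairwise_timepoints(summ, baseline="10LD")

    def test_invalid_alpha_rejected(self):
        summ = self.summaries({"10LD": [0.1, 0.2], "11LD": [0.1, 0.2]})
        with pytest.raises(SamQuantError, match="alpha"):
            pairwise_timepoints(summ, baseline="10LD", alpha=1.5)


class TestSimulationHarness:
    def test_alpha_zero_never_rejects(self):
        res = type1_power_sim(8, 8, 0.0, 200, alpha=1e-12, seed=3)
        assert res.rate == 0.0

    def test_huge_effect_always_rejects(self):
        res = type1_power_sim(5, 5, 50.0, 200, alpha=0.1, seed=3)
        assert res.rate == 1.0

    def test_deterministic_under_seed(self):
        a = type1_power_sim(10, 10, 0.0, 200, 0.1, seed=7)
        b = type1_power_sim(10, 10, 0.0, 200, 0.1, seed=7)
        assert a == b

    def test_too_few_reps_rejected(self):
        with pytest.raises(SamQuantError, match="n_reps"):
            type1_power_sim(10, 10, 0.0, 50, 0.1, seed=0)
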