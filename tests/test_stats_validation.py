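import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from raresig import SampleMeta, bh_fdr, compare_groups, mann_whitney, pearson_validation
from raresig.stats_validation import validate_signatures


def meta_from(counts, groups=None, samples=None):
    samples = samples or [f"s{i}" for i in range(len(counts))]
    table = pd.DataFrame(
        {"cell_count": counts, "group": groups if groups is not None else np.nan},
        index=pd.Index(samples, name="sample"),
    )
    return SampleMeta(table=table)


def scores_from(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=samples, dtype=float)


class TestPearson:
    def test_identity_gives_r_one(self):
        res = pearson_validation(scores_from([1, 2, 3, 4]), meta_from([1, 2, 3, 4]))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_gives_r_minus_one(self):
        res = pearson_validation(scores_from([1, 2, 3, 4]), meta_from([4, 3, 2, 1]))
        assert res.pearson_r == pytest.approx(-1.0)

    def test_closed_form_hand_evaluation(self):
        # x=(1,2,3,4), y=(1,3,2,5): r = cov / (sx sy) evaluated by hand
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        xd, yd = x - x.mean(), y - y.mean()
        hand_r = (xd @ yd) / math.sqrt((xd @ xd) * (yd @ yd))
        res = pearson_validation(scores_from(x), meta_from(y))
        assert abs(res.pearson_r - hand_r) < 1e-12
        ref = sps.pearsonr(x, y)  # independent cross-check
        assert res.pearson_r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = rng.uniform(1, 10, size=12)  # cell counts are non-negative
        base = pearson_validation(scores_from(x), meta_from(y))
        scaled = pearson_validation(scores_from(3.5 * x + 2), meta_from(0.25 * y + 7))
        assert scaled.pearson_r == pytest.approx(base.pearson_r, abs=1e-12)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_samples_without_counts_are_dropped(self):
        res = pearson_validation(
            scores_from([1, 2, 3, 4]), meta_from([1.0, 2.0, 3.0, np.nan])
        )
        assert res.n == 3
        assert res.n_dropped == 1

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_validation(scores_from([1, 2]), meta_from([1, 2]))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_validation(scores_from([1, 1, 1]), meta_from([1, 2, 3]))


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        # ordered: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_upper_clip_at_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_returned_in_input_order(self):
        q = bh_fdr([0.9, 0.001, 0.04])
        assert q[1] < q[2] < q[0]

    def test_out_of_range_p_is_an_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=20))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_flat_adjusted_vector_is_a_fixed_point(self):
        # a constant q-vector (as in the 0.01/0.02/0.03 example) is a fixed
        # point of the step-up; re-adjusting does not move it
        q = bh_fdr([0.01, 0.02, 0.03])
        np.testing.assert_allclose(bh_fdr(q), q)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(pvals), expected, atol=1e-12)


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "normal"  # ties force the approximation

    def test_fully_separated_small_groups_exact(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_group_descriptives(self):
        res = mann_whitney([1.0, 2.0, 6.0], [10.0, 20.0])
        assert res.group_a.n == 3
        assert res.group_a.median == 2.0
        assert res.group_a.mad == 1.0
        assert res.group_b.sd == pytest.approx(np.std([10, 20], ddof=1))

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    def test_exact_mode_with_ties_falls_back_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="raresig.stats_validation"):
            res = mann_whitney([1, 1, 2], [2, 3, 4], mode="exact")
        assert res.method == "normal"
        assert any("ties" in rec.message for rec in caplog.records)

    def test_label_exchange_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=9), rng.normal(size=14)
        assert mann_whitney(a, b).p_value == pytest.approx(mann_whitney(b, a).p_value)
        assert mann_whitney(a, b).u_statistic == mann_whitney(b, a).u_statistic

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=5)
        base = mann_whitney(a, b)
        warped = mann_whitney(np.exp(a), np.exp(b))  # strictly monotone map
        assert warped.p_value == pytest.approx(base.p_value)
        assert warped.u_statistic == base.u_statistic

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (4, 6)])
    def test_exact_matches_permutation_enumeration(self, n1, n2):
        """Exact p equals brute-force enumeration over every rank split."""
        n = n1 + n2
        for split in combinations(range(n), n1):
            values = np.arange(1.0, n + 1)
            a = values[list(split)]
            b = np.delete(values, list(split))
            res = mann_whitney(a, b)
            assert res.method == "exact"
            # brute force: two-sided tail of U over all C(n, n1) splits
            mu = n1 * n2 / 2
            u_obs = sum(x > y for x in a for y in b)
            hits = 0
            total = 0
            for other in combinations(range(n), n1):
                aa = values[list(other)]
                bb = np.delete(values, list(other))
                u = sum(x > y for x in aa for y in bb)
                total += 1
                hits += abs(u - mu) >= abs(u_obs - mu)
            assert res.p_value == pytest.approx(hits / total)

    def test_normal_approximation_tracks_scipy_on_large_tied_data(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 8, size=30).astype(float)
        b = rng.integers(1, 9, size=40).astype(float)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "normal"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestFamilyValidation:
    def test_q_values_bh_adjusted_across_family(self):
        rng = np.random.default_rng(4)
        counts = rng.uniform(1, 20, size=12)
        meta = meta_from(counts)
        tables = {
            "strong": scores_from(counts + rng.normal(scale=0.5, size=12)),
            "noise": scores_from(rng.normal(size=12)),
        }
        out = validate_signatures(tables, meta)
        ps = [out["strong"].p_value, out["noise"].p_value]
        qs = bh_fdr(ps)
        assert out["strong"].q_value == pytest.approx(qs[0])
        assert out["noise"].q_value == pytest.approx(qs[1])

    def test_group_comparison_via_metadata(self):
        scores = scores_from([1, 2, 3, 10, 11, 12])
        meta = meta_from(
            [np.nan] * 6, groups=["a", "a", "a", "b", "b", "b"]
        )
        (la, lb), comp = compare_groups(scores, meta)
        assert (la, lb) == ("a", "b")
        assert comp.method == "exact"
        assert comp.p_value == pytest.approx(2 / 20)


def test_group_shift_detection_power():
    """A 0.7-unit median shift between groups of 25 and 44 samples, with the
    group spreads the validation cohort shows (sd 0.78 and 1.13), is detected
    by the Mann-Whitney test at alpha=0.05 with power >= 0.8."""
    rng = np.random.default_rng(20)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        untreated = rng.normal(loc=5.12, scale=0.78, size=25)
        treated = rng.normal(loc=5.12 - 0.7, scale=1.13, size=44)
        if mann_whitney(treated, untreated).p_value < 0.05:
            rejections += 1
    assert rejections / reps >= 0.8
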