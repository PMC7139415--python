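import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import growth_index_naive, pearson_naive
from gfscan.design import enumerate_conditions
from gfscan.screen import (
    build_index_matrix,
    cell_growth_index,
    group_growth_comparison,
    qc_filter,
    replicate_concordance,
)


def small_catalog():
    from gfscan.design import GrowthFactor

    return enumerate_conditions(
        [
            GrowthFactor("EGF", is_basal=True),
            GrowthFactor("bFGF", is_basal=True),
            GrowthFactor("A"),
            GrowthFactor("B"),
        ]
    )


def make_readouts(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition_id", "replicate", "role", "lum"])


class TestCellGrowthIndex:
    @pytest.mark.parametrize(
        "d0,d6,n6,expected",
        [(1000, 5000, 1000, 4.0), (500, 800, 800, 0.0), (2000, 1500, 2500, -0.5)],
    )
    def test_formula(self, d0, d6, n6, expected):
        assert cell_growth_index(d0, d6, n6) == pytest.approx(expected)

    def test_nonpositive_d0_rejected(self):
        with pytest.raises(ValueError):
            cell_growth_index(0, 100, 100)

    def test_matches_naive_on_random_inputs(self, rng):
        for _ in range(100):
            d0 = rng.uniform(100, 1e5)
            d6, n6 = rng.uniform(0, 1e5, 2)
            assert cell_growth_index(d0, d6, n6) == pytest.approx(
                growth_index_naive(d0, d6, n6)
            )


class TestQcFilter:
    def rows(self, d0, d6):
        return make_readouts(
            [("S1", "A", 1, "D0", d0), ("S1", "A", 1, "D6", d6)]
        )

    @pytest.mark.parametrize(
        "d0,d6,expect_pass,reason",
        [
            (5000, 4000, False, "low_signal"),  # signal at most 5000 fails
            (20000, 6000, False, "low_ratio"),  # ratio 0.3 fails
            (10000, 6000, True, ""),
            (5000, 5000, False, "low_signal"),  # signal exactly 5000 fails (strict)
            (12000, 6000, False, "low_ratio"),  # ratio exactly 0.5 fails (strict)
            (20000, 4000, False, "low_signal;low_ratio"),
        ],
    )
    def test_strict_thresholds(self, d0, d6, expect_pass, reason):
        out = qc_filter(self.rows(d0, d6))
        assert bool(out.iloc[0]["qc_pass"]) is expect_pass
        assert out.iloc[0]["reason"] == reason

    def test_missing_d0_fails_with_warning(self, caplog):
        t = make_readouts([("S1", "A", 1, "D6", 9000)])
        with caplog.at_level("WARNING"):
            out = qc_filter(t)
        assert not out.iloc[0]["qc_pass"]
        assert out.iloc[0]["reason"] == "missing_D0"

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            qc_filter(make_readouts([("S1", "A", 1, "D9", 9000)]))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        d0=st.floats(1000, 30000),
        d6=st.floats(0, 30000),
        bump_signal=st.floats(0, 5000),
        bump_ratio=st.floats(0, 0.5),
    )
    def test_raising_thresholds_never_rescues_a_fail(self, d0, d6, bump_signal, bump_ratio):
        t = self.rows(d0, d6)
        base = qc_filter(t)["qc_pass"].iloc[0]
        stricter = qc_filter(t, 5000 + bump_signal, 0.5 + bump_ratio)["qc_pass"].iloc[0]
        assert not (stricter and not base)


class TestIndexMatrix:
    def test_duplicate_averaging_before_formula(self):
        t = make_readouts(
            [
                ("S1", "A", 1, "D0", 1000),
                ("S1", "A", 2, "D0", 1000),
                ("S1", "A", 1, "D6", 4800),
                ("S1", "A", 2, "D6", 5200),
                ("S1", "NO_GF", 1, "N6", 1000),
            ]
        )
        cat = small_catalog()
        t["condition_id"] = t["condition_id"].replace({"A": "A/B"})
        gim = build_index_matrix(t, cat, min_signal=0, min_ratio=0)
        assert gim.index.loc["S1", "A/B"] == pytest.approx(4.0)
        assert gim.rate.loc["S1", "A/B"] == pytest.approx(5.0)
        assert gim.n_replicates.loc["S1", "A/B"] == 2

    def test_surviving_replicate_used_when_twin_fails_qc(self):
        t = make_readouts(
            [
                ("S1", "A/B", 1, "D0", 1000),
                ("S1", "A/B", 2, "D0", 1000),
                ("S1", "A/B", 1, "D6", 8000),
                ("S1", "A/B", 2, "D6", 400),  # fails the signal rule
                ("S1", "NO_GF", 1, "N6", 1000),
            ]
        )
        gim = build_index_matrix(t, small_catalog())
        assert gim.index.loc["S1", "A/B"] == pytest.approx(7.0)
        assert gim.n_replicates.loc["S1", "A/B"] == 1

    def test_all_replicates_failing_masks_cell(self):
        t = make_readouts(
            [
                ("S1", "A/B", 1, "D0", 1000),
                ("S1", "A/B", 1, "D6", 400),
                ("S1", "NO_GF", 1, "N6", 1000),
            ]
        )
        gim = build_index_matrix(t, small_catalog())
        assert np.isnan(gim.index.loc["S1", "A/B"])
        assert not gim.qc_pass.loc["S1", "A/B"]

    def test_sample_without_n6_is_fully_masked(self, caplog):
        t = make_readouts(
            [("S1", "A/B", 1, "D0", 1000), ("S1", "A/B", 1, "D6", 8000)]
        )
        with caplog.at_level("WARNING"):
            gim = build_index_matrix(t, small_catalog())
        assert gim.index.isna().all().all()

    def test_matches_per_cell_loop_on_random_table(self, rng):
        cat = small_catalog()
        rows = []
        samples = [f"S{i}" for i in range(5)]
        for s in samples:
            for c in cat.labels:
                for rep in (1, 2):
                    rows.append((s, c, rep, "D0", rng.uniform(6000, 14000)))
                    rows.append((s, c, rep, "D6", rng.uniform(3000, 60000)))
            rows.append((s, "NO_GF", 1, "N6", rng.uniform(4000, 12000)))
        t = make_readouts(rows)
        gim = build_index_matrix(t, cat)
        for s in samples:
            n6 = t[(t.sample_id == s) & (t.role == "N6")]["lum"].mean()
            for c in cat.labels:
                sub = t[(t.sample_id == s) & (t.condition_id == c)]
                d0s, d6s = [], []
                for rep in (1, 2):
                    d0 = sub[(sub.replicate == rep) & (sub.role == "D0")]["lum"]
                    d6 = sub[(sub.replicate == rep) & (sub.role == "D6")]["lum"]
                    if len(d6) and d6.iloc[0] > 5000 and d6.iloc[0] / d0.iloc[0] > 0.5:
                        d0s.append(d0.iloc[0])
                        d6s.append(d6.iloc[0])
                if d0s:
                    expected = (np.mean(d6s) - n6) / np.mean(d0s)
                    assert gim.index.loc[s, c] == pytest.approx(expected)
                else:
                    assert np.isnan(gim.index.loc[s, c])

    def test_scale_invariance_per_sample(self, rng):
        cat = small_catalog()
        rows = []
        for c in cat.labels:
            rows.append(("S1", c, 1, "D0", rng.uniform(8000, 12000)))
            rows.append(("S1", c, 1, "D6", rng.uniform(9000, 30000)))
        rows.append(("S1", "NO_GF", 1, "N6", 9000.0))
        t = make_readouts(rows)
        scaled = t.copy()
        scaled["lum"] = scaled["lum"] * 3.7
        a = build_index_matrix(t, cat, min_signal=0, min_ratio=0)
        b = build_index_matrix(scaled, cat, min_signal=0, min_ratio=0)
        pd.testing.assert_frame_equal(a.index, b.index)
        pd.testing.assert_frame_equal(a.rate, b.rate)


class TestConcordance:
    def test_identity_and_affine_transform_give_r2_one(self, rng):
        a = pd.Series(rng.normal(size=10), index=[f"c{i}" for i in range(10)])
        assert replicate_concordance(a, a) == pytest.approx(1.0)
        assert replicate_concordance(a, 2 * a + 1) == pytest.approx(1.0)

    def test_matches_textbook_pearson_on_toy(self):
        a = pd.Series([0.1, 0.5, 1.2, 2.0, 0.9, 1.4], index=list("abcdef"))
        b = pd.Series([0.2, 0.4, 1.0, 2.4, 1.1, 1.2], index=list("abcdef"))
        assert replicate_concordance(a, b) == pytest.approx(pearson_naive(a, b) ** 2)

    def test_too_few_shared_points_rejected(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            replicate_concordance(a, a)


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        means, p = group_growth_comparison([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert p == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self):
        vals = [0, 0.01, -0.01, 5, 5.01, 4.99]
        _, p = group_growth_comparison(vals, list("aaabbb"))
        assert p < 1e-6

    def test_matches_t_distribution_on_fixed_toy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.5, 3.5, 4.5, 6.0])
        _, p = group_growth_comparison(np.r_[x, y], list("aaaabbbb"))
        t, p_ref = stats.ttest_ind(x, y, equal_var=False)
        assert p == pytest.approx(p_ref)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_growth_comparison([1, 2, 3], ["a", "b", "b"])
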