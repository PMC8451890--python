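"""Comparison statistics: matching, through-origin regression, ANOVA, paired t."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airwaymorph.compare import (
    anova_by_strain,
    compare_tables,
    fold_to_quadrant,
    match_branches,
    paired_t_bonferroni,
    regression_through_origin,
)


def table_from(labels, **cols):
    return pd.DataFrame({"label": labels, **cols})


class TestMatchBranches:
    def test_identical_tables_pair_everything(self):
        t = table_from(["1", "11", "12"], length_mm=[3.0, 2.0, 1.5])
        m = match_branches(t, t.copy())
        assert m.n == 3 and not m.only_a and not m.only_b

    def test_disjoint_tables_pair_nothing(self):
        a = table_from(["1", "11"], length_mm=[3.0, 2.0])
        b = table_from(["12", "121"], length_mm=[1.5, 1.0])
        m = match_branches(a, b)
        assert m.n == 0
        assert m.only_a == ["1", "11"] and m.only_b == ["12", "121"]

    def test_missing_airways_reduce_pair_count(self):
        # one table lacks two generation-6 airways of a 63-airway counterpart
        full = [format(i, "b") for i in range(1, 64)]
        a = table_from(full, length_mm=np.linspace(3, 0.3, 63))
        b = table_from(full[:-2], length_mm=np.linspace(3, 0.3, 61))
        assert match_branches(a, b).n == 61

    def test_duplicate_labels_rejected(self):
        bad = table_from(["1", "1"], length_mm=[1.0, 2.0])
        with pytest.raises(ValueError):
            match_branches(bad, bad)


class TestRegressionThroughOrigin:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = regression_through_origin(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)

    def test_exact_negative_proportionality(self):
        x = np.array([1.0, 2.0, 3.0])
        res = regression_through_origin(x, -x)
        assert res.slope == pytest.approx(-1.0)
        assert res.r == pytest.approx(-1.0)

    def test_slope_matches_grid_refinement_minimizer(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.2, 3.0, 50)
        y = 1.7 * x + rng.normal(0, 0.3, 50)
        res = regression_through_origin(x, y)
        # oracle: shrink a grid around the argmin of the residual sum
        lo, hi = -5.0, 5.0
        for _ in range(40):
            grid = np.linspace(lo, hi, 101)
            sse = [(np.sum((y - b * x) ** 2)) for b in grid]
            k = int(np.argmin(sse))
            lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 100)]
        assert res.slope == pytest.approx((lo + hi) / 2, abs=1e-6)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 2, 30)
        y = x + rng.normal(0, 0.1, 30)
        base = regression_through_origin(x, y)
        scaled = regression_through_origin(x, 3.0 * y)
        assert scaled.slope == pytest.approx(3.0 * base.slope)
        assert scaled.r == pytest.approx(base.r)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_scaling_y_scales_slope_keeps_r(self, seed, c):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 2.0, 20)
        y = x + rng.normal(0, 0.2, 20)
        base = regression_through_origin(x, y)
        scaled = regression_through_origin(x, c * y)
        assert scaled.slope == pytest.approx(c * base.slope, rel=1e-9)
        assert scaled.r == pytest.approx(base.r, rel=1e-9)

    def test_zero_variance_flagged(self):
        res = regression_through_origin(np.array([1.0, 2.0]), np.array([1.0, 1.0]))
        assert res.flag == "zero_variance" and np.isnan(res.r)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            regression_through_origin(np.zeros(4), np.arange(4.0))


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        g = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])}
        res = anova_by_strain(g)
        assert res.f == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_match_hand_computed_f(self):
        # classic 3+3 example: between/within mean squares by hand
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        grand = 3.5
        ssb = 3 * ((2.0 - grand) ** 2 + (5.0 - grand) ** 2)
        ssw = sum((a - 2.0) ** 2) + sum((b - 5.0) ** 2)
        f_hand = (ssb / 1) / (ssw / 4)
        res = anova_by_strain({"a": a, "b": b})
        assert res.f == pytest.approx(f_hand)

    def test_p_in_unit_interval_for_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            groups = {s: rng.normal(size=5) for s in "abcd"}
            res = anova_by_strain(groups)
            assert 0.0 <= res.p <= 1.0

    def test_type_one_error_near_alpha(self):
        # 4 identically distributed strains, 5 casts each, 200 replicates:
        # the rejection rate at alpha=.05 must sit within binomial error
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = {s: rng.normal(size=5) for s in "abcd"}
            if anova_by_strain(groups).p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_by_strain({"a": np.array([1.0, 2.0])})


class TestPairedT:
    def test_identical_samples_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        out, thr = paired_t_bonferroni({"same": (a, a.copy())})
        assert out["same"].t == 0.0 and out["same"].flag == "degenerate"
        assert thr == pytest.approx(0.01)

    def test_constant_shift_is_p_to_zero_limit(self):
        a = np.arange(5.0)
        out, _ = paired_t_bonferroni({"shift": (a + 2.0, a)})
        assert np.isinf(out["shift"].t) and out["shift"].p == 0.0

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.8, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        out, _ = paired_t_bonferroni({"cmp": (a, b)})
        d = a - b
        t_obs = abs(out["cmp"].t)
        # exhaustive sign-flip permutation of the differences
        n = len(d)
        count = 0
        for bits in range(2**n):
            signs = np.array([1 if bits >> k & 1 else -1 for k in range(n)])
            dd = d * signs
            t = dd.mean() / (dd.std(ddof=1) / np.sqrt(n))
            if abs(t) >= t_obs - 1e-12:
                count += 1
        p_perm = count / 2**n
        assert out["cmp"].p == pytest.approx(p_perm, abs=0.05)

    def test_bonferroni_adjustment_and_threshold(self):
        rng = np.random.default_rng(12)
        comps = {f"c{i}": (rng.normal(size=6), rng.normal(size=6)) for i in range(4)}
        out, thr = paired_t_bonferroni(comps)
        assert thr == pytest.approx(0.01 / 4)
        for res in out.values():
            assert res.p_adjusted == pytest.approx(min(1.0, 4 * res.p))


class TestAnovaTable:
    def test_strain_shift_detected_per_generation(self):
        rng = np.random.default_rng(3)
        labels = ["1", "11", "12", "111", "112", "121", "122"]

        def cast(shift):
            return table_from(labels,
                              length_mm=np.linspace(3, 1, 7) + shift
                              + rng.normal(0, 0.01, 7),
                              diameter_mm=np.linspace(1.2, 0.5, 7)
                              + rng.normal(0, 0.01, 7))

        from airwaymorph.compare import anova_table
        out = anova_table({"a": [cast(0.0) for _ in range(4)],
                           "b": [cast(0.6) for _ in range(4)]},
                          measures=["length_mm", "diameter_mm"])
        lengths = out[out.measure == "length_mm"]
        assert (lengths.p < 0.01).all()          # shifted measure flagged
        diameters = out[out.measure == "diameter_mm"]
        assert (diameters.p > 0.05).mean() > 0.5  # unshifted mostly quiet
        assert set(lengths.generation) == {1, 2, 3}


class TestCompareTables:
    def test_equal_tables_have_unit_slope(self):
        t = table_from(["1", "11", "12", "111"],
                       length_mm=[3.0, 2.5, 2.0, 1.6],
                       diameter_mm=[1.2, 1.0, 0.8, 0.7],
                       branch_angle_deg=[np.nan, 23.0, 33.0, 25.0],
                       gravity_angle_deg=[90.0, 80.0, 66.0, 70.0])
        res = compare_tables(t, t.copy()).set_index("measure")
        assert res.loc["length_mm", "slope"] == pytest.approx(1.0)
        assert res.loc["diameter_mm", "r"] == pytest.approx(1.0)

    def test_null_slope_concentrates_near_one_as_noise_shrinks(self):
        rng = np.random.default_rng(21)
        d = rng.uniform(0.3, 1.2, 40)
        labels = [format(i, "b") for i in range(1, 41)]
        widths = []
        for noise in (0.1, 0.01):
            a = table_from(labels, diameter_mm=d + rng.normal(0, noise, 40))
            b = table_from(labels, diameter_mm=d + rng.normal(0, noise, 40))
            res = compare_tables(a, b).set_index("measure")
            widths.append(abs(res.loc["diameter_mm", "slope"] - 1.0))
        assert widths[1] < widths[0]
        assert widths[1] < 0.01

    def test_gravity_fold(self):
        assert fold_to_quadrant(np.array([0.0, 90.0, 135.0, 180.0])).tolist() == \
            [0.0, 90.0, 45.0, 0.0]
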