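"""ANOVA, Duncan's multiple-range letters and Pearson correlation windows."""

import numpy as np
import pytest
from scipy import stats as sps

from cherrychill.errors import DegenerateDataError, InputError
from cherrychill.stats import (
    GroupedMeasurements,
    duncan_critical_ranges,
    duncan_mrt,
    one_way_anova,
    pearson,
    significance_stars,
    windowed_correlations,
)
from cherrychill.synthetic import SeasonSpec, StarchTrajectorySpec, gen_season_dataset
from cherrychill.thermal import accumulate


def grouped(*value_lists):
    return GroupedMeasurements(
        labels=tuple(f"g{i}" for i in range(len(value_lists))),
        values=tuple(np.asarray(v, float) for v in value_lists),
    )


class TestOneWayAnova:
    def test_identical_group_means_give_zero_f(self):
        res = one_way_anova(grouped([1, 2, 3], [1, 2, 3]))
        assert res.F == 0.0 and res.p == pytest.approx(1.0)

    def test_zero_within_variance_flagged_degenerate(self):
        res = one_way_anova(grouped([0, 0], [10, 10]))
        assert np.isinf(res.F) and res.degenerate and res.mse == 0.0

    def test_all_values_identical_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova(grouped([5, 5, 5], [5, 5, 5]))

    def test_matches_two_pass_sum_of_squares_oracle(self, rng):
        """Random balanced 4 x 6 layout vs. the textbook decomposition."""
        data = [rng.normal(loc=m, scale=1.0, size=6) for m in (0.0, 0.5, 1.0, 2.0)]
        g = grouped(*data)
        res = one_way_anova(g)
        allv = np.concatenate(data)
        grand = allv.mean()
        ss_b = sum(len(v) * (np.mean(v) - grand) ** 2 for v in data)
        ss_w = sum((x - np.mean(v)) ** 2 for v in data for x in v)
        F = (ss_b / 3) / (ss_w / (24 - 4))
        assert res.F == pytest.approx(F, abs=1e-10)
        scipy_F, scipy_p = sps.f_oneway(*data)
        assert res.F == pytest.approx(scipy_F, rel=1e-12)
        assert res.p == pytest.approx(scipy_p, rel=1e-12)

    def test_f_invariant_to_constant_shift(self, rng):
        data = [rng.normal(size=5) for _ in range(3)]
        f0 = one_way_anova(grouped(*data)).F
        f1 = one_way_anova(grouped(*[v + 100.0 for v in data])).F
        assert f0 == pytest.approx(f1, rel=1e-9)

    def test_group_invariants_enforced(self):
        with pytest.raises(InputError):
            GroupedMeasurements(labels=("a",), values=(np.array([1.0, 2.0]),))
        with pytest.raises(InputError):
            grouped([1.0], [1.0, 2.0])


def oracle_partition(means_sorted, r_p):
    """Exhaustive-pairwise oracle: maximal contiguous all-pairs-nonsig runs."""
    k = len(means_sorted)

    def different(i, j):
        return abs(means_sorted[j] - means_sorted[i]) > r_p[j - i - 1]

    intervals = [
        (a, b)
        for a in range(k)
        for b in range(a, k)
        if all(not different(i, j) for i in range(a, b + 1) for j in range(i + 1, b + 1))
    ]
    return sorted(
        iv for iv in intervals
        if not any(jv != iv and jv[0] <= iv[0] and iv[1] <= jv[1] for jv in intervals)
    )


def partition_from_letters(result):
    """Recover letter runs as (start, stop) index pairs over the sorted means."""
    runs = {}
    for pos, label in enumerate(result.order):
        for letter in result.letters[label]:
            a, b = runs.get(letter, (pos, pos))
            runs[letter] = (min(a, pos), max(b, pos))
    return sorted(runs.values())


class TestDuncan:
    def test_far_apart_means_get_distinct_letters(self, rng):
        g = grouped(rng.normal(0, 0.1, 6), rng.normal(50, 0.1, 6))
        res = duncan_mrt(g, 0.05)
        assert res.letters["g0"] != res.letters["g1"]

    def test_identical_groups_share_one_letter(self):
        g = grouped([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = duncan_mrt(g, 0.05)
        assert set(res.letters.values()) == {"a"}

    def test_partition_matches_exhaustive_pairwise_oracle(self, rng):
        """50 random 5-group layouts against the brute-force R_p oracle."""
        for _ in range(50):
            data = [rng.normal(rng.uniform(0, 3), 1.0, 6) for _ in range(5)]
            g = grouped(*data)
            res = duncan_mrt(g, 0.05, gate_on_anova=False)
            anova = res.anova
            n_h = 5 / np.sum(1.0 / g.sizes)
            r_p = duncan_critical_ranges(5, anova.df_within, anova.mse, n_h, 0.05)
            means_sorted = np.sort(g.means)
            assert partition_from_letters(res) == oracle_partition(means_sorted, r_p)

    def test_two_groups_reduce_to_r2_boundary(self):
        """k = 2: separation iff the mean difference exceeds R_2 exactly."""
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1.0, 8)
        g0 = base - base.mean()
        anova_probe = one_way_anova(grouped(g0, g0 + 1.0))
        r2 = duncan_critical_ranges(2, anova_probe.df_within, anova_probe.mse, 8, 0.05)[0]
        just_under = duncan_mrt(grouped(g0, g0 + r2 * 0.999), 0.05, gate_on_anova=False)
        just_over = duncan_mrt(grouped(g0, g0 + r2 * 1.001), 0.05, gate_on_anova=False)
        assert just_under.letters["g0"] == just_under.letters["g1"]
        assert just_over.letters["g0"] != just_over.letters["g1"]

    def test_letter_runs_are_contiguous(self, rng):
        for _ in range(10):
            data = [rng.normal(rng.uniform(0, 2), 1.0, rng.integers(3, 8)) for _ in range(6)]
            res = duncan_mrt(grouped(*data), 0.05, gate_on_anova=False)
            positions = {}
            for pos, label in enumerate(res.order):
                for letter in res.letters[label]:
                    positions.setdefault(letter, []).append(pos)
            for pos_list in positions.values():
                assert pos_list == list(range(pos_list[0], pos_list[-1] + 1))

    def test_gate_on_nonsignificant_anova(self, rng):
        data = [rng.normal(0, 1.0, 4) for _ in range(4)]
        res = duncan_mrt(grouped(*data), 1e-6)  # alpha tiny -> surely gated
        assert set(res.letters.values()) == {"a"}
        assert res.metadata.get("gated")


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_p_matches_t_transform_at_r_half(self):
        """Exact r = 0.5, n = 12 via Gram-Schmidt; p from the t CDF."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        z = rng.normal(size=12)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        zc = z - z.mean() - (z - z.mean()) @ xc * xc
        zc /= np.linalg.norm(zc)
        y = 0.5 * xc + np.sqrt(0.75) * zc
        res = pearson(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-12)
        t = 0.5 * np.sqrt(10 / 0.75)
        assert res.p == pytest.approx(2 * sps.t.sf(t, 10), rel=1e-12)

    def test_agrees_with_scipy(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        r0 = pearson(x, y).r
        assert pearson(3 * x + 7, y).r == pytest.approx(r0)
        assert pearson(x, -2 * y + 1).r == pytest.approx(-r0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_stars_convention(self):
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"


@pytest.fixture(scope="module")
def season():
    ds = gen_season_dataset(SeasonSpec(seed=6), StarchTrajectorySpec(), with_images=False)
    series = ds.series
    chill = accumulate(series, (series.season_start, series.times[-1]), "chill")
    gt = ds.ground_truth
    import pandas as pd

    fulfillment = pd.Timestamp(gt["fulfillment_date"])
    heat = accumulate(series, (fulfillment, series.times[-1]), "heat")
    starch = [(d, v) for d, v in gt["theta_by_date"].items()]
    return starch, chill, heat, fulfillment


class TestWindowedCorrelations:
    def test_planted_windows_recovered(self, season):
        starch, chill, heat, fulfillment = season
        results, notes = windowed_correlations(starch, chill, heat, fulfillment)
        pre, post = results["pre_fulfillment"], results["post_fulfillment"]
        assert pre is not None and pre.r > 0 and pre.p < 0.01
        assert post is not None and post.r < 0 and post.p < 0.05

    def test_constant_starch_surfaced_as_undefined(self, season):
        starch, chill, heat, fulfillment = season
        flat = [(d, 1.0) for d, _ in starch]
        results, notes = windowed_correlations(flat, chill, heat, fulfillment)
        assert results["pre_fulfillment"] is None
        assert any("constant" in n for n in notes)

    def test_sparse_window_skipped_with_note(self, season):
        starch, chill, heat, fulfillment = season
        results, notes = windowed_correlations(starch[:2], chill, heat, fulfillment)
        assert results["pre_fulfillment"] is None
        assert any("skipped" in n for n in notes)
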