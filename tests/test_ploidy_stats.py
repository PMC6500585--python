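import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nucsize import (bin_classes, bootstrap_moments, class_to_ploidy,
                     compare_moments, fit_size_distribution, kruskal_dunn,
                     median_test, sample_population, sturges_width,
                     summarize_case_study)
from nucsize.ploidy import assign_classes, validate_measurements


class TestSturges:
    def test_formula_on_volume_ranges(self):
        # ranges/counts of the two reference volume populations
        assert sturges_width(118 - 15, 594) == pytest.approx(10.08, abs=0.01)
        assert sturges_width(220 - 20, 893) == pytest.approx(18.51, abs=0.01)

    def test_zero_range_gives_zero_width(self):
        assert sturges_width(0.0, 100) == 0.0

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            sturges_width(10.0, 0)


class TestClasses:
    def test_reference_class_limits(self):
        # 20–45 is class I, 70–95 class III; a 20–220 population has 8 classes
        idx = assign_classes([30.0, 80.0, 44.9, 45.0, 219.0, 220.0])
        assert list(idx) == [1, 3, 1, 2, 8, 8]
        classes, table = bin_classes([30.0, 80.0, 44.9, 45.0, 219.0, 220.0])
        assert len(classes) == 8
        assert (classes[0].lower, classes[0].upper) == (20.0, 45.0)
        assert (classes[2].lower, classes[2].upper) == (70.0, 95.0)

    def test_below_anchor_values_fold_into_class_one(self):
        idx = assign_classes([15.0, 30.0, 60.0])
        assert list(idx) == [1, 1, 2]

    def test_partition_property(self):
        vols = sample_population("lognormal", {"median": 45, "sigma": 0.5}, 500, seed=3)
        _, table = bin_classes(vols)
        assert table["n"].sum() == 500
        idx = assign_classes(vols)
        assert np.all((idx >= 1) & (idx <= table["class_index"].max()))

    def test_per_class_means_lie_inside_class_bounds(self):
        vols = sample_population("lognormal", {"median": 45, "sigma": 0.4}, 400, seed=4)
        _, table = bin_classes(vols)
        occupied = table[table["n"] > 0]
        # means must respect bounds except class I, which absorbs sub-anchor values
        for _, row in occupied.iterrows():
            upper_ok = row["mean_um3"] <= row["upper_um3"]
            lower_ok = (row["mean_um3"] >= row["lower_um3"]) or row["class_index"] == 1
            assert upper_ok and lower_ok

    def test_empty_input_gives_empty_table(self):
        classes, table = bin_classes([])
        assert classes == [] and len(table) == 0

    def test_invalid_width_raises(self):
        with pytest.raises(ValueError):
            bin_classes([10.0], width=0)


class TestPloidyLabels:
    @pytest.mark.parametrize("idx,label", [(1, "2C"), (2, "4C"), (3, "8C"),
                                           (4, "16C"), (8, "256C")])
    def test_reference_labels(self, idx, label):
        assert class_to_ploidy(idx) == label

    def test_ploidy_doubles_per_class(self):
        for k in range(1, 10):
            a = int(class_to_ploidy(k)[:-1])
            b = int(class_to_ploidy(k + 1)[:-1])
            assert b == 2 * a

    def test_index_below_one_raises(self):
        with pytest.raises(ValueError):
            class_to_ploidy(0)


def _hypergeom_two_sided(table) -> float:
    """Enumeration oracle for the 2×2 exact test (fixed margins)."""
    (a, b), (c, d) = table
    n1, n2 = a + c, b + d
    k = a + b
    probs = []
    for x in range(max(0, k - n2), min(k, n1) + 1):
        probs.append((x, math.comb(n1, x) * math.comb(n2, k - x)
                      / math.comb(n1 + n2, k)))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs + 1e-12)


class TestMedianTest:
    def test_identical_samples_not_significant(self):
        r = median_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert r["p_value"] == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact_p(self):
        r = median_test([1, 2, 3, 4], [5, 6, 7, 8])
        assert r["method"] == "exact"
        assert r["p_value"] == pytest.approx(2 / 70)

    def test_constant_data_degenerates_to_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = median_test([2, 2, 2], [2, 2])
        assert r["p_value"] == 1.0

    def test_exact_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 7))
            b = rng.normal(0.5, 1, rng.integers(3, 7))
            r = median_test(a, b)
            assert r["p_value"] == pytest.approx(_hypergeom_two_sided(r["table"]),
                                                 abs=1e-9)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            median_test([], [1.0])


class TestFit:
    def test_lognormal_recovery(self):
        x = sample_population("lognormal", {"mu": 3.7, "sigma": 0.4}, 2000, seed=0)
        f = fit_size_distribution(x)
        assert f["family"] == "lognormal"
        assert f["lognormal"]["sigma"] == pytest.approx(0.4, abs=0.05)
        assert f["lognormal"]["mu"] == pytest.approx(3.7, abs=0.05)

    def test_gamma_recognized(self):
        x = sample_population("gamma", {"shape": 9, "scale": 5}, 2000, seed=1)
        assert fit_size_distribution(x)["family"] == "gamma"

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_size_distribution([1.0] * 9)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_size_distribution([1.0] * 20 + [0.0])


class TestBootstrap:
    def test_seed_fixes_aggregates(self):
        x = sample_population("lognormal", {"median": 40, "sigma": 0.5}, 600, seed=2)
        _, a1 = bootstrap_moments(x, iterations=50, seed=9)
        _, a2 = bootstrap_moments(x, iterations=50, seed=9)
        pd.testing.assert_frame_equal(a1, a2)

    def test_constant_input_errors(self):
        with pytest.raises(RuntimeError):
            bootstrap_moments([5.0] * 50, iterations=20, seed=0)

    def test_mean_consistency(self):
        mu, sigma = math.log(40.0), 0.5
        x = sample_population("lognormal", {"mu": mu, "sigma": sigma}, 2000, seed=3)
        _, agg = bootstrap_moments(x, iterations=200, seed=4)
        row = agg[agg["moment"] == "mean"].iloc[0]
        source_mean = math.exp(mu + sigma ** 2 / 2)
        assert abs(row["mean"] - x.mean()) <= 2 * row["sd"] + abs(x.mean() - source_mean)

    def test_moment_summary_fields(self):
        x = sample_population("lognormal", {"median": 30, "sigma": 0.4}, 500, seed=5)
        summaries, agg = bootstrap_moments(x, iterations=10, resample_n=100,
                                           regen_n=100, seed=6)
        assert len(summaries) == 10
        s = summaries[0]
        assert s.n == 100 and s.sd > 0 and s.cv == pytest.approx(s.sd / s.mean)
        assert set(agg["moment"]) == {"mean", "sd", "cv", "skewness", "kurtosis"}


class TestCompareMoments:
    def _skew_summaries(self, sigma, n_summaries, seed0):
        return [float(sps.skew(np.random.default_rng(seed0 + i)
                               .lognormal(0, sigma, 400), bias=False))
                for i in range(n_summaries)]

    def test_identical_groups_show_no_effect(self):
        vals = self._skew_summaries(0.5, 20, 100)
        r = compare_moments({"a": vals, "b": list(vals)}, "skewness")
        assert r["pairwise"].iloc[0]["diff"] == pytest.approx(0.0, abs=1e-12)
        assert not r["pairwise"].iloc[0]["reject"]

    def test_null_false_positive_rate_controlled(self):
        hits = 0
        runs = 100
        for run in range(runs):
            a = self._skew_summaries(0.5, 12, 1000 + 40 * run)
            b = self._skew_summaries(0.5, 12, 3000 + 40 * run)
            r = compare_moments({"a": a, "b": b}, "skewness")
            hits += int(r["pairwise"]["reject"].any())
        assert hits <= 0.10 * runs

    def test_distinct_shape_groups_detected(self):
        detected = 0
        runs = 20
        for run in range(runs):
            lo = self._skew_summaries(0.3, 30, 5000 + 70 * run)
            hi = self._skew_summaries(0.8, 30, 9000 + 70 * run)
            r = compare_moments({"lo": lo, "hi": hi}, "skewness")
            detected += int(r["pairwise"]["reject"].all())
        assert detected >= 0.9 * runs

    def test_single_summary_group_rejected(self):
        with pytest.raises(ValueError):
            compare_moments({"a": [1.0], "b": [1.0, 2.0]})


class TestKruskalDunn:
    def test_identical_constants_fully_tied(self):
        r = kruskal_dunn({"a": [3.0, 3.0], "b": [3.0, 3.0, 3.0]})
        assert r["H"] == 0.0 and r["p_value"] == 1.0

    def test_exact_enumeration_on_toy_groups(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        r = kruskal_dunn(groups, exact=True)
        # hand value: H = 12/(9·10)·(3·2² + 3·5² + 3·8²) − 3·10 = 7.2
        assert r["H"] == pytest.approx(7.2)
        # 6 of the 1680 assignments reach H ≥ 7.2 (the 3! orderings of the
        # three fully separated rank blocks)
        assert r["p_value"] == pytest.approx(6 / 1680)

    def test_rank_based_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        g = {"a": rng.normal(0, 1, 25), "b": rng.normal(0.7, 1, 25),
             "c": rng.normal(0.2, 1, 25)}
        r1 = kruskal_dunn(g)
        r2 = kruskal_dunn({k: np.exp(v) for k, v in g.items()})
        assert r1["p_value"] == pytest.approx(r2["p_value"])
        np.testing.assert_allclose(r1["pairwise"]["p_adj"], r2["pairwise"]["p_adj"])

    def test_shifted_group_detected_with_power(self):
        rng = np.random.default_rng(9)
        hits = 0
        runs = 60
        for _ in range(runs):
            g = {"a": rng.lognormal(0, 0.4, 50), "b": rng.lognormal(0, 0.4, 50),
                 "c": rng.lognormal(0.5, 0.4, 50)}
            r = kruskal_dunn(g)
            pw = r["pairwise"]
            flagged = set()
            for _, row in pw[pw["reject"]].iterrows():
                flagged.add((row["group1"], row["group2"]))
            if r["p_value"] < 0.05 and ("a", "c") in flagged and ("b", "c") in flagged:
                hits += 1
        assert hits >= 0.9 * runs

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1.0], "b": []})


class TestCaseStudySummary:
    def test_single_group_summary_only(self):
        df = pd.DataFrame({"treatment": ["ctr"] * 10,
                           "volume_um3": np.linspace(20, 60, 10)})
        res = summarize_case_study(df, "treatment")
        assert "kruskal_dunn" not in res
        assert res["summary"].iloc[0]["n"] == 10

    def test_planted_mean_shift_recovered(self):
        rng = np.random.default_rng(10)
        base = rng.lognormal(math.log(40), 0.35, 500)
        df = pd.DataFrame({
            "treatment": ["ctr"] * 500 + ["myc"] * 500,
            "volume_um3": np.concatenate([base, 1.25 * rng.lognormal(math.log(40), 0.35, 500)]),
        })
        res = summarize_case_study(df, "treatment")
        s = res["summary"].set_index("treatment")
        ratio = s.loc["myc", "mean"] / s.loc["ctr", "mean"]
        assert ratio == pytest.approx(1.25, rel=0.05)
        assert res["kruskal_dunn"]["p_value"] < 0.05
        assert set(s["letters"]) == {"a", "b"}

    def test_permuted_labels_not_significant(self):
        rng = np.random.default_rng(11)
        vals = rng.lognormal(math.log(40), 0.4, 300)
        fp = 0
        runs = 40
        for _ in range(runs):
            labels = rng.permutation(["a"] * 150 + ["b"] * 150)
            df = pd.DataFrame({"g": labels, "volume_um3": vals})
            res = summarize_case_study(df, "g")
            fp += int(res["kruskal_dunn"]["pairwise"]["reject"].any())
        assert fp <= 0.1 * runs + 1

    def test_unknown_grouping_field_raises(self):
        df = pd.DataFrame({"g": ["a"], "volume_um3": [30.0]})
        with pytest.raises(ValueError):
            summarize_case_study(df, "nope")


class TestMeasurementTable:
    def test_valid_table_passes(self):
        df = pd.DataFrame({"volume_um3": [20.0, 30.0], "treatment": ["ctr", "myc"]})
        assert validate_measurements(df) is df

    def test_row_without_any_measurement_rejected(self):
        df = pd.DataFrame({"area_um2": [20.0, np.nan], "volume_um3": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            validate_measurements(df)

    def test_nonpositive_measurement_rejected(self):
        df = pd.DataFrame({"volume_um3": [20.0, -1.0]})
        with pytest.raises(ValueError):
            validate_measurements(df)
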