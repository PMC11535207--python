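"""NHPI variation metrics, uncertainty propagation, group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nhpikit.metrics import (
    MetricDistribution,
    average,
    compact_letter_display,
    compare_groups,
    consistency,
    heterogeneity,
    interannual_consistency,
    propagate_uncertainty,
    reversal,
    specialization,
)
from nhpikit.synthetic import simulate_coefficients

finite_vectors = arrays(
    float,
    st.integers(2, 30),
    elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False),
)


class TestPointMetrics:
    def test_hand_examples(self):
        assert average([1, -1]) == 0.0
        assert average([0.5, 0.5, 0.5]) == 0.5
        assert specialization([1, -1]) == 1.0
        assert specialization([0, 0, 0]) == 0.0
        assert heterogeneity([1, -1]) == pytest.approx(np.sqrt(2), abs=1e-9)
        assert heterogeneity([3, 3, 3]) == 0.0

    def test_empty_rejected(self):
        for fn in (average, specialization):
            with pytest.raises(ValueError):
                fn([])
        with pytest.raises(ValueError):
            heterogeneity([1.0])

    @settings(max_examples=200, deadline=None)
    @given(finite_vectors)
    def test_specialization_dominates_average(self, x):
        assert specialization(x) >= abs(average(x)) - 1e-12

    @settings(max_examples=100, deadline=None)
    @given(finite_vectors)
    def test_sign_symmetry(self, x):
        assert average(-x) == pytest.approx(-average(x), abs=1e-9)
        assert specialization(-x) == pytest.approx(specialization(x), abs=1e-9)
        assert heterogeneity(-x) == pytest.approx(heterogeneity(x), abs=1e-9)

    def test_heterogeneity_matches_two_pass_sd(self, rng):
        x = rng.standard_normal(200)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert heterogeneity(x) == pytest.approx(sd, abs=1e-12)


class TestPairMetrics:
    def test_hand_examples(self):
        assert consistency([(1, 1), (-2, -2)]) == 0.0
        assert consistency([(1, 0), (0, 1)]) == 1.0
        assert reversal([(1, -1), (1, 1)]) == 0.5
        assert reversal([(2, 1), (-1, -3)]) == 0.0

    def test_phase_swap_invariance(self, rng):
        pairs = rng.standard_normal((20, 2))
        swapped = pairs[:, ::-1]
        assert consistency(pairs) == pytest.approx(consistency(swapped), abs=1e-12)
        assert reversal(pairs) == pytest.approx(reversal(swapped))

    def test_global_sign_flip_preserves_both(self, rng):
        pairs = rng.standard_normal((25, 2))
        assert consistency(-pairs) == pytest.approx(consistency(pairs), abs=1e-12)
        assert reversal(-pairs) == pytest.approx(reversal(pairs))

    def test_sign_zero_counts_positive(self):
        assert reversal([(0.0, 1.0)]) == 0.0
        assert reversal([(0.0, -1.0)]) == 1.0

    def test_incomplete_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="incomplete"):
            assert consistency([(1.0, np.nan), (2.0, 1.0)]) == 1.0

    def test_reversal_bounded(self, rng):
        for _ in range(20):
            pairs = rng.standard_normal((10, 2))
            assert 0.0 <= reversal(pairs) <= 1.0


class TestInterannualConsistency:
    def test_hand_examples(self):
        assert interannual_consistency([[1, 2, 4]]) == pytest.approx(1.5)
        assert interannual_consistency([[3, 3, 3], [5, 5]]) == 0.0
        assert interannual_consistency([[0, 1], [0, 3]]) == pytest.approx(2.0)

    def test_short_sequences_excluded(self):
        with pytest.warns(UserWarning, match="< 2 years"):
            assert interannual_consistency([[1.0], [0, 2]]) == 2.0

    def test_all_short_rejected(self):
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            interannual_consistency([[1.0]])


class TestPropagateUncertainty:
    def _records(self, x, se):
        return pd.DataFrame(
            {
                "individual": [f"id{i}" for i in range(len(x))],
                "year": 1,
                "phase": "prospecting",
                "cluster": "all",
                "x": x,
                "se": se,
            }
        )

    def test_zero_se_collapses_to_point(self):
        recs = self._records([0.4, -1.2, 0.9], [0.0, 0.0, 0.0])
        dists = propagate_uncertainty(recs, n_sim=50, seed=0)
        for d in dists:
            assert np.all(d.replicates == d.point)

    def test_replicate_spread_matches_se(self):
        recs = self._records([0.0], [1.0])
        (d,) = propagate_uncertainty(recs, metrics=("average",), n_sim=100_000, seed=1)
        assert abs(d.replicates.std(ddof=1) - 1.0) < 0.02

    def test_replicate_mean_unbiased_for_average(self):
        recs = self._records([0.7, -0.3, 1.1], [0.5, 0.5, 0.5])
        (d,) = propagate_uncertainty(recs, metrics=("average",), n_sim=100_000, seed=2)
        mc_se = 0.5 / np.sqrt(3) / np.sqrt(100_000)
        assert abs(d.replicates.mean() - d.point) < 4 * mc_se

    def test_deterministic_per_seed(self):
        recs = self._records([0.1, 0.2, 0.3], [0.2, 0.2, 0.2])
        a = propagate_uncertainty(recs, n_sim=20, seed=7)
        b = propagate_uncertainty(recs, n_sim=20, seed=7)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.replicates, db.replicates)

    def test_groups_split_by_cluster(self):
        recs = pd.concat(
            [
                self._records([1.0, 1.0], [0.0, 0.0]).assign(cluster="lowland"),
                self._records([-1.0, -1.0], [0.0, 0.0]).assign(cluster="upland"),
            ]
        )
        dists = propagate_uncertainty(recs, metrics=("average",), n_sim=5, seed=0, by=["cluster"])
        points = {d.group: d.point for d in dists}
        assert points == {"lowland": 1.0, "upland": -1.0}

    def test_nonconverged_records_excluded(self):
        recs = self._records([0.5, 5.0], [0.1, 0.1]).assign(converged=[True, False])
        with pytest.warns(UserWarning, match="non-converged"):
            (d,) = propagate_uncertainty(recs, metrics=("average",), n_sim=5, seed=0)
        assert d.point == 0.5


class TestCompareGroups:
    def _dist(self, group, values):
        values = np.asarray(values, dtype=float)
        return MetricDistribution("average", group, float(values.mean()), values)

    def test_identical_groups_share_a_letter(self, rng):
        reps = rng.standard_normal(50)
        out = compare_groups([self._dist("a", reps), self._dist("b", reps)])
        assert out["anova"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["letters"] == {}  # omnibus not significant => no letters

    def test_separated_groups_get_distinct_letters(self, rng):
        a = rng.normal(0, 0.01, 60)
        out = compare_groups([self._dist("a", a), self._dist("b", a + 10)])
        assert out["anova"]["p"] < 1e-6
        assert set(out["letters"]["a"]).isdisjoint(out["letters"]["b"])

    def test_f_statistic_matches_textbook_formula(self, rng):
        groups = {g: rng.normal(m, 1.0, 5) for g, m in zip("abc", (0.0, 1.0, 3.0))}
        out = compare_groups([self._dist(g, v) for g, v in groups.items()])
        # closed-form one-way ANOVA
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(5 * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        F = (ssb / 2) / (ssw / 12)
        assert out["anova"]["F"] == pytest.approx(F, rel=1e-9)

    def test_two_way_design(self, rng):
        dists = [
            self._dist(f"{hab}:{ph}", rng.normal(m, 0.05, 30))
            for (hab, ph), m in zip(
                [("low", "p"), ("low", "s"), ("high", "p"), ("high", "s")],
                (0.0, 0.1, 2.0, 2.2),
            )
        ]
        out = compare_groups(dists, design="two-way")
        assert out["anova"]["p_factor1"] < 1e-6

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_groups([self._dist("a", rng.standard_normal(5))])


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        out = compact_letter_display(["a", "b", "c"], set())
        assert len({v for v in out.values()}) == 1

    def test_chain_structure(self):
        # a differs from c; b bridges both
        out = compact_letter_display(["a", "b", "c"], {("a", "c")})
        assert set(out["a"]).isdisjoint(out["c"])
        assert set(out["b"]) & set(out["a"])
        assert set(out["b"]) & set(out["c"])

    def test_all_distinct(self):
        groups = ["a", "b", "c"]
        differ = {("a", "b"), ("a", "c"), ("b", "c")}
        out = compact_letter_display(groups, differ)
        letters = [out[g] for g in groups]
        assert len(set(letters)) == 3
        for i, g in enumerate(groups):
            for j, h in enumerate(groups):
                if i != j:
                    assert set(out[g]).isdisjoint(out[h])


class TestMetricRecoveryFromSimulatedTables:
    def test_bimodal_population(self):
        """A ±1 bimodal population: average ~0 but specialization ~1."""
        rng = np.random.default_rng(5)
        n = 400
        x = rng.choice([-1.0, 1.0], n) + rng.normal(0, 0.1, n)
        assert abs(average(x)) < 3 * np.sqrt((1 + 0.01) / n)
        assert specialization(x) == pytest.approx(1.0, abs=0.05)
        assert heterogeneity(x) == pytest.approx(np.sqrt(1 + 0.01), abs=0.08)

    def test_independent_phase_signs_give_half_reversal(self):
        rng = np.random.default_rng(6)
        pairs = rng.choice([-1.0, 1.0], size=(1000, 2))
        assert reversal(pairs) == pytest.approx(0.5, abs=0.05)

    def test_simulated_coefficient_table_feeds_metrics(self):
        recs = simulate_coefficients(100, mean=0.7, sd=0.2, se_scale=0.05, seed=3)
        dists = propagate_uncertainty(recs, metrics=("average",), n_sim=200, seed=4)
        (d,) = dists
        assert d.point == pytest.approx(0.7, abs=0.1)
        lo, hi = d.quantiles()
        assert lo < d.point < hi
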