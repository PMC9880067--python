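import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import genesieve as gs
from genesieve import scoring


def make_stats(m1, m2, s1, s2, n1=10, n2=10):
    to_arr = lambda x: np.atleast_1d(np.asarray(x, dtype=float))
    k = len(to_arr(m1))
    return scoring.ClassStats(tuple(f"g{i}" for i in range(k)),
                              to_arr(m1), to_arr(m2), to_arr(s1), to_arr(s2),
                              n1, n2)


# --- literal single-gene transcriptions of the printed formulas (oracles) ---

def bd_literal(m1, m2, s1, s2):
    return ((m1 - m2) ** 2 / (8 * (s1**2 + s2**2))
            + 0.5 * math.log((s1**2 + s2**2) / (2 * s1 * s2)))


def ratio_literal(m1, m2, s1, s2, printed):
    den = (s1 - s2) if printed else (s1 + s2)
    return (m1 - m2) / den


def fisher_literal(m1, m2, s1, s2, printed):
    den = (s1**2 - s2**2) if printed else (s1**2 + s2**2)
    return (m1 - m2) ** 2 / den


def t_literal(m1, m2, v1, v2, n1, n2):
    return (m1 - m2) / math.sqrt(v1 / n1 + v2 / n2)


class TestClassStats:
    def test_hand_example(self):
        m = gs.ExpressionMatrix(("g0", "g1"), ("a", "b", "c", "d"),
                                [[0.0, 2.0, 1.0, 3.0], [5.0, 5.0, 5.0, 5.0]])
        labels = gs.ClassLabels({"a": "A", "b": "A", "c": "B", "d": "B"})
        stats = gs.class_stats(m, labels)
        np.testing.assert_allclose(stats.mean_pos, [1.0, 5.0])
        np.testing.assert_allclose(stats.mean_neg, [2.0, 5.0])
        np.testing.assert_allclose(stats.sd_pos, [math.sqrt(2), 0.0])
        np.testing.assert_allclose(stats.sd_neg, [math.sqrt(2), 0.0])
        assert stats.n_pos == stats.n_neg == 2

    def test_class_swap_symmetry(self, tiny_matrix, tiny_labels):
        a = gs.class_stats(tiny_matrix, tiny_labels)
        swapped = gs.ClassLabels(tiny_labels.assignments, positive_class="B")
        b = gs.class_stats(tiny_matrix, swapped)
        np.testing.assert_array_equal(a.mean_pos, b.mean_neg)
        np.testing.assert_array_equal(a.sd_pos, b.sd_neg)

    def test_single_sample_class_rejected(self, tiny_matrix):
        labels_dict = {s: ("A" if j == 0 else "B")
                       for j, s in enumerate(tiny_matrix.sample_ids)}
        with pytest.raises(gs.data_io.ValidationError):
            gs.ClassLabels(labels_dict)


class TestBhattacharyya:
    @pytest.mark.parametrize("m1,m2,s1,s2,expected", [
        (3.0, 3.0, 1.5, 1.5, 0.0),
        (0.0, 1.0, 1.0, 1.0, 0.0625),
        (2.0, 2.0, 1.0, 2.0, 0.5 * math.log(5 / 4)),
    ])
    def test_hand_values(self, m1, m2, s1, s2, expected):
        table = gs.bhattacharyya_score(make_stats(m1, m2, s1, s2))
        assert table.scores[0] == pytest.approx(expected, abs=1e-12)
        assert table.direction == scoring.HIGHER

    def test_zero_variance_flagged_not_fatal(self):
        table = gs.bhattacharyya_score(make_stats([1, 1], [2, 2], [0, 1], [1, 1]))
        assert table.degenerate[0] and not table.degenerate[1]

    def test_oracle_equivalence_random_tuples(self):
        rng = np.random.default_rng(42)
        m1, m2 = rng.normal(size=(2, 100))
        s1, s2 = rng.uniform(0.1, 3.0, size=(2, 100))
        table = gs.bhattacharyya_score(make_stats(m1, m2, s1, s2))
        expected = [bd_literal(*t) for t in zip(m1, m2, s1, s2)]
        np.testing.assert_allclose(table.scores, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(m1=st.floats(-5, 5), m2=st.floats(-5, 5),
           s1=st.floats(0.1, 3), s2=st.floats(0.1, 3),
           a=st.floats(0.1, 4), b=st.floats(-10, 10))
    def test_affine_invariance(self, m1, m2, s1, s2, a, b):
        """A common affine map a*x+b of both classes leaves Bd unchanged."""
        base = gs.bhattacharyya_score(make_stats(m1, m2, s1, s2)).scores[0]
        moved = gs.bhattacharyya_score(
            make_stats(a * m1 + b, a * m2 + b, a * s1, a * s2)).scores[0]
        assert moved == pytest.approx(base, abs=1e-10)


class TestDiscretization:
    def test_hand_values(self):
        disc = gs.discretize_gene(np.array([0.0, 5.0, 10.0]))
        np.testing.assert_array_equal(disc.levels, [0, 10, 20])

    def test_endpoints_map_to_extremes(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            vals = rng.normal(size=30)
            disc = gs.discretize_gene(vals)
            assert disc.levels[np.argmin(vals)] == 0
            assert disc.levels[np.argmax(vals)] == 20
            assert disc.levels.min() >= 0 and disc.levels.max() <= 20

    def test_constant_gene_degenerate(self):
        assert gs.discretize_gene(np.full(5, 3.3)).degenerate

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.01, 100), b=st.floats(-1e3, 1e3))
    def test_positive_affine_invariance(self, a, b):
        vals = np.array([0.1, 0.9, 1.7, 2.4, 4.0, 2.2])
        base = gs.discretize_gene(vals).levels
        moved = gs.discretize_gene(a * vals + b).levels
        np.testing.assert_array_equal(base, moved)

    def test_round_half_up(self):
        # 20*(x-0)/20 + .5 -> level floor(x + .5)
        vals = np.array([0.0, 0.5, 1.49, 1.5, 20.0])
        np.testing.assert_array_equal(gs.discretize_gene(vals).levels,
                                      [0, 1, 1, 2, 20])


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ([0, 7, 0], 0.0),
        ([3, 3], 0.5),
        ([1] * 21, 1 - 21 * (1 / 21) ** 2),
    ])
    def test_level_impurity(self, counts, expected):
        assert gs.gini_level(np.array(counts)) == pytest.approx(expected, abs=1e-12)

    def test_level_impurity_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 10, size=21)
            if counts.sum() == 0:
                continue
            assert 0.0 <= gs.gini_level(counts) <= 20 / 21

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            gs.gini_level(np.zeros(21))

    def test_weighted_average_of_class_impurities(self):
        # class A levels pure (one level), class B two equal levels:
        # weights 1/2 each -> 0.5*0 + 0.5*0.5 = 0.25
        m = gs.ExpressionMatrix(
            ("g0", "pad"), ("a", "b", "c", "d"),
            [[0.0, 0.0, 10.0, 20.0], [1.0, 2.0, 3.0, 4.0]])
        labels = gs.ClassLabels({"a": "A", "b": "A", "c": "B", "d": "B"})
        table = gs.gini_score(m, labels)
        assert table.scores[0] == pytest.approx(0.25, abs=1e-12)
        assert table.direction == scoring.LOWER

    def test_class_pure_levels_score_zero(self):
        m = gs.ExpressionMatrix(("g0", "pad"), ("a", "b", "c", "d"),
                                [[0.0, 0.0, 9.0, 9.0], [1.0, 2.0, 3.0, 4.0]])
        labels = gs.ClassLabels({"a": "A", "b": "A", "c": "B", "d": "B"})
        assert gs.gini_score(m, labels).scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_propagates_degenerate(self):
        m = gs.ExpressionMatrix(("g0", "g1"), ("a", "b", "c", "d"),
                                [[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]])
        labels = gs.ClassLabels({"a": "A", "b": "A", "c": "B", "d": "B"})
        table = gs.gini_score(m, labels)
        assert table.degenerate[0] and not table.degenerate[1]


class TestMeanDifferenceFilters:
    def test_snr_hand_values(self):
        stats = make_stats(1.0, 0.0, 2.0, 1.0)
        assert gs.snr_score(stats, "as_printed").scores[0] == pytest.approx(1.0)
        assert gs.snr_score(stats, "standard_sum").scores[0] == pytest.approx(1 / 3)

    def test_fsc_hand_values(self):
        stats = make_stats(2.0, 0.0, 3.0, 1.0)
        assert gs.fsc_score(stats, "as_printed").scores[0] == pytest.approx(1.0)
        assert gs.fsc_score(stats, "standard_sum").scores[0] == pytest.approx(0.5)

    def test_fisher_hand_values(self):
        stats = make_stats(1.0, 0.0, math.sqrt(2), 1.0)
        assert gs.fisher_score(stats, "as_printed").scores[0] == pytest.approx(1.0)
        assert gs.fisher_score(stats, "standard_sum").scores[0] == pytest.approx(1 / 3)

    def test_equal_spread_degenerate_only_as_printed(self):
        stats = make_stats(1.0, 0.0, 1.5, 1.5)
        assert gs.snr_score(stats, "as_printed").degenerate[0]
        assert not gs.snr_score(stats, "standard_sum").degenerate[0]
        assert gs.fisher_score(stats, "as_printed").degenerate[0]

    def test_no_mean_separation_scores_zero(self):
        stats = make_stats(2.0, 2.0, 2.0, 1.0)
        for fn in (gs.snr_score, gs.fsc_score, gs.fisher_score):
            for variant in ("as_printed", "standard_sum"):
                assert fn(stats, variant).scores[0] == 0.0

    def test_oracle_equivalence_random_tuples(self):
        rng = np.random.default_rng(5)
        m1, m2 = rng.normal(size=(2, 100))
        s1, s2 = rng.uniform(0.1, 3.0, size=(2, 100))
        stats = make_stats(m1, m2, s1, s2)
        for printed, variant in ((True, "as_printed"), (False, "standard_sum")):
            np.testing.assert_allclose(
                gs.snr_score(stats, variant).scores,
                [ratio_literal(*t, printed) for t in zip(m1, m2, s1, s2)],
                atol=1e-12)
            np.testing.assert_allclose(
                gs.fisher_score(stats, variant).scores,
                [fisher_literal(*t, printed) for t in zip(m1, m2, s1, s2)],
                atol=1e-12)


class TestTStatistic:
    def test_hand_value(self):
        # means 1 vs 0, unit variances, n=4 each -> t = 1/sqrt(0.5)
        rng = np.random.default_rng(3)
        base = rng.normal(size=4)
        base = (base - base.mean()) / base.std(ddof=1)  # mean 0, var 1 exactly
        m = gs.ExpressionMatrix(("g0", "pad"),
                                tuple(f"s{j}" for j in range(8)),
                                np.vstack([np.concatenate([base + 1.0, base]),
                                           np.arange(8.0)]))
        labels = gs.ClassLabels({f"s{j}": ("A" if j < 4 else "B")
                                 for j in range(8)})
        table = gs.t_statistic_score(m, labels)
        assert table.scores[0] == pytest.approx(t_literal(1, 0, 1, 1, 4, 4),
                                                abs=1e-10)
        assert table.scores[0] == pytest.approx(1 / math.sqrt(0.5), abs=1e-10)

    def test_class_swap_flips_sign(self, tiny_matrix, tiny_labels):
        a = gs.t_statistic_score(tiny_matrix, tiny_labels)
        swapped = gs.ClassLabels(tiny_labels.assignments, positive_class="B")
        b = gs.t_statistic_score(tiny_matrix, swapped)
        np.testing.assert_allclose(a.scores, -b.scores, atol=1e-12)
        np.testing.assert_allclose(a.ranking_values(), b.ranking_values(),
                                   atol=1e-12)

    def test_constant_equal_gene_scores_zero(self):
        m = gs.ExpressionMatrix(("g0", "pad"), ("a", "b", "c", "d"),
                                [[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]])
        labels = gs.ClassLabels({"a": "A", "b": "A", "c": "B", "d": "B"})
        assert gs.t_statistic_score(m, labels).scores[0] == 0.0


def test_planted_genes_outscore_nulls_on_average(benchmark_dataset):
    """Mean Bhattacharyya of planted informative genes exceeds nulls."""
    ds = benchmark_dataset
    table = gs.bhattacharyya_score(gs.class_stats(ds.matrix, ds.labels))
    mask = np.array([g in ds.truth for g in table.gene_ids])
    assert np.nanmean(table.scores[mask]) > 3 * np.nanmean(table.scores[~mask])
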