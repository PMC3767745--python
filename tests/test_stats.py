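"""Pearson inference and the two-group edge-wise permutation test."""

import math

import numpy as np
import pytest

from ssvepnet import group_permutation_test, metric_snr_correlations, pearson
from ssvepnet.graph_metrics import TopologyMetrics
from ssvepnet.stats import METRIC_COLUMNS, pearson_vectorized

from conftest import make_network


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(5.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        r, p = pearson(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        # two-sided p from the t transform with n-2 df
        from scipy.stats import t as t_dist
        t = expected * math.sqrt(3 / (1 - expected**2))
        assert p == pytest.approx(2 * t_dist.sf(abs(t), df=3), abs=1e-12)

    def test_degenerate_inputs_signal(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="3 observations"):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="non-finite"):
            pearson([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])

    def test_vectorized_agrees_with_scalar(self, rng):
        X = rng.normal(size=(9, 20))
        y = rng.normal(size=9)
        r_vec, p_vec = pearson_vectorized(X, y)
        for j in range(20):
            r, p = pearson(X[:, j], y)
            assert r_vec[j] == pytest.approx(r, abs=1e-12)
            assert p_vec[j] == pytest.approx(p, abs=1e-12)

    def test_vectorized_degenerate_column_is_nan(self, rng):
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        r, p = pearson_vectorized(X, rng.normal(size=5))
        assert np.isnan(r[0]) and p[0] == 1.0
        assert np.isfinite(r[1])


class TestMetricSnrCorrelations:
    def metrics_for(self, values):
        return [
            TopologyMetrics(
                clustering=v, clustering_per_node=np.zeros(3),
                path_length=1 / v, global_eff=v, local_eff=v,
                local_eff_per_node=np.zeros(3),
            )
            for v in values
        ]

    def test_one_row_per_metric_with_expected_signs(self):
        snr = np.array([1.0, 2, 3, 4, 5])
        table = metric_snr_correlations(
            self.metrics_for(snr / 10), snr / 5, snr, "12.5Hz", 0
        )
        assert set(table.metric) == set(METRIC_COLUMNS)
        assert (table.n == 5).all()
        by = table.set_index("metric")
        assert by.loc["clustering", "r"] == pytest.approx(1.0)
        assert by.loc["path_length", "r"] < 0

    def test_constant_metric_reported_as_nan_not_fatal(self):
        snr = np.array([1.0, 2, 3, 4])
        table = metric_snr_correlations(
            self.metrics_for([0.5] * 4), snr / 5, snr, "x", 1
        )
        assert np.isnan(table.set_index("metric").loc["clustering", "r"])

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            metric_snr_correlations(self.metrics_for([1, 2]), [1], [1, 2], "x", 0)


def group_of(rng, n_subjects, shift=0.0, labels=("a", "b", "c", "d")):
    nets = []
    for _ in range(n_subjects):
        w = np.triu(rng.uniform(0.2, 0.8, size=(4, 4)), k=1)
        w[0, 1] = np.clip(w[0, 1] + shift, 0, 1)
        w = w + w.T
        nets.append(make_network(w, labels=labels))
    return nets


class TestGroupPermutationTest:
    def test_exact_mode_enumerates_all_splits_of_four_plus_four(self, rng):
        res = group_permutation_test(
            group_of(rng, 4), group_of(rng, 4), method="exact"
        )
        assert res.method == "exact"
        assert res.n_permutations == 70  # C(8, 4)
        assert np.all(res.p > 0)
        assert np.all(res.p >= 1 / 70 - 1e-12)

    def test_auto_selects_exact_for_small_groups(self, rng):
        res = group_permutation_test(group_of(rng, 4), group_of(rng, 4))
        assert res.method == "exact"

    def test_sampled_p_strictly_positive_with_smoothing(self, rng):
        res = group_permutation_test(
            group_of(rng, 4), group_of(rng, 4), n_perm=200, method="sampled",
            seed=0,
        )
        assert np.all(res.p >= 1 / 201)

    def test_group_relabelling_flips_the_tail(self, rng):
        a, b = group_of(rng, 4), group_of(rng, 4)
        ab = group_permutation_test(a, b, method="exact")
        ba = group_permutation_test(b, a, method="exact")
        assert np.allclose(ab.observed_diff, -ba.observed_diff)
        assert np.allclose(ab.p, ba.p)

    def test_planted_shift_reaches_minimum_attainable_p(self, rng):
        a = group_of(rng, 4, shift=0.9)  # edge (a, b) saturated high
        b = group_of(rng, 4, shift=-0.9)  # edge (a, b) floored low
        res = group_permutation_test(a, b, method="exact")
        i = res.edges.index(("a", "b"))
        assert res.p[i] == pytest.approx(1 / 70)

    def test_sampled_agrees_with_exact(self, rng):
        a = group_of(rng, 4, shift=0.3)
        b = group_of(rng, 4)
        exact = group_permutation_test(a, b, method="exact")
        sampled = group_permutation_test(
            a, b, n_perm=5000, method="sampled", seed=11
        )
        assert np.max(np.abs(exact.p - sampled.p)) < 0.03

    def test_type_one_error_calibrated_under_exchangeability(self, rng):
        """Groups from one distribution: the realized level matches theory.

        The tail is chosen from the sign of the observed difference, so
        'p < 0.05' is effectively a two-sided test at the attainable exact
        levels: P(p < 0.05) = 2 * 3/70 (atoms 1/70, 2/70, 3/70 in each
        tail), about 0.086, not the naive 0.05.
        """
        hits, total = 0, 0
        for _ in range(150):
            res = group_permutation_test(
                group_of(rng, 4), group_of(rng, 4), method="exact"
            )
            hits += int((res.p < 0.05).sum())
            total += res.p.size
        frac = hits / total
        assert frac == pytest.approx(6 / 70, abs=0.025)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            group_permutation_test([], group_of(rng, 4))
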