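"""Duration analytics: KDE PDFs, KS/Wilcoxon tests, response metric, clustering."""

import itertools

import numpy as np
import pytest

from groomkit.grooming_stats import (
    DurationDistribution,
    build_distribution,
    cluster_points,
    compare_totals,
    kde_on_grid,
    ks_compare,
    ks_table,
    response_metric,
)

PEAK = 1.0 / (3.0 * np.sqrt(2.0 * np.pi))  # single-point KDE maximum, bw = 3


class TestKde:
    def test_single_duration_peak_closed_form(self):
        dist = build_distribution([40.0], ("d", "left", "post_drug"))
        assert dist.pdf_at(40.0) == pytest.approx(PEAK, rel=1e-9)
        assert dist.pdf_at(16.0) < 1e-8  # 8 bandwidths away

    def test_full_line_integral_is_one(self):
        rng = np.random.default_rng(0)
        durations = rng.uniform(5, 95, 40)
        grid = np.arange(-40.0, 141.0, 0.25)
        pdf = kde_on_grid(durations, 3.0, grid)
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-6)

    def test_translation_equivariance(self):
        durations = np.array([12.0, 30.0, 55.5])
        grid = np.linspace(0, 80, 161)
        a = kde_on_grid(durations, 3.0, grid)
        b = kde_on_grid(durations + 7.0, 3.0, grid + 7.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_pre_drug_weight_halves_counts(self):
        dist = build_distribution([10.0] * 10, ("d", "left", "pre_drug"))
        assert dist.weight == 0.5
        assert dist.effective_count == 5.0
        assert dist.histogram.sum() == pytest.approx(5.0)

    def test_long_episodes_excluded(self):
        dist = build_distribution([50.0, 120.0, 930.0], ("d", "left", "post_drug"))
        assert list(dist.durations) == [50.0]

    def test_empty_cell_marker(self):
        dist = build_distribution([], ("d", "left", "post_drug"))
        assert dist.is_empty and dist.pdf is None

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_distribution([10.0, 0.0], ("d", "left", "post_drug"))


class TestKsCompare:
    def test_identical_samples(self):
        stat, p = ks_compare([1, 2, 3], [1, 2, 3])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_ecdf_gap(self):
        stat, _ = ks_compare([1, 2, 3], [1, 2, 3, 100])
        assert stat == pytest.approx(0.25)

    def test_matches_brute_force_ecdf_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a = rng.uniform(0, 100, rng.integers(3, 30))
            b = rng.uniform(0, 100, rng.integers(3, 30))
            stat, _ = ks_compare(a, b)
            xs = np.concatenate([a, b])
            gap = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in xs
            )
            assert stat == pytest.approx(gap, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(1, 50, 20), rng.uniform(1, 50, 25)
        assert ks_compare(a, b)[0] == pytest.approx(
            ks_compare(np.exp(a / 10), np.exp(b / 10))[0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_compare([], [1.0])


class TestCompareTotals:
    def test_identical_pairs_give_p_one(self):
        assert compare_totals([3, 4, 5], [3, 4, 5]) == 1.0

    def test_exact_p_matches_sign_flip_enumeration(self):
        a = np.array([12.0, 9.0, 15.0, 4.0, 22.0, 7.0])
        b = np.array([10.0, 11.0, 9.0, 6.0, 15.0, 2.0])
        p = compare_totals(a, b)
        # enumeration oracle over all 2^6 sign assignments of |d| ranks
        d = a - b
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=6)
        ]
        ws = np.array(ws)
        p_oracle = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        assert p == pytest.approx(p_oracle)

    def test_two_sided_p_symmetric_under_swap(self):
        a = [10.0, 14.0, 9.0, 20.0]
        b = [12.0, 11.0, 16.0, 8.0]
        assert compare_totals(a, b) == pytest.approx(compare_totals(b, a))

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compare_totals([1, 2], [1, 2, 3])


class TestResponseMetric:
    def _dist(self, pdf):
        return DurationDistribution(
            cell=("d", "left", "post_drug"), durations=np.array([1.0]), weight=1.0,
            bandwidth=3.0, histogram=np.zeros(100), pdf=pdf)

    def test_uniform_pdf_reads_uniform_values(self):
        point = response_metric(self._dist(np.full(100, 0.01)))
        assert point.y16 == pytest.approx(0.01) and point.y40 == pytest.approx(0.01)

    def test_single_point_kde_ordinates(self):
        dist = build_distribution([40.0], ("d", "left", "post_drug"))
        point = response_metric(dist)
        assert point.y40 == pytest.approx(PEAK, rel=1e-9)
        assert point.y16 < 1e-8

    def test_mixture_weights_order_the_ordinates(self):
        from groomkit.synthetic import sample_duration_dataset

        heavy_long = sample_duration_dataset(600, [(16, 3, 0.2), (40, 3, 0.8)], seed=3)
        heavy_short = sample_duration_dataset(600, [(16, 3, 0.8), (40, 3, 0.2)], seed=3)
        p_long = response_metric(
            build_distribution(heavy_long, ("d", "left", "post_drug")))
        p_short = response_metric(
            build_distribution(heavy_short, ("d", "left", "post_drug")))
        assert p_long.y40 > p_long.y16
        assert p_short.y16 > p_short.y40

    def test_metric_is_continuous_in_the_data(self):
        durations = np.linspace(5, 95, 30)
        base = response_metric(build_distribution(durations, ("d", "l", "post_drug")))
        bumped = durations.copy()
        bumped[10] += 1e-3
        after = response_metric(build_distribution(bumped, ("d", "l", "post_drug")))
        assert abs(after.y16 - base.y16) < 1e-5
        assert abs(after.y40 - base.y40) < 1e-5

    def test_off_grid_duration_rejected(self):
        dist = build_distribution([40.0], ("d", "left", "post_drug"))
        with pytest.raises(ValueError, match="grid"):
            dist.pdf_at(16.5)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            response_metric(build_distribution([], ("d", "l", "post_drug")))


class TestClustering:
    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal([0, 0], 0.05, (20, 2))
        b = rng.normal([5, 5], 0.05, (20, 2))
        res = cluster_points(np.vstack([a, b]), k=2, seed=0)
        assert res.silhouette > 0.9
        assert len(set(res.labels[:20])) == 1 and len(set(res.labels[20:])) == 1
        assert res.labels[0] != res.labels[20]

    def test_k_one_centroid_is_mean(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        res = cluster_points(pts, k=1, seed=0)
        np.testing.assert_allclose(res.centroids[0], [1.0, 1.0])
        assert np.isnan(res.silhouette)

    def test_silhouette_matches_hand_computation(self):
        # two tight pairs: for each point a = dist to its partner,
        # b = mean dist to the other pair; s = (b - a) / max(a, b)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        res = cluster_points(pts, k=2, seed=0)
        dists = np.abs(pts[:, 0][:, None] - pts[:, 0][None, :])
        expected = []
        for i, partner, others in ((0, 1, (2, 3)), (1, 0, (2, 3)),
                                   (2, 3, (0, 1)), (3, 2, (0, 1))):
            a = dists[i, partner]
            b = dists[i, list(others)].mean()
            expected.append((b - a) / max(a, b))
        assert res.silhouette == pytest.approx(np.mean(expected))

    def test_two_sd_ellipses_cover_cluster_spread(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1.0, (200, 2))
        res = cluster_points(pts, k=1, seed=0)
        semi = res.ellipses[0]["semi_axes"]
        assert np.all(semi > 1.5) and np.all(semi < 2.5)  # ~2 SD of unit noise

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_points(np.zeros((3, 2)), k=4)


class TestKsTable:
    def test_layout_and_mean_row(self):
        rng = np.random.default_rng(6)
        cells = {}
        for ds in ("A", "B"):
            for role in ("experimental", "control"):
                for cond in ("pre_drug", "post_drug"):
                    cells[(ds, role, cond)] = rng.uniform(1, 100, 30)
        table = ks_table(cells)
        assert list(table["dataset"]) == ["A", "B", "Mean"]
        cols = ["across_pre", "across_post", "same_experimental", "same_control"]
        for col in cols:
            assert table[col].iloc[-1] == pytest.approx(table[col].iloc[:2].mean())
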