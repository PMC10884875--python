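"""Connectomes, FC-TRC, ICC(2,1), bands, deltas, group summaries."""

import numpy as np
import pytest

from fcreliab import (
    classify_icc,
    delta_map,
    fc_trc,
    group_summary,
    icc_2_1,
    parcel_icc_map,
    pearson_connectome,
    simulate_edge_table,
    split_half,
)
from fcreliab.datatypes import Connectome, ReliabilityMap, SplitHalfPair
from fcreliab.reliability import edgewise_icc

from conftest import make_run


def brute_pearson(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


class TestPearsonConnectome:
    def test_scaled_copy_is_perfectly_correlated(self, rng):
        a = rng.normal(size=50)
        c = pearson_connectome(np.column_stack([a, 2 * a]))
        assert c.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_copy_is_anticorrelated(self, rng):
        a = rng.normal(size=50)
        c = pearson_connectome(np.column_stack([a, -a]))
        assert c.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_elementwise_loop_oracle(self, rng):
        x = rng.normal(size=(4, 3))
        c = pearson_connectome(x)
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else brute_pearson(x[:, i], x[:, j])
                assert c.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_unit_is_missing_not_zero(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 4.0
        c = pearson_connectome(x)
        assert np.isnan(c.matrix[0, 1]) and np.isnan(c.matrix[1, 2])
        assert np.isfinite(c.matrix[0, 2])

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="3 frames"):
            pearson_connectome(rng.normal(size=(2, 4)))


class TestSplitHalf:
    def test_ten_sessions_split_first_and_last_five(self, rng):
        series = [rng.normal(size=(30, 4)) for _ in range(10)]
        pair = split_half(series)
        assert pair.first.provenance["sessions"] == [1, 2, 3, 4, 5]
        assert pair.second.provenance["sessions"] == [6, 7, 8, 9, 10]

    def test_two_sessions_split_one_each(self, rng):
        pair = split_half([rng.normal(size=(30, 4)) for _ in range(2)])
        assert pair.first.provenance["sessions"] == [1]
        assert pair.second.provenance["sessions"] == [2]

    def test_identical_sessions_give_equal_halves(self, rng):
        x = rng.normal(size=(40, 5))
        pair = split_half([x, x, x.copy(), x])
        assert np.allclose(pair.first.matrix, pair.second.matrix, atol=1e-12)

    def test_odd_session_count_requires_explicit_split(self, rng):
        series = [rng.normal(size=(20, 3)) for _ in range(3)]
        with pytest.raises(ValueError, match="odd"):
            split_half(series)
        pair = split_half(series, split=((0,), (1, 2)))
        assert pair.second.provenance["sessions"] == [2, 3]


class TestFcTrc:
    def test_identical_connectomes_give_unity(self, rng):
        c = pearson_connectome(rng.normal(size=(60, 6)))
        m = fc_trc(SplitHalfPair(first=c, second=c))
        assert np.allclose(m.values, 1.0, atol=1e-12)

    def test_negated_off_diagonal_gives_minus_one(self, rng):
        c = pearson_connectome(rng.normal(size=(60, 6)))
        neg = -c.matrix
        np.fill_diagonal(neg, 1.0)
        m = fc_trc(SplitHalfPair(first=c, second=Connectome(neg)))
        assert np.allclose(m.values, -1.0, atol=1e-12)

    def test_four_unit_toy_matches_row_loop_oracle(self, rng):
        a = pearson_connectome(rng.normal(size=(30, 4)))
        b = pearson_connectome(rng.normal(size=(30, 4)))
        m = fc_trc(SplitHalfPair(first=a, second=b))
        for u in range(4):
            keep = [v for v in range(4) if v != u]
            expected = brute_pearson(a.matrix[u, keep], b.matrix[u, keep])
            assert m.values[u] == pytest.approx(expected, abs=1e-12)

    def test_missing_units_excluded_pairwise(self, rng):
        x = rng.normal(size=(30, 6))
        y = rng.normal(size=(30, 6))
        x[:, 2] = 1.0  # zero variance in first half only
        m = fc_trc(SplitHalfPair(first=pearson_connectome(x),
                                 second=pearson_connectome(y)))
        assert np.isnan(m.values[2])
        good = [u for u in range(6) if u != 2]
        assert np.isfinite(m.values[good]).all()


class TestIcc21:
    def test_identical_halves_distinct_subjects_give_one(self):
        res = icc_2_1(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.sigma_eps2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_total_variance_is_missing(self):
        res = icc_2_1(np.full((4, 2), 3.7))
        assert np.isnan(res.icc)
        assert res.reason == "zero total variance"

    def test_matches_anova_mean_squares_oracle(self, rng):
        x = rng.normal(size=(5, 2))
        n, k = x.shape
        g = x.mean()
        msr = k * np.sum((x.mean(axis=1) - g) ** 2) / (n - 1)
        msc = n * np.sum((x.mean(axis=0) - g) ** 2) / (k - 1)
        mse = (np.sum((x - g) ** 2) - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_2_1(x).icc == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_shift_and_positive_scale(self, rng):
        x = rng.normal(size=(8, 2))
        base = icc_2_1(x).icc
        assert icc_2_1(x + 100.0).icc == pytest.approx(base, abs=1e-10)
        assert icc_2_1(x * 3.5).icc == pytest.approx(base, abs=1e-10)

    def test_negative_estimates_reported_and_flagged(self):
        # halves anticorrelated across subjects -> negative ICC
        x = np.array([[1.0, 3.0], [3.0, 1.0], [1.1, 2.9], [2.9, 1.1]])
        res = icc_2_1(x)
        assert res.icc < 0
        assert res.negative

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_recovers_planted_variance_ratio(self, rho):
        """Mean ICC over simulated edges within +-0.05 of the planted ratio."""
        table = simulate_edge_table(rho, n_subjects=20, n_edges=500, seed=17)
        iccs = [icc_2_1(table[e]).icc for e in range(table.shape[0])]
        assert np.mean(iccs) == pytest.approx(rho, abs=0.05)


class TestBands:
    @pytest.mark.parametrize(
        "value,band",
        [(0.3, "poor"), (-0.2, "poor"), (0.0, "poor"), (0.4, "poor"),
         (0.45, "fair"), (0.59, "fair"), (0.6, "good"), (0.65, "good"),
         (0.74, "good"), (0.75, "excellent"), (0.9, "excellent")],
    )
    def test_band_edges(self, value, band):
        assert classify_icc(value) == band

    def test_missing_input_gives_missing_output(self):
        assert classify_icc(np.nan) is None


class TestDeltaAndGroup:
    def test_task_equal_rest_gives_zero(self):
        m = ReliabilityMap(np.full(5, 0.5))
        assert np.allclose(delta_map(m, m).values, 0.0)

    def test_constant_offset(self):
        task = ReliabilityMap(np.full(5, 0.7), state="motor")
        rest = ReliabilityMap(np.full(5, 0.5))
        assert np.allclose(delta_map(task, rest).values, 0.2)

    def test_random_pair_matches_subtraction_oracle(self, rng):
        a, b = rng.normal(size=(2, 9))
        d = delta_map(ReliabilityMap(a), ReliabilityMap(b)).values
        for u in range(9):
            assert d[u] == pytest.approx(a[u] - b[u], abs=1e-15)

    def test_group_summary_identical_maps_zero_sd(self):
        maps = [ReliabilityMap(np.array([0.1, 0.5]))] * 3
        mean, sd = group_summary(maps)
        assert np.allclose(sd.values, 0.0)

    def test_group_summary_two_subject_closed_form(self):
        maps = [ReliabilityMap(np.array([0.2])), ReliabilityMap(np.array([0.6]))]
        mean, sd = group_summary(maps)
        assert mean.values[0] == pytest.approx(0.4)
        assert sd.values[0] == pytest.approx(np.sqrt(2 * 0.2**2), abs=1e-12)

    def test_group_mean_invariant_to_subject_order(self, rng):
        maps = [ReliabilityMap(rng.normal(size=6)) for _ in range(4)]
        m1, _ = group_summary(maps)
        m2, _ = group_summary(maps[::-1])
        assert np.allclose(m1.values, m2.values)


class TestEdgewiseAggregation:
    def test_parcel_map_is_mean_of_incident_edges(self):
        # 3 parcels -> edges (0,1), (0,2), (1,2)
        edge_icc = np.array([0.9, 0.3, 0.6])
        pm = parcel_icc_map(edge_icc, 3)
        assert pm[0] == pytest.approx((0.9 + 0.3) / 2)
        assert pm[1] == pytest.approx((0.9 + 0.6) / 2)
        assert pm[2] == pytest.approx((0.3 + 0.6) / 2)

    def test_edgewise_icc_matches_per_edge_calls(self, rng):
        pairs = []
        for _ in range(4):
            pairs.append(SplitHalfPair(
                first=pearson_connectome(rng.normal(size=(20, 4))),
                second=pearson_connectome(rng.normal(size=(20, 4))),
            ))
        edges = edgewise_icc(pairs)
        iu = np.triu_indices(4, k=1)
        for e in range(iu[0].size):
            table = np.array([[p.first.matrix[iu[0][e], iu[1][e]],
                               p.second.matrix[iu[0][e], iu[1][e]]] for p in pairs])
            assert edges[e] == pytest.approx(icc_2_1(table).icc, abs=1e-12)
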