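import numpy as np
import pytest

from _helpers import block_of, planted_block_matrix
from minetkit.errors import (
    DegenerateScaleError,
    InsufficientSpectrumError,
    NormalizationError,
    ParameterError,
    ThresholdError,
    ValidationError,
)
from minetkit.matrix import IndexMatrix
from minetkit.threshold import (
    apply_threshold,
    distance_to_similarity,
    nearest_neighbour_spacings,
    poisson_spacing_test,
    rmt_scan,
    unfold_eigenvalues,
    zscore_outliers,
)


def wigner_sample(n: int, seed: int) -> np.ndarray:
    """Inverse-CDF draws from the Wigner surmise P(s) = (πs/2)e^(−πs²/4)."""
    u = np.random.default_rng(seed).uniform(size=n)
    return np.sqrt(-4.0 / np.pi * np.log(1.0 - u))


class TestUnfolding:
    def test_equally_spaced_gives_unit_spacings(self):
        ev = np.arange(50, dtype=float)
        s = nearest_neighbour_spacings(unfold_eigenvalues(ev))
        assert np.allclose(s, s.mean(), atol=0.05)
        assert s.mean() == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_goe_mean_spacing_near_one(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(200, 200))
        ev = np.linalg.eigvalsh((a + a.T) / np.sqrt(2))
        s = nearest_neighbour_spacings(unfold_eigenvalues(ev))
        assert 0.95 <= s.mean() <= 1.05

    def test_duplicates_collapsed(self):
        ev = np.repeat(np.arange(15, dtype=float), 3)
        unfolded = unfold_eigenvalues(ev)
        assert unfolded.size == 15

    def test_too_few_eigenvalues(self):
        with pytest.raises(InsufficientSpectrumError):
            unfold_eigenvalues(np.arange(5, dtype=float))


class TestPoissonSpacingTest:
    def test_exponential_passes_both(self):
        s = np.random.default_rng(42).exponential(size=5000)
        assert poisson_spacing_test(s, "chisq") > 0.05
        assert poisson_spacing_test(s, "ks") > 0.05

    def test_wigner_fails_both(self):
        s = wigner_sample(5000, seed=42)
        assert poisson_spacing_test(s, "chisq") < 0.01
        assert poisson_spacing_test(s, "ks") < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            poisson_spacing_test([])

    def test_unknown_test_rejected(self):
        with pytest.raises(ParameterError):
            poisson_spacing_test([1.0] * 20, "anderson")

    def test_degenerate_sample_handled(self):
        # all-equal spacings: p computed normally, no special-casing
        p = poisson_spacing_test(np.ones(100), "ks")
        assert 0.0 <= p <= 1.0


class TestRmtScan:
    def test_asymmetric_rejected(self):
        vals = np.array([[0.0, 0.2], [0.8, 0.0]])
        m = IndexMatrix(["a", "b"], vals, symmetric=False)
        with pytest.raises(ValidationError, match="symmetriz"):
            rmt_scan(m)

    def test_out_of_range_values_rejected(self):
        n = 12
        vals = np.full((n, n), 3.0)
        np.fill_diagonal(vals, 0.0)
        m = IndexMatrix([f"x{i}" for i in range(n)], vals, symmetric=True)
        with pytest.raises(NormalizationError, match="distance_to_similarity"):
            rmt_scan(m)

    def test_deterministic(self):
        m = planted_block_matrix(0, n_blocks=4, block_size=10)
        a = rmt_scan(m, "ks")
        b = rmt_scan(m, "ks")
        assert a.thresholds == b.thresholds
        assert a.p_values == b.p_values
        assert a.chosen_threshold == b.chosen_threshold

    def test_edges_monotone_in_threshold(self):
        m = planted_block_matrix(1, n_blocks=4, block_size=10)
        scan = rmt_scan(m, "ks")
        assert all(
            scan.n_edges_kept[i] >= scan.n_edges_kept[i + 1]
            for i in range(len(scan.n_edges_kept) - 1)
        )

    def test_scan_report_frame(self):
        scan = rmt_scan(planted_block_matrix(2, n_blocks=4, block_size=10), "ks")
        df = scan.to_frame()
        assert list(df.columns) == [
            "threshold", "n_nodes", "n_edges", "statistic", "p_value", "chosen",
        ]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_planted_benchmark_transition(self, seed):
        # noise support is [0, 0.5): the smallest cutoff clearing all noise
        # is 0.50 on the 0.01 grid, so the transition lands in [0.50, 0.80]
        m = planted_block_matrix(seed)
        chosen = rmt_scan(m, "ks").chosen_threshold
        assert chosen is not None
        assert 0.50 <= chosen <= 0.80

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_pure_noise_no_structured_threshold(self, seed):
        # an unstructured matrix should yield no cutoff, or one keeping
        # almost no edges; n large enough for the spacing tests to have power
        rng = np.random.default_rng(seed)
        n = 150
        a = rng.uniform(0, 1, size=(n, n))
        a = np.triu(a, 1)
        a = a + a.T
        m = IndexMatrix([f"n{i:03d}" for i in range(n)], a, True, "similarity")
        scan = rmt_scan(m, "ks")
        if scan.chosen_threshold is not None:
            i = scan.thresholds.index(scan.chosen_threshold)
            total_edges = n * (n - 1) / 2
            assert scan.n_edges_kept[i] < 0.10 * total_edges


class TestZscore:
    FIXTURE = [1.0, 2.0, 3.0, 4.0, 100.0]

    def test_standard_fixture(self):
        res = zscore_outliers(self.FIXTURE, method="standard")
        z100 = res.records.z.iloc[-1]
        assert z100 == pytest.approx(78 / np.sqrt(7610 / 4), rel=1e-12)
        assert z100 == pytest.approx(1.788, abs=1e-3)
        assert not res.records.flagged.iloc[-1]

    def test_modified_fixture(self):
        res = zscore_outliers(self.FIXTURE, method="modified")
        z100 = res.records.z.iloc[-1]
        assert z100 == pytest.approx(0.6745 * 97 / 1, rel=1e-12)
        assert z100 == pytest.approx(65.43, abs=0.01)
        assert res.records.flagged.iloc[-1]
        assert res.implied_value_threshold == 100.0

    def test_standard_scores_sum_to_zero(self):
        rng = np.random.default_rng(0)
        res = zscore_outliers(rng.normal(size=500), method="standard")
        assert abs(res.records.z.sum()) < 1e-9

    def test_modified_z_at_median_is_zero(self):
        res = zscore_outliers([1.0, 2.0, 3.0, 4.0, 100.0], method="modified")
        assert res.records.z.iloc[2] == 0.0

    def test_all_equal_standard_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            zscore_outliers([2.0] * 10, method="standard")

    def test_zero_mad_recommends_standard(self):
        with pytest.raises(DegenerateScaleError, match="standard"):
            zscore_outliers([0.0] * 8 + [5.0, 9.0], method="modified")

    def test_matrix_input_uses_upper_triangle(self):
        vals = np.zeros((4, 4))
        pairs = [(0, 1, 0.1), (0, 2, 0.2), (0, 3, 0.3), (1, 2, 0.4),
                 (1, 3, 0.5), (2, 3, 6.0)]
        for i, j, v in pairs:
            vals[i, j] = vals[j, i] = v
        m = IndexMatrix(list("abcd"), vals, symmetric=True)
        res = zscore_outliers(m, method="modified")
        assert len(res.records) == 6
        assert res.records.flagged.sum() == 1

    def test_calibration_standard_vs_modified(self):
        # on a large normal sample the 0.6745 constant aligns flag rates
        x = np.random.default_rng(7).normal(size=100_000)
        f_std = zscore_outliers(x, method="standard").records.flagged.mean()
        f_mod = zscore_outliers(x, method="modified").records.flagged.mean()
        expected = 0.00698  # 2*(1-Phi(2.698))
        assert f_std == pytest.approx(expected, abs=0.002)
        assert f_mod == pytest.approx(expected, abs=0.002)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            zscore_outliers([1.0, 2.0])


class TestDistanceToSimilarity:
    def _distance_matrix(self):
        vals = np.array(
            [[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]]
        )
        return IndexMatrix(list("abc"), vals, symmetric=True, kind="distance")

    def test_min_pair_maps_to_one(self):
        s = distance_to_similarity(self._distance_matrix())
        assert s.values[0, 1] == 1.0

    def test_max_pair_maps_to_zero(self):
        s = distance_to_similarity(self._distance_matrix())
        assert s.values[0, 2] == 0.0

    def test_order_reversed(self):
        d = self._distance_matrix()
        s = distance_to_similarity(d)
        d_off = d.off_diagonal()
        s_off = s.off_diagonal()
        assert np.all(np.argsort(d_off) == np.argsort(-s_off))

    def test_constant_distances_rejected(self):
        vals = np.ones((3, 3)) - np.eye(3)
        m = IndexMatrix(list("abc"), vals, symmetric=True, kind="distance")
        with pytest.raises(NormalizationError):
            distance_to_similarity(m)


class TestApplyThreshold:
    def test_zero_threshold_complete_graph(self):
        m = planted_block_matrix(0, n_blocks=2, block_size=5)
        net = apply_threshold(m, 0.0)
        n = m.n
        assert net.number_of_edges() >= n * (n - 1) / 2 - n  # zeros possible
        assert net.number_of_nodes() == n

    def test_above_max_threshold_errors(self):
        m = planted_block_matrix(0, n_blocks=2, block_size=5)
        with pytest.raises(ThresholdError):
            apply_threshold(m, 1.01)

    def test_planted_matrix_edges_within_blocks(self):
        m = planted_block_matrix(3)
        chosen = rmt_scan(m, "ks").chosen_threshold
        net = apply_threshold(m, chosen)
        within = sum(
            1 for u, v in net.edges if block_of(u) == block_of(v)
        )
        assert within / net.number_of_edges() >= 0.95

    def test_le_direction_for_distances(self):
        vals = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]])
        m = IndexMatrix(list("abc"), vals, symmetric=True, kind="distance")
        net = apply_threshold(m, 2.0, direction="le")
        assert set(map(frozenset, net.edges)) == {
            frozenset({"a", "b"}), frozenset({"b", "c"})
        }

    def test_weighted_edges(self):
        m = planted_block_matrix(0, n_blocks=2, block_size=5)
        net = apply_threshold(m, 0.8, weighted=True)
        assert all("weight" in d for _, _, d in net.edges(data=True))
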