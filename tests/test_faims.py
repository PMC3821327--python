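import numpy as np
import pytest

from vocfinger.discriminant import ChanceNull, LoocvConfig, chance_null, loocv
from vocfinger.faims import (
    FEATURE_LENGTH,
    GridConfig,
    ScatterStats,
    ThresholdGridResult,
    compute_scatter_stats,
    concatenate_polarities,
    default_selection_thresholds,
    explore_threshold_grid,
    find_robust_region,
    inverse_wavelet,
    select_variables,
    wavelet_transform,
)
from vocfinger.io_formats import FaimsScan, GroupLabel, N_CV_STEPS, N_DF_LINES
from vocfinger.synthetic import CohortConfig, generate_faims_scan


def zero_scan():
    return FaimsScan(
        positive=np.zeros((N_DF_LINES, N_CV_STEPS)),
        negative=np.zeros((N_DF_LINES, N_CV_STEPS)),
    )


class TestConcatenation:
    def test_length(self):
        scan = generate_faims_scan(GroupLabel.BAD, CohortConfig(seed=0), 1)
        assert concatenate_polarities(scan).values.size == 52224

    def test_zero_scan_zero_vector(self):
        assert np.all(concatenate_polarities(zero_scan()).values == 0.0)

    def test_sentinel_position(self):
        scan = zero_scan()
        scan.positive[2, 7] = 123.0
        v = concatenate_polarities(scan)
        assert v.values[2 * 512 + 7] == 123.0
        assert np.count_nonzero(v.values) == 1

    def test_index_map_matches_brute_force(self):
        # oracle: iterate every (polarity, df, cv) triple and check the flat
        # vector holds exactly that matrix entry
        rng = np.random.default_rng(0)
        scan = FaimsScan(
            positive=rng.standard_normal((N_DF_LINES, N_CV_STEPS)),
            negative=rng.standard_normal((N_DF_LINES, N_CV_STEPS)),
        )
        v = concatenate_polarities(scan).values
        mats = (scan.positive, scan.negative)
        seen = np.zeros(FEATURE_LENGTH, dtype=bool)
        for pol in range(2):
            for df in range(N_DF_LINES):
                for cv in range(N_CV_STEPS):
                    idx = pol * 26112 + df * 512 + cv
                    assert v[idx] == mats[pol][df, cv]
                    assert not seen[idx]
                    seen[idx] = True
        assert seen.all()  # bijection onto [0, 52224)


def d4_matrix(n, levels=None):
    """Oracle: explicit transform matrix built column by column."""
    cols = [
        wavelet_transform(np.eye(n)[:, j], levels=levels).coefficients
        for j in range(n)
    ]
    return np.column_stack(cols)


class TestWavelet:
    def test_constant_vector_kills_details(self):
        w = wavelet_transform(np.full(64, 3.7))
        approx_len = 64 >> w.levels
        assert np.all(np.abs(w.coefficients[approx_len:]) < 1e-10)

    def test_orthonormality_against_matrix_oracle(self, rng):
        n = 64
        M = d4_matrix(n)
        np.testing.assert_allclose(M.T @ M, np.eye(n), atol=1e-12)
        x = rng.standard_normal(n)
        np.testing.assert_allclose(
            wavelet_transform(x).coefficients, M @ x, atol=1e-12
        )
        # energy conservation follows, but assert it directly too
        w = wavelet_transform(x)
        assert abs(np.sum(w.coefficients**2) - np.sum(x**2)) < 1e-9

    def test_full_length_round_trip(self):
        scan = generate_faims_scan(GroupLabel.UC, CohortConfig(seed=1), 2)
        v = concatenate_polarities(scan)
        w = wavelet_transform(v)
        assert w.levels == 9
        assert w.coefficients.size == FEATURE_LENGTH
        back = inverse_wavelet(w)
        assert np.max(np.abs(back.values - v.values)) < 1e-8

    def test_parseval_full_length(self, rng):
        x = rng.standard_normal(FEATURE_LENGTH)
        w = wavelet_transform(x)
        e_in, e_out = np.sum(x**2), np.sum(w.coefficients**2)
        assert abs(e_out - e_in) / e_in < 1e-9

    def test_odd_length_at_some_level_errors(self):
        with pytest.raises(ValueError, match="depth"):
            wavelet_transform(np.arange(12, dtype=float), levels=3)  # 12->6->3

    def test_depth_capped_at_nine(self):
        x = np.zeros(2**12)
        assert wavelet_transform(x).levels == 9


class TestScatterStats:
    def test_hand_computed_example(self):
        # classes A={1,2}, B={3,4}, C={5,6}: sigma_i = sqrt(1/2) each,
        # within = (3*sqrt(.5))^2 = 4.5; class means 1.5/3.5/5.5 ->
        # sigma_mu = 2 -> between = 4 / 4.5 = 8/9
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = ["A", "A", "B", "B", "C", "C"]
        stats = compute_scatter_stats(X, y)
        assert stats.within[0] == pytest.approx(4.5, abs=1e-12)
        assert stats.between[0] == pytest.approx(8.0 / 9.0, abs=1e-12)

    def test_constant_variable_everywhere(self):
        X = np.column_stack([np.full(6, 2.0), np.arange(6.0)])
        y = ["A", "A", "B", "B", "C", "C"]
        stats = compute_scatter_stats(X, y)
        assert stats.within[0] == 0.0
        assert stats.between[0] == 0.0  # non-discriminative by convention

    def test_constant_within_class_distinct_means(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = ["A", "A", "B", "B"]
        stats = compute_scatter_stats(X, y)
        assert stats.within[0] == 0.0
        assert np.isposinf(stats.between[0])  # perfectly discriminative

    def test_class_with_one_sample_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_scatter_stats(np.zeros((3, 2)), ["A", "A", "B"])

    def test_shift_invariance(self, rng):
        X = rng.standard_normal((12, 5))
        y = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        s1 = compute_scatter_stats(X, y)
        s2 = compute_scatter_stats(X + 17.3, y)
        np.testing.assert_allclose(s1.within, s2.within, rtol=1e-9)
        np.testing.assert_allclose(s1.between, s2.between, rtol=1e-8)

    def test_scaling_behavior(self, rng):
        X = rng.standard_normal((12, 5))
        y = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        c = -2.5
        s1 = compute_scatter_stats(X, y)
        s2 = compute_scatter_stats(X * c, y)
        np.testing.assert_allclose(s2.within, s1.within * c**2, rtol=1e-9)
        np.testing.assert_allclose(s2.between, s1.between, rtol=1e-9)


class TestSelectVariables:
    def example_stats(self):
        return ScatterStats(
            within=np.array([4.5, 0.0, 10.0]),
            between=np.array([8.0 / 9.0, 0.0, 2.0]),
        )

    def test_all_pass_with_infinite_thresholds(self):
        idx = select_variables(self.example_stats(), np.inf, -np.inf)
        assert list(idx) == [0, 1, 2]

    def test_zero_within_threshold_selects_nothing(self):
        stats = ScatterStats(within=np.zeros(4), between=np.ones(4))
        assert select_variables(stats, 0.0, 0.5).size == 0  # strict inequality

    def test_hand_example_selected(self):
        idx = select_variables(self.example_stats(), 5.0, 0.5)
        assert 0 in idx and 2 not in idx

    def test_matches_brute_force_filter(self, rng):
        within = rng.uniform(0, 10, 200)
        between = rng.uniform(0, 2, 200)
        stats = ScatterStats(within=within, between=between)
        idx = select_variables(stats, 4.0, 1.0)
        brute = [i for i in range(200) if within[i] < 4.0 and between[i] > 1.0]
        assert list(idx) == brute

    def test_inverted_directions(self):
        stats = self.example_stats()
        idx = select_variables(stats, 5.0, 3.0, within_op="gt", between_op="lt")
        assert list(idx) == [2]


class TestThresholdGrid:
    def test_separable_reaches_perfect_accuracy(self, separable_features):
        X, labels = separable_features
        result = explore_threshold_grid(
            X, labels, GridConfig(n_within=5, n_between=5)
        )
        assert np.nanmax(result.accuracy) == 1.0

    def test_one_by_one_grid_equals_direct_loocv(self, separable_features):
        X, labels = separable_features
        stats = compute_scatter_stats(X, labels)
        wt, bt = default_selection_thresholds(stats, cap=15)
        result = explore_threshold_grid(
            X,
            labels,
            GridConfig(
                within_thresholds=np.array([wt]),
                between_thresholds=np.array([bt]),
                cap=10**6,  # loocv applies no cap; match it
            ),
        )
        report = loocv(
            X, labels, LoocvConfig(k=3, selection_thresholds=(wt, bt))
        )
        assert result.accuracy[0, 0] == pytest.approx(report.overall_accuracy)

    def test_permuted_labels_no_robust_region(self, separable_features, rng):
        X, labels = separable_features
        found = 0
        n_seeds = 6
        for _ in range(n_seeds):
            perm = rng.permutation(len(labels))
            shuffled = [labels[i] for i in perm]
            result = explore_threshold_grid(
                X, shuffled, GridConfig(n_within=4, n_between=4)
            )
            found += find_robust_region(result).found
        assert found <= 1  # at most one chance robust region in six nulls

    def test_undefined_cells_marked(self, separable_features):
        X, labels = separable_features
        result = explore_threshold_grid(
            X,
            labels,
            GridConfig(
                within_thresholds=np.array([0.0]),  # selects nothing
                between_thresholds=np.array([0.0]),
            ),
        )
        assert np.isnan(result.accuracy[0, 0])
        assert (0, 0) in result.undefined_reasons


class TestRobustRegion:
    def flat_result(self, acc):
        shape = (2, 2)
        null = ChanceNull(mean=1 / 3, sd=0.05, n=30, class_proportions={})
        return ThresholdGridResult(
            within_thresholds=np.array([1.0, 2.0]),
            between_thresholds=np.array([0.1, 0.2]),
            accuracy=np.full(shape, acc),
            n_selected=np.ones(shape, dtype=int),
            robust_mask=np.zeros(shape, dtype=bool),
            null=null,
            stats=ScatterStats(within=np.array([1.0]), between=np.array([1.0])),
            config=GridConfig(),
        )

    def test_all_chance_grid_has_no_robust_region(self):
        region = find_robust_region(self.flat_result(1 / 3))
        assert not region.found
        assert region.chosen_cell is None
        assert not region.mask.any()

    def test_perfect_cell_is_robust_for_study_composition(self):
        # 110 samples at 23/42/45: chance mean ~= 0.3569, 3 SD bar well below 1
        labels = ["BAD"] * 23 + ["UC"] * 42 + ["CONTROL"] * 45
        null = chance_null(labels)
        result = self.flat_result(1 / 3)
        result.accuracy[1, 1] = 1.0
        region = find_robust_region(result, null)
        assert region.found
        assert region.chosen_cell == (1, 1)
        assert 1.0 > null.threshold

    def test_chosen_variables_cover_planted_signal(self, separable_features):
        # oracle: wavelet-transform the noiseless pairwise group-mean
        # differences; at least one chosen variable must carry substantial
        # energy of that planted-signal template (top decile)
        X, labels = separable_features
        result = explore_threshold_grid(
            X, labels, GridConfig(n_within=5, n_between=5)
        )
        region = find_robust_region(result)
        assert region.found
        config = CohortConfig(effect_size=3.0, noise_sd=0.0, biological_sd=0.0)
        vecs = {
            g: concatenate_polarities(generate_faims_scan(g, config, 0)).values
            for g in GroupLabel
        }
        templates = [
            np.abs(wavelet_transform(vecs[a] - vecs[b]).coefficients)
            for a, b in [
                (GroupLabel.BAD, GroupLabel.CONTROL),
                (GroupLabel.BAD, GroupLabel.UC),
                (GroupLabel.UC, GroupLabel.CONTROL),
            ]
        ]
        template = np.max(templates, axis=0)
        bar = np.quantile(template, 0.9)
        assert template[region.chosen_variables].max() > bar
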