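"""Complexity features: analytic limits, independent oracles and invariances."""

import numpy as np
import pytest
from scipy.linalg import hankel, svdvals

from eegdem import (
    DFAConfig,
    EEGRecording,
    HiguchiConfig,
    SVDEntropyConfig,
    WindowSpec,
    default_montage,
    dfa,
    higuchi_fd,
    hjorth,
    hjorth_scalar,
    segment,
    svd_entropy,
    zero_crossing_rate,
)
from eegdem.features import extract_feature_table, feature_columns


def svd_entropy_oracle(x, order=3, delay=1):
    """Independent reference: explicit Hankel embedding + LAPACK svdvals."""
    rows = len(x) - (order - 1) * delay
    emb = hankel(x[:rows], x[rows - 1 :])[:, :: delay][:, :order]
    sv = svdvals(emb)
    p = sv / sv.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestSVDEntropy:
    def test_constant_window_has_exactly_zero_entropy(self):
        assert svd_entropy(np.full(500, 5.0)) == 0.0

    def test_white_noise_approaches_log2_order(self, rng):
        h = svd_entropy(rng.normal(size=500))
        assert 1.40 < h < np.log2(3) + 1e-12

    def test_entropy_bounded_by_log2_order(self, rng):
        for _ in range(20):
            x = rng.normal(size=500).cumsum()
            assert svd_entropy(x) <= np.log2(3) + 1e-12

    def test_matches_independent_oracle_on_random_windows(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(50, 500))
            assert abs(svd_entropy(x) - svd_entropy_oracle(x)) < 1e-6

    def test_nonunit_delay_matches_oracle(self, rng):
        cfg = SVDEntropyConfig(order=4, delay=3)
        for _ in range(10):
            x = rng.normal(size=200)
            assert abs(svd_entropy(x, cfg) - svd_entropy_oracle(x, 4, 3)) < 1e-6

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            svd_entropy(np.array([1.0, np.nan] * 100))


class TestHiguchi:
    def test_linear_ramp_has_dimension_one(self):
        assert higuchi_fd(0.01 * np.arange(500)) == pytest.approx(1.0, abs=0.02)

    def test_white_noise_has_dimension_two(self):
        vals = [higuchi_fd(np.random.default_rng(i).normal(size=500)) for i in range(50)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.15)

    def test_brownian_path_has_dimension_three_halves(self):
        vals = [
            higuchi_fd(np.cumsum(np.random.default_rng(i).normal(size=500)))
            for i in range(50)
        ]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.15)

    def test_constant_window_is_flat_line(self):
        assert higuchi_fd(np.zeros(500)) == 1.0

    def test_kmax_bounds_enforced(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(30.0), HiguchiConfig(kmax=20))


class TestZeroCrossingRate:
    def test_constant_positive_window(self):
        assert zero_crossing_rate(np.full(100, 3.0)) == 0.0

    def test_alternating_signs_cross_every_pair(self):
        x = np.tile([1.0, -1.0], 250)
        assert zero_crossing_rate(x) == 1.0

    def test_shifted_10hz_sine_matches_direct_count(self):
        t = np.arange(500)
        x = np.sin(2 * np.pi * 10 * t / 500 + 0.1)
        direct = int(np.sum(x[1:] * x[:-1] < 0))  # independent count
        assert direct == 19
        assert zero_crossing_rate(x) == direct / 499

    def test_exact_zero_samples_break_crossings(self):
        assert zero_crossing_rate(np.array([1.0, 0.0, -1.0, 1.0])) == pytest.approx(1 / 3)

    def test_window_of_one_sample_rejected(self):
        with pytest.raises(ValueError):
            zero_crossing_rate(np.array([1.0]))


class TestDFA:
    def test_white_noise_alpha_half(self):
        vals = [dfa(np.random.default_rng(i).normal(size=2000)) for i in range(50)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_brownian_alpha_three_halves(self):
        vals = [
            dfa(np.cumsum(np.random.default_rng(i).normal(size=2000))) for i in range(50)
        ]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.15)

    def test_gain_invariance(self, rng):
        x = rng.normal(size=1000)
        assert dfa(7.3 * x) == pytest.approx(dfa(x), abs=1e-12)

    def test_constant_signal_names_degenerate_scale(self):
        with pytest.raises(ValueError, match="scale n="):
            dfa(np.full(1000, 2.0))

    def test_scale_validation(self):
        with pytest.raises(ValueError, match="4 distinct"):
            DFAConfig(box_sizes=(4, 8)).scales_for(100)


class TestHjorth:
    def test_sine_activity_is_half_squared_amplitude(self):
        x = 2.0 * np.sin(2 * np.pi * 20 * np.arange(2000) / 500)
        assert hjorth(x).activity == pytest.approx(2.0, abs=0.05)

    def test_white_noise_mobility_is_sqrt_two(self):
        vals = [
            hjorth(np.random.default_rng(i).normal(size=2000)).mobility for i in range(20)
        ]
        assert np.mean(vals) == pytest.approx(np.sqrt(2), abs=0.05)

    def test_constant_window_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hjorth(np.full(100, 1.0))

    def test_scalar_summary_is_mean_of_mobility_and_complexity(self, rng):
        for _ in range(20):
            x = rng.normal(size=300).cumsum()
            h = hjorth(x)
            assert hjorth_scalar(x) == pytest.approx((h.mobility + h.complexity) / 2)

    def test_gain_scaling(self, rng):
        x = rng.normal(size=500)
        a, b = hjorth(x), hjorth(4.0 * x)
        assert b.activity == pytest.approx(16.0 * a.activity, rel=1e-9)
        assert b.mobility == pytest.approx(a.mobility, rel=1e-9)
        assert b.complexity == pytest.approx(a.complexity, rel=1e-9)


class TestGainInvariance:
    @pytest.mark.parametrize("fn", [svd_entropy, higuchi_fd, zero_crossing_rate, dfa])
    def test_scale_free_measures(self, fn, rng):
        x = rng.normal(size=1000).cumsum()
        assert fn(2.7 * x) == pytest.approx(fn(x), abs=1e-9)


class TestFeatureTable:
    @pytest.fixture(scope="class")
    def window_set(self):
        rng = np.random.default_rng(5)
        rec = EEGRecording(
            subject_id="sub-T001",
            group="AD",
            fs=500.0,
            signal=rng.normal(size=(19, 1500)).cumsum(axis=1),
            montage=default_montage(),
        )
        return segment(rec, WindowSpec(1.0, 0.9))

    def test_shape_contract(self, window_set):
        table = extract_feature_table(window_set, "svd")
        assert table.shape == (21, 3 + 19)
        assert list(table["subject_id"].unique()) == ["sub-T001"]
        assert feature_columns(table) == list(default_montage().channel_names)

    @pytest.mark.parametrize(
        "measure, scalar",
        [
            ("svd", svd_entropy),
            ("hfd", higuchi_fd),
            ("zcr", zero_crossing_rate),
            ("dfa", dfa),
            ("hjorth", hjorth_scalar),
        ],
    )
    def test_cells_equal_scalar_operation(self, window_set, measure, scalar):
        table = extract_feature_table(window_set, measure)
        for row in (0, 7, 20):
            for ch in (0, 9, 18):
                name = window_set.channel_names[ch]
                expected = scalar(window_set.windows[row, ch])
                assert table.loc[row, name] == pytest.approx(expected, rel=1e-9)

    def test_empty_window_set_gives_empty_table(self, window_set):
        import dataclasses

        empty = dataclasses.replace(
            window_set, windows=np.empty((0, 19, 500)), window_start_samples=()
        )
        table = extract_feature_table(empty, "svd")
        assert len(table) == 0

    def test_unknown_measure_rejected(self, window_set):
        with pytest.raises(ValueError, match="unknown measure"):
            extract_feature_table(window_set, "hurst")

    def test_rows_with_undefined_channels_are_dropped(self, window_set):
        import dataclasses

        windows = window_set.windows.copy()
        windows[3, 4, :] = 1.0  # constant channel: Hjorth undefined
        broken = dataclasses.replace(window_set, windows=windows)
        table = extract_feature_table(broken, "hjorth")
        assert len(table) == 20
        assert 3 not in set(table["window_index"])


class TestClassContrast:
    def test_svd_entropy_separates_ad_from_hc_beyond_pooled_se(self, svd_features_50):
        """Learnability precondition: group means differ by > pooled SE."""
        cols = feature_columns(svd_features_50)
        by_subject = (
            svd_features_50.groupby(["group", "subject_id"])[cols].mean().mean(axis=1)
        )
        ad, hc = by_subject.loc["AD"], by_subject.loc["HC"]
        pooled_se = np.sqrt(ad.var() / len(ad) + hc.var() / len(hc))
        assert abs(ad.mean() - hc.mean()) > pooled_se
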