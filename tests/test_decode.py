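"""Decoder behavior: accuracy, permutation nulls, FDR, rank-sum control."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intentdecode as itd
from intentdecode.decode import _exhaustive_null
from intentdecode.features import FeatureSet


def blob_features(n_per_class=30, separation=6.0, n_features=8, seed=0, offset=0.0):
    """Two Gaussian blobs; separation in units of within-class SD."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, n_features))
    b = rng.standard_normal((n_per_class, n_features)) + separation / np.sqrt(n_features)
    X = np.vstack([a, b])
    y = np.array(["silence"] * n_per_class + ["speech_intent"] * n_per_class)
    return FeatureSet(
        matrix=X,
        labels=y,
        trial_ids=np.arange(2 * n_per_class),
        offset=offset,
        band="high_gamma",
        contrast="silence",
        column_names=[f"f{i}" for i in range(n_features)],
        channel_names=["chA", "chB"],
    )


class TestFitAndTest:
    def test_separable_blobs_decode_above_95(self, fast_decoder):
        res = itd.fit_and_test(blob_features(separation=8.0), fast_decoder)
        assert res.mean_accuracy >= 0.95
        assert len(res.iteration_accuracies) == fast_decoder.n_iterations
        assert res.mean_accuracy == pytest.approx(res.iteration_accuracies.mean())

    def test_grid_search_runs_with_multiple_points(self):
        cfg = itd.DecoderConfig(
            n_iterations=3, n_shuffles=100,
            penalty_grid=(0.1, 1.0, 10.0), kernel_width_grid=(0.01, "1/d", 1.0),
            seed=1,
        )
        res = itd.fit_and_test(blob_features(separation=8.0), cfg)
        assert res.mean_accuracy >= 0.9

    def test_permuted_labels_near_chance(self, fast_decoder):
        fs = blob_features(separation=6.0, seed=2)
        rng = np.random.default_rng(4)
        fs.labels = rng.permutation(fs.labels)
        res = itd.empirical_null_and_p(itd.fit_and_test(fs, fast_decoder), fast_decoder)
        lo, hi = np.percentile(res.null_accuracies, [2.5, 97.5])
        assert lo - 0.1 <= res.mean_accuracy <= hi + 0.1

    def test_duplicated_rows_keep_accuracy(self, fast_decoder):
        fs = blob_features(separation=8.0, seed=3)
        dup = FeatureSet(
            matrix=np.vstack([fs.matrix, fs.matrix]),
            labels=np.concatenate([fs.labels, fs.labels]),
            trial_ids=np.concatenate([fs.trial_ids, fs.trial_ids]),
            offset=0.0, band="high_gamma", contrast="silence",
            column_names=fs.column_names, channel_names=fs.channel_names,
        )
        a = itd.fit_and_test(fs, fast_decoder)
        b = itd.fit_and_test(dup, fast_decoder)
        assert abs(a.mean_accuracy - b.mean_accuracy) < 0.1

    def test_degenerate_features_rejected(self, fast_decoder):
        fs = blob_features()
        fs.matrix = np.zeros_like(fs.matrix)
        with pytest.raises(ValueError, match="variance"):
            itd.fit_and_test(fs, fast_decoder)

    def test_too_few_rows_rejected(self, fast_decoder):
        with pytest.raises(ValueError, match="10 rows"):
            itd.fit_and_test(blob_features(n_per_class=8), fast_decoder)


class TestEmpiricalNull:
    def test_exhaustive_p_matches_bruteforce_enumeration(self, fast_decoder):
        """On small test sets the null enumerates all distinct label
        arrangements; an independent enumeration must agree exactly."""
        from itertools import permutations

        cfg = itd.DecoderConfig(
            n_iterations=2, n_shuffles=500,
            penalty_grid=(1.0,), kernel_width_grid=("1/d",), seed=11,
        )
        fs = blob_features(n_per_class=20, separation=3.0, seed=5)  # test sets of 8
        res = itd.empirical_null_and_p(itd.fit_and_test(fs, cfg), cfg)
        assert res.exhaustive_null

        # oracle: enumerate every full permutation of each test set's labels;
        # the resulting accuracy distribution (with multiplicities) must give
        # the same exceedance probability
        exceed = total = 0
        for y_te, y_pred in res.test_pairs:
            for perm in set(permutations(y_te)):
                acc = np.mean(np.array(perm) == y_pred)
                exceed += acc >= res.mean_accuracy
                total += 1
        assert res.p_value == pytest.approx(exceed / total)

    def test_perfect_decoder_floor_p(self):
        cfg = itd.DecoderConfig(
            n_iterations=5, n_shuffles=500,
            penalty_grid=(1.0,), kernel_width_grid=("1/d",), seed=2,
        )
        fs = blob_features(n_per_class=130, separation=12.0, seed=6)  # test sets of 52
        res = itd.empirical_null_and_p(itd.fit_and_test(fs, cfg), cfg)
        assert not res.exhaustive_null
        assert res.mean_accuracy == 1.0
        assert res.p_value == pytest.approx(1 / 501)

    def test_null_centered_on_half(self, fast_decoder):
        fs = blob_features(n_per_class=30, separation=6.0, seed=7)
        res = itd.empirical_null_and_p(itd.fit_and_test(fs, fast_decoder), fast_decoder)
        assert abs(res.null_accuracies.mean() - 0.5) < 0.02


class TestBhFdr:
    def test_hand_computed_step_up(self):
        p_adj, reject = itd.bh_fdr([0.01, 0.02, 0.04, 0.5], q=0.05)
        # step-up thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05:
        # 0.04 > 0.0375 fails, so only the first two are rejected
        assert list(reject) == [True, True, False, False]
        assert np.allclose(p_adj, [0.04, 0.04, 0.05333333, 0.5])

    def test_all_ones_no_rejections(self):
        _, reject = itd.bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_p_identity(self):
        p_adj, reject = itd.bh_fdr([0.04], q=0.05)
        assert p_adj[0] == pytest.approx(0.04)
        assert reject[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            itd.bh_fdr([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_manual_step_up(self, ps):
        """Oracle: literal Benjamini-Hochberg step-up rule."""
        p_adj, reject = itd.bh_fdr(ps, q=0.05)
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="stable")
        k = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * 0.05 / m:
                k = rank
        expected = np.zeros(m, dtype=bool)
        expected[order[:k]] = True
        assert list(reject) == list(expected)
        # adjusted p monotone in the ordered sequence
        assert np.all(np.diff(p_adj[order]) >= -1e-12)


class TestCompareContrasts:
    def test_disjoint_supports_exact_minimal_p(self):
        p = itd.compare_contrasts([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)  # 2 / C(10,5)

    def test_identical_constant_samples_warn_p1(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            p = itd.compare_contrasts([0.5] * 5, [0.5] * 5)
        assert p == 1.0

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.6, 0.05, 20)
        p_small = itd.compare_contrasts(base, base + 0.02)
        p_large = itd.compare_contrasts(base, base + 0.2)
        assert p_large < p_small

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            itd.compare_contrasts([], [0.5])


class TestSweepMachinery:
    def test_sweep_offset_grids(self):
        from intentdecode.decode import sweep_offsets

        sil = sweep_offsets("silence")
        assert len(sil) == 23
        assert sil[0] == -1.5 and sil[-1] == pytest.approx(0.7)
        assert np.allclose(np.diff(sil), 0.1)
        assert list(sweep_offsets("delay")) == [-0.2, -0.1, 0.0]

    def test_sweep_deterministic_given_seed(self, signal_env, signal_dataset):
        _, _, events, _ = signal_dataset
        cfg = itd.DecoderConfig(
            n_iterations=3, n_shuffles=100,
            penalty_grid=(1.0,), kernel_width_grid=("1/d",), seed=21,
        )
        a = itd.offset_sweep(signal_env, events, cfg, contrast="delay")
        b = itd.offset_sweep(signal_env, events, cfg, contrast="delay")
        assert a.to_frame().equals(b.to_frame())
        assert a.first_significant_offset == b.first_significant_offset

    def test_delay_contrast_significant_at_zero_on_signal(self, signal_env, signal_dataset):
        _, _, events, _ = signal_dataset
        cfg = itd.DecoderConfig(
            n_iterations=5, n_shuffles=200,
            penalty_grid=(1.0, 10.0), kernel_width_grid=("1/d",), seed=22,
        )
        sw = itd.offset_sweep(signal_env, events, cfg, contrast="delay")
        assert sw.results[-1].significant  # offset 0: intent vs mid-delay
        assert sw.accuracy_at(0.0) > 0.8

    def test_group_significance_signal_and_misalignment(self, signal_env, signal_dataset):
        _, _, events, _ = signal_dataset
        cfg = itd.DecoderConfig(
            n_iterations=3, n_shuffles=100,
            penalty_grid=(1.0,), kernel_width_grid=("1/d",), seed=30,
        )
        sweeps = [
            itd.offset_sweep(signal_env, events, cfg, contrast="delay"),
            itd.offset_sweep(
                signal_env, events,
                itd.DecoderConfig(**{**cfg.__dict__, "seed": 31}), contrast="delay",
            ),
        ]
        df = itd.group_significance(sweeps)
        assert bool(df.loc[df["offset_s"] == 0.0, "significant"].iloc[0])
        # misaligned grids rejected
        bad = itd.offset_sweep(
            signal_env, events, cfg, contrast="silence",
            offsets=np.array([-0.2, 0.0]),
        )
        with pytest.raises(ValueError, match="misaligned"):
            itd.group_significance([sweeps[0], bad])
        with pytest.raises(ValueError, match=">= 2"):
            itd.group_significance([sweeps[0]])


class TestSingleElectrodeMap:
    def test_production_channels_significant_silent_not(self, signal_env, signal_dataset):
        _, _, events, truth = signal_dataset
        cfg = itd.DecoderConfig(
            n_iterations=5, n_shuffles=200,
            penalty_grid=(1.0, 10.0), kernel_width_grid=("1/d",), seed=40,
        )
        table = itd.single_electrode_map(signal_env, events, cfg)
        assert len(table) == signal_env.n_channels
        by_role = {
            role: table.loc[
                [i for i, r in enumerate(truth.channel_roles) if r == role],
                "significant",
            ]
            for role in ("production", "silent")
        }
        assert by_role["production"].all()
        assert not by_role["silent"].any()
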