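"""Binning, normalization, pseudo-ensembles, PCA, LDA, and the decoders."""

import numpy as np
import pytest
from scipy import stats

from attnsal import (bh_fdr, bin_rates, build_pseudo_population, decode_cross_temporal,
                     decode_diagonal, lda_fit, pca_reduce, rt_split_decoding,
                     shuffle_significance, zscore_and_smooth)
from attnsal.decoding import (AlignedRateTensor, PseudoEnsemble, _gaussian_taps,
                              _loo_lda_models_naive, loo_lda_models,
                              loo_true_label_posterior, _window_operator)
from attnsal.neurons import NeuronRecording, NeuronTuning, simulate_neuron
from attnsal.task import TaskTrial


def _trial(i, cue="left", t_change=2.0):
    return TaskTrial(trial_id=i, paradigm="D", is_single_stimulus=False, cue_side=cue,
                     trial_type="valid", left_value=2, right_value=4,
                     change_side="right", change_latency_s=0.8, t_change_on=t_change,
                     t_end=3.0)


class TestBinRates:
    def test_spike_at_left_edge_counted_in_that_bin(self):
        rec = NeuronRecording("n0", "OFC", spikes={0: np.array([1.2 + 0.01])})
        t = bin_rates([rec], [_trial(0)], "stim_on", window=(0.0, 0.05), bin_ms=10)
        # spike at exactly +10 ms belongs to the [10, 20) ms bin
        assert t.values[0, 1, 0] == pytest.approx(100.0)
        assert t.values[0, 0, 0] == 0.0

    def test_constant_rate_neuron_recovers_rate(self):
        tuning = NeuronTuning("n0", "OFC", baseline_rate_hz=20.0, coefficients={})
        trials = [_trial(i) for i in range(200)]
        rec = simulate_neuron(tuning, trials, rng=np.random.default_rng(0))
        t = bin_rates([rec], trials, "stim_on")
        assert t.values.mean() == pytest.approx(20.0, rel=0.05)

    def test_empty_spike_train_gives_zero_row(self):
        rec = NeuronRecording("n0", "OFC", spikes={0: np.empty(0)})
        t = bin_rates([rec], [_trial(0)], "stim_on")
        assert np.all(t.values == 0)

    def test_trials_without_event_excluded(self):
        rec = NeuronRecording("n0", "OFC", spikes={0: np.empty(0), 1: np.empty(0)})
        trials = [_trial(0), _trial(1, t_change=None)]
        t = bin_rates([rec], trials, "change_on")
        assert list(t.trial_ids) == [0]

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            bin_rates([], [_trial(0)], "stim_on", bin_ms=0)


class TestZscoreSmooth:
    def _tensor(self, values, bin_ms=10.0):
        n_tr, n_b, n_n = values.shape
        return AlignedRateTensor(values=values, bin_centers=np.arange(n_b) * bin_ms / 1000,
                                 alignment="stim_on", trial_ids=np.arange(n_tr),
                                 neuron_ids=[f"n{i}" for i in range(n_n)], bin_ms=bin_ms)

    def test_constant_rate_neuron_excluded(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((20, 30, 2))
        v[:, :, 1] = 7.0  # zero variance
        out = zscore_and_smooth([self._tensor(v)])
        assert out[0].neuron_ids == ["n0"]

    def test_global_mean_zero_after_zscore(self):
        rng = np.random.default_rng(1)
        tensors = [self._tensor(rng.standard_normal((30, 40, 3)) * 5 + 2),
                   self._tensor(rng.standard_normal((30, 20, 3)) * 5 + 2)]
        out = zscore_and_smooth(tensors)
        for j in range(3):
            pooled = np.concatenate([o.values[:, :, j].ravel() for o in out])
            # smoothing preserves the global mean (edge-renormalized kernel)
            assert abs(pooled.mean()) < 0.02

    def test_white_noise_variance_reduced_by_kernel_power(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((200, 101, 1))
        out = zscore_and_smooth([self._tensor(v)])[0]
        taps = _gaussian_taps(50.0, 100.0, 10.0)
        interior = out.values[:, 20:-20, 0]
        assert interior.var() == pytest.approx(float((taps ** 2).sum()), rel=0.05)


class TestPseudoPopulation:
    def _tensor(self, n_trials=250, n_neurons=4, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((n_trials, 10, n_neurons))
        labels = np.tile([-1, 1], n_trials // 2)
        t = AlignedRateTensor(values=v, bin_centers=np.linspace(0, 0.09, 10),
                              alignment="stim_on", trial_ids=np.arange(n_trials),
                              neuron_ids=[f"n{i}" for i in range(n_neurons)], bin_ms=10.0)
        return t, labels

    def test_balanced_m(self):
        t, labels = self._tensor()
        ens = build_pseudo_population(t, labels, n_per_class=100, seed=1)
        assert ens.values.shape[0] == 200
        assert (ens.labels == -1).sum() == (ens.labels == 1).sum() == 100

    def test_neuron_below_threshold_rejected(self):
        t, labels = self._tensor(n_trials=198)  # 99 per class
        with pytest.raises(ValueError):
            build_pseudo_population(t, labels, n_per_class=100, seed=1)

    def test_determinism(self):
        t, labels = self._tensor()
        a = build_pseudo_population(t, labels, n_per_class=50, seed=7)
        b = build_pseudo_population(t, labels, n_per_class=50, seed=7)
        assert np.array_equal(a.values, b.values)


class TestPcaReduce:
    def _ens(self, values):
        return PseudoEnsemble(values=values, labels=np.repeat([-1, 1], len(values) // 2),
                              bin_centers=np.arange(values.shape[1]) * 0.01,
                              neuron_ids=[f"n{i}" for i in range(values.shape[2])])

    def test_threshold_one_keeps_full_rank(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((40, 3, 6))
        ens = pca_reduce(self._ens(v), "per_bin", var_threshold=1.0)
        assert all(d == 6 for d in ens.dims)

    def test_rank_one_data_keeps_one_component(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal((40, 1, 1))
        w = rng.standard_normal((1, 1, 6))
        ens = pca_reduce(self._ens(u * w), "per_bin", var_threshold=0.1)
        assert all(d == 1 for d in ens.dims)

    def test_joint_dimension_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((200, 4, 50)) * np.linspace(3, 0.5, 50)
        ens = pca_reduce(self._ens(v), "joint", var_threshold=0.70)
        flat = v.reshape(-1, 50)
        flat = flat - flat.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(flat.T @ flat))[::-1]
        q = int(np.searchsorted(np.cumsum(evals) / evals.sum(), 0.70 - 1e-12) + 1)
        assert ens.dims == [q]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            pca_reduce(self._ens(np.zeros((10, 2, 3))), "per_bin", var_threshold=1.5)


class TestLda:
    def _one_d_data(self):
        a = 1 / np.sqrt(2)
        x = np.array([-1 - a, -1 + a, 1 - a, 1 + a])
        y = np.array([0, 0, 1, 1])
        return x, y

    def test_symmetric_point_has_posterior_half(self):
        x, y = self._one_d_data()
        m = lda_fit(x, y)
        assert m.posterior([0.0])[0] == pytest.approx(0.5)

    def test_closed_form_posterior_at_one(self):
        x, y = self._one_d_data()
        m = lda_fit(x, y)
        assert m.posterior([1.0])[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)

    def test_identical_means_posterior_half_everywhere(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        m = lda_fit(x, y)
        assert np.allclose(m.posterior(np.linspace(-3, 3, 7)), 0.5)

    @pytest.mark.parametrize("p,n,seed", [(2, 24, 0), (5, 40, 1), (3, 30, 2)])
    def test_matches_brute_force_gaussian_densities(self, p, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = np.repeat([0, 1], n // 2)
        X[y == 1] += 0.8
        m = lda_fit(X, y)
        m0, m1 = X[y == 0].mean(0), X[y == 1].mean(0)
        D = X - np.where(y[:, None] == 1, m1, m0)
        cov = D.T @ D / (n - 2)
        f0 = stats.multivariate_normal(m0, cov).pdf(X)
        f1 = stats.multivariate_normal(m1, cov).pdf(X)
        post = f1 / (f0 + f1)
        assert np.allclose(m.posterior(X), post, atol=1e-10)
        assert np.array_equal(m.predict(X), np.where(post > 0.5, 1, 0))

    def test_sklearn_cross_check(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 4))
        y = np.repeat([0, 1], 30)
        X[y == 1, 0] += 1.5
        mine = lda_fit(X, y)
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        assert np.array_equal(mine.predict(X), ref.predict(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((6, 2)), np.zeros(6))

    @pytest.mark.parametrize("p,m,seed", [(3, 20, 0), (8, 60, 1), (1, 12, 2)])
    def test_loo_downdate_equals_per_fold_refit(self, p, m, seed):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((m, p))
        y = np.repeat([0, 1], m // 2)
        W1, b1 = loo_lda_models(F, y)
        W2, b2 = _loo_lda_models_naive(F, y)
        assert np.allclose(W1, W2, atol=1e-9)
        assert np.allclose(b1, b2, atol=1e-9)


def _label_tensor(n_trials, n_neurons, signal, seed, bins=40):
    """Tensor whose post-onset bins carry a cue-side signal of given size."""
    rng = np.random.default_rng(seed)
    labels = np.tile([-1, 1], n_trials // 2)
    centers = np.arange(bins) * 0.01 - 0.2
    v = rng.standard_normal((n_trials, bins, n_neurons))
    post = centers > 0
    v[:, post, :] += signal * labels[:, None, None]
    return AlignedRateTensor(values=v, bin_centers=centers, alignment="stim_on",
                             trial_ids=np.arange(n_trials),
                             neuron_ids=[f"n{i}" for i in range(n_neurons)],
                             bin_ms=10.0), labels


class TestDecoders:
    def test_shuffled_labels_decode_at_chance(self):
        t, labels = _label_tensor(240, 12, signal=1.0, seed=0)
        res = decode_diagonal(t, labels, n_per_class=80, n_resample=5,
                              shuffle_labels=True, seed=1)
        assert np.all(np.abs(res.mean_posterior - 0.5) < 0.06)

    def test_strong_signal_decodes_post_onset(self):
        t, labels = _label_tensor(240, 12, signal=1.5, seed=2)
        res = decode_diagonal(t, labels, n_per_class=80, n_resample=3, seed=3)
        post = res.mean_posterior[res.bin_centers > 0.05]
        pre = res.mean_posterior[res.bin_centers < -0.05]
        assert post.mean() > 0.95
        assert np.abs(pre.mean() - 0.5) < 0.05

    def test_more_resamples_reduce_se_not_mean(self):
        t, labels = _label_tensor(240, 6, signal=0.25, seed=4)
        kw = dict(n_per_class=80, decode_bin_ms=25, step_ms=25)
        r1 = decode_diagonal(t, labels, n_resample=2, seed=5, **kw)
        r2 = decode_diagonal(t, labels, n_resample=16, seed=5, **kw)
        assert abs(r1.mean_posterior.mean() - r2.mean_posterior.mean()) < 0.05
        se1 = r1.posteriors.mean(axis=1).std(axis=0, ddof=1) / np.sqrt(r1.posteriors.shape[0])
        se2 = r2.posteriors.mean(axis=1).std(axis=0, ddof=1) / np.sqrt(r2.posteriors.shape[0])
        assert se2.mean() < se1.mean()

    def test_cross_temporal_diagonal_matches_diagonal_decoder(self):
        t, labels = _label_tensor(160, 8, signal=1.0, seed=6)
        diag = decode_diagonal(t, labels, n_per_class=60, n_resample=1,
                               pca_mode="joint", seed=11)
        cross = decode_cross_temporal(t, labels, train_spec="all", n_per_class=60,
                                      n_resample=1, seed=11)
        n_bins = len(diag.bin_centers)
        diag_of_cross = np.stack([cross.posteriors[0, :, t, t] for t in range(n_bins)],
                                 axis=1)
        assert np.allclose(diag.posteriors[0], diag_of_cross, atol=1e-10)

    def test_sign_flip_gives_below_chance_generalization(self):
        rng = np.random.default_rng(7)
        n_trials, n_neurons = 240, 16
        labels = np.tile([-1, 1], n_trials // 2)
        centers = np.arange(40) * 0.01 - 0.2
        v = rng.standard_normal((n_trials, 40, n_neurons))
        v[:, centers < 0, :] += 1.0 * labels[:, None, None]
        v[:, centers > 0.1, :] -= 1.0 * labels[:, None, None]  # flipped code
        t = AlignedRateTensor(values=v, bin_centers=centers, alignment="stim_on",
                              trial_ids=np.arange(n_trials),
                              neuron_ids=[f"n{i}" for i in range(n_neurons)], bin_ms=10.0)
        res = decode_cross_temporal(t, labels, train_spec=("window", (-0.2, -0.05)),
                                    n_per_class=80, n_resample=3, seed=8)
        late = res.mean_posterior[res.bin_centers > 0.15]
        assert np.all(late < 0.2)

    def test_time_constant_coding_generalizes_everywhere(self):
        rng = np.random.default_rng(9)
        labels = np.tile([-1, 1], 100)
        v = rng.standard_normal((200, 30, 10)) + 0.8 * labels[:, None, None]
        t = AlignedRateTensor(values=v, bin_centers=np.arange(30) * 0.01,
                              alignment="stim_on", trial_ids=np.arange(200),
                              neuron_ids=[f"n{i}" for i in range(10)], bin_ms=10.0)
        res = decode_cross_temporal(t, labels, train_spec="all", n_per_class=80,
                                    n_resample=2, seed=10)
        assert np.all(res.posteriors.mean(axis=(0, 1)) > 0.5)


class TestSignificance:
    def test_bh_step_up_by_hand(self):
        reject, adj = bh_fdr([0.001, 0.02, 0.9], alpha=0.05)
        assert list(reject) == [True, True, False]

    def test_zero_difference_never_significant(self):
        t, labels = _label_tensor(160, 6, signal=0.8, seed=12)
        res = decode_diagonal(t, labels, n_per_class=60, n_resample=2, seed=13)
        mask = shuffle_significance(res, res, alpha=0.01)
        assert not mask.above.any() and not mask.below.any()
        assert np.all(mask.p == 1.0)

    def test_null_population_significant_fraction_below_alpha(self):
        t, labels = _label_tensor(200, 8, signal=0.0, seed=14)
        a = decode_diagonal(t, labels, n_per_class=80, n_resample=4,
                            shuffle_labels=True, seed=15)
        b = decode_diagonal(t, labels, n_per_class=80, n_resample=4,
                            shuffle_labels=True, seed=16)
        mask = shuffle_significance(a, b, alpha=0.01)
        assert (mask.above | mask.below).mean() <= 0.05


class TestRtSplit:
    def test_identical_rts_flagged_degenerate(self):
        t, labels = _label_tensor(160, 6, signal=0.5, seed=17)
        with pytest.raises(ValueError, match="degenerate"):
            rt_split_decoding(t, labels, np.full(160, 0.25), n_per_class=30, seed=18)

    def test_split_preserves_class_balance_and_detects_construction(self):
        # cue coding strength scales inversely with RT
        rng = np.random.default_rng(19)
        n_trials = 320
        labels = np.tile([-1, 1], n_trials // 2)
        rts = np.tile(np.repeat([0.15, 0.35], n_trials // 4), 2)[:n_trials]
        centers = np.arange(30) * 0.01 - 0.1
        gain = np.where(rts < 0.25, 0.8, 0.1)
        v = rng.standard_normal((n_trials, 30, 10))
        v += (gain * labels)[:, None, None]
        t = AlignedRateTensor(values=v, bin_centers=centers, alignment="stim_on",
                              trial_ids=np.arange(n_trials),
                              neuron_ids=[f"n{i}" for i in range(10)], bin_ms=10.0)
        res = rt_split_decoding(t, labels, rts, n_per_class=70, n_resample=3, seed=20)
        assert res.fast.mean_posterior.mean() > res.slow.mean_posterior.mean() + 0.1
        # per-class balance within each half
        for half in (res.fast, res.slow):
            vals, counts = np.unique(half.labels, return_counts=True)
            assert abs(counts[0] - counts[1]) <= 1


def test_window_operator_drops_partial_windows():
    centers = np.arange(10) * 0.01  # 0 .. 90 ms at 10 ms bins
    ops, win_centers = _window_operator(centers, 10.0, 25.0, 10.0)
    assert win_centers[0] >= 0.0075
    assert win_centers[-1] <= 0.0925
    assert np.allclose(ops.sum(axis=0), 1.0)
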