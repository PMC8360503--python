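"""Decoding machinery: folds, noise normalization, summary trials, the
batched maximum-margin solver, pairwise/percept decoding, and the
activation-pattern transform."""

import numpy as np
import pytest

from cpdecode import (
    assign_folds,
    average_rdm,
    decode_all_pairs,
    decode_pair,
    decode_percept,
    estimate_noise_covariance,
    haufe_transform,
    make_sensor_layout,
    make_summary_trials,
    whiten,
)
from cpdecode._svm import svm_decision, svm_train_batch
from cpdecode.mvpa import (
    PAIRS,
    DecodingTimecourse,
    RDMSeries,
    pair_index,
    whitening_matrix,
)
from cpdecode.synth import EpochSet, default_times

from conftest import make_epochs


class TestAssignFolds:
    def test_forty_trials_five_folds_gives_eights(self):
        labels = np.repeat([1, 2], 40)
        fa = assign_folds(labels, k=5, seed=0)
        for cond in (1, 2):
            sizes = np.bincount(fa.folds[labels == cond], minlength=5)
            assert sizes.tolist() == [8] * 5

    def test_balanced_remainder(self):
        fa = assign_folds(np.ones(7, dtype=int), k=5, seed=1)
        sizes = sorted(np.bincount(fa.folds, minlength=5), reverse=True)
        assert sizes == [2, 2, 1, 1, 1]

    def test_determinism_and_reshuffling(self):
        labels = np.repeat([1, 2], 20)
        a = assign_folds(labels, k=5, seed=3)
        b = assign_folds(labels, k=5, seed=3)
        c = assign_folds(labels, k=5, seed=4)
        assert np.array_equal(a.folds, b.folds)
        assert not np.array_equal(a.folds, c.folds)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="k=5"):
            assign_folds(np.array([1, 1, 1, 2, 2, 2, 2, 2]), k=5)


class TestNoiseCovariance:
    def test_identity_recovery_improves_with_n(self):
        rng = np.random.default_rng(0)
        errs = []
        for n in (20, 200):
            data = rng.standard_normal((n, 6, 30))
            labels = np.repeat([0, 1], n // 2)
            cov = estimate_noise_covariance(data, labels, shrinkage=0.0)
            errs.append(np.linalg.norm(cov.matrix - np.eye(6)))
        assert errs[1] < errs[0]
        assert errs[1] < 0.15

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(1)
        n = 4000
        z = rng.standard_normal((n, 2, 10))
        data = z.copy()
        data[:, 1] = 0.8 * z[:, 0] + np.sqrt(1 - 0.8**2) * z[:, 1]
        cov = estimate_noise_covariance(data, np.repeat([0, 1], n // 2), shrinkage=0.0)
        assert cov.matrix[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_full_shrinkage_returns_scaled_identity(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((40, 5, 8)) * np.array([1, 2, 3, 4, 5])[None, :, None]
        cov = estimate_noise_covariance(data, np.repeat([0, 1], 20), shrinkage=1.0)
        nu = np.trace(cov.matrix) / 5
        np.testing.assert_allclose(cov.matrix, nu * np.eye(5), atol=1e-12)

    def test_singleton_condition_rejected(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 4, 5))
        with pytest.raises(ValueError, match="single training trial"):
            estimate_noise_covariance(data, np.array([0, 0, 1]))

    def test_residuals_remove_condition_means(self):
        # covariance of pure condition-mean differences is ~zero
        rng = np.random.default_rng(4)
        means = rng.standard_normal((2, 4)) * 10
        data = np.repeat(means[:, None, :, None], 20, axis=1).reshape(40, 4, 1)
        data = data + 0.01 * rng.standard_normal(data.shape)
        cov = estimate_noise_covariance(data, np.repeat([0, 1], 20), shrinkage=0.0)
        assert np.abs(cov.matrix).max() < 0.01


class TestWhiten:
    def test_identity_covariance_is_noop(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 4, 6))
        np.testing.assert_allclose(whiten(data, np.eye(4)), data, atol=1e-12)

    def test_whitened_residual_covariance_is_identity(self):
        rng = np.random.default_rng(1)
        mix = rng.standard_normal((6, 6))
        data = np.einsum("ij,njt->nit", mix, rng.standard_normal((400, 6, 20)))
        labels = np.repeat([0, 1], 200)
        cov = estimate_noise_covariance(data, labels, shrinkage=0.0)
        white = whiten(data, cov.matrix)
        recov = estimate_noise_covariance(white, labels, shrinkage=0.0)
        np.testing.assert_allclose(recov.matrix, np.eye(6), atol=0.12)

    def test_whitening_matrix_is_symmetric_inverse_root(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((5, 5))
        cov = a @ a.T + 5 * np.eye(5)
        w = whitening_matrix(cov)
        np.testing.assert_allclose(w, w.T, atol=1e-12)
        np.testing.assert_allclose(w @ cov @ w, np.eye(5), atol=1e-10)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            whitening_matrix(np.diag([1.0, 0.0]))


class TestSummaryTrials:
    def test_identical_trials_average_to_themselves(self):
        data = np.tile(np.arange(12.0).reshape(1, 3, 4), (8, 1, 1))
        labels = np.ones(8, dtype=int)
        fa = assign_folds(labels, k=4, seed=0)
        sdata, slab, sfold = make_summary_trials(data, labels, fa)
        assert sdata.shape == (4, 3, 4)
        np.testing.assert_allclose(sdata, np.broadcast_to(data[0], sdata.shape), atol=1e-12)

    def test_noise_variance_reduced_by_averaging_factor(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4000, 1, 1))
        labels = np.ones(4000, dtype=int)
        fa = assign_folds(labels, k=5, seed=1)
        sdata, _, _ = make_summary_trials(data, labels, fa)
        # each summary averages 800 trials -> variance 1/800
        assert sdata.var() == pytest.approx(1 / 800, rel=0.5)

    def test_one_summary_per_condition_per_fold(self):
        labels = np.repeat([1, 2, 3], 10)
        fa = assign_folds(labels, k=5, seed=2)
        _, slab, sfold = make_summary_trials(np.zeros((30, 2, 2)), labels, fa)
        assert sorted(zip(slab, sfold)) == [(c, f) for c in (1, 2, 3) for f in range(5)]


class TestBatchedSVM:
    def test_matches_sklearn_svc_decision_values(self):
        # dual-route check: the batched SMO against libsvm on random problems
        from sklearn.svm import SVC

        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            n_pos = int(rng.integers(1, n))
            y = np.array([1.0] * n_pos + [-1.0] * (n - n_pos))
            x = rng.normal(size=(n, 6)) + y[:, None] * rng.uniform(0, 2)
            k = (x @ x.T)[None]
            alpha, b = svm_train_batch(k, y, C=1.0, tol=1e-8, max_iter=20000)
            ref = SVC(kernel="precomputed", C=1.0, tol=1e-8).fit(k[0], y)
            xt = rng.normal(size=(5, 6))
            kt = (xt @ x.T)[None]
            np.testing.assert_allclose(
                svm_decision(kt, alpha, b, y)[0], ref.decision_function(kt[0]), atol=1e-5
            )

    def test_known_maximum_margin_geometry(self):
        # two points per class symmetric about x = 0: the maximum-margin
        # separator is the y-axis, so the decision value is proportional to x
        x = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        k = (x @ x.T)[None]
        alpha, b = svm_train_batch(k, y, C=1e6, tol=1e-10, max_iter=10000)
        tests = np.array([[0.5, 0.3], [-0.2, 0.9], [0.0, -2.0]])
        dec = svm_decision((tests @ x.T)[None], alpha, b, y)[0]
        np.testing.assert_allclose(dec, tests[:, 0], atol=1e-6)

    def test_degenerate_all_zero_kernel_gives_zero_decision(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        alpha, b = svm_train_batch(np.zeros((3, 4, 4)), y)
        dec = svm_decision(np.zeros((3, 2, 4)), alpha, b, y)
        np.testing.assert_allclose(dec, 0.0, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            svm_train_batch(np.eye(3)[None], np.ones(3))


def _planted_two_class_epochs(n_per_class=20, n_time=12, sep=0.0, noise=1.0, seed=0):
    """Minimal EpochSet with two stimulus conditions and a planted separation."""
    rng = np.random.default_rng(seed)
    layout = make_sensor_layout()
    n = 2 * n_per_class
    data = noise * rng.standard_normal((n, 306, n_time))
    labels = np.repeat([1, 2], n_per_class)
    if sep:
        pattern = rng.standard_normal(306)
        pattern /= np.linalg.norm(pattern)
        signs = np.where(labels == 1, 1.0, -1.0)
        data[:, :, n_time // 2 :] += sep * signs[:, None, None] * pattern[None, :, None]
    times = np.arange(n_time) * 20.0 - 40.0
    return EpochSet(
        data=data,
        times=times,
        stimulus=labels,
        percept=np.full(n, "none"),
        task="passive",
        subject_id="T01",
        layout=layout,
    )


class TestDecodePair:
    def test_noiseless_separation_decodes_perfectly(self):
        ep = _planted_two_class_epochs(sep=5.0, noise=0.05, seed=1)
        tc = decode_pair(ep, 1, 2, k=5, n_reps=2, seed=0)
        n_time = len(ep.times)
        assert np.all(tc.values[n_time // 2 :] == 100.0)
        assert abs(tc.values[: n_time // 2].mean() - 50.0) < 25.0

    def test_label_permutation_is_at_chance(self):
        ep = _planted_two_class_epochs(sep=4.0, noise=1.0, seed=2)
        rng = np.random.default_rng(3)
        permuted = rng.permutation(ep.stimulus)
        tc = decode_pair(ep, 1, 2, k=5, n_reps=10, seed=0, labels=permuted)
        se = tc.values.std(ddof=1) / np.sqrt(len(tc.values))
        assert abs(tc.values.mean() - 50.0) <= max(3 * se, 5.0)

    def test_no_test_trial_enters_covariance_estimation(self):
        ep = _planted_two_class_epochs(seed=4)
        audit = []
        decode_pair(ep, 1, 2, k=5, n_reps=2, seed=0, audit=audit)
        assert len(audit) == 10  # 2 repetitions x 5 fold rotations
        for record in audit:
            assert not set(record["cov_trials"]) & set(record["test_trials"])
            assert len(record["cov_trials"]) + len(record["test_trials"]) == ep.n_trials

    def test_monotone_in_planted_separation(self):
        accs = []
        for sep in (0.5, 1.5, 4.0):
            ep = _planted_two_class_epochs(sep=sep, noise=1.0, seed=5)
            tc = decode_pair(ep, 1, 2, k=5, n_reps=3, seed=1)
            accs.append(tc.values[len(ep.times) // 2 :].mean())
        assert accs[0] < accs[1] < accs[2]

    def test_missing_condition_rejected(self):
        ep = _planted_two_class_epochs()
        with pytest.raises(ValueError, match="present"):
            decode_pair(ep, 1, 9)


class TestDecodeAllPairs:
    def test_rdm_ranks_recover_planted_distances(self, layout, behavior):
        # high SNR and wide planted spread keep pair accuracies off both
        # chance and ceiling so that the rank structure is identifiable
        kw = dict(snr=0.8, category_gain=3.0, ambiguity_gain=3.0)
        ep = make_epochs(layout, behavior, sfreq=50.0, seed=6, **kw)
        rdm = decode_all_pairs(ep, k=5, n_reps=2, seed=0)
        assert rdm.values.shape == (len(ep.times), 45)
        from scipy.stats import spearmanr
        from cpdecode.synth import (
            GeometrySpec,
            condition_templates,
            _pattern_basis,
        )
        from scipy.spatial.distance import pdist

        spec = GeometrySpec.active_like(**kw)
        basis = _pattern_basis(306, ep.subject_id, spec.subject_jitter)
        templates = condition_templates(spec, behavior.prop_ba(ep.subject_id), ep.times, basis)
        norms = [np.linalg.norm(templates[:, :, i]) for i in range(len(ep.times))]
        ti = int(np.argmax(norms))
        planted = pdist(templates[:, :, ti])
        # average decoded RDM over a small window around the template peak
        window = slice(max(ti - 2, 0), ti + 3)
        rho = spearmanr(planted, rdm.values[window].mean(axis=0)).statistic
        assert rho > 0.6

    def test_pair_index_convention(self):
        assert pair_index(1, 2) == 0
        assert pair_index(1, 10) == 8  # (1,2)..(1,10) occupy the first nine slots
        assert pair_index(2, 3) == 9
        assert pair_index(9, 10) == 44
        assert pair_index(7, 4) == pair_index(4, 7)
        with pytest.raises(ValueError):
            pair_index(5, 5)

    def test_matrix_view_is_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        rdm = RDMSeries(times=np.arange(3.0), values=rng.uniform(40, 60, (3, 45)))
        m = rdm.matrix_at(1)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert m[0, 1] == rdm.values[1, pair_index(1, 2)]


class TestDecodePercept:
    def test_equals_decode_pair_on_percept_pseudoconditions(self, layout, behavior):
        ep = make_epochs(layout, behavior, task="active", snr=0.5, sfreq=50.0, seed=7)
        a = decode_percept(ep, k=5, n_reps=2, seed=11)
        pseudo = np.where(ep.percept == "ba", 1, 2)
        b = decode_pair(ep, 1, 2, k=5, n_reps=2, seed=11, labels=pseudo)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_missing_class_rejected(self, layout, behavior):
        ep = make_epochs(layout, behavior, task="passive", preset="passive-like")
        with pytest.raises(ValueError, match="both classes"):
            decode_percept(ep)


class TestAverageRDM:
    def test_constant_pairs_average_to_constant(self):
        rdm = RDMSeries(times=np.arange(4.0), values=np.full((4, 45), 50.0))
        assert np.all(average_rdm(rdm).values == 50.0)

    def test_matches_direct_mean_and_is_order_invariant(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, (6, 45))
        rdm = RDMSeries(times=np.arange(6.0), values=vals)
        out = average_rdm(rdm).values
        np.testing.assert_allclose(out, vals.mean(axis=1), atol=1e-12)
        shuffled = RDMSeries(times=np.arange(6.0), values=vals[:, rng.permutation(45)])
        np.testing.assert_allclose(average_rdm(shuffled).values, out, atol=1e-12)


class TestHaufeTransform:
    def test_identity_covariance_returns_weights(self):
        w = np.array([1.0, -2.0, 0.5])
        a = haufe_transform(w, np.eye(3), 1.0)
        np.testing.assert_allclose(a.values, w, atol=1e-12)

    def test_forward_model_recovery(self):
        # x = a s + noise: the transformed weights point along a
        rng = np.random.default_rng(0)
        c, n = 306, 4000
        a_true = rng.standard_normal(c)
        snr = 2.0
        s = rng.choice([-1.0, 1.0], size=n)
        sigma = np.linalg.norm(a_true) / (snr * np.sqrt(c))
        x = s[:, None] * a_true[None, :] + sigma * rng.standard_normal((n, c))
        # linear discriminant weights (any linear backward model qualifies)
        cov = np.cov(x.T)
        w = np.linalg.solve(cov + 1e-6 * np.eye(c), x[s > 0].mean(0) - x[s < 0].mean(0))
        latent_var = np.var(x @ w)
        pattern = haufe_transform(w, cov, latent_var).values
        cos = np.dot(pattern, a_true) / (np.linalg.norm(pattern) * np.linalg.norm(a_true))
        assert cos > 0.95

    def test_homogeneity_under_data_rescaling(self):
        rng = np.random.default_rng(1)
        cov = np.eye(4) + 0.3
        w = rng.standard_normal(4)
        a1 = haufe_transform(w, cov, 2.0).values
        a2 = haufe_transform(w, (3.0**2) * cov, (3.0**2) * 2.0).values
        cos = np.dot(a1, a2) / (np.linalg.norm(a1) * np.linalg.norm(a2))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_singular_latent_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            haufe_transform(np.ones(3), np.eye(3), 0.0)


class TestSensorSubsets:
    def test_hemisphere_decoding_sees_only_its_own_channels(self, layout):
        # plant a class separation confined to left-hemisphere channels:
        # left-subset decoding succeeds, right-subset stays near chance
        rng = np.random.default_rng(8)
        left = layout.subset_indices("left")
        n_time = 10
        data = rng.standard_normal((80, 306, n_time))
        labels = np.repeat([1, 2], 40)
        pattern = np.zeros(306)
        pattern[left] = rng.standard_normal(len(left))
        pattern /= np.linalg.norm(pattern)
        signs = np.where(labels == 1, 1.0, -1.0)
        data += 4.0 * signs[:, None, None] * pattern[None, :, None]
        ep = EpochSet(
            data=data,
            times=np.arange(n_time) * 20.0,
            stimulus=labels,
            percept=np.full(80, "none"),
            task="passive",
            subject_id="T01",
            layout=layout,
        )
        tc_left = decode_pair(ep, 1, 2, n_reps=2, seed=0, sensor_subset="left")
        tc_right = decode_pair(ep, 1, 2, n_reps=2, seed=0, sensor_subset="right")
        assert tc_left.values.mean() > 90.0
        assert abs(tc_right.values.mean() - 50.0) < 12.0
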