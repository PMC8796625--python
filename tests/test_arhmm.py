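"""State-inference tests: PCA oracle, EM behavior, Viterbi vs brute force."""

import itertools

import numpy as np
import pytest

import ethoseq as eq
from ethoseq.arhmm import _emission_loglik, _model_to_weights, _prepare_blocks
from ethoseq.types import ARHMMModel


class TestPCA:
    def test_default_dimensionality(self):
        import inspect

        assert inspect.signature(eq.fit_pca).parameters["n_components"].default == 15

    def test_rank_one_data_explains_everything(self):
        rng = np.random.default_rng(0)
        direction = np.array([1.0, 2.0, -1.0])
        feats = rng.standard_normal((500, 1)) * direction
        sess = eq.PoseSession("a", "wt", 30.0, feats, np.ones(500, bool), 500 / 1800)
        model = eq.fit_pca([sess], n_components=3)
        assert model.explained_variance[0] / model.explained_variance.sum() == pytest.approx(1.0)

    def test_explained_variance_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((400, 6)) @ rng.standard_normal((6, 6))
        sess = eq.PoseSession("a", "wt", 30.0, feats, np.ones(400, bool), 400 / 1800)
        model = eq.fit_pca([sess], n_components=4)
        cov = np.cov(feats, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(model.explained_variance, eig[:4], rtol=1e-10)
        # loadings orthonormal, variances non-increasing
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(4), atol=1e-10)
        assert (np.diff(model.explained_variance) <= 1e-12).all()

    def test_too_many_components_rejected(self):
        sess = eq.PoseSession("a", "wt", 30.0, np.zeros((10, 2)), np.ones(10, bool), 1.0)
        with pytest.raises(ValueError):
            eq.fit_pca([sess], n_components=3)


def _random_model(K, P, rng, L=1):
    """Small random-but-valid ARHMM for decoder tests."""
    ar = rng.uniform(-0.3, 0.3, size=(K, L, P, P))
    intercepts = rng.standard_normal((K, P)) * 2
    covs = np.array([np.eye(P) * rng.uniform(0.5, 1.5) for _ in range(K)])
    trans = rng.uniform(0.2, 1.0, size=(K, K))
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.uniform(0.2, 1.0, size=K)
    return ARHMMModel(ar, intercepts, covs, trans, init / init.sum())


def _brute_force_best_path(model, X):
    """Exhaustive enumeration of all K^(T-L) paths (oracle)."""
    data = _prepare_blocks([X], None, model.ar_order)
    weights, covs = _model_to_weights(model)
    logB = _emission_loglik(data, weights, covs)
    K = model.n_states
    M = logB.shape[0]
    best_ll, best_path = -np.inf, None
    logA = np.log(model.transition_matrix)
    logpi = np.log(model.initial_distribution)
    for path in itertools.product(range(K), repeat=M):
        ll = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, M):
            ll += logA[path[t - 1], path[t]] + logB[t, path[t]]
        if ll > best_ll + 1e-12:
            best_ll, best_path = ll, path
    return best_ll, np.array(best_path)


class TestViterbi:
    def test_single_state_all_zero(self):
        model = eq.build_demo_model(K=1, P=2)
        X = np.random.default_rng(0).standard_normal((50, 2))
        seq = eq.viterbi_decode(model, X)
        assert (seq.labels == 0).all()

    def test_matches_exhaustive_enumeration(self):
        """Viterbi path equals brute-force search over all 3^10 paths."""
        rng = np.random.default_rng(5)
        model = _random_model(3, 2, rng)
        X = rng.standard_normal((11, 2))  # 10 scored frames after AR warm-up
        seq = eq.viterbi_decode(model, X)
        best_ll, best_path = _brute_force_best_path(model, X)
        assert seq.log_likelihood == pytest.approx(best_ll, abs=1e-9)
        np.testing.assert_array_equal(seq.labels[1:], best_path)

    def test_tie_break_prefers_lowest_state(self):
        """Uniform transitions and identical emissions: the decoded path
        attains the brute-force maximum and resolves ties to state 0."""
        P = 2
        ar = np.zeros((3, 1, P, P))
        intercepts = np.zeros((3, P))
        covs = np.array([np.eye(P)] * 3)
        model = ARHMMModel(ar, intercepts, covs, np.full((3, 3), 1 / 3), np.full(3, 1 / 3))
        X = np.random.default_rng(1).standard_normal((8, P))
        seq = eq.viterbi_decode(model, X)
        best_ll, _ = _brute_force_best_path(model, X)
        assert seq.log_likelihood == pytest.approx(best_ll, abs=1e-9)
        assert (seq.labels == 0).all()


class TestEMFitting:
    def test_single_state_model(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 2))
        fit = eq.fit_arhmm([X], None, K=1, L=1, seed=0)
        np.testing.assert_allclose(fit.model.transition_matrix, [[1.0]])
        assert (fit.state_sequences[0].labels == 0).all()

    def test_loglik_monotone_and_rows_stochastic(self, fitted_3state):
        _sess, _scores, fit = fitted_3state
        ll = fit.log_likelihoods
        assert (np.diff(ll) >= -1e-8 * np.abs(ll[:-1])).all()
        rows = fit.model.transition_matrix.sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)
        fit.model.validate()

    def test_two_state_recovery(self):
        """Well-separated 2-state data is decoded to >= 95% frame accuracy up
        to label permutation (ground truth from the generator)."""
        model = eq.build_demo_model(K=2, P=2)
        sess, gt = eq.simulate_arhmm_session(model, minutes=3, gap_spec=None, seed=21)
        fit = eq.fit_arhmm([sess.features], None, K=2, L=1, seed=0)
        lab = fit.state_sequences[0].labels
        perm = eq.match_states(gt.states, lab, 2)
        acc = np.mean(perm[lab] == gt.states)
        assert acc >= 0.95

    def test_transition_matrix_recovery_within_005(self, demo_model_3):
        """3 sessions x 10 min: estimated transition entries within 0.05 of
        the generating matrix after optimal state matching."""
        sessions = [
            eq.simulate_arhmm_session(demo_model_3, minutes=10, gap_spec=None, seed=100 + i)
            for i in range(3)
        ]
        scores = [s.features for s, _ in sessions]
        fit = eq.fit_arhmm(scores, None, K=3, L=1, seed=1)
        truth = np.concatenate([g.states for _, g in sessions])
        est = np.concatenate([s.labels for s in fit.state_sequences])
        perm = eq.match_states(truth, est, 3)
        # reorder estimated matrix into the ground-truth state order
        order = np.argsort(perm)
        A = fit.model.transition_matrix[np.ix_(order, order)]
        assert np.abs(A - demo_model_3.transition_matrix).max() < 0.05

    def test_decode_partition_invariant_under_state_relabeling(self, fitted_3state):
        """Permuting the states of a fitted model permutes the decoded labels
        accordingly (same partition of frames)."""
        sess, scores, fit = fitted_3state
        m = fit.model
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        permuted = ARHMMModel(
            m.ar_coefs[perm],
            m.intercepts[perm],
            m.covariances[perm],
            m.transition_matrix[np.ix_(perm, perm)],
            m.initial_distribution[perm],
        )
        a = eq.viterbi_decode(m, scores, sess.valid_mask).labels
        b = eq.viterbi_decode(permuted, scores, sess.valid_mask).labels
        ok = a >= 0
        np.testing.assert_array_equal(inv[a[ok]], b[ok])

    def test_short_block_emission_only_fallback(self, fitted_3state, caplog):
        _sess, scores, fit = fitted_3state
        mask = np.zeros(scores.shape[0], bool)
        mask[:40] = True
        mask[50] = True  # isolated 1-frame block, shorter than L+1
        seq = eq.viterbi_decode(fit.model, scores, mask)
        assert seq.labels[50] >= 0
        assert (seq.labels[41:50] == -1).all()

    def test_iid_special_case_agrees_with_hmmlearn(self):
        """With zero AR coefficients the model is a plain Gaussian HMM; the
        decoded path and likelihood must match hmmlearn's (independent
        implementation)."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        model = _random_model(3, 2, rng)
        model.ar_coefs[:] = 0.0
        X = rng.standard_normal((200, 2)) + 1.0
        ours = eq.viterbi_decode(model, X)
        gh = hmm.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        gh.startprob_ = model.initial_distribution
        gh.transmat_ = model.transition_matrix
        gh.means_ = model.intercepts
        gh.covars_ = model.covariances
        ll_ref, path_ref = gh.decode(X[1:])  # our AR(1) fit conditions on the first frame
        np.testing.assert_array_equal(ours.labels[1:], path_ref)
        assert ours.log_likelihood == pytest.approx(ll_ref, rel=1e-10)


class TestEnsemble:
    def test_r1_equals_single_fit(self, fitted_3state):
        sess, scores, fit = fitted_3state
        ens = eq.run_ensemble([scores], [sess.valid_mask], K=3, L=1, R=1, master_seed=0, max_iter=100)
        np.testing.assert_array_equal(
            ens.fits[0].state_sequences[0].labels, fit.state_sequences[0].labels
        )

    def test_seeds_distinct_and_deterministic(self, fitted_3state):
        sess, scores, _ = fitted_3state
        ens = eq.run_ensemble([scores], [sess.valid_mask], K=3, L=1, R=3, master_seed=5)
        assert [f.seed for f in ens.fits] == [5, 6, 7]
        ens2 = eq.run_ensemble([scores], [sess.valid_mask], K=3, L=1, R=3, master_seed=5)
        for a, b in zip(ens.fits, ens2.fits):
            np.testing.assert_array_equal(
                a.state_sequences[0].labels, b.state_sequences[0].labels
            )

    def test_failing_fit_reports_seed(self):
        X = np.random.default_rng(0).standard_normal((30, 2))
        with pytest.raises(RuntimeError, match="seed 4"):
            eq.run_ensemble([X], None, K=25, L=1, R=1, master_seed=4)
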