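"""HMM core: initialization, EM, Viterbi against brute force, MSE, model
selection, state matching and labeling."""

import itertools

import numpy as np
import pytest

import polstate as ps
from polstate import hmm
from polstate.simulate import EmissionReference
from polstate.tracks import EnrichmentMatrix, StatePath


def make_matrix(arrays):
    data = {}
    for i, arr in enumerate(arrays):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = np.column_stack([arr] * 5)
        data[(f"chr{i}", "+")] = arr
    return EnrichmentMatrix(data=data)


def sample_hmm(params: hmm.HMMParams, n, rng):
    """Independent oracle sampler for a Gaussian HMM."""
    K = params.n_states
    z = np.empty(n, dtype=int)
    z[0] = rng.choice(K, p=params.startprob)
    for t in range(1, n):
        z[t] = rng.choice(K, p=params.transmat[z[t - 1]])
    chol = np.linalg.cholesky(params.covariances)
    x = params.means[z] + np.einsum(
        "nij,nj->ni", chol[z], rng.standard_normal((n, params.n_features)))
    return x, z


def brute_force_viterbi(X, params):
    """Exhaustive enumeration of all K^N paths (ties to lowest indices)."""
    N = X.shape[0]
    K = params.n_states
    logB = hmm._log_gaussian(X, params.means, params.covariances)
    logpi = np.log(params.startprob)
    logA = np.log(np.maximum(params.transmat, 1e-300))
    best, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=N):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, N):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best:  # itertools order makes first max the lexicographic min
            best, best_path = lp, path
    return np.array(best_path)


def random_params(K, D, rng, spread=3.0):
    trans = rng.uniform(0.2, 1.0, (K, K))
    trans /= trans.sum(1, keepdims=True)
    pi = rng.uniform(0.2, 1.0, K)
    pi /= pi.sum()
    means = rng.normal(0, spread, (K, D))
    covs = np.array([np.eye(D) * rng.uniform(0.5, 1.5) for _ in range(K)])
    return hmm.HMMParams(startprob=pi, transmat=trans, means=means,
                         covariances=covs)


class TestInitParams:
    def test_transition_rows_sum_to_one_and_deterministic(self):
        X = make_matrix([np.random.default_rng(0).normal(size=(200, 5))])
        p1 = hmm.init_params(X, K=4, seed=3)
        p2 = hmm.init_params(X, K=4, seed=3)
        np.testing.assert_allclose(p1.transmat.sum(axis=1), 1.0)
        np.testing.assert_array_equal(p1.means, p2.means)
        np.testing.assert_array_equal(p1.transmat, p2.transmat)

    def test_kmeans_centers_on_separable_clouds(self, rng):
        a = rng.normal(0, 0.01, (300, 5))
        b = rng.normal(5, 0.01, (300, 5))
        X = make_matrix([np.vstack([a, b])])
        p = hmm.init_params(X, K=2, seed=0)
        centers = p.means[np.argsort(p.means[:, 0])]
        assert np.abs(centers[0] - 0).max() < 0.05
        assert np.abs(centers[1] - 5).max() < 0.05


class TestEMFit:
    def test_loglik_trace_monotone_nondecreasing(self, rng):
        p = random_params(3, 5, rng)
        x, _ = sample_hmm(p, 800, rng)
        res = hmm.em_fit(make_matrix([x]), K=3, seed=0)
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_two_state_parameter_recovery(self, rng):
        truth = hmm.HMMParams(
            startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.95, 0.05], [0.05, 0.95]]),
            means=np.array([[0.0] * 5, [3.0] * 5]),
            covariances=np.array([np.eye(5), np.eye(5)]))
        x, _ = sample_hmm(truth, 6000, rng)
        res = hmm.em_fit(make_matrix([x]), K=2, seed=1)
        match = hmm.match_states(truth, res.params)
        assert np.abs(res.params.means[match] - truth.means).max() < 0.1
        assert np.abs(res.params.transmat[np.ix_(match, match)]
                      - truth.transmat).max() < 0.05

    def test_single_state_closed_form(self, rng):
        x = rng.normal(1.5, 2.0, size=(400, 5))
        res = hmm.em_fit(make_matrix([x]), K=1, seed=0, n_restarts=1)
        np.testing.assert_allclose(res.params.means[0], x.mean(0), atol=1e-6)
        np.testing.assert_allclose(res.params.covariances[0],
                                   np.cov(x, rowvar=False, ddof=0)
                                   + 1e-4 * np.eye(5), atol=1e-4)

    def test_sequence_order_invariance_of_likelihood(self, rng):
        p = random_params(2, 5, rng)
        xs = [sample_hmm(p, 300, rng)[0] for _ in range(3)]
        m1 = ps.PhosphoHMM(make_matrix(xs), n_states=2)
        m2 = ps.PhosphoHMM(make_matrix(xs[::-1]), n_states=2)
        assert m1.loglikelihood(p) == pytest.approx(m2.loglikelihood(p))

    def test_loglik_agrees_with_hmmlearn(self, rng):
        # independent cross-check of the forward algorithm
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        p = random_params(3, 5, rng)
        x, _ = sample_hmm(p, 500, rng)
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                     init_params="")
        model.startprob_ = p.startprob
        model.transmat_ = p.transmat
        model.means_ = p.means
        model.covars_ = p.covariances
        ours = ps.PhosphoHMM(make_matrix([x]), n_states=3).loglikelihood(p)
        assert ours == pytest.approx(model.score(x), abs=1e-6)


class TestViterbi:
    def test_worked_two_state_example(self):
        params = hmm.HMMParams(
            startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
            means=np.array([[0.0], [3.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]))
        X = EnrichmentMatrix(data={("c", "+"): np.array([[0.], [0.], [3.], [3.]])},
                             marks=("m",))
        path = hmm.viterbi(X, params)
        np.testing.assert_array_equal(path.data[("c", "+")], [0, 0, 1, 1])
        np.testing.assert_array_equal(
            brute_force_viterbi(np.array([[0.], [0.], [3.], [3.]]), params),
            [0, 0, 1, 1])

    def test_single_bin_is_argmax_of_initial_times_emission(self, rng):
        p = random_params(3, 5, rng)
        x = rng.normal(size=(1, 5))
        path = hmm.viterbi(make_matrix([x]), p)
        logB = hmm._log_gaussian(x, p.means, p.covariances)
        assert path.data[("chr0", "+")][0] == np.argmax(np.log(p.startprob) + logB[0])

    @pytest.mark.parametrize("K,N", [(2, 5), (3, 6), (3, 8), (2, 8)])
    def test_equals_brute_force_enumeration(self, K, N, rng):
        for trial in range(5):
            p = random_params(K, 3, rng, spread=1.0)
            x, _ = sample_hmm(p, N, rng)
            X = EnrichmentMatrix(data={("c", "+"): x}, marks=("a", "b", "c"))
            fast = hmm.viterbi(X, p).data[("c", "+")]
            np.testing.assert_array_equal(fast, brute_force_viterbi(x, p))


class TestMSE:
    def _params(self, means):
        K, D = means.shape
        return hmm.HMMParams(startprob=np.full(K, 1 / K),
                             transmat=np.full((K, K), 1 / K),
                             means=means,
                             covariances=np.array([np.eye(D)] * K))

    def test_perfect_fit_gives_zero(self):
        means = np.arange(10.0).reshape(2, 5)
        X = make_matrix([means[[0, 1, 0]]])
        path = StatePath(data={("chr0", "+"): np.array([0, 1, 0])}, n_states=2)
        assert hmm.mse(X, path, self._params(means)) == 0.0

    def test_two_strand_unit_residual_example(self):
        # one bin per strand, each residual with squared norm 5 -> (5+5)/10 = 1
        means = np.zeros((1, 5))
        x = np.full((1, 5), 1.0)  # ||x - mu||^2 = 5
        X = EnrichmentMatrix(data={("c", "+"): x, ("c", "-"): x.copy()})
        path = StatePath(data={("c", "+"): np.array([0]),
                               ("c", "-"): np.array([0])}, n_states=1)
        assert hmm.mse(X, path, self._params(means)) == pytest.approx(1.0)

    def test_quadratic_homogeneity(self, rng):
        means = np.zeros((1, 5))
        x = rng.normal(size=(20, 5))
        X1, X3 = make_matrix([x]), make_matrix([3 * x])
        path = StatePath(data={("chr0", "+"): np.zeros(20, dtype=int)}, n_states=1)
        p = self._params(means)
        assert hmm.mse(X3, path, p) == pytest.approx(9 * hmm.mse(X1, path, p))

    def test_misaligned_path_raises(self):
        X = make_matrix([np.zeros((4, 5))])
        path = StatePath(data={("chr0", "+"): np.zeros(3, dtype=int)}, n_states=1)
        with pytest.raises(ValueError, match="misaligned"):
            hmm.mse(X, path, self._params(np.zeros((1, 5))))

    def test_true_path_beats_corrupted_path(self, rng):
        truth = hmm.HMMParams(
            startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
            means=np.array([[0.0] * 5, [3.0] * 5]),
            covariances=np.array([0.2 * np.eye(5)] * 2))
        x, z = sample_hmm(truth, 400, rng)
        X = make_matrix([x])
        true_path = StatePath(data={("chr0", "+"): z}, n_states=2)
        corrupt = z.copy()
        flip = rng.choice(400, 60, replace=False)
        corrupt[flip] = 1 - corrupt[flip]
        bad_path = StatePath(data={("chr0", "+"): corrupt}, n_states=2)
        assert hmm.mse(X, true_path, truth) < hmm.mse(X, bad_path, truth)


class TestSelectK:
    def test_recovers_three_separated_states(self, rng):
        truth = hmm.HMMParams(
            startprob=np.full(3, 1 / 3),
            transmat=np.array([[0.9, 0.05, 0.05],
                               [0.05, 0.9, 0.05],
                               [0.05, 0.05, 0.9]]),
            means=np.array([[-4.0] * 5, [0.0] * 5, [4.0] * 5]),
            covariances=np.array([0.3 * np.eye(5)] * 3))
        x, _ = sample_hmm(truth, 3000, rng)
        sel = hmm.select_k(make_matrix([x]), k_range=range(2, 6), seed=0)
        assert sel.chosen_k == 3
        # MSE non-increasing in K up to noise
        assert np.all(np.diff(sel.mses) < 0.05)

    def test_singleton_range_returns_that_k(self, rng):
        x = rng.normal(size=(300, 5))
        sel = hmm.select_k(make_matrix([x]), k_range=[4], seed=0)
        assert sel.chosen_k == 4


class TestMatchAndLabel:
    def test_permutation_recovery_and_identity(self, rng):
        a = random_params(4, 5, rng)
        perm = np.array([2, 0, 3, 1])
        b = hmm.HMMParams(startprob=a.startprob, transmat=a.transmat,
                          means=a.means[perm], covariances=a.covariances[perm])
        # b's state j carries a's state perm[j]; match[a_state] = b_state
        match = hmm.match_states(a, b)
        np.testing.assert_array_equal(match, np.argsort(perm))
        np.testing.assert_array_equal(hmm.match_states(a, a), np.arange(4))

    def test_assignment_cost_beats_all_enumerated_permutations(self, rng):
        for _ in range(5):
            a = random_params(3, 5, rng, spread=1.0)
            b = random_params(3, 5, rng, spread=1.0)
            match = hmm.match_states(a, b)
            cost = np.linalg.norm(a.means - b.means[match], axis=1).sum()
            for perm in itertools.permutations(range(3)):
                alt = np.linalg.norm(a.means - b.means[list(perm)], axis=1).sum()
                assert cost <= alt + 1e-9

    def test_k_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            hmm.match_states(random_params(3, 5, rng), random_params(4, 5, rng))

    def test_exact_reference_gives_identity_labeling(self):
        ref = EmissionReference.default()
        p = hmm.HMMParams(startprob=np.full(8, 1 / 8),
                          transmat=np.full((8, 8), 1 / 8),
                          means=ref.means, covariances=ref.covariances)
        labels = hmm.label_states(p, ref)
        assert labels == {i: lab for i, lab in enumerate(ref.labels)}

    def test_labeling_stable_under_small_perturbation(self, rng):
        ref = EmissionReference.default()
        p = hmm.HMMParams(startprob=np.full(8, 1 / 8),
                          transmat=np.full((8, 8), 1 / 8),
                          means=ref.means + rng.normal(0, 0.05, (8, 5)),
                          covariances=ref.covariances)
        assert hmm.label_states(p, ref) == {i: lab for i, lab
                                            in enumerate(ref.labels)}

    def test_fewer_states_than_labels_leaves_labels_unused(self, rng):
        ref = EmissionReference.default()
        p = hmm.HMMParams(startprob=np.full(6, 1 / 6),
                          transmat=np.full((6, 6), 1 / 6),
                          means=ref.means[:6], covariances=ref.covariances[:6])
        labels = hmm.label_states(p, ref)
        assert len(labels) == 6
        assert len(set(labels.values())) == 6


class TestResultsObject:
    def test_summary_and_json_roundtrip(self, tmp_path, rng):
        p = random_params(2, 5, rng)
        x, _ = sample_hmm(p, 500, rng)
        res = hmm.em_fit(make_matrix([x]), K=2, seed=0)
        res.label_states(EmissionReference.default())
        s = res.summary()
        assert "states (K):        2" in s and "MSE" in s
        path = tmp_path / "model.json"
        res.save(path)
        params, labels = hmm.PhosphoHMMResults.load_params(path)
        np.testing.assert_allclose(params.means, res.params.means)
        assert labels == res.labels
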