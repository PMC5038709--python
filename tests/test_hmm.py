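"""HMM checks: quantization, decoding against brute-force enumeration,
VPC counting, and SVI update behaviour."""

import itertools

import numpy as np
import pytest

from psychstate.hmm import (
    Codebook,
    HMMParams,
    greedy_decode,
    quantize_observations,
    sequence_log_likelihood,
    svi_train,
    viterbi_decode,
    vpc_train,
)
from psychstate.states import STATES


def random_model(rng, m=3, K=4):
    return HMMParams(
        pi=rng.dirichlet(np.ones(m)),
        trans=rng.dirichlet(np.ones(m), m),
        emis=rng.dirichlet(np.ones(K), m),
        states=STATES[:m],
    )


def brute_force_best_path(params, obs):
    """Enumerate every state path and maximize the joint log probability."""
    m, T = params.m, len(obs)
    log_pi, log_t = params.log_pi(), params.log_trans()
    log_e = params.log_emission(obs)
    best_logp, best_paths = -np.inf, []
    for path in itertools.product(range(m), repeat=T):
        logp = log_pi[path[0]] + log_e[0, path[0]]
        for t in range(1, T):
            logp += log_t[path[t - 1], path[t]] + log_e[t, path[t]]
        if logp > best_logp + 1e-12:
            best_logp, best_paths = logp, [path]
        elif logp > best_logp - 1e-12:
            best_paths.append(path)
    return best_logp, best_paths


class TestQuantization:
    def test_one_symbol_per_distinct_vector(self, rng):
        X = rng.normal(size=(6, 2))
        symbols, codebook = quantize_observations(X, K=6, seed=0)
        assert len(set(symbols)) == 6
        # zero quantization error: every vector sits on its centroid
        np.testing.assert_allclose(codebook.centroids[symbols], X, atol=1e-9)

    def test_single_cluster_collapses_symbols(self, rng):
        X = rng.normal(size=(20, 3))
        symbols, _ = quantize_observations(X, K=1, seed=0)
        assert set(symbols) == {0}

    def test_separated_clusters_are_pure(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        ids = rng.integers(0, 3, size=150)
        X = centers[ids] + rng.normal(0, 0.3, size=(150, 2))
        symbols, _ = quantize_observations(X, K=3, seed=1)
        for c in range(3):
            assert len(set(symbols[ids == c])) == 1

    def test_assignment_deterministic(self, rng):
        X = rng.normal(size=(30, 2))
        s1, cb = quantize_observations(X, K=4, seed=7)
        np.testing.assert_array_equal(s1, cb.assign(X))


class TestViterbi:
    def test_single_state_model(self):
        params = HMMParams(
            pi=np.array([1.0]), trans=np.array([[1.0]]),
            emis=np.array([[0.5, 0.5]]), states=("N",),
        )
        path, _, _ = viterbi_decode(params, np.array([0, 1, 0, 1]))
        assert path == ["N"] * 4

    def test_deterministic_emissions_recover_symbols(self):
        params = HMMParams(
            pi=np.full(3, 1 / 3), trans=np.full((3, 3), 1 / 3),
            emis=np.eye(3),
        )
        obs = np.array([0, 2, 1, 1, 0])
        path, _, _ = viterbi_decode(params, obs)
        assert path == [STATES[i] for i in obs]

    def test_matches_brute_force_on_random_models(self, rng):
        for _ in range(25):
            params = random_model(rng)
            obs = rng.integers(0, 4, size=6)
            path, logp, _ = viterbi_decode(params, obs)
            best_logp, best_paths = brute_force_best_path(params, obs)
            assert logp == pytest.approx(best_logp, abs=1e-9)
            if len(best_paths) == 1:
                assert tuple(STATES.index(s) for s in path) == best_paths[0]

    def test_path_beats_random_paths(self, rng):
        params = random_model(rng)
        obs = rng.integers(0, 4, size=12)
        _, logp, _ = viterbi_decode(params, obs)
        log_pi, log_t = params.log_pi(), params.log_trans()
        log_e = params.log_emission(obs)
        for _ in range(1000):
            path = rng.integers(0, 3, size=len(obs))
            lp = log_pi[path[0]] + log_e[0, path[0]]
            for t in range(1, len(obs)):
                lp += log_t[path[t - 1], path[t]] + log_e[t, path[t]]
            assert logp >= lp - 1e-9

    def test_impossible_observation_flagged(self):
        params = HMMParams(
            pi=np.array([0.5, 0.5, 0.0]), trans=np.full((3, 3), 1 / 3),
            emis=np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]]),
        )
        path, _, floored = viterbi_decode(params, np.array([0, 1, 0]))
        assert floored
        assert len(path) == 3


class TestGreedy:
    def test_agrees_with_viterbi_on_deterministic_emissions(self):
        params = HMMParams(
            pi=np.full(3, 1 / 3), trans=np.full((3, 3), 1 / 3), emis=np.eye(3)
        )
        obs = np.array([2, 0, 1])
        assert greedy_decode(params, obs) == viterbi_decode(params, obs)[0]

    def test_disagrees_with_viterbi_sometimes(self, rng):
        """The stepwise argmax is myopic: over many random instances it
        must diverge from the global optimum at least once."""
        diffs = 0
        for _ in range(1000):
            params = random_model(rng, K=3)
            obs = rng.integers(0, 3, size=6)
            if greedy_decode(params, obs) != viterbi_decode(params, obs)[0]:
                diffs += 1
        assert diffs > 0


class TestVPC:
    def test_pure_counts_in_supervised_mode(self):
        seqs = [np.zeros(5, dtype=int)] * 4
        labels = [["N"] * 5] * 4
        params = vpc_train(seqs, labels=labels, K=2, smoothing=1e-9)
        assert params.trans[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert params.emis[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_large_smoothing_pushes_to_uniform(self):
        seqs = [np.zeros(5, dtype=int)] * 4
        labels = [["N"] * 5] * 4
        params = vpc_train(seqs, labels=labels, K=2, smoothing=1e6)
        np.testing.assert_allclose(params.trans, 1 / 3, atol=1e-3)
        np.testing.assert_allclose(params.emis, 1 / 2, atol=1e-3)

    def test_rows_are_distributions_after_training(self, rng):
        true = random_model(rng, K=5)
        seqs, labels = [], []
        for _ in range(30):
            states, obs = _sample_sequence(true, 40, rng)
            seqs.append(obs)
            labels.append(states)
        params = vpc_train(seqs, labels=labels, K=5)
        assert np.all(params.pi >= 0)
        np.testing.assert_allclose(params.pi.sum(), 1.0, atol=1e-9)
        np.testing.assert_allclose(params.trans.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(params.emis.sum(axis=1), 1.0, atol=1e-9)

    def test_unsupervised_mode_runs_single_pass(self, rng):
        true = random_model(rng, K=5)
        seqs = [_sample_sequence(true, 40, rng)[1] for _ in range(20)]
        params = vpc_train(seqs, K=5, seed=3)
        np.testing.assert_allclose(params.trans.sum(axis=1), 1.0, atol=1e-9)

    def test_recovery_error_shrinks_with_data(self, rng):
        true = _well_conditioned_model()
        errs = []
        for n in (50, 200, 800):
            seqs, labels = [], []
            r = np.random.default_rng(11)
            for _ in range(n):
                states, obs = _sample_sequence(true, 100, r)
                seqs.append(obs)
                labels.append(states)
            est = vpc_train(seqs, labels=labels, K=true.emis.shape[1])
            errs.append(np.abs(est.trans - true.trans).max())
        assert errs[2] < errs[0]

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vpc_train([np.zeros(4, dtype=int)], labels=[["N"] * 3], K=2)


def _well_conditioned_model():
    return HMMParams(
        pi=np.array([0.5, 0.3, 0.2]),
        trans=np.array([[0.8, 0.15, 0.05], [0.1, 0.7, 0.2], [0.05, 0.25, 0.7]]),
        emis=np.array(
            [[0.7, 0.2, 0.05, 0.05],
             [0.1, 0.6, 0.2, 0.1],
             [0.05, 0.1, 0.25, 0.6]]
        ),
    )


def _sample_sequence(params, T, rng):
    states = [rng.choice(params.m, p=params.pi)]
    for _ in range(T - 1):
        states.append(rng.choice(params.m, p=params.trans[states[-1]]))
    obs = np.array([rng.choice(params.emis.shape[1], p=params.emis[s]) for s in states])
    return [STATES[s] for s in states], obs


class TestSVI:
    def test_zero_step_size_keeps_initialization(self, rng):
        seqs = [rng.integers(0, 4, size=20) for _ in range(8)]
        params = svi_train(
            seqs, K=4, batch_size=4, learning_rate=0.0, n_iterations=10, seed=5
        )
        # with rho = 0 every update is a no-op: the result is the
        # normalized initial Dirichlet parameters
        r = np.random.default_rng(5)
        u_pi = 1.0 + 0.01 * r.random(3)
        np.testing.assert_allclose(params.pi, u_pi / u_pi.sum(), atol=1e-12)

    def test_full_batch_unit_step_equals_batch_update(self, rng):
        """One SVI step at batch = full data, rho = 1 must coincide with
        the closed-form batch variational update (prior + statistics)."""
        from scipy.special import digamma

        from psychstate.hmm import _forward_backward

        seqs = [rng.integers(0, 4, size=15) for _ in range(6)]
        params = svi_train(
            seqs, K=4, batch_size=6, learning_rate=1.0, kappa=0.0,
            n_iterations=1, seed=9,
        )
        # independent replication of the same single update
        r = np.random.default_rng(9)
        u_pi = 1.0 + 0.01 * r.random(3)
        u_trans = 1.0 + 0.01 * r.random((3, 3))
        u_emis = 1.0 + 0.01 * r.random((3, 4))
        batch = r.choice(6, size=6, replace=False)
        e = lambda u: digamma(u) - digamma(u.sum(axis=-1, keepdims=True))
        s_pi, s_trans = np.zeros(3), np.zeros((3, 3))
        s_emis = np.zeros((3, 4))
        for idx in batch:
            seq = seqs[idx]
            gamma, xi = _forward_backward(e(u_pi), e(u_trans), e(u_emis)[:, seq].T)
            s_pi += gamma[0]
            s_trans += xi
            for j in range(3):
                np.add.at(s_emis[j], seq, gamma[:, j])
        expect_pi = 1.0 + s_pi
        np.testing.assert_allclose(params.pi, expect_pi / expect_pi.sum(), atol=1e-9)
        expect_trans = 1.0 + s_trans
        np.testing.assert_allclose(
            params.trans, expect_trans / expect_trans.sum(axis=1, keepdims=True),
            atol=1e-9,
        )

    def test_oversized_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            svi_train([rng.integers(0, 3, size=5)], K=3, batch_size=2)

    def test_per_iteration_cost_independent_of_dataset_size(self, rng):
        """SVI's per-iteration work touches exactly batch_size sequences
        regardless of how many sequences the dataset holds."""
        import psychstate.hmm as hmm_mod

        counts = {}
        original = hmm_mod._forward_backward

        def counting_fb(*args, **kwargs):
            counts["n"] = counts.get("n", 0) + 1
            return original(*args, **kwargs)

        for n_seqs in (20, 200):
            seqs = [rng.integers(0, 3, size=10) for _ in range(n_seqs)]
            counts["n"] = 0
            hmm_mod._forward_backward = counting_fb
            try:
                svi_train(seqs, K=3, batch_size=5, n_iterations=7, seed=0)
            finally:
                hmm_mod._forward_backward = original
            assert counts["n"] == 7 * 5


def test_params_json_round_trip(tmp_path, rng):
    params = random_model(rng)
    path = tmp_path / "hmm.json"
    params.to_json(path)
    loaded = HMMParams.from_json(path)
    np.testing.assert_array_equal(params.pi, loaded.pi)
    np.testing.assert_array_equal(params.trans, loaded.trans)
    np.testing.assert_array_equal(params.emis, loaded.emis)


def test_gaussian_emissions_supported(rng):
    params = HMMParams(
        pi=np.full(3, 1 / 3),
        trans=np.full((3, 3), 1 / 3),
        means=np.array([[0.0], [5.0], [10.0]]),
        variances=np.full((3, 1), 0.25),
    )
    obs = np.array([[0.1], [5.2], [9.8], [4.9]])
    path, _, _ = viterbi_decode(params, obs)
    assert path == ["N", "A", "E", "A"]


def test_forward_likelihood_cross_checked_against_hmmlearn(rng):
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    params = random_model(rng, K=5)
    obs = rng.integers(0, 5, size=30)
    ref = hmmlearn.CategoricalHMM(n_components=3)
    ref.startprob_ = params.pi
    ref.transmat_ = params.trans
    ref.emissionprob_ = params.emis
    expected = ref.score(obs.reshape(-1, 1))
    assert sequence_log_likelihood(params, obs) == pytest.approx(expected, abs=1e-8)
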