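"""Hidden Markov model over the psychiatric state alphabet.

The model is the triple lambda = {pi, T', E'}: initial state
probabilities, an m x m transition matrix and an emission model, all over
the hidden states (N, A, E).  Emissions are by default a discrete
distribution over a k-means codebook of the reduced (GDA) feature
vectors; diagonal-Gaussian emissions over the continuous features are
available behind the same interface.

Two trainers are provided: Viterbi Path Counting (VPC), which learns the
parameters in a single pass by counting events along labelled or
best-decoded paths, and Stochastic Variational Inference (SVI), which
performs noisy natural-gradient updates of Dirichlet posteriors from
mini-batches and therefore has a per-iteration cost independent of the
dataset size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma
from sklearn.cluster import KMeans

from .states import STATES, STATE_INDEX

__all__ = [
    "LOG_FLOOR",
    "HMMParams",
    "quantize_observations",
    "Codebook",
    "vpc_train",
    "svi_train",
    "viterbi_decode",
    "greedy_decode",
    "sequence_log_likelihood",
]

LOG_FLOOR = -1e9  # additive floor standing in for log(0)
VARIANCE_FLOOR = 1e-6


def _safe_log(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, LOG_FLOOR, dtype=float)
    mask = p > 0
    out[mask] = np.log(p[mask])
    return out


@dataclass
class HMMParams:
    """lambda = {pi, T', E'} with either discrete or Gaussian emissions."""

    pi: np.ndarray
    trans: np.ndarray
    emis: np.ndarray | None = None  # (m, K) discrete
    means: np.ndarray | None = None  # (m, d) Gaussian
    variances: np.ndarray | None = None  # (m, d) diagonal
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if self.emis is not None:
            self.emis = np.asarray(self.emis, dtype=float)
        if self.means is not None:
            self.means = np.asarray(self.means, dtype=float)
            self.variances = np.maximum(
                np.asarray(self.variances, dtype=float), VARIANCE_FLOOR
            )
        self.validate()

    @property
    def m(self) -> int:
        return len(self.states)

    @property
    def kind(self) -> str:
        return "discrete" if self.emis is not None else "gaussian"

    def validate(self) -> None:
        m = self.m
        if self.pi.shape != (m,) or self.trans.shape != (m, m):
            raise ValueError("pi/trans shapes inconsistent with the state set")
        rows = [("pi", self.pi[None, :]), ("trans", self.trans)]
        if self.emis is not None:
            if self.emis.shape[0] != m:
                raise ValueError("emission rows must match the state count")
            rows.append(("emis", self.emis))
        elif self.means is None:
            raise ValueError("need either discrete or Gaussian emissions")
        for name, mat in rows:
            if np.any(mat < -1e-12):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1 (tol 1e-9)")

    # -- log quantities -----------------------------------------------------
    def log_pi(self) -> np.ndarray:
        return _safe_log(self.pi)

    def log_trans(self) -> np.ndarray:
        return _safe_log(self.trans)

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """(T, m) log emission probabilities of an observation sequence."""
        obs = np.asarray(obs)
        if self.kind == "discrete":
            symbols = obs.astype(int)
            if symbols.ndim != 1:
                raise ValueError("discrete observations must be 1-D symbol indices")
            if symbols.min() < 0 or symbols.max() >= self.emis.shape[1]:
                raise ValueError("symbol outside codebook range")
            return _safe_log(self.emis)[:, symbols].T
        X = np.atleast_2d(obs.astype(float))
        out = np.empty((len(X), self.m))
        for j in range(self.m):
            var = self.variances[j]
            out[:, j] = -0.5 * np.sum(
                np.log(2 * np.pi * var) + (X - self.means[j]) ** 2 / var, axis=1
            )
        return out

    # -- JSON ---------------------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "states": list(self.states),
            "pi": self.pi.tolist(),
            "trans": self.trans.tolist(),
            "emis": None if self.emis is None else self.emis.tolist(),
            "means": None if self.means is None else self.means.tolist(),
            "variances": None if self.variances is None else self.variances.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "HMMParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pi=np.array(d["pi"]),
            trans=np.array(d["trans"]),
            emis=None if d["emis"] is None else np.array(d["emis"]),
            means=None if d["means"] is None else np.array(d["means"]),
            variances=None if d["variances"] is None else np.array(d["variances"]),
            states=tuple(d["states"]),
        )


# ---------------------------------------------------------------------------
# observation quantization


@dataclass
class Codebook:
    """k-means codebook bridging continuous features to discrete emissions."""

    centroids: np.ndarray

    @property
    def K(self) -> int:
        return len(self.centroids)

    def assign(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def quantize_observations(
    vectors: np.ndarray, K: int, seed: int
) -> tuple[np.ndarray, Codebook]:
    """Cluster feature vectors into a K-symbol codebook (deterministic seed)."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    n_distinct = len(np.unique(X, axis=0))
    k = min(K, n_distinct)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    codebook = Codebook(centroids=km.cluster_centers_.copy())
    return codebook.assign(X), codebook


# ---------------------------------------------------------------------------
# decoding


def _labels_to_idx(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    return np.array([STATE_INDEX[s] for s in arr], dtype=int)


def viterbi_decode(
    params: HMMParams, obs: np.ndarray
) -> tuple[list[str], float, bool]:
    """Most likely hidden path by the max-product dynamic program.

    Runs in log space with backpointers; argmax ties resolve to the
    lowest state index (N < A < E).  Returns (path, log joint
    probability, floored) where ``floored`` flags that some observation
    had zero probability under every state and the log floor was used.
    """
    log_e = params.log_emission(obs)
    T = len(log_e)
    if T == 0:
        raise ValueError("empty observation sequence")
    floored = bool(np.all(log_e <= LOG_FLOOR / 2, axis=1).any())
    log_t = params.log_trans()
    delta = params.log_pi() + log_e[0]
    back = np.zeros((T, params.m), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_t  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(params.m)] + log_e[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return [params.states[i] for i in path], float(np.max(delta)), floored


def greedy_decode(params: HMMParams, obs: np.ndarray) -> list[str]:
    """Stepwise argmax decoder (no backtracking).

    At each slot the state maximizing (running path probability) x
    (transition from the previously chosen state) x (emission) is chosen
    using only the past — the literal one-pass reading of the recursion,
    kept alongside :func:`viterbi_decode` for comparison.
    """
    log_e = params.log_emission(obs)
    if len(log_e) == 0:
        raise ValueError("empty observation sequence")
    log_t = params.log_trans()
    scores = params.log_pi() + log_e[0]
    q = int(np.argmax(scores))
    logp = scores[q]
    path = [q]
    for t in range(1, len(log_e)):
        scores = logp + log_t[q] + log_e[t]
        q = int(np.argmax(scores))
        logp = scores[q]
        path.append(q)
    return [params.states[i] for i in path]


def sequence_log_likelihood(params: HMMParams, obs: np.ndarray) -> float:
    """Marginal log likelihood by the scaled forward recursion."""
    log_e = params.log_emission(obs)
    shift = log_e.max(axis=1, keepdims=True)
    B = np.exp(log_e - shift)
    A = params.trans
    alpha = params.pi * B[0]
    ll = 0.0
    for t in range(len(B)):
        if t:
            alpha = (alpha @ A) * B[t]
        c = alpha.sum()
        if c <= 0:
            return float(LOG_FLOOR)
        ll += np.log(c)
        alpha = alpha / c
    return float(ll + shift.sum())


# ---------------------------------------------------------------------------
# VPC training


def _normalize_rows(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=-1, keepdims=True)
    sums = np.where(sums > 0, sums, 1.0)
    return counts / sums


def vpc_train(
    sequences: list[np.ndarray],
    labels: list | None = None,
    m: int = len(STATES),
    K: int = 16,
    smoothing: float = 1.0,
    seed: int = 0,
) -> HMMParams:
    """Viterbi Path Counting: learn lambda in a single pass over the data.

    Supervised mode (``labels`` given): count initial states, transitions
    and emissions directly along the labelled paths.  Unsupervised mode:
    start from a uniformly-perturbed lambda, decode each sequence once
    with Viterbi, and count along those best paths.  ``smoothing`` is the
    Laplace pseudo-count added to every cell before normalization.
    """
    if not sequences:
        raise ValueError("no training sequences")
    sequences = [np.asarray(s, dtype=int) for s in sequences]
    if smoothing < 0:
        raise ValueError("smoothing pseudo-count must be >= 0")
    pi_c = np.full(m, smoothing, dtype=float)
    trans_c = np.full((m, m), smoothing, dtype=float)
    emis_c = np.full((m, K), smoothing, dtype=float)

    if labels is not None:
        if len(labels) != len(sequences):
            raise ValueError("labels and sequences must align")
        paths = []
        for seq, lab in zip(sequences, labels):
            lab = _labels_to_idx(lab)
            if len(lab) != len(seq):
                raise ValueError("label/sequence length mismatch")
            paths.append(lab)
    else:
        rng = np.random.default_rng(seed)
        init = HMMParams(
            pi=_normalize_rows(np.ones(m) + 0.01 * rng.dirichlet(np.ones(m))),
            trans=_normalize_rows(np.ones((m, m)) + 0.01 * rng.dirichlet(np.ones(m), m)),
            emis=_normalize_rows(np.ones((m, K)) + 0.01 * rng.dirichlet(np.ones(K), m)),
        )
        paths = [_labels_to_idx(viterbi_decode(init, seq)[0]) for seq in sequences]

    for seq, path in zip(sequences, paths):
        pi_c[path[0]] += 1
        np.add.at(trans_c, (path[:-1], path[1:]), 1)
        np.add.at(emis_c, (path, seq), 1)
    return HMMParams(
        pi=_normalize_rows(pi_c),
        trans=_normalize_rows(trans_c),
        emis=_normalize_rows(emis_c),
    )


# ---------------------------------------------------------------------------
# SVI training


def _expected_log(u: np.ndarray) -> np.ndarray:
    """E[log theta] under a Dirichlet with natural parameter rows ``u``."""
    return digamma(u) - digamma(u.sum(axis=-1, keepdims=True))


def _forward_backward(
    log_pi: np.ndarray, log_t: np.ndarray, log_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior state marginals and expected transition counts of one sequence.

    Scaled (Rabiner-style) alpha-beta recursions in the linear domain;
    per-step emission shifts keep subnormalized expected-parameter inputs
    well conditioned.
    """
    T, m = log_e.shape
    # per-step emission shifts are absorbed by the scaling constants;
    # pi/A rows are (sub)normalized probabilities and exponentiate safely
    B = np.exp(log_e - log_e.max(axis=1, keepdims=True))
    pi = np.exp(log_pi)
    A = np.exp(log_t)
    alpha = np.empty((T, m))
    c = np.empty(T)
    a = pi * B[0]
    for t in range(T):
        if t:
            a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= 0:  # impossible observation: fall back to uniform
            a = np.full(m, 1.0 / m)
            c[t] = 1.0
        alpha[t] = a / c[t]
    beta = np.empty((T, m))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        xi = A * (alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None]))
        xi *= (T - 1) / xi.sum()  # each slot transition contributes unit mass
    else:
        xi = np.zeros((m, m))
    return gamma, xi


def svi_train(
    sequences: list[np.ndarray],
    m: int = len(STATES),
    K: int = 16,
    batch_size: int = 11,
    learning_rate: float = 0.9,
    kappa: float = 0.6,
    n_iterations: int = 200,
    seed: int = 0,
    prior: float = 1.0,
) -> HMMParams:
    """Stochastic variational inference for the discrete-emission HMM.

    Dirichlet posteriors over the pi, transition and emission rows are
    updated by noisy natural-gradient steps: each iteration subsamples
    ``batch_size`` sequences, computes expected sufficient statistics by
    forward-backward under the current variational means (E[log theta]),
    scales them to full-data size, and blends old and new natural
    parameters with step size ``rho_i = learning_rate * i**(-kappa)``.
    Returns the variational-mean parameters.
    """
    if not sequences:
        raise ValueError("no training sequences")
    n = len(sequences)
    if batch_size > n:
        raise ValueError(f"batch_size {batch_size} exceeds the {n} sequences")
    sequences = [np.asarray(s, dtype=int) for s in sequences]
    rng = np.random.default_rng(seed)
    u_pi = prior + 0.01 * rng.random(m)
    u_trans = prior + 0.01 * rng.random((m, m))
    u_emis = prior + 0.01 * rng.random((m, K))

    scale = n / batch_size
    for it in range(1, n_iterations + 1):
        rho = learning_rate * it ** (-kappa)
        batch = rng.choice(n, size=batch_size, replace=False)
        s_pi = np.zeros(m)
        s_trans = np.zeros((m, m))
        s_emis = np.zeros((m, K))
        e_log_pi = _expected_log(u_pi)
        e_log_t = _expected_log(u_trans)
        e_log_e = _expected_log(u_emis)
        for idx in batch:
            seq = sequences[idx]
            gamma, xi = _forward_backward(e_log_pi, e_log_t, e_log_e[:, seq].T)
            s_pi += gamma[0]
            s_trans += xi
            for j in range(m):
                np.add.at(s_emis[j], seq, gamma[:, j])
        u_pi = (1 - rho) * u_pi + rho * (prior + scale * s_pi)
        u_trans = (1 - rho) * u_trans + rho * (prior + scale * s_trans)
        u_emis = (1 - rho) * u_emis + rho * (prior + scale * s_emis)

    return HMMParams(
        pi=_normalize_rows(u_pi),
        trans=_normalize_rows(u_trans),
        emis=_normalize_rows(u_emis),
    )
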