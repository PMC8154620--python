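"""Discrete-emission hidden Markov models for macrostate and substate resolution.

The observed process is the cluster index of each frame in the global
descriptor discretization; the hidden process is the macrostate
(coil/globule) or a conformational substate.  Fitting is plain
Baum–Welch (EM) with the scaled forward–backward recursions; the
log-likelihood is non-decreasing over iterations, which the fitter
asserts.  Trajectories are strided by the model lag before fitting, so
hidden transition probabilities refer to the lag as their unit step.

Initialisation matters for EM: :func:`initial_emissions_from_groups`
builds emission rows from a microstate grouping (e.g. a PCCA split of a
microstate Markov model), which in practice places the two hidden
states on the right macrostates from iteration one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "HiddenMSM",
    "baum_welch",
    "viterbi_assign",
    "initial_emissions_from_groups",
    "spectral_initial_groups",
]

_EMISSION_FLOOR = 1e-12


@dataclass
class HiddenMSM:
    """Fitted discrete-emission HMM at a lag.

    ``hidden_transition_matrix`` (n_hidden x n_hidden) and
    ``emission_matrix`` (n_hidden x n_symbols) are row-stochastic;
    ``log_likelihood`` is the per-iteration EM trace.
    """

    n_hidden: int
    lag: int
    hidden_transition_matrix: np.ndarray
    emission_matrix: np.ndarray
    initial_distribution: np.ndarray
    log_likelihood: np.ndarray = field(repr=False)
    stationary: np.ndarray | None = None
    macrostate_map: dict[int, str] | None = None
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        assert np.allclose(self.hidden_transition_matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(self.emission_matrix.sum(axis=1), 1.0, atol=1e-9)

    @property
    def n_symbols(self) -> int:
        return self.emission_matrix.shape[1]


@njit(cache=True)
def _forward_backward(obs, startp, A, B):  # pragma: no cover - numba
    """Scaled forward-backward; returns loglik and E-step sufficient statistics."""
    T = obs.shape[0]
    K = A.shape[0]
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    scale = np.empty(T)

    for k in range(K):
        alpha[0, k] = startp[k] * B[k, obs[0]]
    s = alpha[0].sum()
    if s <= 0.0:
        s = 1e-300
    scale[0] = s
    alpha[0] /= s
    for t in range(1, T):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * B[k, obs[t]]
        s = alpha[t].sum()
        if s <= 0.0:
            s = 1e-300
        scale[t] = s
        alpha[t] /= s

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[k, j] * B[j, obs[t + 1]] * beta[t + 1, j]
            beta[t, k] = acc / scale[t + 1]

    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])

    gamma = alpha * beta
    for t in range(T):
        g = gamma[t].sum()
        if g > 0.0:
            gamma[t] /= g

    M = B.shape[1]
    trans_num = np.zeros((K, K))
    emis_num = np.zeros((K, M))
    for t in range(T - 1):
        denom = 0.0
        for j in range(K):
            for k in range(K):
                denom += alpha[t, j] * A[j, k] * B[k, obs[t + 1]] * beta[t + 1, k]
        if denom <= 0.0:
            denom = 1e-300
        for j in range(K):
            for k in range(K):
                trans_num[j, k] += (
                    alpha[t, j] * A[j, k] * B[k, obs[t + 1]] * beta[t + 1, k] / denom
                )
    for t in range(T):
        for k in range(K):
            emis_num[k, obs[t]] += gamma[t, k]

    return loglik, trans_num, emis_num, gamma[0]


@njit(cache=True)
def _viterbi(obs, startp, A, B):  # pragma: no cover - numba
    T = obs.shape[0]
    K = A.shape[0]
    logA = np.log(A + 1e-300)
    logB = np.log(B + 1e-300)
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = np.log(startp[k] + 1e-300) + logB[k, obs[0]]
    for t in range(1, T):
        for k in range(K):
            best = -1e300
            arg = 0
            for j in range(K):
                v = delta[t - 1, j] + logA[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + logB[k, obs[t]]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def spectral_initial_groups(
    transition_matrix: np.ndarray, n_groups: int, seed: int = 0
) -> np.ndarray:
    """PCCA-style microstate grouping from the top right eigenvectors.

    For ``n_groups == 2`` this reduces to the sign split of the second
    right eigenvector; for more groups, microstates are k-means
    clustered in the space of the first ``n_groups`` right eigenvectors.
    """
    from sklearn.cluster import KMeans

    T = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(T)
    order = np.argsort(-np.real(vals))
    V = np.real(vecs[:, order[:n_groups]])
    if n_groups == 2:
        v2 = V[:, 1]
        if v2.sum() < 0:
            v2 = -v2
        return (v2 > 0).astype(int)
    km = KMeans(n_clusters=n_groups, n_init=5, random_state=seed).fit(V)
    return km.labels_


def initial_emissions_from_groups(
    groups: np.ndarray,
    trajectories: list[np.ndarray],
    n_symbols: int,
    smoothing: float = 0.1,
) -> np.ndarray:
    """Emission matrix seeded from a symbol->group assignment.

    Row h is proportional to the empirical symbol counts within group h,
    plus a small uniform smoothing mass so EM can reassign symbols.
    """
    groups = np.asarray(groups, dtype=int)
    n_hidden = groups.max() + 1
    counts = np.zeros(n_symbols)
    for t in trajectories:
        counts += np.bincount(t, minlength=n_symbols)
    B = np.full((n_hidden, n_symbols), smoothing / n_symbols)
    for h in range(n_hidden):
        mask = np.zeros(n_symbols, dtype=bool)
        mask[np.flatnonzero(groups == h)] = True
        c = np.where(mask, counts, 0.0)
        if c.sum() > 0:
            B[h] += c / c.sum()
    return B / B.sum(axis=1, keepdims=True)


def baum_welch(
    trajectories: list[np.ndarray] | np.ndarray,
    n_hidden: int,
    lag: int = 1,
    n_symbols: int | None = None,
    init_emissions: np.ndarray | None = None,
    init_transitions: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
    seed: int = 0,
    frame_spacing: float = 1.0,
    update_emissions: bool = True,
) -> HiddenMSM:
    """Fit a discrete-emission HMM by EM on lag-strided trajectories.

    Each input sequence contributes ``lag`` strided phase-shifted
    subsequences so no frame is discarded.  Stops when the relative
    log-likelihood improvement drops below ``tol`` or after
    ``max_iter`` iterations.  Raises if the likelihood ever decreases
    beyond numerical noise.

    ``update_emissions=False`` freezes the emission matrix at its
    initial value and lets EM fit only the hidden transition and start
    probabilities.  This pins each hidden state to a prescribed symbol
    group (e.g. a PCCA split), which is the right behaviour when the
    hidden states must keep a fixed physical meaning and only the
    kinetics between them are unknown.
    """
    if n_hidden < 2:
        raise ValueError("n_hidden must be >= 2")
    if isinstance(trajectories, np.ndarray) and trajectories.ndim == 1:
        trajectories = [trajectories]
    seqs: list[np.ndarray] = []
    for t in trajectories:
        t = np.ascontiguousarray(np.asarray(t, dtype=np.int64))
        for phase in range(lag):
            s = t[phase::lag]
            if s.size >= 2:
                seqs.append(np.ascontiguousarray(s))
    if not seqs:
        raise ValueError(f"no trajectory yields >= 2 frames at lag {lag}")
    if n_symbols is None:
        n_symbols = max(int(s.max()) for s in seqs) + 1

    rng = np.random.default_rng(seed)
    if init_transitions is None:
        A = np.full((n_hidden, n_hidden), 0.05 / max(n_hidden - 1, 1))
        np.fill_diagonal(A, 0.95)
    else:
        A = np.array(init_transitions, dtype=float)
    if init_emissions is None:
        B = rng.uniform(0.5, 1.5, size=(n_hidden, n_symbols))
        B /= B.sum(axis=1, keepdims=True)
    else:
        B = np.array(init_emissions, dtype=float)
    startp = np.full(n_hidden, 1.0 / n_hidden)

    loglik_trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        total_ll = 0.0
        trans_num = np.zeros((n_hidden, n_hidden))
        emis_num = np.zeros((n_hidden, n_symbols))
        gamma0 = np.zeros(n_hidden)
        for s in seqs:
            ll, tn, en, g0 = _forward_backward(s, startp, A, B)
            total_ll += ll
            trans_num += tn
            emis_num += en
            gamma0 += g0
        loglik_trace.append(total_ll)
        if total_ll + 1e-6 * max(1.0, abs(total_ll)) < prev:
            raise RuntimeError(
                f"EM log-likelihood decreased: {prev:.6f} -> {total_ll:.6f}"
            )
        converged = (
            np.isfinite(prev)
            and abs(total_ll - prev) < tol * max(1.0, abs(total_ll))
        )
        prev = total_ll

        A = trans_num / np.maximum(trans_num.sum(axis=1, keepdims=True), 1e-300)
        zero_rows = trans_num.sum(axis=1) <= 0
        if zero_rows.any():
            A[zero_rows] = 1.0 / n_hidden
        if update_emissions:
            B = emis_num
            collapsed = B.sum(axis=1) <= 0
            if collapsed.any():
                warnings.warn(
                    f"{collapsed.sum()} emission row(s) collapsed; re-regularised",
                    stacklevel=2,
                )
            B = np.maximum(B, _EMISSION_FLOOR)
            B /= B.sum(axis=1, keepdims=True)
        startp = gamma0 / max(gamma0.sum(), 1e-300)
        startp = np.maximum(startp, 1e-12)
        startp /= startp.sum()
        if converged:
            break

    from .msm import stationary_distribution

    return HiddenMSM(
        n_hidden=n_hidden,
        lag=lag,
        hidden_transition_matrix=A,
        emission_matrix=B,
        initial_distribution=startp,
        log_likelihood=np.array(loglik_trace),
        stationary=stationary_distribution(A),
        frame_spacing=frame_spacing,
    )


def viterbi_assign(model: HiddenMSM, trajectory: np.ndarray) -> np.ndarray:
    """Most probable hidden path for a full-resolution discrete trajectory.

    Decoding runs at the model lag on each strided phase and the phase
    paths are re-interleaved, so every frame receives a label.  Symbols
    outside the fitted alphabet are handled through the emission floor,
    with a warning.
    """
    obs = np.ascontiguousarray(np.asarray(trajectory, dtype=np.int64))
    B = model.emission_matrix
    if obs.max() >= model.n_symbols:
        warnings.warn(
            "observed symbol outside the fitted alphabet; using emission floor",
            stacklevel=2,
        )
        extra = obs.max() + 1 - model.n_symbols
        B = np.hstack([B, np.full((model.n_hidden, extra), _EMISSION_FLOOR)])
        B = B / B.sum(axis=1, keepdims=True)
    path = np.empty(obs.size, dtype=np.int64)
    for phase in range(model.lag):
        s = obs[phase :: model.lag]
        if s.size == 0:
            continue
        path[phase :: model.lag] = _viterbi(
            s, model.initial_distribution, model.hidden_transition_matrix, B
        )
    return path
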