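"""Markov state models on discretized descriptor space.

Discretization is global: the per-dimension standard scaler and the
k-means centres are fit once on descriptors pooled over all
temperatures, so that cluster indices are comparable between
per-temperature models.  Transition matrices are estimated from
sliding-window transition counts at a lag; the reversible variant
row-normalises the symmetrised counts (C + C^T)/2, which satisfies
detailed balance exactly.  Mean first passage times come from the
standard linear first-passage system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .chain import InsufficientDataError

__all__ = [
    "Discretization",
    "MarkovModel",
    "DESCRIPTOR_COLUMNS",
    "fit_discretization",
    "assign",
    "split_discrete_trajectories",
    "count_transitions",
    "estimate_transition_matrix",
    "stationary_distribution",
    "implied_timescales",
    "recommend_lag",
    "pcca_two_state",
    "mfpt",
]

DESCRIPTOR_COLUMNS = ["rg_nm", "sasa_nm2", "omega_rad", "nu"]


@dataclass
class Discretization:
    """Fitted standard scaler + k-means centres in scaled 4D descriptor space."""

    mean: np.ndarray
    scale: np.ndarray
    centers: np.ndarray  # (n_centers, n_dims), scaled coordinates

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def fit_discretization(
    descriptors: pd.DataFrame,
    n_clusters: int = 250,
    seed: int = 0,
    columns: list[str] | None = None,
) -> Discretization:
    """Standard-scale pooled descriptors, then k-means with k-means++ seeding.

    The pooled table must span every temperature that will later be
    modelled; per-temperature MSMs share these centres.
    """
    columns = columns or DESCRIPTOR_COLUMNS
    X = descriptors[columns].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("descriptors contain non-finite values")
    if X.shape[0] < 10 * n_clusters:
        raise ValueError(
            f"need >= {10 * n_clusters} pooled frames for {n_clusters} clusters, "
            f"got {X.shape[0]}"
        )
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    km = KMeans(n_clusters=n_clusters, n_init=1, random_state=seed).fit(Xs)
    return Discretization(
        mean=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        centers=km.cluster_centers_.copy(),
    )


def assign(
    disc: Discretization,
    descriptors: pd.DataFrame,
    columns: list[str] | None = None,
) -> np.ndarray:
    """Nearest-centre cluster index per frame; ties broken by lowest index."""
    columns = columns or DESCRIPTOR_COLUMNS
    X = descriptors[columns].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X).all(axis=1)).ravel()[0]
        key = descriptors.iloc[bad][["temperature", "replica", "frame"]].tolist()
        raise ValueError(f"non-finite descriptor at (T, replica, frame)={key}")
    Xs = disc.transform(X)
    # squared distances; argmin returns the lowest index on ties
    d2 = (
        (Xs**2).sum(axis=1, keepdims=True)
        - 2 * Xs @ disc.centers.T
        + (disc.centers**2).sum(axis=1)
    )
    return np.argmin(d2, axis=1)


def split_discrete_trajectories(
    descriptors: pd.DataFrame, labels: np.ndarray
) -> dict[tuple[float, int], np.ndarray]:
    """Split a pooled per-frame label array into one sequence per (T, replica)."""
    out: dict[tuple[float, int], np.ndarray] = {}
    keys = descriptors[["temperature", "replica"]]
    for (T, rep), idx in keys.groupby(
        ["temperature", "replica"], sort=True
    ).indices.items():
        order = np.argsort(descriptors["frame"].to_numpy()[idx])
        out[(float(T), int(rep))] = np.asarray(labels)[idx][order]
    return out


def count_transitions(
    trajectories: list[np.ndarray] | np.ndarray,
    lag: int,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition counts C_ij = #{t : s_t = i, s_{t+lag} = j}.

    Counts never cross trajectory boundaries.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if isinstance(trajectories, np.ndarray) and trajectories.ndim == 1:
        trajectories = [trajectories]
    trajs = [np.asarray(t, dtype=int) for t in trajectories]
    if n_states is None:
        n_states = max(int(t.max()) for t in trajs if t.size) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    any_pairs = False
    for t in trajs:
        if t.size <= lag:
            continue
        any_pairs = True
        np.add.at(C, (t[:-lag], t[lag:]), 1)
    if not any_pairs:
        raise InsufficientDataError(f"no trajectory longer than lag={lag}")
    return C


@dataclass
class MarkovModel:
    """Row-stochastic transition matrix at a lag, with stationary distribution."""

    lag: int
    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    stationary: np.ndarray
    active_set: np.ndarray  # original state indices of the matrix rows
    reversible: bool = False
    frame_spacing: float = 1.0  # ns per frame (lag 1)

    def __post_init__(self) -> None:
        T = self.transition_matrix
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(self.stationary @ T, self.stationary, atol=1e-10)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalised."""
    vals, vecs = np.linalg.eig(T.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_transition_matrix(
    count_matrix: np.ndarray,
    lag: int = 1,
    reversible: bool = False,
    frame_spacing: float = 1.0,
) -> MarkovModel:
    """Maximum-likelihood transition matrix from transition counts.

    Non-reversible: row-normalised counts.  Reversible: row-normalised
    symmetrised counts (C + C^T)/2, which obeys detailed balance with a
    stationary distribution proportional to the symmetrised row sums.
    States with zero outgoing counts are dropped from the active set
    with a warning.
    """
    C = np.asarray(count_matrix, dtype=float)
    rowsums = C.sum(axis=1)
    seen = (rowsums > 0) | (C.sum(axis=0) > 0)
    active = np.flatnonzero(rowsums > 0)
    dropped = np.flatnonzero(seen & (rowsums == 0))
    if dropped.size:
        warnings.warn(
            f"dropping {dropped.size} absorbing zero-outgoing state(s): "
            f"{dropped.tolist()[:10]}",
            stacklevel=2,
        )
    Ca = C[np.ix_(active, active)]
    if reversible:
        Cs = 0.5 * (Ca + Ca.T)
        T = Cs / Cs.sum(axis=1, keepdims=True)
        pi = Cs.sum(axis=1) / Cs.sum()
    else:
        T = Ca / Ca.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
    return MarkovModel(
        lag=lag,
        count_matrix=C,
        transition_matrix=T,
        stationary=pi,
        active_set=active,
        reversible=reversible,
        frame_spacing=frame_spacing,
    )


def implied_timescales(
    model: MarkovModel, n_timescales: int = 5
) -> np.ndarray:
    """t_i = -lag / ln(lambda_i) for the largest non-unit eigenvalues.

    Eigenvalues with a non-negligible imaginary part are excluded (with
    a warning); eigenvalues at or above 1 map to infinity.
    """
    vals = np.linalg.eigvals(model.transition_matrix)
    order = np.argsort(-np.abs(vals))
    vals = vals[order][1 : n_timescales + 1]  # skip the unit eigenvalue
    ts = []
    for lam in vals:
        if abs(lam.imag) > 1e-8 * max(1.0, abs(lam.real)):
            warnings.warn(f"complex eigenvalue {lam:.4g} excluded", stacklevel=2)
            continue
        lam = lam.real
        if lam >= 1.0:
            ts.append(np.inf)
        elif lam <= 0.0:
            ts.append(0.0)
        else:
            ts.append(-model.lag / np.log(lam))
    return np.array(ts)


def recommend_lag(
    trajectories: list[np.ndarray],
    candidate_lags: list[int] | None = None,
    reversible: bool = False,
    rel_tol: float = 0.10,
) -> int:
    """Smallest lag whose slowest implied timescale is stable on doubling.

    Stability: |t2(2*lag) - t2(lag)| / t2(lag) < ``rel_tol``.  Falls back
    to the largest candidate when no lag plateaus.
    """
    if candidate_lags is None:
        candidate_lags = [1, 2, 5, 10, 20, 50]
    for lag in candidate_lags:
        try:
            m1 = estimate_transition_matrix(
                count_transitions(trajectories, lag), lag, reversible
            )
            m2 = estimate_transition_matrix(
                count_transitions(trajectories, 2 * lag), 2 * lag, reversible
            )
        except InsufficientDataError:
            break
        t1 = implied_timescales(m1, 1)
        t2 = implied_timescales(m2, 1)
        if t1.size and t2.size and np.isfinite(t1[0]) and np.isfinite(t2[0]):
            if abs(t2[0] - t1[0]) / t1[0] < rel_tol:
                return lag
    return candidate_lags[-1]


def pcca_two_state(model: MarkovModel) -> np.ndarray:
    """Two-macrostate split by the sign of the second right eigenvector.

    Returns an integer array over active states (0/1).  Components at
    exactly zero join the side carrying the larger stationary mass.
    """
    T = model.transition_matrix
    if T.shape[0] < 2:
        raise ValueError("need at least 2 active states")
    vals, vecs = np.linalg.eig(T)
    order = np.argsort(-np.real(vals))
    lam2 = vals[order[1]]
    if abs(lam2.imag) > 1e-8:
        raise ValueError(
            f"second eigenvalue {lam2:.4g} is complex; try a larger lag"
        )
    v2 = np.real(vecs[:, order[1]])
    # deterministic sign convention: positive sum
    if v2.sum() < 0:
        v2 = -v2
    groups = (v2 > 0).astype(int)
    zero = np.abs(v2) < 1e-12
    if zero.any():
        mass1 = model.stationary[groups == 1].sum()
        mass0 = model.stationary[groups == 0].sum()
        groups[zero] = int(mass1 >= mass0)
    if groups.min() == groups.max():  # pathological: force a split at the extremes
        groups = np.zeros_like(groups)
        groups[np.argmax(v2)] = 1
    return groups


def mfpt(
    transition_matrix: np.ndarray,
    source: np.ndarray | list[int],
    target: np.ndarray | list[int],
    lag: int = 1,
    frame_spacing: float = 1.0,
    stationary: np.ndarray | None = None,
) -> float:
    """Mean first passage time from ``source`` into ``target``, in time units.

    Solves m_i = 0 on the target and m_i = 1 + sum_j T_ij m_j elsewhere,
    then averages over source states weighted by the stationary
    distribution restricted to the source.  The step count is converted
    to time by ``lag * frame_spacing``.
    """
    T = np.asarray(transition_matrix, dtype=float)
    n = T.shape[0]
    target = np.asarray(target, dtype=int)
    source = np.asarray(source, dtype=int)
    if target.size == 0 or source.size == 0:
        raise ValueError("source and target must be non-empty")
    in_target = np.zeros(n, dtype=bool)
    in_target[target] = True
    if in_target.all() or in_target[source].all():
        return 0.0
    Q = np.flatnonzero(~in_target)
    A = np.eye(Q.size) - T[np.ix_(Q, Q)]
    try:
        m_Q = np.linalg.solve(A, np.ones(Q.size))
    except np.linalg.LinAlgError as err:
        raise ValueError("target unreachable from some source state") from err
    if not np.isfinite(m_Q).all() or (m_Q < -1e-9).any():
        raise ValueError("target unreachable from some source state")
    m = np.zeros(n)
    m[Q] = m_Q
    if stationary is None:
        stationary = stationary_distribution(T)
    w = stationary[source]
    if w.sum() <= 0:
        w = np.ones(source.size)
    w = w / w.sum()
    return float((w * m[source]).sum() * lag * frame_spacing)
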