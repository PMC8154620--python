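"""Synthetic bead-chain data with exact ground truth.

Two generator tiers stand in for long atomistic simulations of a
thermosensitive 20-mer:

1. A *mechanistic* Metropolis Monte Carlo sampler of a generic bead
   chain (harmonic bonds, harmonic bending, short-range non-bonded
   attraction).  The attraction strength grows linearly with
   temperature, which is the minimal mechanism for LCST-like behaviour:
   heating favours the collapsed globule.  MC frames carry no dynamics;
   their nominal frame spacing is a label.

2. A *hidden-Markov emission* generator: a discrete hidden chain over
   conformational substates with a known row-stochastic transition
   matrix, each state emitting a reference template conformation plus
   isotropic Gaussian bead noise.  This tier has exact thermodynamic
   (stationary odds) and kinetic (first-passage) ground truth, which the
   MC sampler cannot provide, and is what the recovery studies use.

Closed-form series generators produce van't Hoff equilibrium-constant
and Eyring rate tables with optional multiplicative lognormal noise.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so replica-level streams are
independent yet reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .chain import ChainTrajectory, GroundTruth
from .constants import R_GAS, R_GAS_KJ

__all__ = [
    "BeadChainParams",
    "simulate_bead_chain",
    "sample_harmonic_bond_1d",
    "generate_hidden_state_trajectory",
    "emit_conformations",
    "generate_equilibrium_series",
    "generate_rate_series",
    "helix_template",
    "default_substate_templates",
    "metropolis_transition_matrix",
    "CGTStudy",
    "make_cgt_study",
]


# ---------------------------------------------------------------------------
# Metropolis bead-chain sampler
# ---------------------------------------------------------------------------

@dataclass
class BeadChainParams:
    """Energy and move parameters of the Monte Carlo bead chain.

    Energies in kJ/mol, lengths in nm.  The effective pair attraction is
    eps_eff(T) = attract_eps0 + attract_slope * (T - 300 K); a positive
    slope strengthens collapse on heating (LCST-like).
    """

    bond_k: float = 8000.0  # kJ/mol/nm^2: keeps bond fluctuations ~7% of b0
    bond_b0: float = 0.25  # nm
    bend_k: float = 2.0  # kJ/mol/rad^2, 0 = fully flexible
    attract_eps0: float = 0.0  # kJ/mol at 300 K
    attract_slope: float = 0.0  # kJ/mol/K, >= 0
    attract_cutoff: float = 0.6  # nm
    step_size: float = 0.04  # nm, max single-bead displacement

    def eps_eff(self, temperature: float) -> float:
        return self.attract_eps0 + self.attract_slope * (temperature - 300.0)


@njit(cache=True)
def _pair_energy(r2, eps, rc):  # pragma: no cover - numba
    if r2 >= rc * rc:
        return 0.0
    x = 1.0 - r2 / (rc * rc)
    return -eps * x * x


@njit(cache=True)
def _bead_energy(coords, i, bond_k, b0, bend_k, eps, rc):  # pragma: no cover
    """Energy terms involving bead i: its bonds, the angles it touches,
    and all its non-bonded pair interactions."""
    n = coords.shape[0]
    e = 0.0
    for j in (i - 1, i):
        if 0 <= j < n - 1:
            dx = coords[j + 1, 0] - coords[j, 0]
            dy = coords[j + 1, 1] - coords[j, 1]
            dz = coords[j + 1, 2] - coords[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            e += 0.5 * bond_k * (r - b0) ** 2
    if bend_k > 0.0:
        for c in (i - 1, i, i + 1):
            if 1 <= c < n - 1:
                ax = coords[c, 0] - coords[c - 1, 0]
                ay = coords[c, 1] - coords[c - 1, 1]
                az = coords[c, 2] - coords[c - 1, 2]
                bx = coords[c + 1, 0] - coords[c, 0]
                by = coords[c + 1, 1] - coords[c, 1]
                bz = coords[c + 1, 2] - coords[c, 2]
                na = np.sqrt(ax * ax + ay * ay + az * az)
                nb = np.sqrt(bx * bx + by * by + bz * bz)
                ct = (ax * bx + ay * by + az * bz) / (na * nb)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                theta = np.arccos(ct)  # 0 = straight
                e += 0.5 * bend_k * theta * theta
    if eps != 0.0:
        for j in range(n):
            if abs(j - i) >= 2:
                dx = coords[i, 0] - coords[j, 0]
                dy = coords[i, 1] - coords[j, 1]
                dz = coords[i, 2] - coords[j, 2]
                e += _pair_energy(dx * dx + dy * dy + dz * dz, eps, rc)
    return e


@njit(cache=True)
def _mc_run(coords, beads, disps, unifs, beta, bond_k, b0, bend_k, eps, rc,
            save_every, out):  # pragma: no cover - numba
    n_steps = beads.shape[0]
    n_saved = 0
    accepted = 0
    for step in range(n_steps):
        i = beads[step]
        e_old = _bead_energy(coords, i, bond_k, b0, bend_k, eps, rc)
        ox, oy, oz = coords[i, 0], coords[i, 1], coords[i, 2]
        coords[i, 0] = ox + disps[step, 0]
        coords[i, 1] = oy + disps[step, 1]
        coords[i, 2] = oz + disps[step, 2]
        e_new = _bead_energy(coords, i, bond_k, b0, bend_k, eps, rc)
        de = e_new - e_old
        if de <= 0.0 or unifs[step] < np.exp(-beta * de):
            accepted += 1
        else:
            coords[i, 0], coords[i, 1], coords[i, 2] = ox, oy, oz
        if (step + 1) % save_every == 0:
            out[n_saved] = coords
            n_saved += 1
    return accepted


def simulate_bead_chain(
    n_beads: int,
    temperature: float,
    n_steps: int,
    params: BeadChainParams | None = None,
    seed: int = 0,
    save_every: int = 10,
    warmup_steps: int = 0,
    replica_id: int = 0,
) -> ChainTrajectory:
    """Metropolis Monte Carlo of the bead chain; returns every k-th frame.

    Single-bead displacement moves (uniform in a cube of half-width
    ``step_size``) accepted with the Metropolis criterion at the given
    temperature.  Bit-reproducible for a fixed seed.  Logs a warning if
    the post-warm-up acceptance ratio leaves (0.05, 0.95).
    """
    import warnings

    params = params or BeadChainParams()
    if n_beads < 4:
        raise ValueError(f"n_beads must be >= 4, got {n_beads}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if params.attract_slope < 0:
        raise ValueError("attract_slope must be >= 0 (LCST-like collapse)")
    rng = np.random.default_rng(seed)
    # start from a slightly perturbed straight chain to break collinearity
    coords = np.zeros((n_beads, 3))
    coords[:, 0] = np.arange(n_beads) * params.bond_b0
    coords += rng.normal(0.0, 0.01 * params.bond_b0, size=coords.shape)
    beta = 1.0 / (R_GAS_KJ * temperature)
    eps = params.eps_eff(temperature)

    def _run(steps, collect):
        beads = rng.integers(0, n_beads, size=steps)
        disps = rng.uniform(-params.step_size, params.step_size, size=(steps, 3))
        unifs = rng.random(steps)
        n_out = steps // save_every if collect else 0
        out = np.empty((max(n_out, 1), n_beads, 3))
        acc = _mc_run(
            coords, beads, disps, unifs, beta, params.bond_k, params.bond_b0,
            params.bend_k, eps, params.attract_cutoff,
            save_every if collect else steps + 1, out,
        )
        return acc, out[:n_out]

    if warmup_steps > 0:
        _run(warmup_steps, collect=False)
    accepted, frames = _run(n_steps, collect=True)
    ratio = accepted / n_steps
    if not 0.05 < ratio < 0.95:
        warnings.warn(
            f"MC acceptance ratio {ratio:.3f} outside (0.05, 0.95); "
            "consider adjusting step_size",
            stacklevel=2,
        )
    return ChainTrajectory(
        coordinates=frames,
        temperature=temperature,
        replica_id=replica_id,
        frame_spacing=1.0,
    )


def sample_harmonic_bond_1d(
    bond_k: float,
    temperature: float,
    n_steps: int,
    step_size: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """1D two-bead harmonic test mode: Metropolis samples of the bond extension.

    The stationary distribution is Gaussian with variance R T / bond_k
    (equipartition), which anchors the sampler against a closed form.
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / (R_GAS_KJ * temperature)
    x = 0.0
    disps = rng.uniform(-step_size, step_size, size=n_steps)
    unifs = rng.random(n_steps)
    out = np.empty(n_steps)
    for t in range(n_steps):
        xn = x + disps[t]
        de = 0.5 * bond_k * (xn * xn - x * x)
        if de <= 0 or unifs[t] < np.exp(-beta * de):
            x = xn
        out[t] = x
    return out


# ---------------------------------------------------------------------------
# Hidden-Markov emission generator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _markov_walk(cum_rows, start, unifs):  # pragma: no cover - numba
    n = unifs.shape[0]
    seq = np.empty(n, dtype=np.int64)
    state = start
    seq[0] = state
    for t in range(1, n):
        u = unifs[t]
        row = cum_rows[state]
        s = 0
        while row[s] < u:
            s += 1
        state = s
        seq[t] = state
    return seq


def generate_hidden_state_trajectory(
    transition_matrix: np.ndarray,
    n_frames: int,
    initial_distribution: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Realisation of a discrete Markov chain with the given matrix."""
    T = np.asarray(transition_matrix, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1 within 1e-9")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n = T.shape[0]
    rng = np.random.default_rng(seed)
    if initial_distribution is None:
        from .msm import stationary_distribution

        initial_distribution = stationary_distribution(T)
    start = int(rng.choice(n, p=np.asarray(initial_distribution, dtype=float)))
    unifs = rng.random(n_frames)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0 + 1e-12  # guard the closed upper edge
    return _markov_walk(np.ascontiguousarray(cum), start, unifs)


def emit_conformations(
    state_sequence: np.ndarray,
    templates: np.ndarray,
    noise_sd: float,
    seed: int = 0,
    temperature: float = 300.0,
    replica_id: int = 0,
    frame_spacing: float = 1.0,
) -> ChainTrajectory:
    """Frame = template of the frame's hidden state + isotropic Gaussian noise.

    ``templates`` has shape (n_states, n_beads, 3) in nm; ``noise_sd``
    is the per-coordinate displacement standard deviation (nm).
    """
    seq = np.asarray(state_sequence, dtype=int)
    templates = np.asarray(templates, dtype=float)
    if templates.ndim != 3 or templates.shape[2] != 3:
        raise ValueError("templates must have shape (n_states, n_beads, 3)")
    if seq.max() >= templates.shape[0] or seq.min() < 0:
        raise ValueError("state sequence refers to a missing template")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    coords = templates[seq]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    return ChainTrajectory(
        coordinates=coords,
        temperature=temperature,
        replica_id=replica_id,
        frame_spacing=frame_spacing,
    )


# ---------------------------------------------------------------------------
# Closed-form thermodynamic / kinetic series
# ---------------------------------------------------------------------------

def generate_equilibrium_series(
    dH: float,
    dS: float,
    temperatures: np.ndarray,
    noise_sd: float = 0.0,
    n_replicas: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Van't Hoff K_eq(T) table: ln K = -dH/(R T) + dS/R + Normal(0, noise_sd^2).

    ``dH`` in kJ/mol, ``dS`` in J/(mol K).  Multiplicative lognormal
    noise keeps K_eq > 0.  Columns: temperature, replica, K_eq.
    """
    T = np.asarray(temperatures, dtype=float)
    if (T <= 0).any():
        raise ValueError("temperatures must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicas):
        lnK = -dH * 1000.0 / (R_GAS * T) + dS / R_GAS
        if noise_sd > 0:
            lnK = lnK + rng.normal(0.0, noise_sd, size=T.shape)
        rows.append(
            pd.DataFrame({"temperature": T, "replica": rep, "K_eq": np.exp(lnK)})
        )
    return pd.concat(rows, ignore_index=True)


def generate_rate_series(
    c: float,
    dG_dagger: float,
    temperatures: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Eyring rate table: k(T) = c T exp(-dG_dagger/(R T)) with lognormal noise.

    ``c`` in 1/(ns K), ``dG_dagger`` in kJ/mol; rates in 1/ns.
    """
    T = np.asarray(temperatures, dtype=float)
    if c <= 0 or (T <= 0).any():
        raise ValueError("c and temperatures must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lnk = np.log(c * T) - dG_dagger * 1000.0 / (R_GAS * T)
    if noise_sd > 0:
        lnk = lnk + rng.normal(0.0, noise_sd, size=T.shape)
    return pd.DataFrame({"temperature": T, "rate": np.exp(lnk)})


# ---------------------------------------------------------------------------
# Study construction: substate templates + temperature-dependent hidden chains
# ---------------------------------------------------------------------------

def helix_template(
    n_beads: int, radius: float, rise: float, bond: float = 0.25
) -> np.ndarray:
    """Helical bead template with exact bond length (nm).

    The turn angle per bead is chosen so the chord plus the per-bead
    rise reproduces ``bond``; small radius + large rise gives a nearly
    extended chain, large radius + small rise a compact coil.
    """
    chord2 = bond * bond - rise * rise
    if chord2 <= 0:
        raise ValueError("rise must be smaller than the bond length")
    dtheta = 2.0 * np.arcsin(np.sqrt(chord2) / (2.0 * radius))
    k = np.arange(n_beads)
    coords = np.column_stack(
        [radius * np.cos(k * dtheta), radius * np.sin(k * dtheta), k * rise]
    )
    return coords - coords.mean(axis=0)


def default_substate_templates(n_beads: int = 20, bond: float = 0.25) -> np.ndarray:
    """Four reference conformations, ordered [C0, C1, G1, G0].

    C0 is the most extended coil (largest Rg), G0 the tightest globule
    (smallest Rg); helical constructions avoid collinear bead triples so
    every backbone torsion is well defined.
    """
    return np.stack(
        [
            helix_template(n_beads, radius=0.25, rise=0.96 * bond, bond=bond),  # C0
            helix_template(n_beads, radius=0.35, rise=0.72 * bond, bond=bond),  # C1
            helix_template(n_beads, radius=0.45, rise=0.24 * bond, bond=bond),  # G1
            helix_template(n_beads, radius=0.30, rise=0.12 * bond, bond=bond),  # G0
        ]
    )


def metropolis_transition_matrix(
    stationary: np.ndarray, proposal: np.ndarray
) -> np.ndarray:
    """Reversible row-stochastic matrix with the given stationary distribution.

    Metropolis construction: T_ij = q_ij * min(1, pi_j / pi_i) for
    i != j (``proposal`` q must be symmetric with row sums <= 1), and
    the diagonal absorbs the remainder.  Detailed balance holds exactly.
    """
    pi = np.asarray(stationary, dtype=float)
    q = np.asarray(proposal, dtype=float)
    if not np.allclose(q, q.T):
        raise ValueError("proposal matrix must be symmetric")
    n = pi.size
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and q[i, j] > 0:
                T[i, j] = q[i, j] * min(1.0, pi[j] / pi[i])
        T[i, i] = 1.0 - T[i].sum()
        if T[i, i] < 0:
            raise ValueError("proposal rows too heavy; reduce q")
    return T


@dataclass
class CGTStudy:
    """A complete synthetic coil-globule study: trajectories + ground truth."""

    trajectories: list
    ground_truth: GroundTruth
    temperatures: np.ndarray
    n_replicas: int
    templates: np.ndarray


def make_cgt_study(
    temperatures: np.ndarray | None = None,
    n_replicas: int = 4,
    n_frames: int = 20_000,
    dH: float = 100.0,
    dS: float = 351.86,
    noise_sd: float = 0.03,
    n_beads: int = 20,
    seed: int = 0,
    q_intra: float = 0.3,
    q_bridge: float = 0.25,
    coil_split: tuple[float, float] = (0.6, 0.4),
    globule_split: tuple[float, float] = (0.55, 0.45),
    frame_spacing: float = 1.0,
) -> CGTStudy:
    """Emission-generator study with van't Hoff thermodynamics built in.

    Hidden states are ordered [C0, C1, G1, G0].  At each temperature the
    stationary coil/globule odds follow ln K = -dH/(R T) + dS/R with the
    given within-macrostate splits; the hidden transition matrix is the
    Metropolis matrix for that stationary vector with exchange proposals
    ``q_intra`` (C0<->C1, G1<->G0) and ``q_bridge`` (the C1<->G1 and
    C0<->G0 crossings).  Ground-truth rates are reciprocal first-passage
    times of the true matrix.

    Defaults are scaled to a realistic thermoresponsive 20-mer: dH/dS place
    the transition temperature T* = 284.2 K inside the scanned range, and
    the six temperatures straddle it so both macrostates keep at least
    a quarter of the population everywhere; crossing proposals are fast
    enough that pooled occupancies resolve K_eq to a few percent at the
    default number of frames.
    """
    from .msm import mfpt

    if temperatures is None:
        temperatures = np.array([277.0, 280.0, 283.0, 286.0, 289.0, 292.0])
    temperatures = np.asarray(temperatures, dtype=float)
    templates = default_substate_templates(n_beads)
    macro = {0: "coil", 1: "coil", 2: "globule", 3: "globule"}

    q = np.zeros((4, 4))
    q[0, 1] = q[1, 0] = q_intra
    q[2, 3] = q[3, 2] = q_intra
    q[1, 2] = q[2, 1] = q_bridge  # C1 <-> G1
    q[0, 3] = q[3, 0] = q_bridge  # C0 <-> G0

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(temperatures) * n_replicas + 1)

    matrices: dict[float, np.ndarray] = {}
    sequences: dict[tuple[float, int], np.ndarray] = {}
    trajectories = []
    true_K: dict[float, float] = {}
    true_rates: dict[float, tuple[float, float]] = {}
    idx = 0
    for T in temperatures:
        lnK = -dH * 1000.0 / (R_GAS * T) + dS / R_GAS
        K = float(np.exp(lnK))
        p_glob = K / (1.0 + K)
        pi = np.array(
            [
                (1 - p_glob) * coil_split[0],
                (1 - p_glob) * coil_split[1],
                p_glob * globule_split[0],
                p_glob * globule_split[1],
            ]
        )
        M = metropolis_transition_matrix(pi, q)
        matrices[float(T)] = M
        true_K[float(T)] = K
        t_fwd = mfpt(M, [0, 1], [2, 3], 1, frame_spacing, stationary=pi)
        t_bwd = mfpt(M, [2, 3], [0, 1], 1, frame_spacing, stationary=pi)
        true_rates[float(T)] = (1.0 / t_fwd, 1.0 / t_bwd)
        for rep in range(n_replicas):
            child = child_seeds[idx]
            idx += 1
            s_seq, s_emit = (int(x) % (2**31) for x in child.generate_state(2))
            seq = generate_hidden_state_trajectory(M, n_frames, pi, seed=s_seq)
            traj = emit_conformations(
                seq,
                templates,
                noise_sd,
                seed=s_emit,
                temperature=float(T),
                replica_id=rep,
                frame_spacing=frame_spacing,
            )
            sequences[(float(T), rep)] = seq
            trajectories.append(traj)

    gt = GroundTruth(
        hidden_transition_matrix=matrices,
        state_sequences=sequences,
        macrostate_of_state=macro,
        dH_true=dH,
        dS_true=dS,
        extras={
            "K_eq_true": true_K,
            "rates_true": true_rates,
            "T_star_true": dH * 1000.0 / dS,
            "state_names": ["C0", "C1", "G1", "G0"],
            "noise_sd": noise_sd,
        },
    )
    return CGTStudy(
        trajectories=trajectories,
        ground_truth=gt,
        temperatures=temperatures,
        n_replicas=n_replicas,
        templates=templates,
    )
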