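"""Core in-memory containers for bead-chain trajectories and generator ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateGeometryError(ValueError):
    """A frame's geometry makes a descriptor undefined (e.g. zero-length segment vector)."""


class InsufficientDataError(ValueError):
    """Too few frames/samples for the requested estimate."""


@dataclass
class ChainTrajectory:
    """Multi-frame conformation record of a linear bead chain.

    Parameters
    ----------
    coordinates : ndarray, shape (n_frames, n_beads, 3)
        Bead positions in nm.
    temperature : float
        Simulation temperature in K.
    replica_id : int
        Replica index within the temperature group.
    frame_spacing : float
        Nominal time between saved frames in ns.  For Monte Carlo
        trajectories this is a label without dynamical meaning.
    """

    coordinates: np.ndarray
    temperature: float
    replica_id: int = 0
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (frames, beads, 3), got {self.coordinates.shape}"
            )
        if self.n_beads < 4:
            raise ValueError(f"need at least 4 beads, got {self.n_beads}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]

    def bond_lengths(self) -> np.ndarray:
        """Consecutive bead distances, shape (n_frames, n_beads - 1)."""
        d = np.diff(self.coordinates, axis=1)
        return np.linalg.norm(d, axis=2)

    def validate_bonds(self, b0: float, low: float = 0.5, high: float = 2.0) -> None:
        """Check bonded distances stay within (low*b0, high*b0)."""
        bl = self.bond_lengths()
        if bl.min() <= low * b0 or bl.max() >= high * b0:
            raise ValueError(
                f"bond lengths outside ({low * b0:.3g}, {high * b0:.3g}) nm: "
                f"range [{bl.min():.3g}, {bl.max():.3g}]"
            )


@dataclass
class GroundTruth:
    """Exact generating quantities of a synthetic dataset, for recovery tests.

    ``hidden_transition_matrix`` maps temperature -> row-stochastic matrix at
    lag 1 (in frames); ``macrostate_of_state`` maps hidden-state index ->
    "coil"/"globule".
    """

    hidden_transition_matrix: dict = field(default_factory=dict)
    state_sequences: dict = field(default_factory=dict)
    macrostate_of_state: dict = field(default_factory=dict)
    dH_true: float | None = None  # kJ/mol
    dS_true: float | None = None  # J/(mol K)
    dG_dagger_true: float | None = None  # kJ/mol
    c_true: float | None = None  # 1/(ns K)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for T, mat in self.hidden_transition_matrix.items():
            mat = np.asarray(mat, dtype=float)
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"transition matrix at T={T} is not row-stochastic")
            self.hidden_transition_matrix[T] = mat
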