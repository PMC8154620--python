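"""Conformational descriptors for linear bead chains.

The chain is viewed as a freely jointed chain (FJC) of short rigid
segments (default 3 monomers, one persistence length).  Four per-frame
descriptors summarise a conformation:

* ``Rg`` — mass-weighted radius of gyration (nm),
* ``sigma`` — solvent-accessible surface area by Shrake–Rupley (nm^2),
* ``Omega`` — sum of angles between consecutive FJC segments (rad);
  0 for a fully extended chain,
* ``nu`` — number of non-adjacent segment pairs whose centres of mass
  are closer than a cutoff.

Backbone dihedrals (one per consecutive bead quadruple) feed the
conformational-entropy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .chain import ChainTrajectory, DegenerateGeometryError

__all__ = [
    "SegmentModel",
    "DescriptorConfig",
    "segment_chain",
    "segment_vectors",
    "sum_of_segment_angles",
    "segment_contacts",
    "radius_of_gyration",
    "sasa",
    "sphere_points",
    "backbone_dihedrals",
    "descriptor_series",
    "dihedral_series",
]

_EPS_DEGENERATE = 1e-12


@dataclass(frozen=True)
class SegmentModel:
    """Partition of the chain into equal-length contiguous segments.

    Trailing monomers that do not fill a full segment are excluded from
    all segment-based quantities (they still count for Rg, SASA and
    dihedrals, which operate on the full chain).
    """

    segment_length: int
    segment_index_ranges: tuple[tuple[int, int], ...]  # half-open [start, stop)

    @property
    def n_segments(self) -> int:
        return len(self.segment_index_ranges)


def segment_chain(n_beads: int, segment_length: int = 3) -> SegmentModel:
    """Split ``n_beads`` into consecutive windows of ``segment_length`` monomers."""
    if segment_length < 2:
        raise ValueError(f"segment_length must be >= 2, got {segment_length}")
    if n_beads < 2 * segment_length:
        raise ValueError(
            f"need at least 2 segments: n_beads={n_beads} < {2 * segment_length}"
        )
    n_segments = n_beads // segment_length
    ranges = tuple(
        (i * segment_length, (i + 1) * segment_length) for i in range(n_segments)
    )
    return SegmentModel(segment_length=segment_length, segment_index_ranges=ranges)


def segment_vectors(coords: np.ndarray, model: SegmentModel) -> np.ndarray:
    """End-to-end vector of each segment: last monomer minus first monomer.

    ``coords`` may be a single frame (n_beads, 3) or a stack
    (n_frames, n_beads, 3); the result has a matching leading shape.
    """
    coords = np.asarray(coords, dtype=float)
    first = np.array([r[0] for r in model.segment_index_ranges])
    last = np.array([r[1] - 1 for r in model.segment_index_ranges])
    return coords[..., last, :] - coords[..., first, :]


def _unit_vectors(vecs: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vecs, axis=-1, keepdims=True)
    bad = norms[..., 0] < _EPS_DEGENERATE
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise DegenerateGeometryError(
            f"zero-length segment vector at index {tuple(int(i) for i in idx)}"
        )
    return vecs / norms


def sum_of_segment_angles(
    coords: np.ndarray, model: SegmentModel, pairs: str = "consecutive"
) -> np.ndarray | float:
    """Omega: sum of inter-segment angles, arccos of unit-vector dot products.

    ``pairs="consecutive"`` (default) sums over the n_segments - 1
    neighbouring pairs, bounded by (n_segments - 1) * pi; ``pairs="all"``
    sums over every segment pair.
    """
    u = _unit_vectors(segment_vectors(coords, model))
    if pairs == "consecutive":
        dots = np.einsum("...id,...id->...i", u[..., :-1, :], u[..., 1:, :])
    elif pairs == "all":
        i, j = np.triu_indices(model.n_segments, k=1)
        dots = np.einsum("...id,...id->...i", u[..., i, :], u[..., j, :])
    else:
        raise ValueError(f"pairs must be 'consecutive' or 'all', got {pairs!r}")
    omega = np.arccos(np.clip(dots, -1.0, 1.0)).sum(axis=-1)
    return float(omega) if omega.ndim == 0 else omega


def segment_centers_of_mass(
    coords: np.ndarray, model: SegmentModel, masses: np.ndarray | None = None
) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    n_beads = coords.shape[-2]
    if masses is None:
        masses = np.ones(n_beads)
    masses = np.asarray(masses, dtype=float)
    coms = []
    for start, stop in model.segment_index_ranges:
        m = masses[start:stop]
        coms.append(
            np.einsum("b,...bd->...d", m, coords[..., start:stop, :]) / m.sum()
        )
    return np.stack(coms, axis=-2)


def segment_contacts(
    coords: np.ndarray,
    model: SegmentModel,
    cutoff: float = 0.8,
    masses: np.ndarray | None = None,
) -> np.ndarray | int:
    """nu: count of segment pairs (i, j), j >= i + 2, with COM distance < cutoff.

    Adjacent pairs are excluded because bonded neighbours are trivially
    in contact.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    coms = segment_centers_of_mass(coords, model, masses)
    i, j = np.triu_indices(model.n_segments, k=2)
    d = np.linalg.norm(coms[..., i, :] - coms[..., j, :], axis=-1)
    nu = (d < cutoff).sum(axis=-1)
    return int(nu) if nu.ndim == 0 else nu


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> np.ndarray | float:
    """Mass-weighted RMS distance of beads from the centre of mass (nm)."""
    coords = np.asarray(coords, dtype=float)
    n_beads = coords.shape[-2]
    if masses is None:
        masses = np.ones(n_beads)
    masses = np.asarray(masses, dtype=float)
    if masses.sum() <= 0:
        raise ValueError("total mass must be positive")
    w = masses / masses.sum()
    com = np.einsum("b,...bd->...d", w, coords)
    dr = coords - com[..., None, :]
    rg2 = np.einsum("b,...b->...", w, np.einsum("...bd,...bd->...b", dr, dr))
    rg = np.sqrt(rg2)
    return float(rg) if rg.ndim == 0 else rg


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@njit(cache=True)
def _sasa_kernel(coords, radii, probe, points):  # pragma: no cover - numba
    n_frames, n_beads = coords.shape[0], coords.shape[1]
    n_points = points.shape[0]
    out = np.zeros(n_frames)
    for f in range(n_frames):
        total = 0.0
        for i in range(n_beads):
            ri = radii[i] + probe
            exposed = 0
            for p in range(n_points):
                px = coords[f, i, 0] + ri * points[p, 0]
                py = coords[f, i, 1] + ri * points[p, 1]
                pz = coords[f, i, 2] + ri * points[p, 2]
                buried = False
                for j in range(n_beads):
                    if j == i:
                        continue
                    rj = radii[j] + probe
                    dx = px - coords[f, j, 0]
                    dy = py - coords[f, j, 1]
                    dz = pz - coords[f, j, 2]
                    if dx * dx + dy * dy + dz * dz < rj * rj:
                        buried = True
                        break
                if not buried:
                    exposed += 1
            total += 4.0 * np.pi * ri * ri * exposed / n_points
        out[f] = total
    return out


def sasa(
    coords: np.ndarray,
    radii: np.ndarray | float = 0.25,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
    points: np.ndarray | None = None,
) -> np.ndarray | float:
    """Shrake–Rupley solvent-accessible surface area (nm^2).

    Each bead is expanded by the probe radius; test points on the
    expanded sphere count as exposed when outside every other expanded
    sphere.  ``points`` overrides the default golden-spiral point set
    (e.g. to rotate the quadrature with the frame).
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    n_beads = coords.shape[1]
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n_beads,)).copy()
    if (radii <= 0).any() or probe_radius < 0:
        raise ValueError("radii must be positive and probe_radius non-negative")
    if points is None:
        if n_sphere_points < 100:
            raise ValueError(f"n_sphere_points must be >= 100, got {n_sphere_points}")
        points = sphere_points(n_sphere_points)
    points = np.ascontiguousarray(points, dtype=float)
    out = _sasa_kernel(np.ascontiguousarray(coords), radii, probe_radius, points)
    return float(out[0]) if single else out


def backbone_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Signed torsions in (-pi, pi] for each consecutive bead quadruple.

    A planar trans quadruple gives |angle| = pi, a cis one 0.  Raises
    :class:`DegenerateGeometryError` when three consecutive beads are
    collinear (torsion undefined).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2] < 4:
        raise ValueError("need at least 4 beads for a dihedral")
    b = np.diff(coords, axis=-2)
    b1, b2, b3 = b[..., :-2, :], b[..., 1:-1, :], b[..., 2:, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1, axis=-1)
    n2n = np.linalg.norm(n2, axis=-1)
    bad = (n1n < 1e-10) | (n2n < 1e-10)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise DegenerateGeometryError(
            f"collinear bead triple makes torsion {tuple(int(i) for i in idx)} undefined"
        )
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("...d,...d->...", n1, n2)
    y = np.einsum("...d,...d->...", np.cross(n1, n2), b2u)
    phi = np.arctan2(y, x)
    # map the closed -pi endpoint onto +pi so values live in (-pi, pi]
    phi = np.where(phi <= -np.pi + 1e-15, np.pi, phi)
    return phi


@dataclass
class DescriptorConfig:
    """Parameters of the four-descriptor evaluation."""

    segment_length: int = 3
    contact_cutoff: float = 0.8  # nm, segment-COM contact distance
    bead_radius: float = 0.25  # nm
    probe_radius: float = 0.14  # nm
    n_sphere_points: int = 960
    omega_pairs: str = "consecutive"
    masses: np.ndarray | None = field(default=None, repr=False)


def descriptor_series(
    traj: ChainTrajectory, config: DescriptorConfig | None = None
) -> pd.DataFrame:
    """Per-frame (Rg, sigma, Omega, nu) table for one trajectory.

    Columns: ``temperature, replica, frame, rg_nm, sasa_nm2, omega_rad, nu``.
    """
    config = config or DescriptorConfig()
    model = segment_chain(traj.n_beads, config.segment_length)
    coords = traj.coordinates
    rg = radius_of_gyration(coords, config.masses)
    omega = sum_of_segment_angles(coords, model, config.omega_pairs)
    nu = segment_contacts(coords, model, config.contact_cutoff, config.masses)
    sigma = sasa(
        coords,
        radii=config.bead_radius,
        probe_radius=config.probe_radius,
        n_sphere_points=config.n_sphere_points,
    )
    return pd.DataFrame(
        {
            "temperature": traj.temperature,
            "replica": traj.replica_id,
            "frame": np.arange(traj.n_frames),
            "rg_nm": rg,
            "sasa_nm2": sigma,
            "omega_rad": omega,
            "nu": nu.astype(int),
        }
    )


def dihedral_series(traj: ChainTrajectory) -> pd.DataFrame:
    """Per-frame backbone torsions (rad); columns ``phi_1 .. phi_{n_beads-3}``."""
    phi = backbone_dihedrals(traj.coordinates)
    cols = {f"phi_{i + 1}": phi[:, i] for i in range(phi.shape[1])}
    return pd.DataFrame(
        {
            "temperature": traj.temperature,
            "replica": traj.replica_id,
            "frame": np.arange(traj.n_frames),
            **cols,
        }
    )
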