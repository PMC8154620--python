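"""On-disk formats: multi-frame XYZ trajectories, PDB templates, tables, manifests.

Conventions: internal lengths are nm.  The XYZ comment line carries
``frame=<i> temperature=<K> replica=<id> spacing_ns=<dt> unit=<nm|angstrom>``;
PDB files (MODEL/ENDMDL, one pseudo-atom per bead) are in Angstrom as
the format requires and converted on read.  Tables are CSV with a fixed
column order and JSON with sorted keys; floats are written at 12
significant digits so re-running a pipeline with the same seed
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import ChainTrajectory

__all__ = [
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "write_template_pdb",
    "read_trajectory_pdb",
    "read_trajectory",
    "write_csv",
    "write_json",
    "sha256_of",
    "write_manifest",
    "verify_manifest",
]

_FLOAT_FMT = "%.12g"


def write_trajectory_xyz(traj: ChainTrajectory, path: str | Path) -> Path:
    """Multi-frame XYZ with element column 'C' and metadata comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(
                f"frame={f} temperature={traj.temperature:.6g} "
                f"replica={traj.replica_id} spacing_ns={traj.frame_spacing:.6g} "
                f"unit=nm\n"
            )
            for x, y, z in traj.coordinates[f]:
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")
    return path


def read_trajectory_xyz(path: str | Path) -> ChainTrajectory:
    """Parse a multi-frame XYZ written by :func:`write_trajectory_xyz`.

    The ``unit=`` tag on the comment line is honoured (nm or angstrom);
    an unknown tag or inconsistent bead counts raise a format error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty trajectory file")
    frames = []
    temperature, replica, spacing = 300.0, 0, 1.0
    scale = 1.0
    i = 0
    n_beads = None
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as err:
            raise ValueError(f"{path}: bad atom count at line {i + 1}") from err
        if n_beads is None:
            n_beads = n
        elif n != n_beads:
            raise ValueError(
                f"{path}: frame {frame_no} has {n} beads, expected {n_beads}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok
        )
        if "temperature" in meta:
            temperature = float(meta["temperature"])
        if "replica" in meta:
            replica = int(meta["replica"])
        if "spacing_ns" in meta:
            spacing = float(meta["spacing_ns"])
        unit = meta.get("unit", "nm").lower()
        if unit == "nm":
            scale = 1.0
        elif unit in ("angstrom", "a", "ang"):
            scale = 0.1
        else:
            raise ValueError(f"{path}: unknown unit tag {unit!r}")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame {frame_no}")
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(coords * scale)
        i += 2 + n
        frame_no += 1
    return ChainTrajectory(
        coordinates=np.stack(frames),
        temperature=temperature,
        replica_id=replica,
        frame_spacing=spacing,
    )


def write_template_pdb(
    coords: np.ndarray, path: str | Path, name: str = "BEA"
) -> Path:
    """Write bead frames as CA pseudo-atoms in PDB MODEL blocks (nm -> A)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_beads = coords.shape[1]
    atoms = struc.AtomArrayStack(coords.shape[0], n_beads)
    atoms.coord = coords * 10.0  # nm -> Angstrom
    atoms.chain_id = np.full(n_beads, "A")
    atoms.res_id = np.arange(1, n_beads + 1)
    atoms.res_name = np.full(n_beads, name)
    atoms.atom_name = np.full(n_beads, "CA")
    atoms.element = np.full(n_beads, "C")
    atoms.hetero = np.full(n_beads, False)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))
    return Path(path)


def read_trajectory_pdb(
    path: str | Path,
    temperature: float = 300.0,
    replica_id: int = 0,
    frame_spacing: float = 1.0,
) -> ChainTrajectory:
    """Read MODEL/ENDMDL bead frames from PDB (Angstrom -> nm)."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure()
    coords = atoms.coord / 10.0
    if coords.ndim == 2:
        coords = coords[None]
    return ChainTrajectory(
        coordinates=np.asarray(coords, dtype=float),
        temperature=temperature,
        replica_id=replica_id,
        frame_spacing=frame_spacing,
    )


def read_trajectory(path: str | Path, format: str | None = None, **kwargs) -> ChainTrajectory:
    """Dispatch on format ('xyz' or 'pdb'; inferred from the suffix by default)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return read_trajectory_xyz(path)
    if fmt == "pdb":
        return read_trajectory_pdb(path, **kwargs)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _round_sig(x: float, sig: int = 12) -> float:
    return float(f"%.{sig}g" % x)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_sig(float(obj))
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path: str | Path) -> Path:
    """JSON with sorted keys and floats at 12 significant digits (byte-stable)."""
    path = Path(path)

    def _clean(o):
        if isinstance(o, dict):
            return {str(k): _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        if isinstance(o, np.ndarray):
            return _clean(o.tolist())
        if isinstance(o, (float, np.floating)):
            return _round_sig(float(o))
        if isinstance(o, (np.integer,)):
            return int(o)
        return o

    with open(path, "w") as fh:
        json.dump(_clean(obj), fh, sort_keys=True, indent=1)
        fh.write("\n")
    return path


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with fixed column order and 12-significant-digit floats."""
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    run_dir: str | Path,
    config: dict,
    artifacts: dict[str, str | Path],
    stages: dict[str, str],
) -> Path:
    """Run manifest: config hash, artifact checksums, stage status.

    Deliberately free of timestamps so identical runs produce identical
    manifests; wall-clock information belongs in the log.
    """
    run_dir = Path(run_dir)
    cfg_blob = json.dumps(config, sort_keys=True, default=_json_default)
    manifest = {
        "config_hash": hashlib.sha256(cfg_blob.encode()).hexdigest(),
        "config": json.loads(cfg_blob),
        "artifacts": {
            name: {
                "path": str(Path(p).relative_to(run_dir)),
                "sha256": sha256_of(p),
            }
            for name, p in sorted(artifacts.items())
        },
        "stages": stages,
    }
    return write_json(manifest, run_dir / "manifest.json")


def verify_manifest(run_dir: str | Path) -> dict[str, str]:
    """Check that every manifest artifact exists and matches its checksum.

    Returns {artifact name: "ok" | "missing" | "checksum mismatch"}; raises
    if the manifest itself is absent.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    status: dict[str, str] = {}
    for name, entry in manifest.get("artifacts", {}).items():
        p = run_dir / entry["path"]
        if not p.exists():
            status[name] = "missing"
        elif sha256_of(p) != entry["sha256"]:
            status[name] = "checksum mismatch"
        else:
            status[name] = "ok"
    return status
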