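"""Multi-model PDB trajectory I/O and frame-time handling.

A trajectory is exchanged as a multi-model PDB file (one MODEL per frame,
chains A/B/C, coordinates in Å) plus frame times in nanoseconds.  Times come
from a sidecar JSON (``<traj>.times.json``, written automatically) or from a
constant frame spacing ``dt``; the sidecar wins when both are present, and
the absence of both is an error because downstream convergence windows are
defined on the time axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from triplexlens.errors import SchemaError, ValidationError
from triplexlens.topology import Topology

_RES_TO_PDB = {"A": "RA", "C": "RC", "G": "RG", "U": "RU", "T": "DT", "C+": "RCP"}
_PDB_TO_RES = {v: k for k, v in _RES_TO_PDB.items()}
# DNA residues share base letters with RNA in this toy model; encode by chain
_RES_TO_PDB_DNA = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_PDB_TO_RES.update({v: k for k, v in _RES_TO_PDB_DNA.items()})


@dataclass
class Trajectory:
    """Frames of Å coordinates over a fixed topology, with ns times."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) strictly increasing, ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times.shape != (self.coords.shape[0],):
            raise ValidationError("times must have one entry per frame")
        if self.coords.shape[0] > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _pdb_res_name(res_name: str, chain_id: str) -> str:
    if chain_id == "A":
        return _RES_TO_PDB[res_name]
    return _RES_TO_PDB_DNA[res_name]


def write_trajectory(
    trajectory: Trajectory,
    topology: Topology,
    path,
    write_times_sidecar: bool = True,
) -> None:
    """Write a multi-model PDB file (one MODEL per frame) plus time sidecar."""
    path = Path(path)
    if trajectory.n_atoms != topology.n_atoms:
        raise SchemaError(
            f"trajectory has {trajectory.n_atoms} atoms, topology "
            f"{topology.n_atoms}"
        )
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for a in topology.atoms:
            x, y, z = trajectory.coords[f, a.index]
            resn = _pdb_res_name(a.res_name, a.chain_id)
            lines.append(
                f"ATOM  {a.index + 1:5d} {a.name:<4s} {resn:>3s} {a.chain_id}"
                f"{a.level:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if write_times_sidecar:
        write_times(path, trajectory.times)


def times_sidecar_path(traj_path) -> Path:
    return Path(str(traj_path) + ".times.json")


def write_times(traj_path, times: np.ndarray) -> None:
    with open(times_sidecar_path(traj_path), "w") as fh:
        json.dump({"times_ns": [float(t) for t in times]}, fh)


def read_trajectory(
    pdb_path,
    topology: Topology,
    dt: float | None = None,
    times: np.ndarray | None = None,
) -> Trajectory:
    """Read a multi-model PDB trajectory and validate it against a topology.

    Atom serial/name/chain/residue records must match the topology in order;
    the first offending atom is named in the error.  A final MODEL without
    ENDMDL is an error, not a silent drop.  Frame times come from ``times``,
    the sidecar JSON, or ``dt`` (in that order of precedence).
    """
    pdb_path = Path(pdb_path)
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] | None = None
    cursor = 0
    with open(pdb_path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                if current is not None:
                    raise SchemaError("nested MODEL record (missing ENDMDL)")
                current = []
                cursor = 0
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    raise SchemaError("ATOM record outside MODEL block")
                if cursor >= topology.n_atoms:
                    raise SchemaError(
                        f"frame {len(frames) + 1} has more atoms than the "
                        f"topology ({topology.n_atoms})"
                    )
                atom = topology.atoms[cursor]
                name = line[12:16].strip()
                resn = line[17:20].strip()
                chain = line[21:22].strip()
                resseq = int(line[22:26])
                expected_resn = _pdb_res_name(atom.res_name, atom.chain_id)
                if (
                    name != atom.name
                    or chain != atom.chain_id
                    or resn != expected_resn
                    or resseq != atom.level
                ):
                    raise SchemaError(
                        f"atom {cursor + 1} mismatch in frame {len(frames) + 1}: "
                        f"file has {name}/{resn}/{chain}/{resseq}, topology "
                        f"expects {atom.name}/{expected_resn}/{atom.chain_id}/"
                        f"{atom.level}"
                    )
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                current.append((x, y, z))
                cursor += 1
            elif rec == "ENDMDL":
                if current is None:
                    raise SchemaError("ENDMDL without MODEL")
                if cursor != topology.n_atoms:
                    raise SchemaError(
                        f"frame {len(frames) + 1} truncated: {cursor} atoms, "
                        f"expected {topology.n_atoms}"
                    )
                frames.append(np.array(current))
                current = None
    if current is not None:
        raise SchemaError("truncated final MODEL (no ENDMDL)")
    if not frames:
        raise SchemaError(f"no MODEL records found in {pdb_path}")

    coords = np.stack(frames)
    if times is not None:
        times_arr = np.asarray(times, dtype=float)
    else:
        sidecar = times_sidecar_path(pdb_path)
        if sidecar.exists():
            with open(sidecar) as fh:
                times_arr = np.asarray(json.load(fh)["times_ns"], dtype=float)
        elif dt is not None:
            times_arr = np.arange(len(frames)) * float(dt)
        else:
            raise ValidationError(
                "no frame times available: provide a times sidecar or dt"
            )
    if times_arr.shape[0] != coords.shape[0]:
        raise SchemaError(
            f"{times_arr.shape[0]} times for {coords.shape[0]} frames"
        )
    return Trajectory(coords=coords, times=times_arr)


def select(topology: Topology, **kwargs) -> np.ndarray:
    """Module-level alias for :meth:`Topology.select`."""
    return topology.select(**kwargs)


__all__ = [
    "Trajectory",
    "write_trajectory",
    "read_trajectory",
    "write_times",
    "times_sidecar_path",
    "select",
]
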