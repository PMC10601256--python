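"""Geometric hydrogen-bond detection and register-resolved occurrence maps.

A hydrogen bond is reported between a donor (with its covalent hydrogen) and
an acceptor when the donor–acceptor distance is at most ``d_max`` (default
3.5 Å) and the hydrogen–donor–acceptor angle is at most ``a_max`` (default
30°) — the common geometric convention of MD analysis tools.  Only bonds
crossing the RNA/DNA divide are considered.

A bond is *in register* when its DNA partner is the purine-strand (chain B)
residue at the same register level as the RNA residue; every other RNA↔DNA
bond (shifted level, or to the pyrimidine strand) is *out of register*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from triplexlens.errors import TopologyError, ValidationError
from triplexlens.geometry import converged_window
from triplexlens.topology import (
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_HYDROGEN,
    ROLE_RNA,
    Topology,
)
from triplexlens.trajio import Trajectory

REGISTER_IN = "in"
REGISTER_OUT = "out"


@dataclass(frozen=True)
class HBond:
    """One detected RNA↔DNA hydrogen bond in one frame."""

    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    rna_level: int
    dna_chain: str
    dna_level: int
    distance: float
    angle: float
    register: str


def _donor_tables(topology: Topology):
    """(donor idx, hydrogen idx) pairs and acceptor indices, split RNA/DNA."""
    rna_chain = topology.chain_of_role(ROLE_RNA)
    donors = []
    for a in topology.atoms:
        if ROLE_HYDROGEN in a.roles:
            if a.parent is None:
                raise TopologyError(f"hydrogen {a.index} lacks a donor parent")
            donors.append((a.parent, a.index))
    for a in topology.atoms:
        if ROLE_DONOR in a.roles and not any(d == a.index for d, _ in donors):
            raise TopologyError(f"donor {a.index} has no attached hydrogen")
    acceptors = [a.index for a in topology.atoms if ROLE_ACCEPTOR in a.roles]
    is_rna = lambda i: topology.atoms[i].chain_id == rna_chain  # noqa: E731
    rna_donors = [(d, h) for d, h in donors if is_rna(d)]
    dna_donors = [(d, h) for d, h in donors if not is_rna(d)]
    rna_acc = [i for i in acceptors if is_rna(i)]
    dna_acc = [i for i in acceptors if not is_rna(i)]
    return rna_donors, dna_donors, rna_acc, dna_acc


def classify_register(
    rna_level: int, dna_chain: str, dna_level: int, topology: Topology
) -> str:
    """"in" iff the DNA partner is chain B at the RNA residue's level."""
    purine_chain = topology.chain_of_role("dna_purine")
    if dna_chain == purine_chain and dna_level == rna_level:
        return REGISTER_IN
    return REGISTER_OUT


def detect_hbonds(
    frame_coords: np.ndarray,
    topology: Topology,
    d_max: float = 3.5,
    a_max: float = 30.0,
    frame_index: int = 0,
) -> list[HBond]:
    """Detect RNA↔DNA hydrogen bonds in one frame (deterministic order)."""
    if d_max <= 0 or a_max <= 0:
        raise ValidationError("d_max and a_max must be positive")
    rna_donors, dna_donors, rna_acc, dna_acc = _donor_tables(topology)
    rna_chain = topology.chain_of_role(ROLE_RNA)

    bonds: list[HBond] = []
    for donors, acceptors in ((rna_donors, dna_acc), (dna_donors, rna_acc)):
        if not donors or not acceptors:
            continue
        d_idx = np.array([d for d, _ in donors])
        h_idx = np.array([h for _, h in donors])
        a_idx = np.array(acceptors)
        dist = cdist(frame_coords[d_idx], frame_coords[a_idx])
        for di, ai in zip(*np.nonzero(dist <= d_max)):
            d, h, a = int(d_idx[di]), int(h_idx[di]), int(a_idx[ai])
            v_h = frame_coords[h] - frame_coords[d]
            v_a = frame_coords[a] - frame_coords[d]
            denom = np.linalg.norm(v_h) * np.linalg.norm(v_a)
            if denom == 0.0:
                continue
            cosang = float(np.clip(np.dot(v_h, v_a) / denom, -1.0, 1.0))
            angle = float(np.degrees(np.arccos(cosang)))
            if angle > a_max:
                continue
            donor_atom = topology.atoms[d]
            acc_atom = topology.atoms[a]
            if donor_atom.chain_id == rna_chain:
                rna_level = donor_atom.level
                dna_chain, dna_level = acc_atom.chain_id, acc_atom.level
            else:
                rna_level = acc_atom.level
                dna_chain, dna_level = donor_atom.chain_id, donor_atom.level
            bonds.append(
                HBond(
                    frame=frame_index,
                    donor=d,
                    hydrogen=h,
                    acceptor=a,
                    rna_level=rna_level,
                    dna_chain=dna_chain,
                    dna_level=dna_level,
                    distance=float(dist[di, ai]),
                    angle=angle,
                    register=classify_register(
                        rna_level, dna_chain, dna_level, topology
                    ),
                )
            )
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def iter_hbonds(
    trajectory: Trajectory,
    topology: Topology,
    d_max: float = 3.5,
    a_max: float = 30.0,
    frames: np.ndarray | None = None,
):
    """Yield (frame index, bond list) over the requested frames."""
    if frames is None:
        frames = np.arange(trajectory.n_frames)
    for f in frames:
        yield int(f), detect_hbonds(
            trajectory.coords[f], topology, d_max, a_max, frame_index=int(f)
        )


def count_series(
    trajectory: Trajectory,
    topology: Topology,
    d_max: float = 3.5,
    a_max: float = 30.0,
    tail: float | None = None,
    clip_levels: list[int] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-frame RNA↔DNA bond counts plus the converged-window mean.

    ``tail`` (ns) sets the convergence window; ``None`` means the package
    default of 400 ns (all frames if the trajectory is shorter).
    ``clip_levels`` restricts the count to bonds whose RNA and DNA residues
    both sit at the given register levels (extended-model comparison).
    """
    keep = None if clip_levels is None else set(clip_levels)
    counts = np.empty(trajectory.n_frames, dtype=int)
    for f, bonds in iter_hbonds(trajectory, topology, d_max, a_max):
        if keep is not None:
            bonds = [b for b in bonds if b.rna_level in keep and b.dna_level in keep]
        counts[f] = len(bonds)
    window = converged_window(trajectory, 400.0 if tail is None else tail)
    mean = float(counts[window].mean())
    table = pd.DataFrame({"time_ns": trajectory.times, "count": counts})
    return table, mean


def running_average(series, window: int = 5) -> np.ndarray:
    """Centered running mean with truncated (shrinking) edge windows.

    ``window`` must be odd; window 1 is the identity.  Series length is
    preserved so smoothed curves stay aligned with the time axis.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 1, got {window}")
    values = pd.Series(np.asarray(series, dtype=float))
    return (
        values.rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )


def occurrence_map(
    trajectory: Trajectory,
    topology: Topology,
    d_max: float = 3.5,
    a_max: float = 30.0,
    min_freq: float = 0.01,
    tail: float | None = None,
    all_frames: bool = False,
) -> pd.DataFrame:
    """Per (RNA residue, DNA residue) bond occurrence over the analysis window.

    Returns a table with one row per residue pair that ever bonds, plus one
    row for every in-register pair (reported even at zero occurrence, so the
    register lanes are complete).  Columns:

    * ``fraction`` — share of analyzed frames with at least one bond;
    * ``units`` — mean simultaneous bonds per frame ("H-bond units", can
      exceed 1);
    * ``register`` — "in"/"out";
    * ``rendered`` — False for out-of-register pairs below ``min_freq``
      (suppressed from plots/rendered output but kept in the raw table).
    """
    if all_frames:
        frames = np.arange(trajectory.n_frames)
    else:
        frames = converged_window(trajectory, 400.0 if tail is None else tail)
    n = len(frames)

    frames_with_bond: dict[tuple[int, str, int], int] = {}
    total_bonds: dict[tuple[int, str, int], int] = {}
    for _f, bonds in iter_hbonds(trajectory, topology, d_max, a_max, frames):
        seen_this_frame = set()
        for b in bonds:
            key = (b.rna_level, b.dna_chain, b.dna_level)
            total_bonds[key] = total_bonds.get(key, 0) + 1
            if key not in seen_this_frame:
                frames_with_bond[key] = frames_with_bond.get(key, 0) + 1
                seen_this_frame.add(key)

    purine_chain = topology.chain_of_role("dna_purine")
    keys = set(total_bonds)
    keys.update((lvl, purine_chain, lvl) for lvl in range(1, topology.n_levels + 1))

    rows = []
    for key in sorted(keys, key=lambda k: (k[0], k[1], k[2])):
        rna_level, dna_chain, dna_level = key
        fraction = frames_with_bond.get(key, 0) / n
        units = total_bonds.get(key, 0) / n
        register = classify_register(rna_level, dna_chain, dna_level, topology)
        rendered = register == REGISTER_IN or fraction > min_freq
        rows.append(
            {
                "rna_res": rna_level,
                "dna_chain": dna_chain,
                "dna_res": dna_level,
                "level_offset": dna_level - rna_level,
                "fraction": fraction,
                "units": units,
                "register": register,
                "rendered": rendered,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "HBond",
    "REGISTER_IN",
    "REGISTER_OUT",
    "detect_hbonds",
    "iter_hbonds",
    "count_series",
    "running_average",
    "classify_register",
    "occurrence_map",
]
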