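"""Pairwise LJ+Coulomb energies and per-base-pair-level decomposition.

All energies are short-range cutoff sums in kJ/mol over Å coordinates and
electron-unit charges.  Lorentz–Berthelot combining is used for LJ
(``sigma_ij = (sigma_i + sigma_j)/2``, ``eps_ij = sqrt(eps_i * eps_j)``)
and the Coulomb term is ``f * q_i * q_j / r`` with
``f = 1389.35458 kJ mol^-1 Å e^-2``.  Pairs beyond the cutoff contribute
exactly zero to both terms.

The per-level decomposition follows the triplet geometry of the topology
(level ``i`` = one residue in each of chains A, B, C):

* hydrogen-bond term: all atom pairs between the three same-level
  inter-chain residue pairs (A_i,B_i), (B_i,C_i), (A_i,C_i);
* cross term: the central chain-B residue against the level i−1 and i+1
  residues of chains A and C;
* stacking term: the (i, i+1) intra-chain residue steps of all three chains.

Any contribution involving a terminal residue (level 1 or L) is excluded
everywhere so every included level sums the same number of terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from triplexlens.errors import ExclusionError, SingularityError, ValidationError
from triplexlens.geometry import converged_window
from triplexlens.topology import Atom, ForceFieldParams, Topology
from triplexlens.trajio import Trajectory


def pair_energy(
    atom_i: Atom, atom_j: Atom, r: float, params: ForceFieldParams
) -> tuple[float, float]:
    """(LJ, Coulomb) energy of one atom pair at distance ``r`` Å.

    Returns (0, 0) beyond the cutoff; raises for r == 0.
    """
    if r < 0:
        raise ValidationError("distance must be non-negative")
    if r == 0.0:
        raise SingularityError(
            f"zero distance between atoms {atom_i.index} and {atom_j.index}"
        )
    if r > params.cutoff:
        return 0.0, 0.0
    sigma = 0.5 * (atom_i.sigma + atom_j.sigma)
    eps = float(np.sqrt(atom_i.epsilon * atom_j.epsilon))
    sr6 = (sigma / r) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    e_cb = params.coulomb_f * atom_i.charge * atom_j.charge / r
    return e_lj, e_cb


def _group_energy(
    coords: np.ndarray,
    topology: Topology,
    params: ForceFieldParams,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
) -> tuple[float, float]:
    """Vectorized cutoff LJ+CB sum over the atom-pair block idx_a × idx_b."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        return 0.0, 0.0
    r = cdist(coords[idx_a], coords[idx_b])
    if np.any(r == 0.0):
        raise SingularityError("coincident atoms in energy evaluation")
    mask = r <= params.cutoff
    if not mask.any():
        return 0.0, 0.0
    sigma = 0.5 * (topology.sigma[idx_a][:, None] + topology.sigma[idx_b][None, :])
    eps = np.sqrt(topology.epsilon[idx_a][:, None] * topology.epsilon[idx_b][None, :])
    qq = topology.charge[idx_a][:, None] * topology.charge[idx_b][None, :]
    with np.errstate(divide="ignore"):
        sr6 = np.where(mask, (sigma / r) ** 6, 0.0)
        e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
        e_cb = np.where(mask, params.coulomb_f * qq / r, 0.0)
    return float(e_lj[mask].sum()), float(e_cb[mask].sum())


def interaction_energy_series(
    trajectory: Trajectory,
    topology: Topology,
    params: ForceFieldParams | None = None,
    clip_levels: list[int] | None = None,
) -> pd.DataFrame:
    """Total RNA↔DNA interaction energy per frame (backbone included).

    Sums LJ and Coulomb over every (RNA atom, DNA atom) pair within the
    cutoff.  ``clip_levels`` restricts both sides to residues at the given
    register levels (the extended-model comparison case).
    """
    if params is None:
        params = ForceFieldParams(cutoff=10.0)
    idx_rna = topology.select(selection="rna", levels=clip_levels)
    idx_dna = topology.select(selection="duplex", levels=clip_levels)
    e_lj = np.empty(trajectory.n_frames)
    e_cb = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        e_lj[f], e_cb[f] = _group_energy(
            trajectory.coords[f], topology, params, idx_rna, idx_dna
        )
    return pd.DataFrame(
        {
            "time_ns": trajectory.times,
            "e_lj": e_lj,
            "e_cb": e_cb,
            "e_total": e_lj + e_cb,
        }
    )


def _residue_pair_energy(
    coords: np.ndarray,
    topology: Topology,
    params: ForceFieldParams,
    chain_a: str,
    level_a: int,
    chain_b: str,
    level_b: int,
) -> float:
    lj, cb = _group_energy(
        coords,
        topology,
        params,
        topology.residue_atoms(chain_a, level_a),
        topology.residue_atoms(chain_b, level_b),
    )
    return lj + cb


def _check_interior(topology: Topology, i: int, what: str) -> None:
    if not (1 <= i <= topology.n_levels):
        raise ValidationError(f"level {i} outside 1..{topology.n_levels}")
    if topology.is_terminal_level(i):
        raise ExclusionError(
            f"{what} excludes terminal level {i} (terminal-residue rule)"
        )


def level_hbond_energy(
    frame_coords: np.ndarray,
    topology: Topology,
    params: ForceFieldParams,
    i: int,
    rna_pairs_only: bool = False,
) -> float:
    """Same-level inter-chain LJ+CB energy at register level ``i``.

    Sums the three residue pairs (A_i,B_i), (B_i,C_i), (A_i,C_i);
    ``rna_pairs_only`` restricts to the two RNA-involving pairs (a
    sensitivity-analysis variant).  Terminal levels are excluded.
    """
    _check_interior(topology, i, "hydrogen-bond energy")
    pairs = [("A", "B"), ("A", "C")] if rna_pairs_only else [
        ("A", "B"),
        ("B", "C"),
        ("A", "C"),
    ]
    return sum(
        _residue_pair_energy(frame_coords, topology, params, x, i, y, i)
        for x, y in pairs
    )


def level_cross_energy(
    frame_coords: np.ndarray,
    topology: Topology,
    params: ForceFieldParams,
    i: int,
) -> float:
    """Cross-term energy at level ``i``: chain B's residue i against the
    level i±1 residues of chains A and C.  Terminal levels are excluded
    (which also guarantees both neighbors exist)."""
    _check_interior(topology, i, "cross energy")
    total = 0.0
    for other in ("A", "C"):
        for j in (i - 1, i + 1):
            total += _residue_pair_energy(
                frame_coords, topology, params, "B", i, other, j
            )
    return total


def level_stack_energy(
    frame_coords: np.ndarray,
    topology: Topology,
    params: ForceFieldParams,
    i: int,
) -> float:
    """Stacking energy of base-pair step (i, i+1): intra-chain residue pairs
    X_i–X_{i+1} summed over the three chains.  Under the terminal-exclusion
    rule both step residues must be interior, so valid steps are
    2 <= i <= L-2."""
    L = topology.n_levels
    if i >= L:
        raise ValidationError(f"no step at the last level (i={i}, L={L})")
    _check_interior(topology, i, "stacking energy")
    _check_interior(topology, i + 1, "stacking energy")
    return sum(
        _residue_pair_energy(frame_coords, topology, params, chain, i, chain, i + 1)
        for chain in ("A", "B", "C")
    )


def level_profile(
    trajectory: Trajectory,
    topology: Topology,
    params: ForceFieldParams | None = None,
    tail: float | None = None,
    all_frames: bool = False,
    rna_pairs_only: bool = False,
) -> pd.DataFrame:
    """Frame-averaged per-level energy decomposition over the analysis window.

    One row per interior level i (2..L-1) with columns ``e_hb``, ``e_cross``,
    ``e_stack``, ``e_total``.  The stacking column holds the (i, i+1) step
    energy, zero at i = L-1 where no fully interior step exists;
    ``e_total = e_hb + e_cross + e_stack`` by construction.
    """
    if params is None:
        params = ForceFieldParams(cutoff=10.0)
    L = topology.n_levels
    if L < 3:
        raise ValidationError(f"level profile needs >= 3 levels, got {L}")
    if all_frames:
        frames = np.arange(trajectory.n_frames)
    else:
        frames = converged_window(trajectory, 400.0 if tail is None else tail)

    levels = list(range(2, L))
    e_hb = np.zeros(len(levels))
    e_cross = np.zeros(len(levels))
    e_stack = np.zeros(len(levels))
    for f in frames:
        coords = trajectory.coords[f]
        for k, i in enumerate(levels):
            e_hb[k] += level_hbond_energy(
                coords, topology, params, i, rna_pairs_only=rna_pairs_only
            )
            e_cross[k] += level_cross_energy(coords, topology, params, i)
            if i <= L - 2:
                e_stack[k] += level_stack_energy(coords, topology, params, i)
    n = len(frames)
    e_hb /= n
    e_cross /= n
    e_stack /= n
    return pd.DataFrame(
        {
            "level": levels,
            "e_hb": e_hb,
            "e_cross": e_cross,
            "e_stack": e_stack,
            "e_total": e_hb + e_cross + e_stack,
        }
    )


__all__ = [
    "pair_energy",
    "interaction_energy_series",
    "level_hbond_energy",
    "level_cross_energy",
    "level_stack_energy",
    "level_profile",
]
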