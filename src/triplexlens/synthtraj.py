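"""Ideal-triplex construction and seeded synthetic trajectory generation.

The builder places three helical strands (RNA third strand A, DNA purine B,
DNA pyrimidine C) on an ideal helix (default rise 3.4 Å, twist 30°/level).
Donor/hydrogen/acceptor atoms are posed at hydrogen-bonding geometry
(donor…acceptor 2.9 Å, in-line hydrogen) at canonically matched levels and
at open, non-bonding geometry (≥ 5 Å) at mismatch levels.

The trajectory synthesizer plants per-residue-pair Bernoulli hydrogen-bond
occupancies on top of the reference geometry, adds iid isotropic Gaussian
coordinate noise, and can optionally fray the terminal levels (linear
drift of the outer strands away from the purine strand after a chosen
frame).  Everything is reproducible from a single seed, and the planted
parameters are serialized alongside the trajectory as a machine-readable
truth file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from triplexlens.errors import ValidationError
from triplexlens.topology import (
    ATOM_NAMES,
    ForceFieldParams,
    Topology,
    default_params,
    template_atoms,
)
from triplexlens.trajio import Trajectory
from triplexlens.triplexcode import TriplexAlignment, complement_dna, SequenceRecord

#: donor…acceptor distance of a posed hydrogen bond (Å)
BOND_DISTANCE = 2.9
#: donor–hydrogen distance along the donor→acceptor line (Å)
DH_DISTANCE = 1.9
#: lateral displacement applied to open (non-bonded) donor groups (Å)
OPEN_SHIFT = 3.0

# Local in-plane coordinates (x, y) of the 5-atom residue templates, one
# triplet level, before helical rotation/translation.  Chain B's acceptor
# sits at the origin; chain A's donor points at it from +x, chain B's donor
# points at chain C's acceptor on the -x side.  Offsets are chosen so the
# only donor–acceptor contacts within 3.5 Å are the posed bonds.
_LOCAL = {
    "A": {"D": (2.9, 0.0), "HD": (1.0, 0.0), "B": (4.0, 3.0), "S": (5.5, 1.0), "P": (7.0, 2.0)},
    "B": {"B": (0.0, 0.0), "D": (-6.0, 0.0), "HD": (-7.9, 0.0), "S": (-3.0, -3.0), "P": (-3.0, -4.8)},
    "C": {"B": (-8.9, 0.0), "D": (-11.0, 2.0), "HD": (-12.0, 2.6), "S": (-10.5, -1.5), "P": (-12.0, -2.5)},
}

_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _level_transform(level: int, rise: float, twist_deg: float) -> tuple[np.ndarray, float]:
    """Rotation matrix (about z) and z-offset for register level (1-based)."""
    theta = math.radians(twist_deg) * (level - 1)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, rise * (level - 1)


def _place(local_xy: tuple[float, float], rot: np.ndarray, z: float) -> np.ndarray:
    v = np.array([local_xy[0], local_xy[1], 0.0])
    return rot @ v + np.array([0.0, 0.0, z])


def build_ideal_triplex(
    alignment: TriplexAlignment,
    rise: float = 3.4,
    twist: float = 30.0,
    params: ForceFieldParams | None = None,
) -> tuple[Topology, np.ndarray]:
    """Build an ideal three-strand topology and reference coordinates.

    Level ``i`` hosts the i-th alignment position: chain A carries the RNA
    base, chain B the purine-strand base, chain C its Watson–Crick
    complement.  Interior RNA cytosines are instantiated as the protonated
    residue ``C+``.  Returns ``(topology, coords)`` with coords in Å,
    shape (n_atoms, 3).  Deterministic given its inputs.
    """
    L = len(alignment)
    if L < 4:
        raise ValidationError(f"alignment must span at least 4 levels, got {L}")
    if params is None:
        params = default_params()

    pyr = complement_dna(
        SequenceRecord(id="pyr", sequence=alignment.purine_window, kind="dna")
    ).sequence

    atoms = []
    coords = []
    matched = [c == "|" for c in alignment.pairing]
    idx = 0
    for chain_id, seq in (("A", alignment.rna_window), ("B", alignment.purine_window), ("C", pyr)):
        for level in range(1, L + 1):
            res = seq[level - 1]
            if chain_id == "A" and res == "C" and level not in (1, L):
                res = "C+"
            atoms.extend(template_atoms(chain_id, res, level, params, idx))
            idx += len(ATOM_NAMES)
            rot, z = _level_transform(level, rise, twist)
            for name in ATOM_NAMES:
                x, y = _LOCAL[chain_id][name]
                # open pose for the RNA donor group at mismatch levels
                if chain_id == "A" and name in ("D", "HD") and not matched[level - 1]:
                    x += OPEN_SHIFT
                # keep the duplex's own donor open too at mismatch levels
                if chain_id == "B" and name in ("D", "HD") and not matched[level - 1]:
                    x += OPEN_SHIFT
                coords.append(_place((x, y), rot, z))
    return Topology(atoms), np.array(coords)


# ---------------------------------------------------------------------------
# Planted occupancies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPair:
    """One planted hydrogen-bond occupancy.

    ``(rna_level, dna_chain, dna_level)`` identifies the residue pair;
    ``occupancy`` is the per-frame Bernoulli probability that the bond(s)
    exist; ``n_bonds`` (1 or 2) is the number of simultaneous bonds posed
    when they do (2 is only supported in-register, chain B, same level).
    """

    rna_level: int
    dna_chain: str
    dna_level: int
    occupancy: float
    n_bonds: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(
                f"occupancy must be in [0, 1], got {self.occupancy}"
            )
        if self.dna_chain not in ("B", "C"):
            raise ValidationError("dna_chain must be 'B' or 'C'")
        if self.n_bonds not in (1, 2):
            raise ValidationError("n_bonds must be 1 or 2")
        if self.n_bonds == 2 and not self.in_register:
            raise ValidationError("n_bonds=2 is only supported in-register")

    @property
    def in_register(self) -> bool:
        return self.dna_chain == "B" and self.dna_level == self.rna_level

    def key(self) -> tuple[int, str, int]:
        return (self.rna_level, self.dna_chain, self.dna_level)


@dataclass(frozen=True)
class FraySpec:
    """Terminal strand separation: after ``after_frame`` the outer strands
    (A and C) at the ``n_levels`` outermost levels drift radially apart,
    linearly up to ``max_shift`` Å."""

    after_frame: int
    n_levels: int = 2
    max_shift: float = 12.0


@dataclass
class PlantedTruth:
    """Everything needed to recompute the expected analysis outputs."""

    pairs: list[PlantedPair]
    noise_sigma: float
    seed: int
    dt: float
    n_frames: int
    fray: FraySpec | None = None
    times: np.ndarray = field(default=None, repr=False)

    @property
    def expected_bonds_per_frame(self) -> float:
        """Expected RNA↔DNA bond count per (un-frayed) frame."""
        return sum(p.occupancy * p.n_bonds for p in self.pairs)

    def to_json(self, path) -> None:
        payload = {
            "pairs": [
                {
                    "rna_level": p.rna_level,
                    "dna_chain": p.dna_chain,
                    "dna_level": p.dna_level,
                    "occupancy": p.occupancy,
                    "n_bonds": p.n_bonds,
                }
                for p in self.pairs
            ],
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "dt": self.dt,
            "n_frames": self.n_frames,
            "fray": None
            if self.fray is None
            else {
                "after_frame": self.fray.after_frame,
                "n_levels": self.fray.n_levels,
                "max_shift": self.fray.max_shift,
            },
            "expected_bonds_per_frame": self.expected_bonds_per_frame,
            "times_ns": [float(t) for t in self.times],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        fray = d.get("fray")
        return cls(
            pairs=[PlantedPair(**p) for p in d["pairs"]],
            noise_sigma=float(d["noise_sigma"]),
            seed=int(d["seed"]),
            dt=float(d["dt"]),
            n_frames=int(d["n_frames"]),
            fray=None if fray is None else FraySpec(**fray),
            times=np.asarray(d["times_ns"], dtype=float),
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValidationError("zero-length direction vector")
    return v / n


def synthesize_trajectory(
    topology: Topology,
    reference: np.ndarray,
    n_frames: int,
    dt: float,
    noise_sigma: float,
    occupancies: list[PlantedPair] | dict,
    seed: int,
    fray: FraySpec | None = None,
) -> tuple[Trajectory, PlantedTruth]:
    """Generate a synthetic trajectory with planted H-bond occupancies.

    Frame ``t`` starts from the reference with *all* RNA donor groups in the
    open (non-bonded) pose; for every planted pair an independent Bernoulli
    draw decides whether its bond(s) are posed at bonding geometry this
    frame.  Isotropic Gaussian noise of ``noise_sigma`` Å is then added to
    every coordinate, and the optional fray drift applied last (so frayed
    bonds break).  Bit-reproducible from ``seed``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if isinstance(occupancies, dict):
        pairs = [
            PlantedPair(rna_level=k[0], dna_chain=k[1], dna_level=k[2], **(
                v if isinstance(v, dict) else {"occupancy": v}
            ))
            for k, v in sorted(occupancies.items())
        ]
    else:
        pairs = sorted(occupancies, key=lambda p: p.key())

    L = topology.n_levels
    seen_donors: set[int] = set()
    for p in pairs:
        if not (1 <= p.rna_level <= L and 1 <= p.dna_level <= L):
            raise ValidationError(f"planted pair {p.key()} outside levels 1..{L}")
        if p.rna_level in seen_donors:
            raise ValidationError(
                f"RNA residue {p.rna_level} appears in more than one planted pair"
            )
        seen_donors.add(p.rna_level)

    def atom(chain: str, level: int, name: str) -> int:
        idx = topology.residue_atoms(chain, level)
        for i in idx:
            if topology.atoms[i].name == name:
                return int(i)
        raise ValidationError(f"no atom {name} at {chain}/{level}")

    # open-pose base frame: every RNA donor group displaced off its acceptor
    base = reference.copy()
    open_shift = np.zeros((L + 1, 3))
    for level in range(1, L + 1):
        d = atom("A", level, "D")
        h = atom("A", level, "HD")
        acc = atom("B", level, "B")
        u = _unit(reference[d] - reference[acc])
        # ensure >= 5 Å from the in-register acceptor
        target = reference[acc] + u * max(BOND_DISTANCE + OPEN_SHIFT, 5.9)
        open_shift[level] = target - reference[d]
        base[d] = target
        base[h] = target - u * DH_DISTANCE

    # precompute posed coordinates per planted pair
    poses: list[list[tuple[int, np.ndarray]]] = []
    for p in pairs:
        moves: list[tuple[int, np.ndarray]] = []
        d = atom("A", p.rna_level, "D")
        h = atom("A", p.rna_level, "HD")
        acc = atom(p.dna_chain, p.dna_level, "B")
        u = _unit(reference[d] - reference[acc])
        moves.append((d, reference[acc] + u * BOND_DISTANCE))
        moves.append((h, reference[acc] + u * (BOND_DISTANCE - DH_DISTANCE)))
        if p.n_bonds == 2:
            # second bond: DNA purine donor to the RNA acceptor, pulled in
            bd = atom("B", p.dna_level, "D")
            bh = atom("B", p.dna_level, "HD")
            ra = atom("A", p.rna_level, "B")
            v = _unit(reference[ra] - reference[bd])
            moves.append((ra, reference[bd] + v * BOND_DISTANCE))
            moves.append((bh, reference[bd] + v * DH_DISTANCE))
        poses.append(moves)

    rng = np.random.default_rng(seed)
    bond_draws = rng.random((n_frames, len(pairs))) < np.array(
        [p.occupancy for p in pairs]
    )

    fray_atoms: list[tuple[int, np.ndarray]] = []
    if fray is not None:
        if not (0 <= fray.after_frame < n_frames):
            raise ValidationError("fray.after_frame must be within the trajectory")
        fray_levels = set(range(1, fray.n_levels + 1)) | set(
            range(L - fray.n_levels + 1, L + 1)
        )
        for level in sorted(fray_levels):
            centroid_b = reference[topology.residue_atoms("B", level)].mean(axis=0)
            for chain in ("A", "C"):
                idx = topology.residue_atoms(chain, level)
                direction = _unit(reference[idx].mean(axis=0) - centroid_b)
                for i in idx:
                    fray_atoms.append((int(i), direction))
        span = max(1, n_frames - 1 - fray.after_frame)
        drift_rate = 2.0 * fray.max_shift / span

    coords = np.empty((n_frames, topology.n_atoms, 3))
    for t in range(n_frames):
        frame = base.copy()
        for p_idx, moves in enumerate(poses):
            if bond_draws[t, p_idx]:
                for i, xyz in moves:
                    frame[i] = xyz
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, frame.shape)
        if fray is not None and t > fray.after_frame:
            shift = min(fray.max_shift, drift_rate * (t - fray.after_frame))
            for i, direction in fray_atoms:
                frame[i] = frame[i] + shift * direction
        coords[t] = frame

    times = np.arange(n_frames) * float(dt)
    trajectory = Trajectory(coords=coords, times=times)
    truth = PlantedTruth(
        pairs=pairs,
        noise_sigma=noise_sigma,
        seed=seed,
        dt=dt,
        n_frames=n_frames,
        fray=fray,
        times=times,
    )
    return trajectory, truth


__all__ = [
    "BOND_DISTANCE",
    "DH_DISTANCE",
    "OPEN_SHIFT",
    "PlantedPair",
    "FraySpec",
    "PlantedTruth",
    "build_ideal_triplex",
    "synthesize_trajectory",
]
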