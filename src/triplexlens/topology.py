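"""Three-strand triplex topology: chains, register levels, atoms, parameters.

Chain naming convention (fixed across the package):

* chain ``A`` — RNA third strand (``rna_third_strand``),
* chain ``B`` — DNA purine strand, the central strand (``dna_purine``),
* chain ``C`` — DNA pyrimidine strand (``dna_pyrimidine``).

Each register level ``i`` (1..L) holds exactly one residue per chain.  A
residue is represented by a minimal 5-atom template:

* ``P``  — backbone phosphate,
* ``S``  — backbone sugar,
* ``B``  — base heavy-atom acceptor,
* ``D``  — base heavy-atom donor,
* ``HD`` — hydrogen covalently bonded to ``D``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from triplexlens.errors import TopologyError, ValidationError

ROLE_RNA = "rna_third_strand"
ROLE_PURINE = "dna_purine"
ROLE_PYRIMIDINE = "dna_pyrimidine"

CHAIN_ROLES = {"A": ROLE_RNA, "B": ROLE_PURINE, "C": ROLE_PYRIMIDINE}

ATOM_NAMES = ("P", "S", "B", "D", "HD")

#: atom-level roles
ROLE_DONOR = "donor"
ROLE_HYDROGEN = "hydrogen"
ROLE_ACCEPTOR = "acceptor"
ROLE_BACKBONE = "backbone"

_TEMPLATE_ROLES = {
    "P": frozenset({ROLE_BACKBONE}),
    "S": frozenset({ROLE_BACKBONE}),
    "B": frozenset({ROLE_ACCEPTOR}),
    "D": frozenset({ROLE_DONOR}),
    "HD": frozenset({ROLE_HYDROGEN}),
}

_TEMPLATE_ELEMENT = {"P": "P", "S": "C", "B": "O", "D": "N", "HD": "H"}


@dataclass(frozen=True)
class Atom:
    """One atom of the topology (flat indexing across the whole system)."""

    index: int
    name: str
    element: str
    chain_id: str
    res_name: str
    level: int
    charge: float
    sigma: float
    epsilon: float
    roles: frozenset
    parent: int | None = None  # donor heavy-atom index, for hydrogens

    def __post_init__(self) -> None:
        if not np.isfinite(self.charge):
            raise TopologyError(f"non-finite charge on atom {self.index}")
        if self.sigma <= 0:
            raise TopologyError(f"sigma must be > 0 on atom {self.index}")
        if self.epsilon < 0:
            raise TopologyError(f"epsilon must be >= 0 on atom {self.index}")


@dataclass(frozen=True)
class ForceFieldParams:
    """Toy LJ/Coulomb parameter set (Lorentz–Berthelot combining).

    ``coulomb_f`` is the Coulomb prefactor in kJ·mol⁻¹·Å·e⁻²; ``cutoff``
    the short-range cutoff in Å applied to both LJ and Coulomb terms.
    """

    atom_types: dict = field(default_factory=dict)  # name -> (sigma, epsilon)
    residue_charges: dict = field(default_factory=dict)  # resname -> {atom: q}
    coulomb_f: float = 1389.35458
    cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be > 0")
        for name, (sigma, _eps) in self.atom_types.items():
            if sigma <= 0:
                raise ValidationError(f"sigma for atom type {name!r} must be > 0")

    def charge_of(self, res_name: str, atom_name: str) -> float:
        table = self.residue_charges.get(res_name, self.residue_charges["*"])
        return table.get(atom_name, self.residue_charges["*"][atom_name])

    def lj_of(self, atom_name: str) -> tuple[float, float]:
        return self.atom_types[atom_name]

    def to_json(self, path) -> None:
        payload = {
            "atom_types": {k: list(v) for k, v in self.atom_types.items()},
            "residue_charges": self.residue_charges,
            "coulomb_f": self.coulomb_f,
            "cutoff": self.cutoff,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ForceFieldParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            atom_types={k: tuple(v) for k, v in payload["atom_types"].items()},
            residue_charges=payload["residue_charges"],
            coulomb_f=float(payload.get("coulomb_f", 1389.35458)),
            cutoff=float(payload.get("cutoff", 10.0)),
        )


def default_params(cutoff: float = 10.0) -> ForceFieldParams:
    """Bundled toy parameter set (not a real nucleic-acid force field)."""
    return ForceFieldParams(
        atom_types={
            "P": (3.74, 0.84),
            "S": (3.40, 0.55),
            "B": (3.20, 0.60),
            "D": (3.25, 0.60),
            # polar hydrogen: no LJ contribution, Coulomb only
            "HD": (0.40, 0.00),
        },
        residue_charges={
            "*": {"P": -1.00, "S": 0.35, "B": -0.48, "D": 0.34, "HD": 0.30},
            # protonated cytosine: extra positive charge on the donor group
            "C+": {"P": -1.00, "S": 0.35, "B": -0.48, "D": 0.64, "HD": 0.50},
        },
        cutoff=cutoff,
    )


class Topology:
    """Immutable triplex topology over three chains and L register levels."""

    def __init__(self, atoms: list[Atom], chains: dict[str, str] | None = None):
        self.atoms = list(atoms)
        self.chains = dict(chains) if chains is not None else dict(CHAIN_ROLES)
        self._validate()
        # cached flat arrays for vectorized analyses
        self.charge = np.array([a.charge for a in self.atoms])
        self.sigma = np.array([a.sigma for a in self.atoms])
        self.epsilon = np.array([a.epsilon for a in self.atoms])
        self.level = np.array([a.level for a in self.atoms])
        self.chain_id = np.array([a.chain_id for a in self.atoms])

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if set(self.chains) != {"A", "B", "C"}:
            raise TopologyError("topology must have exactly chains A, B, C")
        if self.chains.get("B") != ROLE_PURINE:
            raise TopologyError("chain B must carry role dna_purine")
        if set(self.chains.values()) != {ROLE_RNA, ROLE_PURINE, ROLE_PYRIMIDINE}:
            raise TopologyError("chain roles must cover all three strand roles")
        levels_per_chain: dict[str, set[int]] = {"A": set(), "B": set(), "C": set()}
        for a in self.atoms:
            if a.chain_id not in self.chains:
                raise TopologyError(f"atom {a.index} has unknown chain {a.chain_id}")
            levels_per_chain[a.chain_id].add(a.level)
        all_levels = levels_per_chain["A"]
        if not all_levels:
            raise TopologyError("empty topology")
        if not (levels_per_chain["B"] == levels_per_chain["C"] == all_levels):
            raise TopologyError("each level must hold one residue per chain")
        if all_levels != set(range(1, max(all_levels) + 1)):
            raise TopologyError("levels must be contiguous from 1")
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise TopologyError(f"atom index {a.index} out of order (slot {i})")
            if ROLE_HYDROGEN in a.roles:
                if a.parent is None:
                    raise TopologyError(
                        f"hydrogen atom {a.index} has no covalent donor parent"
                    )
                parent = self.atoms[a.parent]
                if ROLE_DONOR not in parent.roles:
                    raise TopologyError(
                        f"hydrogen atom {a.index} parented to non-donor {a.parent}"
                    )

    # -- basic properties ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_levels(self) -> int:
        return int(self.level.max())

    def is_terminal_level(self, level: int) -> bool:
        return level in (1, self.n_levels)

    def chain_of_role(self, role: str) -> str:
        for cid, r in self.chains.items():
            if r == role:
                return cid
        raise TopologyError(f"no chain with role {role!r}")

    def residue_name(self, chain_id: str, level: int) -> str:
        for a in self.atoms:
            if a.chain_id == chain_id and a.level == level:
                return a.res_name
        raise TopologyError(f"no residue at chain {chain_id} level {level}")

    # -- selections ---------------------------------------------------------

    def select(
        self,
        chain: str | None = None,
        role: str | None = None,
        levels: list[int] | None = None,
        selection: str | None = None,
    ) -> np.ndarray:
        """Deterministic atom index set for chain/role/level selectors.

        ``selection`` accepts the composite labels ``"rna"`` (the third
        strand), ``"duplex"`` (both DNA strands) and ``"all"``.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if selection is not None:
            if selection == "rna":
                mask &= self.chain_id == self.chain_of_role(ROLE_RNA)
            elif selection == "duplex":
                mask &= (self.chain_id == self.chain_of_role(ROLE_PURINE)) | (
                    self.chain_id == self.chain_of_role(ROLE_PYRIMIDINE)
                )
            elif selection == "all":
                pass
            else:
                raise ValidationError(
                    f"unknown selection {selection!r} (available: rna, duplex, all)"
                )
        if chain is not None:
            if chain not in self.chains:
                raise ValidationError(
                    f"unknown chain {chain!r} (available: {sorted(self.chains)})"
                )
            mask &= self.chain_id == chain
        if role is not None:
            role_mask = np.array([role in a.roles for a in self.atoms])
            if not role_mask.any():
                raise ValidationError(
                    f"unknown or empty atom role {role!r} "
                    f"(available: donor, hydrogen, acceptor, backbone)"
                )
            mask &= role_mask
        if levels is not None:
            mask &= np.isin(self.level, np.asarray(levels))
        return np.flatnonzero(mask)

    def residue_atoms(self, chain_id: str, level: int) -> np.ndarray:
        return np.flatnonzero((self.chain_id == chain_id) & (self.level == level))

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "chains": self.chains,
            "atoms": [
                {
                    "index": a.index,
                    "name": a.name,
                    "element": a.element,
                    "chain_id": a.chain_id,
                    "res_name": a.res_name,
                    "level": a.level,
                    "charge": a.charge,
                    "sigma": a.sigma,
                    "epsilon": a.epsilon,
                    "roles": sorted(a.roles),
                    "parent": a.parent,
                }
                for a in self.atoms
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Topology":
        with open(path) as fh:
            payload = json.load(fh)
        atoms = [
            Atom(
                index=int(d["index"]),
                name=d["name"],
                element=d["element"],
                chain_id=d["chain_id"],
                res_name=d["res_name"],
                level=int(d["level"]),
                charge=float(d["charge"]),
                sigma=float(d["sigma"]),
                epsilon=float(d["epsilon"]),
                roles=frozenset(d["roles"]),
                parent=None if d.get("parent") is None else int(d["parent"]),
            )
            for d in payload["atoms"]
        ]
        return cls(atoms, chains=payload["chains"])


def template_atoms(
    chain_id: str,
    res_name: str,
    level: int,
    params: ForceFieldParams,
    start_index: int,
) -> list[Atom]:
    """Instantiate the 5-atom residue template for one residue."""
    atoms = []
    donor_index = None
    for offset, name in enumerate(ATOM_NAMES):
        idx = start_index + offset
        if name == "D":
            donor_index = idx
        sigma, epsilon = params.lj_of(name)
        atoms.append(
            Atom(
                index=idx,
                name=name,
                element=_TEMPLATE_ELEMENT[name],
                chain_id=chain_id,
                res_name=res_name,
                level=level,
                charge=params.charge_of(res_name, name),
                sigma=sigma,
                epsilon=epsilon,
                roles=_TEMPLATE_ROLES[name],
                parent=donor_index if name == "HD" else None,
            )
        )
    return atoms


__all__ = [
    "Atom",
    "Topology",
    "ForceFieldParams",
    "default_params",
    "template_atoms",
    "ATOM_NAMES",
    "CHAIN_ROLES",
    "ROLE_RNA",
    "ROLE_PURINE",
    "ROLE_PYRIMIDINE",
    "ROLE_DONOR",
    "ROLE_HYDROGEN",
    "ROLE_ACCEPTOR",
    "ROLE_BACKBONE",
]
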