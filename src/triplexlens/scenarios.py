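"""Named synthetic scenario presets and bundled example sequences.

Four presets emulate the qualitative behaviour of the four modelled triplex
systems: two alternative binding modes of one promoter (one stable, one
less stable) and a short model that frays at the termini next to its
extended, stable variant.  Planted occupancies are chosen so the analysis
readouts reproduce the qualitative orderings (H-bond means, interaction
energies, register lanes) without copying any MD-derived magnitude.

The bundled sequences are illustrative stand-ins constructed to carry the
documented interface: a 15-nt parallel pyrimidine window whose canonical
pairing is interrupted by exactly one C·dT and one G·dG mismatch, the
latter immediately followed by a U·A triplet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from triplexlens.errors import ValidationError
from triplexlens.synthtraj import (
    FraySpec,
    PlantedPair,
    PlantedTruth,
    build_ideal_triplex,
    synthesize_trajectory,
)
from triplexlens.topology import ForceFieldParams, Topology, default_params
from triplexlens.trajio import Trajectory, write_trajectory
from triplexlens.triplexcode import (
    SequenceRecord,
    TriplexAlignment,
    align_windows,
    clip_levels as _clip_levels,
)

# ---------------------------------------------------------------------------
# Bundled example sequences (illustrative stand-ins)
# ---------------------------------------------------------------------------

#: 15-nt purine-strand window of the "A" promoter model and its RNA partner;
#: canonical except one C·dT (position 6) and one G·dG (position 10).
PROMOTER_A_PURINE_15 = "GAAGATGAGGAGGAA"
RNA_A_15 = "CUUCUCCUCGUCCUU"

#: short "N" promoter model (mismatches at positions 7 and 11) ...
PROMOTER_N_PURINE_15 = "AGGAAGTAAGGAGAA"
RNA_N_15 = "UCCUUCCUUCGUCUU"
#: ... and its extended variant: three extra canonically paired levels on
#: each side, so the core is recovered by clipping.
PROMOTER_N_PURINE_EXT = "GAA" + PROMOTER_N_PURINE_15 + "GAG"
RNA_N_EXT = "CUU" + RNA_N_15 + "CUC"

#: 30-nt RNA binding domain embedding RNA_A_15 at positions 8..22, flanked
#: by purine-rich spacers that cannot pair canonically.
RNA_DBD_30 = "AGAGAGA" + RNA_A_15 + "AGAGAGAG"
#: 40-nt promoter purine strand embedding PROMOTER_A_PURINE_15 at 13..27.
PROMOTER_A_PURINE_40 = "GGTGGTGGTGGT" + PROMOTER_A_PURINE_15 + "GGTGGTGGTGGTG"


def example_sequences() -> dict[str, SequenceRecord]:
    """Bundled example records keyed by a short name."""
    return {
        "rna_dbd": SequenceRecord("rna_dbd", RNA_DBD_30, "rna"),
        "promoter_A": SequenceRecord("promoter_A", PROMOTER_A_PURINE_40, "dna"),
        "rna_A_core": SequenceRecord("rna_A_core", RNA_A_15, "rna"),
        "promoter_A_core": SequenceRecord(
            "promoter_A_core", PROMOTER_A_PURINE_15, "dna"
        ),
        "rna_N_core": SequenceRecord("rna_N_core", RNA_N_15, "rna"),
        "promoter_N_core": SequenceRecord(
            "promoter_N_core", PROMOTER_N_PURINE_15, "dna"
        ),
        "rna_N_ext": SequenceRecord("rna_N_ext", RNA_N_EXT, "rna"),
        "promoter_N_ext": SequenceRecord(
            "promoter_N_ext", PROMOTER_N_PURINE_EXT, "dna"
        ),
    }


def alignment_a_core() -> TriplexAlignment:
    seqs = example_sequences()
    return align_windows(seqs["rna_A_core"], 1, seqs["promoter_A_core"], 1, 15)


def alignment_n_core() -> TriplexAlignment:
    seqs = example_sequences()
    return align_windows(seqs["rna_N_core"], 1, seqs["promoter_N_core"], 1, 15)


def alignment_n_ext() -> TriplexAlignment:
    seqs = example_sequences()
    return align_windows(seqs["rna_N_ext"], 1, seqs["promoter_N_ext"], 1, 21)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioPreset:
    """Versioned, deterministic recipe for one synthetic system."""

    name: str
    description: str
    alignment_factory: object = field(repr=False)
    occupancy_in_register: float = 1.0
    bonds_in_register: int = 2
    extra_pairs: tuple = ()  # extra PlantedPairs beyond the in-register set
    fray: FraySpec | None = None
    n_frames: int = 2000
    dt: float = 0.3
    noise_sigma: float = 0.1
    core_alignment_factory: object | None = field(default=None, repr=False)

    def alignment(self) -> TriplexAlignment:
        return self.alignment_factory()

    def core_alignment(self) -> TriplexAlignment | None:
        if self.core_alignment_factory is None:
            return None
        return self.core_alignment_factory()

    def planted_pairs(self) -> list[PlantedPair]:
        aln = self.alignment()
        pairs = [
            PlantedPair(
                rna_level=i,
                dna_chain="B",
                dna_level=i,
                occupancy=self.occupancy_in_register,
                n_bonds=self.bonds_in_register,
            )
            for i, c in enumerate(aln.pairing, start=1)
            if c == "|"
        ]
        pairs.extend(self.extra_pairs)
        return pairs


PRESETS: dict[str, ScenarioPreset] = {
    # stable binding mode: every matched level doubly bonded, plus one
    # out-of-register contact from a mismatch-level residue → 27 expected
    # RNA↔DNA bonds per frame.
    "stable_A": ScenarioPreset(
        name="stable_A",
        description="stable promoter-A binding mode (27 expected bonds/frame)",
        alignment_factory=alignment_a_core,
        occupancy_in_register=1.0,
        bonds_in_register=2,
        extra_pairs=(
            PlantedPair(rna_level=6, dna_chain="B", dna_level=7, occupancy=1.0),
        ),
    ),
    # alternative binding mode of the same promoter: weaker occupancies
    "unstable_A": ScenarioPreset(
        name="unstable_A",
        description="less stable promoter-A binding mode (~20 bonds/frame)",
        alignment_factory=alignment_a_core,
        occupancy_in_register=0.72,
        bonds_in_register=2,
        extra_pairs=(
            PlantedPair(rna_level=6, dna_chain="B", dna_level=7, occupancy=1.0),
        ),
    ),
    # short model whose termini separate mid-run
    "short_frayed": ScenarioPreset(
        name="short_frayed",
        description="short promoter-N model with terminal strand separation",
        alignment_factory=alignment_n_core,
        occupancy_in_register=0.75,
        bonds_in_register=2,
        extra_pairs=(
            PlantedPair(
                rna_level=7, dna_chain="B", dna_level=8, occupancy=0.5
            ),
        ),
        fray=FraySpec(after_frame=1000, n_levels=2),
    ),
    # extended model: same core, wider boundaries, no fraying
    "extended_stable": ScenarioPreset(
        name="extended_stable",
        description="extended promoter-N model (clip to the core for "
        "comparison with short_frayed)",
        alignment_factory=alignment_n_ext,
        occupancy_in_register=0.95,
        bonds_in_register=2,
        extra_pairs=(
            PlantedPair(
                rna_level=10, dna_chain="B", dna_level=11, occupancy=0.5
            ),
        ),
        core_alignment_factory=alignment_n_core,
    ),
}


@dataclass
class ScenarioBundle:
    """In-memory result of generating one preset."""

    preset: ScenarioPreset
    alignment: TriplexAlignment
    topology: Topology
    reference: object
    trajectory: Trajectory
    truth: PlantedTruth
    params: ForceFieldParams
    core_alignment: TriplexAlignment | None = None
    clip_levels: list[int] | None = None


def generate_scenario(
    preset_name: str,
    seed: int,
    n_frames: int | None = None,
    params: ForceFieldParams | None = None,
) -> ScenarioBundle:
    """Build topology + synthetic trajectory + truth for a named preset."""
    if preset_name not in PRESETS:
        raise ValidationError(
            f"unknown preset {preset_name!r} (available: {sorted(PRESETS)})"
        )
    preset = PRESETS[preset_name]
    if params is None:
        params = default_params()
    alignment = preset.alignment()
    topology, reference = build_ideal_triplex(alignment, params=params)

    frames = preset.n_frames if n_frames is None else n_frames
    fray = preset.fray
    if fray is not None and n_frames is not None:
        # keep the fray point at the same relative position when rescaling
        rel = preset.fray.after_frame / preset.n_frames
        fray = FraySpec(
            after_frame=int(round(rel * frames)),
            n_levels=preset.fray.n_levels,
            max_shift=preset.fray.max_shift,
        )
    trajectory, truth = synthesize_trajectory(
        topology,
        reference,
        n_frames=frames,
        dt=preset.dt,
        noise_sigma=preset.noise_sigma,
        occupancies=preset.planted_pairs(),
        seed=seed,
        fray=fray,
    )
    core = preset.core_alignment()
    levels = None if core is None else _clip_levels(alignment, core)
    return ScenarioBundle(
        preset=preset,
        alignment=alignment,
        topology=topology,
        reference=reference,
        trajectory=trajectory,
        truth=truth,
        params=params,
        core_alignment=core,
        clip_levels=levels,
    )


def make_scenario(
    preset_name: str,
    out_dir,
    seed: int,
    n_frames: int | None = None,
) -> dict[str, Path]:
    """Generate a preset and write every artefact other modules consume.

    Writes: ``alignment.json``, ``topology.json``, ``params.json``,
    ``traj.pdb`` (+ time sidecar), ``truth.json`` and, when the preset has a
    clip region, ``core_alignment.json`` and ``clip_levels.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = generate_scenario(preset_name, seed=seed, n_frames=n_frames)

    paths = {
        "alignment": out_dir / "alignment.json",
        "topology": out_dir / "topology.json",
        "params": out_dir / "params.json",
        "trajectory": out_dir / "traj.pdb",
        "truth": out_dir / "truth.json",
    }
    with open(paths["alignment"], "w") as fh:
        json.dump(bundle.alignment.to_dict(), fh, indent=1)
    bundle.topology.to_json(paths["topology"])
    bundle.params.to_json(paths["params"])
    write_trajectory(bundle.trajectory, bundle.topology, paths["trajectory"])
    bundle.truth.to_json(paths["truth"])
    if bundle.core_alignment is not None:
        paths["core_alignment"] = out_dir / "core_alignment.json"
        with open(paths["core_alignment"], "w") as fh:
            json.dump(bundle.core_alignment.to_dict(), fh, indent=1)
        paths["clip_levels"] = out_dir / "clip_levels.json"
        with open(paths["clip_levels"], "w") as fh:
            json.dump({"levels": bundle.clip_levels}, fh)
    return paths


__all__ = [
    "PRESETS",
    "ScenarioPreset",
    "ScenarioBundle",
    "example_sequences",
    "alignment_a_core",
    "alignment_n_core",
    "alignment_n_ext",
    "generate_scenario",
    "make_scenario",
    "RNA_DBD_30",
    "PROMOTER_A_PURINE_40",
]
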