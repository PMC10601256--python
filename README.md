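# triplexlens

Prediction and trajectory analysis of parallel RNA:DNA triple helices, plus
the small qPCR normalizations used alongside them.

The package has two halves:

1. **Sequence level** — a strict canonical-code scanner for parallel
   (pyrimidine-motif) triplex target sites: an RNA third strand read 5'→3'
   against the purine strand of a DNA duplex, with U·A and C·G counted as
   matches and everything else annotated as a mismatch. Includes alignment
   rendering/parsing, binding-domain extraction (1-based inclusive
   coordinates) and clipping of extended models back to their core span.
2. **Structure level** — analyses over three-strand trajectories on a
   register-level topology (chain A = RNA, chain B = DNA purine strand,
   chain C = DNA pyrimidine strand):
   - geometric hydrogen-bond detection (donor–acceptor ≤ 3.5 Å,
     H–donor–acceptor angle ≤ 30°, both tunable), per-frame counts with
     window-5 running average, and in-register / out-of-register occurrence
     maps in "H-bond units" (mean simultaneous bonds per frame, may
     exceed 1);
   - short-range LJ+Coulomb pair energies (Lorentz–Berthelot, 10 Å cutoff,
     f = 1389.35458 kJ·mol⁻¹·Å·e⁻²), total RNA↔DNA interaction-energy time
     series (backbone included, optional level clipping), and a
     per-base-pair-level decomposition into hydrogen-bond / cross /
     stacking terms with terminal-residue exclusion;
   - Kabsch superposition, RMSD series and trailing convergence-window
     selection (default: last 400 ns).

Because real MD trajectories are not desk-reproducible, the package ships a
synthetic generator: an ideal-helix triplex builder (rise 3.4 Å, twist
30°/level, 5-atom residue templates with donor/hydrogen/acceptor/backbone
roles and toy charges) and a seeded trajectory synthesizer with planted
per-pair Bernoulli bond occupancies, Gaussian coordinate noise and optional
terminal fraying — everything serialized next to a machine-readable truth
file so analyses can be validated against planted ground truth. Four named
scenario presets (`stable_A`, `unstable_A`, `short_frayed`,
`extended_stable`) cover the qualitative regimes the analyses are meant to
distinguish.

## CLI

All functionality is exposed through the `triplexlens` entry point:

```sh
# scan for triplex target sites (TSV + optional BED6 output)
triplexlens tts-scan --rna rna.fa --dna promoter.fa \
    --window 15 --max-mismatch 2 --out tts.tsv --bed tts.bed

# generate a named synthetic scenario (trajectory, topology, truth, ...)
triplexlens synth-scenario --preset stable_A --seed 7 --out scenario/

# or synthesize directly from an alignment JSON
triplexlens synth --alignment scenario/alignment.json --frames 2000 \
    --dt 0.3 --noise 0.1 --seed 7 --out traj.pdb

# analyses over a multi-model PDB trajectory
triplexlens rmsd   --traj scenario/traj.pdb --topology scenario/topology.json \
    --selection rna --out rmsd.tsv
triplexlens hbonds --traj scenario/traj.pdb --topology scenario/topology.json \
    --window 5 --min-freq 0.01 --out-prefix hb
triplexlens energy --traj scenario/traj.pdb --topology scenario/topology.json \
    --params scenario/params.json --out-prefix en \
    [--alignment ext.json --clip-to core.json]

# qPCR quantification from a tidy Ct table
triplexlens quant ddct --input ct.tsv --target MyGene --out out.tsv
triplexlens quant chip --input ct.tsv --target MyAntibody --out out.tsv
triplexlens quant clip --input ct.tsv --target MyAntibody --out out.tsv
```

Trajectories are exchanged as multi-model PDB (one MODEL per frame) with
frame times in a `<traj>.times.json` sidecar or via `--dt`.

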