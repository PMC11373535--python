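# csens

Conformational-sensitivity analysis of predicted peptide chemical shifts.

Given two groups of near-identical conformers of a short peptide (e.g. the
most stretched and most globular frames of a disordered-peptide trajectory,
each with its most similar neighbors), `csens` asks whether per-atom
chemical-shift predictions can tell the two conformations apart:

- **structio** — multi-model PDB I/O, mass-weighted radius of gyration,
  Kabsch superposition/RMSD, extreme-frame and nearest-neighbor selection,
  backbone dihedrals and per-atom alignability.
- **fragmenter** — per-residue QM-input fragments: all residues within a
  distance cutoff of a central unit, ACE/NME caps sealing chain breaks, and
  optional first-shell micro-solvation; PDB/XYZ output with atom-map sidecars.
- **referencing** — isotropic shielding → chemical shift conversion (TMS for
  ¹H/¹³C; methylamine secondary standard for ¹⁵N with literature anchors
  244.6 / 249.5 ppm) and assembly of per-fragment central-residue shifts.
- **sensitivity** — the core statistic: per-atom two-group separation in
  multiples of the pooled standard deviation, the 10%-overlap / 3.29σ
  threshold, atom categorization, cap/oxygen exclusion, per-residue
  aggregation and the cross-method agreement matrix.
- **validation** — mean relative error against an experimental table and
  secondary chemical shifts (Δδ, ΔΔδ_αβ with α/β/coil calls) against a
  random-coil baseline.
- **features** — per-atom biophysical feature table (Δ-distances, Δφ/Δψ,
  ΔSASA via Shrake–Rupley, alignability, categoricals, negative controls)
  and random-forest permutation importance with grouped one-hot shuffling.
- **synthdata** — fully seeded synthetic systems: ideal-geometry conformer
  groups built from per-group (φ, ψ) targets, shift tables with planted
  separations, and experimental/random-coil tables with exactly controlled
  errors.

## CLI

Every stage is exposed under the `csens` command; the synthetic generator
produces inputs every other subcommand consumes verbatim:

```sh
csens simulate --seed 1 --out sim/
csens select    --pdb traj.pdb --k 4 --out groups/
csens fragment  --pdb sim/stretched.pdb --cutoff 4.0 --out frags/
csens reference --shieldings sigma.csv --refs refs.csv --out shifts.csv
csens sensitivity --shifts sim/shifts_method-1.csv --out sens.csv
csens agreement --shifts sim/shifts_method-1.csv --shifts sim/shifts_method-2.csv --out agree.csv
csens mre       --exp sim/experimental.csv --shifts sim/shifts_method-1.csv
csens secondary --shifts sim/shifts_method-1.csv --rc sim/random_coil.csv --out sec.csv
csens features  --stretched sim/stretched.pdb --globular sim/globular.pdb \
                --shifts sim/shifts_method-1.csv --out feat.csv
csens importance --table feat.csv --repeats 50 --out imp.csv
```

Shift tables use one long CSV schema throughout:
`method, conformer_id, group, residue_number, residue_name, atom_name,
element, value_ppm`.

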