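# ifacedyn

Protein–protein interface dynamics analysis: a reusable, tested pipeline for
asking *why a single point substitution destabilises one receptor complex
but not a homologous one*.

The motivating case is an interface arginine of a shared cytokine-receptor
subunit (GP130 R281, in the D3/D3 contact with the IL-11 α-receptor) whose
substitution by glutamine removes a salt bridge and hydrogen-bond network,
leaving the side chain flexible, the interdomain separation increased and
the buried interface reduced — selectively breaking IL-11-type signalling
while IL-6-type signalling survives.  `ifacedyn` implements the analysis
layer of that kind of study, for anyone with conformational ensembles
(multi-MODEL PDB), alignments (FASTA) and variant tables (TSV):

- **geometry** — Kabsch superposition; per-frame interdomain
  center-of-mass distance `d_t = ‖COM(A) − COM(B)‖`; rotamer-flexibility
  RMSD of one residue vs its 0 ns pose after backbone-Cα superposition.
- **interface** — buried area `B = SASA_A + SASA_B − SASA_{A∪B}` by
  Shrake–Rupley sphere sampling on a deterministic golden-spiral lattice;
  geometric hydrogen-bond and salt-bridge inventories with
  wild-type/variant diffs.
- **mutate** — backbone-preserving side-chain substitution at the
  highest-probability rotamer of a bundled mini library; χ-angle
  measurement.
- **conservation** — AL2CO-style entropy scores `1 − H/ln 20` per
  alignment column, mapped onto structure residues, with minor-allele
  frequency annotation.
- **stats** — exact two-sided Mann–Whitney U (`p = 2·Pr(U ≤ min(Ux,Uy))`)
  and Fisher's exact test; snout-deviation angle for penetrance scoring of
  craniofacial phenotypes.
- **synthetic_data** — toy two-helix complexes with an engineered
  Arg↔(Tyr, Thr, Asp) interface triad, simulated breathing/jitter
  ensembles and synthetic alignments, so the whole pipeline runs without
  any downloads.
- **pipeline / CLI** — `ifacedyn analyze|conserve|synth|stats`.

See `docs/methods.md` for the model assumptions and numerical choices.

## Worked example

Build the toy complex, its Arg→Gln variant, simulate a stable wild-type
ensemble and a destabilised variant ensemble (interdomain shift +0.8 Å,
side-chain χ jitter 25° vs 5°), and run the comparison:

```python
from ifacedyn import (EnsembleParams, ToyComplexSpec, analyze_pair,
                      build_toy_complex, simulate_ensemble,
                      substitute_residue, toy_complex_layout)

spec = ToyComplexSpec(seed=0)
layout = toy_complex_layout(spec)          # domains A:261-300 / B:242-281
wt_model = build_toy_complex(spec)
var_model = substitute_residue(wt_model, *layout.arg, "GLN")

wt = simulate_ensemble(wt_model, EnsembleParams(
    n_frames=500, dt=0.002, com_shift=0.0, com_sigma=0.3,
    chi_jitter_deg=5.0, seed=1), mutated_residue=layout.arg)
var = simulate_ensemble(var_model, EnsembleParams(
    n_frames=500, dt=0.002, com_shift=0.8, com_sigma=0.3,
    chi_jitter_deg=25.0, seed=2), mutated_residue=layout.arg)

report = analyze_pair(wt, var, layout.dom_a, layout.dom_b, residue=layout.arg)
s = report.summary_dict()
print(f"distance  wt {s['com_distance']['wt']['mean']:.3f} Å, "
      f"variant {s['com_distance']['variant']['mean']:.3f} Å, "
      f"p = {s['com_distance']['mann_whitney']['p_value']:.3g}")
print(f"flexibility  wt {s['flexibility']['wt']['mean_rmsd']:.3f} Å, "
      f"variant {s['flexibility']['variant']['mean_rmsd']:.3f} Å")
print(f"buried area  wt {s['buried_area']['wt']['mean']:.1f} Å², "
      f"variant {s['buried_area']['variant']['mean']:.1f} Å²")
print("lost contacts:", s["contacts"]["lost"])
```

prints

```
distance  wt 13.086 Å, variant 13.995 Å, p = 1.44e-156
flexibility  wt 0.301 Å, variant 0.935 Å
buried area  wt 234.0 Å², variant 85.1 Å²
lost contacts: ['hbond:A281-B260', 'hbond:A281-B263', 'saltbridge:A281-B264']
```

The variant's interdomain distance sits ~0.9 Å above the wild type
(0.8 Å planted destabilisation plus the small center-of-mass offset of the
lighter glutamine side chain) at overwhelming Mann–Whitney significance;
its side chain is three times as mobile; the buried interface shrinks; and
the diff names exactly the engineered triad — the salt bridge to the
aspartate and the hydrogen bonds to the tyrosine hydroxyl and threonine
OG1 — as lost.

The same comparison is available from the shell on PDB inputs:

```sh
ifacedyn synth complex --out wt.pdb
ifacedyn synth complex --out mut.pdb --mutate-to-gln
ifacedyn synth ensemble --structure wt.pdb  --out wt_traj.pdb  --frames 500 --jitter 5  --seed 1
ifacedyn synth ensemble --structure mut.pdb --out mut_traj.pdb --frames 500 --jitter 25 --shift 0.8 --seed 2
ifacedyn analyze --wt wt_traj.pdb --mut mut_traj.pdb \
    --domain-a A:261-300 --domain-b B:242-281 --residue A:281 --out report/
```

which writes `distance.tsv`, `flexibility.tsv`, `buried_area.tsv`,
`contacts.tsv` and a deterministic `summary.json`.

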