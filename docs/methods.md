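# Methods

`ifacedyn` quantifies how a point substitution destabilises one side of a
protein–protein interface while leaving a homologous interface intact — the
situation of a receptor residue (an interface arginine such as GP130 R281)
whose loss of anchoring selectively breaks one cytokine receptor complex
(IL-11-type) but not another (IL-6-type).  The package implements the
trajectory-derived observables, the surface and contact geometry, the
conservation mapping and the nonparametric tests for that comparison, plus
generators that emulate the statistical structure of such data so every
stage is testable without any structure downloads or MD engine.

## Observables

**Superposition.**  Rigid-body fits use the Kabsch algorithm: SVD of the
weighted covariance of centred point sets, with the reflection correction
(`det = +1` enforced), so the rotation is always proper even for
near-planar inputs.  Fits may be mass-weighted; the reported RMSD is the
unweighted post-fit value, matching common trajectory-analysis practice.
Collinear point sets are rejected rather than silently fitted.

**Interdomain distance.**  For two domain selections (chain + inclusive
author-numbered residue range, defaults A:198–298 and B:215–317, the D3/D3
pairing of the motivating system), each frame contributes the Euclidean
distance between mass-weighted heavy-atom centers of mass.  Distances are
rigid-motion invariant, so no superposition is applied.  The summary is the
series mean and sample SD; the wild-type and variant series are compared
with the two-sided Mann–Whitney U test, treating frames as exchangeable
samples.  Temporal autocorrelation of an MD trajectory violates that
independence assumption; the test is reproduced here as the field applies
it, and the caveat stands.

**Rotamer flexibility.**  For a watched residue (default 281), each frame
is superposed onto frame 0 on backbone Cα atoms (default: all of them),
then the RMSD of the residue's side-chain heavy atoms (Cβ outward;
configurable to start at Cγ) against their 0 ns positions is recorded.
`mean_rmsd` averages frames t ≥ 1.  An anchored side chain yields a low
mean; one that has lost its hydrogen-bond/salt-bridge partners explores
rotamer space and the mean rises.

**Buried interface area.**  `B = SASA(A) + SASA(B) − SASA(A∪B)` on the two
domains extracted from the complex, clamped at zero.  SASA is
Shrake–Rupley sphere sampling: each atom's sphere of radius (vdW + probe,
probe 1.4 Å, Bondi radii from a built-in table) carries a deterministic
golden-spiral lattice (default 960 points; seedless), and the accessible
fraction is the fraction of lattice points outside every neighbour's
expanded sphere.  This is a solvent-*accessible* buried area standing in
for the solvent-*excluded* (molecular) buried surface the original
Chimera-based analysis used: a reduced-surface algorithm is out of
proportion to what the comparison needs, the wild-type-vs-variant Δ is the
consumed quantity, and both definitions rank toy interfaces identically.
Numerically the sampling is accurate to ~0.1 % against the two-sphere
closed form at 960 points.  A trajectory is summarised at `n` equally
distributed time points (default 10), indices `round(i·(F−1)/(T−1))` so the
first and last frame are always included; per-residue ΔSASA contributions
are ranked at the last frame, with residues above 1 Å² counted as interface
residues.

**Contacts.**  Hydrogen bonds: donor heavy atom (N/O bearing an attachable
proton, per a residue-specific table plus backbone N) to acceptor (carbonyl
and side-chain O, His ring N) within 3.5 Å; a D–H···A angle ≥ 120°
criterion applies only when the structure carries explicit hydrogens,
since MD snapshots are saved with or without protons.  Salt bridges:
Arg NE/NH1/NH2, Lys NZ or His ring N to Asp/Glu carboxylate O within
4.0 Å.  A pair that qualifies as a salt bridge is recorded as such only,
never duplicated as a hydrogen bond, so "number of salt bridges" is well
defined.  Wild-type vs variant inventories are diffed at the
(kind, residue-pair) level into lost / gained / retained sets.

**In-silico substitution.**  A substitution keeps the backbone fixed
(N, CA, C, O untouched; Cβ kept, or rebuilt with the standard −122.5°
improper for L-chirality) and rebuilds the side chain from ideal bond
lengths and angles by internal-coordinate (NeRF) placement at the rotamer
with the highest probability in a bundled backbone-independent mini
library (ties broken by file order) — the same selection rule used when a
variant is modelled from a rotamer library.  Explicit χ angles may be
passed instead, which is how ensembles re-pose a side chain.  The library
is a TSV of 2–5 canonical rotamers per residue type with plausible
backbone-independent probabilities; the selection *rule*, not any
particular published library, is the tested behaviour.  No steric
relaxation is performed (the original workflow minimised inside an MD
engine; that is out of scope here) and proline ring closure is not
enforced.

**Conservation.**  Per alignment column, amino-acid frequencies over
non-gap symbols give Shannon entropy `H`, and the score is `1 − H/ln 20` —
the unweighted entropy measure of the AL2CO family, chosen because it is
the family's default; sequence weighting is stubbed off.  Columns with gap
fraction above 0.5 are undefined (NaN), never a number.  Scores map onto a
structure chain via a reference row whose ungapped sequence must match the
chain exactly (the first discordant position is reported), and can be
annotated with population minor-allele frequencies (absent residues get 0;
duplicate variant rows are summed and logged).

**Statistics.**  Mann–Whitney U uses mid-ranks for ties.  Exact two-sided
p = `2·Pr(U ≤ min(Ux, Uy))` capped at 1, from the classical count
recurrence (cached per sample-size pair; counts stay below 2⁵³ so float64
arithmetic is exact); exact mode requires tie-free data.  `auto` uses the
exact route for n_x + n_y ≤ 16 without ties and otherwise the normal
approximation with tie correction and continuity correction — so
trajectory-scale comparisons (500 frames per arm) always use the
approximation, which matches the reference asymptotic implementation to
1e-12.  Under the null the exact test's analytic type-I error at α = 0.05
with 20 observations per arm is 0.0491, and the empirical rate over 10 000
simulations is asserted at 0.05 ± 0.01.  Fisher's exact test sums
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed table's (relative tolerance 1e-7
against floating-point ties).  The snout-deviation angle α is the unsigned
angle between the posterior→anterior midline direction and the
posterior→tip vector of 2-D landmarks; the wild-type variability threshold
is a configuration value with no built-in default, because that band is an
empirical property of a given colony.

## Synthetic data: what it emulates and what it does not

`build_toy_complex` constructs two ideal poly-alanine α-helices
(φ = −57°, ψ = −47°, ideal bond geometry) on chains A and B.  With the
interface triad enabled, chain A carries an arginine at author number 281
and chain B a tyrosine/threonine/aspartate at 260/263/264; the helices are
docked by a deterministic rigid-body search (fixed starting orientations,
Nelder–Mead refinement of a distance-target + clash penalty, small
discrete rotamer trials for the chain-B residues) until the salt bridge
(≤ 3.4 Å) and both hydrogen bonds (≤ 3.25 Å) are satisfied without steric
collapse.  The designed residue numbers sit at spatially adjacent helix
positions; the author numbers of a real receptor's triad cannot be
reproduced on a single ideal helix because residues 21 positions apart are
~30 Å away along the axis.  A per-seed 0.02 Å coordinate jitter makes
seeds distinguishable without endangering any threshold; topology is
seed-independent.

`simulate_ensemble` reproduces only the *analysed statistics* of a short
MD run: per frame the mobile chain translates rigidly along the
interdomain axis by `Normal(shift, σ²)` and the watched side chain is
rebuilt at χ angles jittered by `Normal(0, jitter²)`.  Defaults are the
study conditions of the motivating comparison: 500 frames for distance
analysis (dt 0.002 ns over 1 ns), snapshots every 0.1 ns for rotamer
flexibility, breathing σ 0.3 Å, a destabilisation shift of +0.8 Å for the
variant condition, and χ jitter of 25° (variant) vs 5° (wild type).  Frame
0 is the re-idealised input pose.  No force field, solvent, thermostat,
backbone flexibility or correlated dynamics is modelled — so passing tests
demonstrate that the *analysis* recovers planted statistical structure,
not that the generator resembles physical MD in any other respect.

Parameter-recovery checks compare the same base complex under wild-type
and shifted breathing statistics.  Comparing the substituted complex
instead adds a small systematic offset (the lighter glutamine side chain
moves the domain center of mass by ~0.05 Å at the default 40-residue
domain size), which is why the end-to-end substituted comparison is
asserted directionally while recovery of the planted 0.8 Å shift is
asserted quantitatively.

`simulate_msa` plants fully conserved columns in a uniform-random
background — adequate for closed-form conservation checks, with none of
the phylogenetic correlation of real alignments.

## Numerical and design choices

- Hydrogens are parsed but excluded from every metric by default, so
  wild-type/variant comparisons do not depend on protonation bookkeeping.
- Altloc records other than ' '/'A' are skipped; insertion codes are
  rejected; HETATM (ligands, waters) dropped with a logged count.
- PDB round-trips preserve topology exactly and coordinates to 1e-3 Å
  (the fixed-width limit).
- Element table: C 12.011, N 14.007, O 15.999, S 32.06, H 1.008 amu; Bondi
  radii C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å.
- Distance series use the sample SD (ddof 1); flexibility frame 0 is
  exactly 0 by definition.
- The whole pipeline is a pure function of (inputs, config, seeds):
  `summary.json` contains no timestamps and serialises with sorted keys,
  so two runs on identical inputs are byte-identical.
- Test problem sizes (ensemble lengths, SASA lattice densities in
  integration tests) are scaled to keep the suite fast while leaving every
  statistical assertion comfortably powered; the headline checks run at
  the full study conditions (500 frames, 960 lattice points).

## Known limitations

- Solvent-accessible rather than solvent-excluded buried area (above).
- Exact Mann–Whitney mode refuses ties instead of enumerating the
  mid-rank permutation distribution.
- The rotamer library is a compact stand-in: correct χ definitions and
  selection rule, but not the statistics of any published library.
- Ring geometry of rebuilt aromatic side chains is idealised atom-by-atom
  rather than closed exactly; proline's CD–N ring bond is not enforced.
- The toy docking search is a construction device, not a docking method;
  it raises rather than degrades when a requested motif is infeasible.
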