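# motifbench

Quantify and benchmark the nonbonded interaction energies that hold
kinase-inhibitor-like ligands inside protein binding sites.

## The problem

Protein–ligand recognition is dominated by a handful of recurring
noncovalent contact types between a ligand fragment and a single binding-site
residue: CH–π contacts, π–π stacking, cation–π attraction, hydrogen bonds,
and salt bridges.  Quantum-chemical reference energies for a library of such
two-monomer *motifs* make it possible to (a) characterize how strong each
interaction class really is, in the gas phase and in water, and (b) score
cheaper approximate methods (dispersion-corrected DFT) against the reference
by mode-resolved error statistics.

`motifbench` implements that pipeline end to end:

| stage | module | what it does |
|---|---|---|
| geometry | `motifbench.motifs` | parse two-monomer PDB motifs, perceive bonds and aromatic rings, measure plane angles / centroid separations / hydrogen-bond geometry, classify the interaction mode |
| dispersion | `motifbench.dispersion` | pairwise dispersion energy with Becke–Johnson damping, coordination-number-interpolated C6/C8 coefficients, per-functional damping parameters |
| extrapolation | `motifbench.cbs` | two-point inverse-cube extrapolation of correlation energies to the basis-set limit and the composite coupled-cluster total |
| assembly | `motifbench.assembly` | supramolecular interaction energies, counterpoise fragment bookkeeping (ghost atoms), and the gas → dehydration → aqueous thermodynamic cycle |
| statistics | `motifbench.benchmark` | RMSD / MAE / signed-average / max-percentage error, per-mode stratification, per-mode reference summaries, accuracy-vs-cost Pareto front |
| synthetic data | `motifbench.synthetic` | seeded generators for motifs, basis-set series, and whole energy ledgers with known planted truth |
| orchestration | `motifbench.pipeline`, `motifbench.cli` | validated run configuration, staged execution, JSON reports, `motifbench` command-line interface |

The package ships a 49-motif reference library
(`motifbench.reference`): per-motif interaction energies
`dE_gas`, `dE_deh` (dehydration penalty), and `dE_aq = dE_gas + dE_deh`
in kcal/mol, plus the tabulated geometric descriptors of each motif.

## Model and notation

- A **motif** is a pair of monomers — a ligand fragment and one amino-acid
  residue — cut from a crystal structure.  Energies are interaction
  energies: `ΔE = E(AB) − E(A) − E(B)`, negative = attractive, kcal/mol.
- **Counterpoise correction** evaluates the monomers in the dimer basis
  (ghost atoms) to remove basis-set superposition error:
  `ΔE_CP = E(AB) − E(A·ghostB) − E(B·ghostA)`.
- **Dispersion** is the damped pairwise sum
  `E = −½ Σ_{A≠B} [ s6·C6/(R⁶+f(R0)⁶) + s8·C8/(R⁸+f(R0)⁸) ]` with
  `f(R0) = a1·√(C8/C6) + a2`; C6 coefficients are interpolated over
  fractional coordination numbers.
- **Basis-set limit**: correlation energies at cardinal numbers X−1 and X
  follow `E(X) = E_∞ + A·X⁻³`; the two-point formula
  `E_∞ = [X³E_X − (X−1)³E_{X−1}] / [X³ − (X−1)³]` eliminates A exactly.
- **Solvation cycle**: `ΔE_aq = ΔE_gas + ΔE_deh`, where
  `ΔE_deh = G_sol(AB) − G_sol(A) − G_sol(B)` is the dehydration penalty.
- **Error metrics** against a reference method: RMSD, MAE, AVG
  (signed mean of calc − reference; positive = less attractive than the
  reference), and MAX% (largest absolute error as a percentage of the
  absolute reference value).

## Worked example

Generate a π-stacked ring pair with known geometry, then measure and
classify it:

```sh
$ python -c "
from motifbench.synthetic import gen_ring_pair
txt, truth = gen_ring_pair(43.85, 3.55, seed=7)
open('motif.pdb', 'w').write(txt)
print(truth)"
{'mode': 'pi-pi', 'plane_angle': 43.85, 'centroid_sep': 3.55}

$ motifbench measure --pdb motif.pdb --ligand LIG --residue 90
{
  "mode": "pi-pi",
  "closest_heavy_distance": 2.67,
  "plane_angle": 43.85
}

$ motifbench d3 --coords motif.pdb --functional B3LYP
E_disp(B3LYP) = -38.734051 kcal/mol
```

Simulate an energy ledger with a planted method error, assemble the
per-motif energies, and score the method:

```sh
$ motifbench simulate --seed 11 --n-motifs 5 --bias 0.2 --sigma 0.1 --out sim
sim

$ motifbench assemble --ledger sim/ledger.tsv --solvation sim/solvation.tsv --method dft | head -4
motif_id	dE_gas	dE_deh	dE_aq
m0001	-1.8	1.1	-0.7
m0002	-2.4	0.3	-2.1
m0003	-1.4	0.4	-1.0
```

Summaries of the packaged reference library are one call away:

```python
>>> from motifbench.benchmark import mode_summary
>>> from motifbench.reference import load_energy_table
>>> s = {(x.mode, x.phase): x.mean for x in mode_summary(load_energy_table())}
>>> s[("salt-bridge", "gas")], s[("salt-bridge", "aqueous")]
(-99.5, -4.4)
```

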