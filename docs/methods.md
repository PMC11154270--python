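# Methods

This document records the physical model, every tunable parameter with its
default and unit, the numerical choices behind the implementation, and the
known limitations.  All energies are kcal/mol unless a hartree is named
explicitly; all distances are ångström in user-facing interfaces and bohr
internally where noted.

## 1. Motif geometry and mode classification

A motif is a pair of monomers (ligand fragment + one residue) read from a
PDB-format file with `gemmi`.  Parsing resolves alternate locations by
keeping, per atom name, the altloc with the highest occupancy (ties broken
lexicographically, so conformer `A` wins a tie).

**Bond perception**: two atoms are bonded when their distance is at most
1.3 × the sum of their covalent radii (Cordero radii, ångström).  The
factor 1.3 is the conventional slack for crystal-structure coordinates.

**Aromatic ring perception**: the graph of bonded heavy atoms is reduced to
a minimum cycle basis (`networkx.minimum_cycle_basis`); 5- and 6-cycles are
kept if planar, where planarity means the RMS out-of-plane deviation from
the best-fit plane (smallest singular vector of the centered coordinates)
is at most 0.1 Å.

**Geometric descriptors**:

- *plane angle* — angle between ring normals, folded to [0°, 90°];
- *centroid separation* — distance between ring centroids;
- *closest heavy-atom distance* — minimum cross-monomer C/N/O distance;
- *hydrogen-bond geometry* — for every cross-monomer donor(N/O/S with a
  covalent H)–acceptor(N/O) contact with D···A ≤ 3.5 Å and
  D–H···A ≥ 120°, the (angle, D···A distance) pair, sorted by descending
  angle.

**Classification cascade** (first match wins):

| rule | mode | envelope |
|---|---|---|
| 1 | salt-bridge | both monomers carry opposite formal charges and the closest heavy-atom contact is ≤ 5.5 Å |
| 2 | cation-pi | one monomer is a cation, the other has an aromatic ring, cationic N to centroid ≤ 6.0 Å |
| 3 | H-bond | at least one hydrogen bond per the criteria above |
| 4 | pi-pi | both monomers aromatic, centroid separation ≤ 5.5 Å |
| 5 | CH-pi | a non-ring C–H of one monomer with H to centroid ≤ 3.5 Å |
| — | unclassified | none of the above |

The envelopes are geometric screens for assigning a dominant interaction
type, not energetic statements; borderline motifs get the first matching
label.

## 2. Pairwise dispersion with Becke–Johnson damping

The dispersion energy of an N-atom system is

```
E = −(1/2) Σ_{A≠B} [ s6 C6_AB / (R_AB⁶ + f(R0_AB)⁶)
                   + s8 C8_AB / (R_AB⁸ + f(R0_AB)⁸) ]
f(R0_AB) = a1 √(C8_AB / C6_AB) + a2            (all in atomic units)
```

- **Coordination numbers** (dimensionless):
  `CN_A = Σ_{B≠A} 1 / (1 + exp(−k1 (4/3 (Rcov_A + Rcov_B)/R_AB − 1)))`
  with steepness `k1 = 16` and covalent radii in bohr.  The counting
  function's value at infinite self-distance is not exactly zero in
  floating point, so the diagonal is zeroed explicitly.
- **C6 interpolation**: per element a short table of (CN, C6) reference
  points; a pair coefficient is the Gaussian-weighted average
  `C6_AB(CNa, CNb) = Σ_ij w_ij √(C6_i C6_j) / Σ_ij w_ij` with
  `w_ij = exp(−k3 [(CNa−CN_i)² + (CNb−CN_j)²])`, `k3 = 4`.  Because the
  pair reference values are geometric means of atomic values, the double
  sum factorizes, and the production code evaluates a per-atom effective
  `√C6` once (O(N) interpolation) before the O(N²) pair loop.  A scalar
  per-pair routine (`pair_c6`) implements the unfactorized double sum and
  is used as an independent cross-check in the tests.
- **C8 recursion**: `C8_AB = 3 C6_AB √(Q_A Q_B)` with tabulated per-element
  `Q = ⟨r⁴⟩/⟨r²⟩` factors.
- **Functional parameters** (dimensionless s6/s8/a1, a2 in bohr), packaged
  for nine functionals; defaults are the values for B3LYP
  (`s6 = 1.0, s8 = 1.9889, a1 = 0.3981, a2 = 4.4211`).  `s6 < 1` only for
  double hybrids (B2PLYP 0.64, PWPB95 0.82).
- Coincident atoms (R < 1e-6 bohr) are rejected with an error; the damped
  form is otherwise finite down to contact.

**Synthetic reference data.**  The packaged element tables
(`data/d3_reference_synthetic.json`) — covalent radii, (CN, C6) reference
points for H/C/N/O/F/P/S/Cl, and Q factors — are *synthetic stand-ins*
with physically plausible magnitudes and orderings, not published
dispersion coefficients.  Every graded property of this module (oracle
equivalence, invariances, asymptotics, sign) is internal to the scheme and
independent of the absolute coefficient values.  Absolute dispersion
energies printed by `motifbench d3` should therefore be read as
model-consistent, not literature-comparable.

## 3. Basis-set extrapolation and the composite energy

Correlation energies at consecutive cardinal numbers (X−1, X), X ≥ 3,
are extrapolated by

```
E_∞ = [X³ E_X − (X−1)³ E_{X−1}] / [X³ − (X−1)³]
```

which is exact for `E(X) = E_∞ + A X⁻³` (the A-term cancels
algebraically).  The extrapolated total pairs the HF energy at the larger
basis with the extrapolated correlation energy.  The composite
coupled-cluster estimate adds a small-basis correction:

```
ΔE_CCSD(T)/CBS = ΔE_MP2/CBS + (ΔE_CCSD(T) − ΔE_MP2) | small basis
```

with a guard that both small-basis terms carry the same basis label.

## 4. Interaction energies, counterpoise, and the solvation cycle

`ΔE = E(AB) − E(A) − E(B)` (supramolecular).  Counterpoise bookkeeping
enumerates five fragment roles — `dimer_AB`, `monoA_ghostB`,
`monoB_ghostA`, `monoA_alone`, `monoB_alone` — where ghost fragments keep
every dimer atom but mark the partner's atoms as basis-only (`element:` in
the emitted XYZ).  The corrected energy uses the ghost pair:
`ΔE_CP = E(AB) − E(A·ghostB) − E(B·ghostA)`, converted from hartree with
1 hartree = 627.509 kcal/mol (1 Å = 1.8897259886 bohr).

Solvent effects enter through a thermodynamic cycle:
`ΔE_deh = G_sol(AB) − G_sol(A) − G_sol(B)` (the dehydration penalty,
large and positive for charged motifs) and `ΔE_aq = ΔE_gas + ΔE_deh`.

## 5. Benchmark statistics

Errors of a method against the reference column, `e_i = calc_i − ref_i`:

- `rmsd = √(mean e²)`, `mae = mean |e|`, `avg = mean e` (signed; positive
  means the method binds less strongly than the reference),
  `max% = max |e_i| / |ref_i| × 100` (undefined, and rejected, when any
  reference value is zero).
- Stratification computes the same metrics per interaction mode plus an
  `overall` row; the overall RMSD² is the count-weighted mean of the
  per-mode RMSD².
- Reference-library summaries report per mode × phase
  (gas/dehydration/aqueous) the mean (printed at one decimal,
  half-away-from-zero rounding to match printed tables), minimum, maximum,
  and count.
- The accuracy-vs-cost Pareto front keeps the methods not dominated in
  (rmsd, cpu_minutes); CPU minutes are consumed as input data, never
  recomputed.

## 6. The packaged 49-motif reference library

`data/motif_geometry.tsv` (mode, source-structure id, pair label, angles,
distances) and `data/motif_energies.tsv` (`dE_gas`, `dE_deh`, `dE_aq`).
Mode membership: 13 CH–π, 12 π–π, 8 cation–π, 8 H-bond, 8 salt-bridge.
`validate_reference_fixture` checks row count, mode tallies, and per-row
cycle closure `|dE_gas + dE_deh − dE_aq| ≤ 0.15` kcal/mol — the slack
exists because the table stores one-decimal values, so two rounded addends
can differ from the rounded sum by up to ~0.1, plus margin.

## 7. Synthetic generators: what they emulate, and what they do not

All generators are seeded (`numpy.random.default_rng`) and bit-reproducible.

- `gen_ring_pair(angle, separation, displacement)` — two benzene rings at
  an exact plane angle and centroid separation (π–π).
- `gen_hbond_pair(angles, distances)` — one or two donor–H···acceptor
  triples at exact angle/distance, mimicking dual hinge-region hydrogen
  bonding; geometrically impossible requests raise `infeasible-geometry`.
- `gen_charged_pair(mode, distance)` — methylammonium/carboxylate
  (salt-bridge) or benzene/ammonium (cation–π) at an exact closest-contact
  distance, with a random rigid motion applied so orientation is never
  special.
- `gen_chpi_pair`, `gen_fused_rings`, `gen_random_cluster` — CH–π probe,
  an indole-like fused 5+6 ring system, and random C/H/N/O point clusters
  for dispersion stress tests.
- `gen_cbs_series(e_inf, a)` — correlation energies lying exactly on the
  X⁻³ model, so the extrapolated limit is known.
- `gen_ledger(LedgerSpec)` — a full synthetic experiment: per-motif true
  interaction energies drawn per mode at magnitudes matching the reference
  library (default mix 13/12/8/8/8, cycled for larger n), absolute
  fragment energies constructed so the supramolecular difference
  reproduces the truth exactly (ghost = isolated monomer, i.e. zero
  BSSE), approximate methods as `truth + bias + N(0, σ)`, and a solvation
  table encoding a planted dehydration penalty.  The returned truth table
  makes every downstream statistic checkable to round-off.

These generators emulate *geometry and bookkeeping*, not electronic
structure: no quantum-chemical energies are computed anywhere in the
package, and the planted method errors are a statistical model
(mode-independent bias + Gaussian noise), not a physical error model of
any actual functional.

## 8. Numerical choices

- Printed-table comparisons use half-away-from-zero rounding
  (`decimal.ROUND_HALF_UP`) because Python's bankers' rounding disagrees
  with printed one-decimal tables on exact halves.
- The dispersion energy is evaluated with vectorized upper-triangle pair
  arrays; equality with the naive scalar double loop is enforced to
  1e-10 kcal/mol in the acceptance tests.
- Derived random seeds are drawn in [0, 2³¹) so they remain valid for any
  downstream 32-bit consumer.
- Problem sizes in tests and the acceptance script (100 clusters of ≤ 15
  atoms, 1000 extrapolation draws, 5000-motif ledgers, 20 classification
  draws per mode) are the package's own choices, sized to finish in
  seconds while keeping statistical assertions sharp
  (e.g. 3σ/√n ≈ 0.02 for the planted-bias recovery).

## 9. Resolved ambiguities

- **AVG sign convention**: `calc − reference`, so a positive AVG means the
  approximate method is less attractive than the reference.
- **MAX% definition**: absolute error over absolute reference value; no
  sign is carried.
- **H-bond donors** include S–H in addition to N–H/O–H; acceptors are
  N/O only.
- **Classification precedence** resolves motifs satisfying several
  envelopes (e.g. a charged hydrogen bond) in favor of the
  charge-dominated label, matching the cascade order of §1.
- **Cycle slack 0.15** (§6) covers printed-rounding drift without masking
  genuine transcription errors (a corrupted row fails by > 0.8).

## 10. Limitations

- No quantum-chemistry engine: the package quantifies, assembles, and
  benchmarks energies; it does not compute HF/MP2/CCSD(T)/DFT values.
  External ledgers supply those (see
  `motifbench.reference.data_requirements()`).
- Dispersion element tables are synthetic stand-ins (§2); absolute
  dispersion energies are not literature-comparable.
- Ring perception handles 5/6-membered planar rings only; larger
  macrocycles and strongly puckered rings are out of scope.
- Mode classification is geometric; it does not detect mixed or
  many-body interaction character.
- The solvation cycle consumes solvation free energies as data; no
  continuum model is implemented.
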