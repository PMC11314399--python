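# Methods

## The problem and the model

Coarse-grained (CG) molecular dynamics of the Martini family represents
~2–4 heavy atoms by one interaction site ("bead"), which buys orders of
magnitude in accessible time and length scale at the cost of atomistic
detail.  Recovering an atomistic (AA) structure from a CG frame —
back-mapping — is underdetermined: many AA configurations are consistent
with one bead arrangement.  `beadcast` resolves the ambiguity with a
*template* prior: every molecule type carries one energy-minimized AA
reference conformation, and the CG frame only decides where that
conformation goes and how it bends.

The protocol has five stages, applied per system:

1. **Superpose.** For each CG molecule, the template is rigidly fitted onto
   the beads by minimizing the RMSD between the beads and their *mapped
   atoms* (one designated AA atom per bead) over proper rotations and
   translations.  This is the Kabsch problem; the SVD solution is
   sign-corrected so that det(R) = +1 always.  Reflections would fit
   mirror-image conformations equally well, and silently inverting a
   stereocenter is exactly the failure mode geometric back-mappers are
   prone to — forbidding improper rotations is what makes handedness a
   structural invariant of the method rather than a hope.
2. **Vacuum relaxation.** Each molecule is relaxed alone (no intermolecular
   interactions) with a harmonic position restraint ½k|x − x_ref|² tethering
   every mapped atom to its bead position: steepest-descent minimization, a
   short stochastic-dynamics run, then a final minimization.  The restraint
   pulls the template into the conformation the CG frame dictates; the
   bonded terms keep the internal geometry sane while it bends.
3. **Assembly.** Molecules are merged in topology order; the box is copied
   from the CG input and molecules are wrapped into the primary cell by
   centroid, so they stay whole.
4. **Resolvation.** Each W/WF bead becomes four 3-site waters (O–H
   0.09572 nm, H–O–H 104.52°) with oxygens on a tetrahedron of radius
   0.31 nm and a seeded uniform random cluster orientation.  Each ion bead
   becomes one ion plus a four-water first shell (ion–O 0.23 nm for Na⁺,
   0.31 nm for Cl⁻), oxygen toward cations and hydrogens toward anions.
   Anti-freeze WF beads are a CG artifact and back-map identically to W.
5. **System relaxation.** The whole system relaxes at constant volume with
   all restraints active and the repulsive nonbonded term now acting across
   molecules under periodic minimum-image distances, so overlapping solvent
   placements resolve.  Finally the structure is audited: every declared
   stereocenter's signed tetrahedral volume
   (b−c₀)·((a−c₀)×(c−c₀)) must keep its template sign, and a periodic
   cell-list search must find no inter-molecular heavy-atom pair below the
   clash cutoff.

## The internal force field

Relaxation runs on a deliberately minimal potential:

- harmonic bonds ½k_b(r − b₀)² and angles ½k_θ(θ − θ₀)², with equilibria
  from the molecule's itp when present and otherwise measured from the
  template geometry (missing angle triples are derived from the bond
  graph); stiff defaults k_b = 5000 kJ mol⁻¹ nm⁻², k_θ = 500 kJ mol⁻¹ rad⁻²;
- a capped quadratic repulsion E(r) = ε(1 − r/r_c)² for r < r_c, with
  ε = 100 kJ mol⁻¹ and r_c = 0.25 nm, on all non-excluded pairs (1-2 and
  1-3 pairs through the bond graph are excluded).  The cap keeps energy and
  force finite at exact overlap — the property a soft-core potential
  provides in an MD engine — so freshly placed waters can start on top of
  each other and still relax apart;
- position restraints as above.

Dihedral and improper torsions are intentionally absent.  Chirality is
protected structurally (proper-rotation fits plus the audit), not
energetically, and the short restrained relaxations do not need torsional
barriers.  This force field prepares structures; it makes no thermodynamic
claims.  Production-quality energetics (PME electrostatics, thermostats,
barostats, constraints) belong to the external engine, for which the
pipeline can export a GRO structure, an assembled `[ molecules ]` topology
and per-molecule `[ position_restraints ]` stanzas.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| restraint k (mapped atoms) | 10000 | kJ mol⁻¹ nm⁻² | thermal spread √(k_BT/k) ≈ 0.016 nm at 313 K: mapped atoms visibly overlap their beads |
| restraint k (solvent O, ions) | 1000 | kJ mol⁻¹ nm⁻² | keeps the Martini solvent distribution while letting clashes resolve |
| temperature | 313 | K | the membrane-fluid-phase temperature the study systems use |
| SD time step / friction | 0.0005 / 50 | ps, kJ mol⁻¹ ps nm⁻² | see numerical choices |
| SD steps (vacuum / system) | 1000 / 100 | — | "short": decorrelates conformations without drifting off the beads |
| EM step0 / f_tol | 0.005 / 10 | nm, kJ mol⁻¹ nm⁻¹ | displacement-capped steepest descent; tolerance far below restraint forces of interest |
| clash cutoff | 0.08 | nm | below any physical heavy-atom contact; hits only genuine placement failures |

## Numerical choices

- **Integrator.** Overdamped Langevin (Euler–Maruyama):
  x ← x + (F/γ)Δt + √(2k_BTΔt/γ)ξ.  Stability requires k_eff·Δt/γ < 2 for
  the stiffest harmonic mode.  The angle term dominates: about a vertex
  with arm r it acts like a spatial spring of ~4k_θ/r²
  (≈ 10⁵ kJ mol⁻¹ nm⁻² for r ≈ 0.14 nm), which is why the defaults are
  Δt = 0.5 fs with γ = 50 rather than a larger step.  The guard computes
  the per-angle arm lengths from the actual input geometry and raises,
  advising a smaller Δt, before an unstable run starts.  Placed waters get
  scaffolding bonds (k_b = 20000) and a softer angle (k_θ = 150) chosen to
  hold their geometry through the short relax without dominating the
  stability budget.
- **Minimizer.** Steepest descent, step expressed as a cap on the largest
  atomic displacement; accepted steps grow the cap ×1.2, rejected steps
  shrink it ×0.2.  Accepted energies are monotone non-increasing by
  construction, which is asserted, not assumed.
- **Degenerate fits.** For one bead, two beads, or collinear beads the
  least-RMSD rotation is non-unique; the tie breaks deterministically to
  the minimal-angle rotation achieving the optimum (identity for a single
  bead).  One-bead molecules therefore translate exactly onto their bead.
- **Repulsion at r = 0.** The energy is finite by construction; the force
  direction is undefined, so a fixed axis is used — the pair separates
  deterministically.
- **Periodic boundaries.** Orthorhombic boxes only; triclinic cells are
  parsed and rejected with a clear error.  Bead positions of a molecule
  split across the boundary are made whole by minimum image relative to the
  first bead before fitting.
- **Determinism.** Every stochastic stage takes a seed.  Molecule i derives
  its seed from (run seed, i) via `SeedSequence`, so per-molecule work can
  be farmed out to any number of worker processes and the output is
  bit-identical to a serial run.

## What the synthetic systems emulate — and what they do not

The fixtures module generates toy amphiphiles (3 CG beads, ~10 atoms: a
polar head bearing one declared stereocenter, an alkyl zigzag tail),
lattice bilayers with jittered leaflets, Fibonacci-sphere micelles, water
slabs with 10% anti-freeze beads, and NaCl beads, plus a tiny peptide for
the per-residue protein mapping.  They reproduce the *structure* of real
back-mapping inputs — topology/structure bookkeeping, solvent routing,
multi-residue mapping, PBC, chirality bookkeeping — at a scale where
brute-force oracles (rotation sampling, O(N²) clash search, finite
differences, the equipartition closed form) are exact enough to test
against.  They do not reproduce real Martini bead chemistry, real lipid
force fields, or realistic conformational disorder: a CG frame from a long
Martini run strains templates far harder than a jittered lattice does.
Passing tests therefore certify the machinery (stoichiometry, optimality,
invariants, determinism, audits), not the biophysical quality of any
particular converted membrane — that is what the exported engine files and
a subsequent production run are for.

## Problem sizes

The test suite and the acceptance script run the full protocol on a
64-lipid toy bilayer (~5300 atoms after resolvation), 100 randomized
two-molecule micelle conversions for the chirality property, 1000 random
point clouds against a 10⁴-rotation oracle, and a 10⁵-step single-atom
stochastic run for the equipartition check.  These sizes were chosen so
each oracle remains exact and each run completes in seconds on one CPU;
the pipeline itself has no intrinsic size limit beyond memory and the
5-digit serial fields of the output formats (which wrap, by convention).

## Known limitations

- One mapped atom per bead; center-of-mass (many-to-many) mappings are out
  of scope by design.
- Ring-piercing is only approximated by the clash audit; an exact
  topological test is future work.
- Protein instances are delimited by chain boundaries in the CG input;
  systems that interleave chains within one molecule block will not
  partition.
- The internal relaxation is a structure-preparation tool, not an MD
  engine; exported systems should be minimized and equilibrated under the
  target force field before production.
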