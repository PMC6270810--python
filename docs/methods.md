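# Methods

## Scope and data

The package models structure–affinity relationships in the CoMFA
tradition: a congeneric series aligned on a common scaffold, described by
probe interaction energies on a lattice, regressed on activity by PLS.
Two kinds of input are supported:

1. **The packaged CB1/CB2 affinity tables** — transcriptions of a
   published aminoalkylindole assay series (49 molecules for CB1, 80 for
   CB2, with fixed train/test splits of 36/13 and 60/20). These are
   numbers-only: Ki (nM), actual pKi, predicted pKi, residual, split. All
   derived statistics (pKi conversion, residuals, PRESS/SD/r²_pred) are
   recomputed from them and checked at printed precision. The original 3D
   structures of that series are not publicly machine-readable, so the
   full field/PLS pipeline cannot be (and is not) validated against that
   series' internal q²/r²/SEE/F; those are replaced by oracle and
   recovery guarantees on synthetic data (below).
2. **User structures** (SDF V2000 or MOL2) with a scaffold template and an
   explicit atom-correspondence map, plus an activity CSV.

A note on the printed tables: the Ki column is rounded (to ~1 decimal at
sub-nM values), so for a few rows the printed pKi differs from
−log₁₀(Ki·10⁻⁹) by more than the pKi column's own rounding (up to 0.03 at
Ki = 0.7 nM). The per-row consistency invariant therefore checks that the
printed pKi lies inside the interval implied by the printed Ki's half-ulp,
rather than a fixed tolerance.

## Conformer preparation

The energy model is intentionally light: Lennard-Jones 6-12 plus Coulomb
(1-2/1-3 exclusions, distance-dependent dielectric D = d, Coulomb constant
332.0 kcal·Å/mol/e²) and a single generic threefold torsion term
(V₃ = 0.2 kcal/mol) on every proper torsion. There are no bond-stretch or
angle-bend terms (a declared non-goal), so:

* **Minimization** (L-BFGS, gradient tolerance 0.005 kcal/mol/Å, up to
  1000 cycles) is meaningful for relaxing nonbonded contacts and poses; it
  is guaranteed never to return a higher-energy structure than its input.
* **Large conformational moves are made in torsion space**, where bond
  lengths and angles are exactly invariant: simulated annealing runs
  Metropolis Monte Carlo over rotatable bonds (single, acyclic, both ends
  ≥2 neighbors), one random bond per step, moves uniform in ±30°, at
  700 K for 1000 steps followed by a linear cool to 200 K over 1000 steps.
  Temperature endpoints mirror the heating/annealing protocol such studies
  use; Monte Carlo steps stand in for femtosecond MD steps. The procedure
  is bit-for-bit reproducible per seed.

Alignment is rigid least-squares superposition (Kabsch, proper rotations
only) over an explicit scaffold atom map. The map is supplied as a file
(two 1-based columns), never inferred by substructure search: explicitness
removes both a heavy dependency and an ambiguity about which indole-like
atoms correspond.

Partial charges are PEOE (Gasteiger) sigma charges: χ = a + b·q + c·q² per
atom type (coefficients packaged, standard literature values), transfers
along bonds damped by 0.5^iteration, 6 iterations by default. They agree
with RDKit's implementation to <0.01 e on test molecules. The "Hückel π"
component used by some modelling suites is approximated by spreading the
formal charge of each conjugated system uniformly over its atoms (a no-op
for neutral systems) and can be disabled (`use_huckel_pi=False`); full
Hückel theory adds little for neutral ligand series and would not be
testable against ground truth here. Van der Waals parameters are a
packaged Tripos-style per-element table (C 1.70 Å/0.107 kcal/mol, etc.);
it is data, not code, and swappable.

## Fields and descriptor processing

Defaults follow common CoMFA practice: 2.0 Å lattice spacing, 4.0 Å
margin snapped outward to whole-spacing multiples, sp³-carbon/+1 probe,
±30 kcal/mol truncation, electrostatic values at buried points (steric at
cap) replaced by the column mean over non-buried molecules, minimum-sigma
column filter 2.0 kcal/mol, block weighting by inverse overall standard
deviation. Each is a config field; the column filter is applied to both
the cross-validated and final fits so the descriptor space is identical in
both (applying it only to the final fit, as some descriptions suggest,
would make q² and r² incomparable). Block scaling can be set to `none`
for sensitivity analysis, since published percent contributions can depend
on the scaling variant.

## PLS and statistics

PLS1 by NIPALS with deflation; coefficients mapped back to descriptor
space via B = W(PᵀW)⁻¹q, so latent-path and coefficient-path predictions
agree to 1e−8 (tested). No per-column autoscaling (field units are kept,
CoMFA convention). Degrees of freedom for SEP/SEE are n − N − 1 (the
convention of the major commercial implementation), configurable to n − N.

Leave-one-out cross-validation refits the model for every left-out sample
(exact, no approximation; at n ≤ 100 this costs nothing — a SAMPLS-style
acceleration would change the runtime, not the statistic, and the CLI
accepts `--sampls` as a logged synonym). The component scan exploits the
nestedness of NIPALS components: one LOO pass at the deepest N yields the
held-out predictions of every smaller model, and a test asserts exact
agreement with component-by-component refitting.

Component selection defaults to argmax q² over the scan (this reproduces
the published CB1 choice N = 2 from its printed q² row). Two alternatives
exist because published model choices do not always follow any simple
rule: `("first_within", tol)` for plateau detection and
`("override", N)` to reproduce a run whose N was fixed by hand (the
published CB2 model, N = 10, requires the override — its printed q² rises
monotonically past 10 while SEP is minimal at 7, matching neither simple
rule).

External validation: PRESS and SD are sums over the test set (SD around
the *training* mean), r²_pred = (SD − PRESS)/SD. SD = 0 raises an error
rather than silently reporting 0.

Percent field contributions are block sums of |coefficient| × column
standard deviation in the fitted descriptor space, normalized to 100.
StDev\*Coeff contour values use the same per-column products scattered
back onto the lattice (masked columns exactly zero), so the sum of
absolute map values equals the contribution bookkeeping (tested).
Contour levels default to the 80th/20th percentiles of retained-column
values — the common display default; published figures rarely state their
levels, so levels are configurable per map.

## Synthetic ground truth

The generator emulates the study design of a scaffold-aligned series
without claiming any pharmacology:

* 92 molecules (default) sharing a rigid planar fused 6-5 bicyclic
  scaffold (9 heavy atoms, one ring nitrogen) at identical coordinates;
* three substitution regions with pseudo-substituents — element-typed
  groups of 1–6 atoms (H/F/Cl/Br/methyl/…/bulky 6-atom cluster) whose vdW
  parameters and PEOE charges are fully determined;
* activities = Σ weights × field values at `n_hotspots = 4` informative
  lattice columns (split between fields, spatially separated, column
  σ ≥ 2 kcal/mol so they survive the downstream filter), rescaled so the
  noiseless span is 4.0 log units (the dynamic range typical of a
  published binding series), centered at pKi 7, plus Gaussian noise of
  0.2 log units by default;
* randomly rotated/translated copies emitted alongside for alignment
  testing; hotspots, weights and noiseless activities recorded as truth.

What passing recovery tests shows: the field evaluation, descriptor
processing, PLS, CV machinery and contour bookkeeping are internally
consistent and can recover a known sparse field→activity mechanism under
realistic noise. What it does not show: anything about real conformational
flexibility, solvation, tautomers, or assay noise structure — the
generator's molecules are rigid and its noise is i.i.d. Gaussian.

## Numerical choices and degenerate inputs

* Interatomic distances floored at 1e−3 Å in the energy (1e−12 Å in field
  evaluation, where the ±cap truncation handles singularities); overlap
  below 1e−6 Å logs a warning.
* Column standard deviations use ddof = 1.
* NIPALS stops (and `fit_pls` raises, naming the achievable rank) when the
  residual covariance norm falls below 1e−12 relative to scale.
* Ties in argmax-q² resolve to the smallest N.
* Zero-variance y, empty molecule lists, all-masked descriptor blocks,
  sub-3-atom or collinear scaffold maps, and unknown elements/types all
  raise typed errors; nothing silently defaults.
* All stochastic stages (generator, annealing, splits) take explicit seeds
  and are reproducible; the pipeline embeds a configuration hash and seed
  in every artifact, and two runs with equal hashes are byte-identical.

## Problem sizes used in the test suite

Module tests run on toy systems (≤10 atoms, ≤20×20 matrices). Recovery
and localization guarantees run the full default study size (92 molecules,
~1200 lattice points, LOO at N up to 10) over 100 generator seeds —
roughly three minutes of compute — chosen as the smallest replication
count at which the ≥90/100 guarantees are meaningful.

## Known limitations

* No hydrophobic or hydrogen-bond fields (CoMSIA-style), no region
  focusing, no bootstrapping or progressive scrambling.
* The energy model cannot refine bond lengths/angles (by design); do not
  feed it distorted covalent geometry and expect repair.
* MOL2 support is read-only; SDF is the write format, with real-valued
  charges carried in an `ATOM_PARTIAL_CHARGES` property block because
  V2000 has no standard real-charge field.
* Aromaticity is taken from the input bond orders (order 4 = aromatic);
  there is no perception pass.
* The packaged vdW/PEOE parameter tables are small (common organic
  elements); unknown elements fail loudly and the tables are swappable by
  path.
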