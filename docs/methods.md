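# Methods

This note documents the models, numerical choices and limitations behind
`pkagrid`, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic test systems do and do not show.

## Electrostatic model

Protonation free energies are computed in a semi-continuum dielectric
picture.  The solute is a fixed-geometry point-charge model (PARSE-style
partial charges, Pauling-type van der Waals radii); the response of the
environment is carried entirely by a spatially varying static permittivity
ε(r) and, in solvent, by linearized Debye screening.  Three energy terms
enter each site's titration behaviour:

1. **Dielectric response (Born-type) term.**  The self-energy of the
   protonation charge difference Δq = q(protonated) − q(deprotonated),
   computed in the full protein/membrane environment minus the same
   quantity for the site's *model compound* — the residue rasterized alone
   in pure water on the identical grid.  The model-compound reference is
   the standard convention of multi-site titration packages: it makes a
   fully solvent-exposed residue's shift vanish by construction and
   cancels the grid self-energy of the spread charges exactly, because
   both runs share one grid placement, one charge spreading and one
   focusing protocol.
2. **Background term.**  The interaction of Δq with all permanent partial
   charges (every atom except the variable-charge atoms of all titratable
   sites).
3. **Pairwise couplings.**  W_ij = interaction of Δq_i with Δq_j through
   the heterogeneous dielectric, symmetrized as (W_ij + W_ji)/2; the
   asymmetry before averaging is a discretization diagnostic (≤ ~1%).

### Sign conventions

All energies are computed with the Δq (protonated-minus-deprotonated)
distribution, so acids and bases share one code path; the class-dependent
part is isolated in a single function with property tests.  The response
shift is +ΔΔG/1.364 for acids and −ΔΔG/1.364 for bases: burial
destabilizes the charged form, which for an acid is the deprotonated state
(pKa up) and for a base the protonated state (pKa down).  The background
shift is −ΔG_back/1.364 for both classes: a field that favours Δq favours
protonation and raises the pKa, whatever the acid/base class.  (A
convention that flips this sign for bases would make a field that
stabilizes a lysine's charged form *lower* its pKa, contradicting the
requirement that stabilizing the charged form keeps the site charged.)

## Permittivity map

* **Protein interior.**  Voxels inside the solvent-excluded surface are
  assigned one of four discrete layers, ε ∈ {3, 5, 10, 20}, the load-bearing
  part of the heterogeneous-dielectric treatment.  The driver is the local
  density of polar side-chain O and N atoms (backbone carbonyls and amides
  excluded), counted in a hard 5 Å kernel.  The density → ε curve is a
  pluggable monotone piecewise-linear map; the default breakpoints
  (0 → ε 2, 0.002 → 4, 0.005 → 7.5, 0.010 → 15, 0.020 atoms/Å³ → 25) put
  hydrophobic interiors in the ε-3 layer and densely polar solvated loops
  in the ε-20 layer.  Quantization picks the nearest layer with ties
  breaking upward (toward higher screening).
* **Solvent-excluded surface.**  A voxel belongs to the protein if it lies
  inside any atom sphere; the mask is then closed (dilation + erosion) with
  a 1.4 Å spherical probe footprint, which fills probe-inaccessible
  crevices at grid resolution, as DelPhi-style surfacing does.
* **Membrane.**  An implicit slab normal to z: an acyl core (default
  ε 2.0; 2.5 as a sensitivity variant) flanked by headgroup bands of 8 Å
  per leaflet (default ε 20; 40 as a variant, bracketing glycerol-like
  headgroup polarizabilities).  The slab claims only non-protein voxels.
* **Solvent.**  ε 81, ionic strength 0.05–0.2 M (default 0.2 M).  Mobile
  ions are excluded from a 2 Å Stern shell around all non-solvent regions.

## Poisson–Boltzmann solver

Linearized PBE, ∇·(ε∇φ) − εκ²φ = −4πρ, on a node-centred regular grid:
7-point stencil, harmonic-mean permittivity on cell faces, trilinear
spreading of point charges, screened-monopole Dirichlet boundary values on
the box faces, conjugate gradients with Jacobi preconditioning to a 1e-6
relative residual.  Boxes enclose the solute plus 10–17 Å margins
(default 15 Å).  Fine spacings are reached by two-level focusing: a coarse
solve supplies boundary values for a fine sub-box around the site; charges
outside the fine box act only through those boundary values.  Verified
accuracy on closed forms: ≤ 2% against Coulomb beyond four grid spacings
(node-aligned separations), ≤ 3% against the analytic Born sphere-transfer
energy at 0.25 Å focused spacing, and monotone Debye screening with ionic
strength.  The screened-monopole boundary condition reproduces the Debye
form e^(−κr)/εr to ~2–5% at coarse spacings.

Energy bookkeeping is in kcal/mol; potentials are stored in kT/e; pKa
units are kcal/mol divided by ln10·RT = 1.364 kcal/mol (298 K).

## Titration

Microstate energies (in pKa units) are
E(x, pH) = Σ x_i (pH − pKa_intr,i) + ½ ΣΣ W_ij δq_i δq_j, with δq the
deviation of the site charge from its charged reference state (acids
deprotonated, bases protonated) — consistent with W computed from
charge-difference distributions.  For a single site this is exactly
Henderson–Hasselbalch.

* **Exact enumeration** over all 2^N states (N ≤ 20) is the oracle.
* **Metropolis MC**: one attempted flip per site per scan, plus a joint
  flip per strongly coupled pair (|W| > 2 pKa units), vectorized across
  the pH grid.  Protonation fractions are accumulated with a
  Rao-Blackwellized estimator — the conditional protonation probability of
  each site given the others — which is exact for uncoupled sites and
  substantially reduces variance otherwise.  Errors are batch-mean
  standard errors over 10 batches.
* **Schedule.**  1 000 burn-in + 50 000 production scans per pH point.
  The production length was sized so that the sampling error of the
  extracted pKa stays below ~0.003 pH units on weakly coupled toy systems
  (most pairs < 0.1 pKa units, occasional pairs near 1), the regime of
  membrane-protein titration problems; strongly coupled toys (several
  pairs of 1–2 pKa units) mix more slowly and need longer runs.
* **pKa extraction** interpolates the 0.5 crossing linearly on the
  default 0.0–14.0, step-0.2 pH grid.  On exactly enumerated curves this
  introduces < 0.01 pH units of error (bounded by 0.03 in the acceptance
  checks); with several crossings the one nearest the site's intrinsic pKa
  is taken and flagged.

## Ensemble statistics

Per-frame ledgers over trajectory snapshots give each site's total shift
series: born + background + the pairwise contributions of pairs with
|W| ≥ 0.5 pKa units (weaker pairs contribute little and only add noise to
the fluctuation statistics; the full W always enters the titration model
itself).  A thresholded neighbour enters with its charged reference state
(weight −1 for acid neighbours, +1 for base neighbours).  The fluctuation
SD is the sample SD of that series; the ensemble pKa titrates the
frame-averaged components (configurable to per-frame titration followed by
averaging), with uncertainty SD/√N_eff where N_eff discounts the series
autocorrelation (initial-positive-sequence estimator).  A single frame
yields an undefined (NaN) uncertainty rather than an error.

## Parameter set

The bundled charge/radius table is a PARSE-style united-heavy-atom set:
hydrogen charges are folded into their bonded heavy atom, so hydrogen-free
structures carry exact integer formal charges (verified to 1e-6 e per
residue at assignment time); radii are Pauling-type values by element
(C 1.70, N 1.50, O 1.40, S 1.85 Å).  Titratable residues ship both
protonation variants with protonated-minus-deprotonated sums of exactly
+1 e.  Model pKas: Asp 4.0, Glu 4.4, Tyr 9.6, Lys 10.4, Arg 12.0, His 6.3,
Cys 8.3, N-terminus 7.5, C-terminus 3.8 — standard continuum-titration
baselines, overridable via a user table.

## Synthetic fixtures: what they show and what they do not

* **Born spheres / charge pairs** carry closed-form energies and validate
  the solver, not the biology.
* **Helix-in-slab peptides** are ideal α-helices (1.5 Å rise, 100°/residue)
  with rotamer-0-like side chains; geometry is deterministic.  They place
  titratable groups at controlled depths in core/headgroup/solvent regions
  but have none of a real protein's packing, hydrogen bonding or backbone
  relaxation.
* **Pseudo-trajectories** add iid Gaussian jitter per atom — no bonds, no
  physics.  They exercise the fluctuation ledger (SDs scale linearly with
  jitter, means stay unbiased) and nothing more; conclusions about real MD
  ensembles require real snapshots.
* **Toy coding sequences** are reverse-translated from a fixed codon table
  to match a requested residue census exactly.  The bundled PsbS-like CDS
  is synthetic: it reproduces the published census figures (756 nt; 41-aa
  transit peptide with 5 Arg/1 Lys/1 His; 210-aa mature protein with 9 Arg,
  12 Lys, 4 Tyr, 10 Glu, 7 Asp and no His/Cys) but not the real nucleotide
  or amino-acid sequence.

Test problem sizes (short helices, ~30–45 Å boxes at 1.0 Å coarse /
0.25–0.5 Å focused spacing, ≤ 12 trajectory frames, 10–12-site titration
toys) were chosen so the full suite runs on a laptop-class single core in
a couple of minutes while still exercising every stage at meaningful
accuracy.

## Known limitations

* Linearized PBE only; no nonlinear salt response.
* Fixed protonation geometry: no conformational relaxation between
  protonation states, no tautomers.
* The density → ε calibration is a package default, not a fitted law; the
  four-level quantization is the structural assumption, the breakpoints are
  adjustable.
* Proton-binding kinetics are out of scope; fluctuation SDs quantify
  structural variability of the energetics, not rate processes.
* The ideal-helix generator is for testing, not structure prediction.
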