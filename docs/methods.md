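# Methods

This note documents the models, numerical choices and limitations of the
fluorff pipeline in one place. Units throughout: kJ/mol, Angstrom, radians
internally (degrees at public torsion interfaces), amu, Kelvin;
k_C = 1389.3546 kJ·mol⁻¹·Å·e⁻², k_B = 8.3144621×10⁻³ kJ·mol⁻¹·K⁻¹. The
internal time unit is √(amu·Å²/(kJ/mol)) = 100 fs exactly, so a 1 fs leapfrog
step is 0.01 internal units.

## Force-field model

The potential is the standard class-I form: harmonic bonds and angles, a
cosine series per torsion in the AMBER convention
(V_n/2)(1 + cos(nφ − γ_n)), and pairwise 12-6 Lennard-Jones plus Coulomb
terms over all intramolecular pairs except 1-2/1-3 (excluded) and 1-4
(scaled by 0.5 for LJ and 1/1.2 for Coulomb, the AMBER defaults).
Lennard-Jones cross terms use Lorentz–Berthelot combination. No cutoffs are
applied: the target systems are single gas-phase molecules of ≤ ~30 atoms.
Parameters are stored per topological term (per bond, per angle, per
torsion quadruple), not per atom type; exclusions and 1-4 pairs are derived
from the bond list alone.

Torsion sign follows the right-hand IUPAC convention about the 2-3 axis,
with range [−180°, 180°) and −180° canonical for the anti boundary. Forces
are fully analytic (including the torsion term, via the standard
cross-product gradient expressions) and are validated against central
finite differences (h = 10⁻⁵ Å, relative tolerance 10⁻⁴) in the test suite.
Minimization uses SciPy's L-BFGS-B with the analytic gradient; convergence
is declared on the force max-norm, and a non-converged run returns the
best-so-far geometry with a warning rather than failing.

## RESP charge derivation

Charges minimize ‖Aq − b‖² + a·Σ_varying(√(q_j² + w²) − w) subject to an
exact total-charge constraint and within-group equality constraints, where
A[m,i] = k_C/|r_m − x_i| stacks all conformations (the multiconformational
fit is a single stacked least-squares system). The hyperbolic restraint
width is w = 0.1 e. The objective is taken literally in these units — the
design matrix carries the Coulomb prefactor — so the conventional stage
scales a = 0.01 (stage 1, all atoms free, no equivalences) and a = 0.001
(stage 2, only symmetry-equivalent atoms free and tied, all others frozen
at stage-1 values) leave a well-determined fit essentially unbiased while
still regularizing genuinely underdetermined directions at large a. The
solver is iteratively reweighted least squares on the KKT system of the
constrained normal equations (diagonal weight a/(2√(q² + w²)) per varying
charge), converged when max|Δq| < 10⁻⁶ e, at most 200 iterations. Stage 2
is skipped with a logged notice when no symmetry groups are declared.

## Hybrid and nested MC-MC sampling

Hybrid MC resamples all momenta from the Maxwell distribution at T each
move, integrates n leapfrog steps (velocity Verlet, kick-drift-kick), and
accepts with min(1, exp(−ΔH/k_B T)); the integrator is symplectic and
time-reversible (round-trip error < 10⁻⁸ checked in tests). Defaults mirror
the study design: 100 leapfrog steps of 1 fs, inner chain at 350 K, target
ensemble at 300 K, 2.5×10⁴ sweeps.

The nested sampler runs the inner hybrid-MC chain on the cheap potential at
T_low and, every `switch_period` moves, proposes the inner state x′ against
the last accepted high-level state x with acceptance

  min{1, exp(−[U_high(x′) − U_high(x)]/k_B·T_target
            + [U_low(x′) − U_low(x)]/k_B·T_low)}.

On rejection the inner chain resets to x. This two-temperature criterion
reduces to the textbook nested MC-MC rule at equal temperatures. The
high-level ensemble records the retained state at every switch attempt —
repeating the previous state on rejection — because recording only accepted
states would bias ensemble moments; with this convention the outer chain is
a valid Metropolis chain whose invariant distribution is the high-level
Boltzmann distribution at T_target, verified in the tests against direct
Metropolis sampling (total-variation distance < 0.05 on a double well) and
against closed-form harmonic moments using batch-means Monte Carlo standard
errors. Both acceptance fractions are reported as diagnostics: the hybrid-MC
acceptance measures short-trajectory energy conservation, the switch
acceptance the similarity of the two potentials.

## Bonded-parameter reoptimization

The objective is X_U + Θ with

  X_U = Σ_i ω_i (U_i^ref − U_i^MM − Δ̄)² / Var(U^ref),
  Θ   = α Σ_m (p_m − p_m⁰)² / γ_m²,

where Δ̄ is the ω-weighted mean residual (making X_U invariant to constant
shifts of either energy column), Var(U^ref) the unweighted population
variance of the reference energies, ω_i uniform by default (the weights
field is pluggable), and α = 1/N_p unless overridden. Only bonded
parameters are optimized — bond K_b and r_eq, angle K_θ and θ_eq, torsion
barrier heights V_n, and torsion phases γ_n only when phase optimization is
explicitly enabled (phases leaving {0, π} break the energy equivalence of
mirror-image conformers and trigger a warning). Lennard-Jones parameters
and charges are never touched.

Default prior widths: γ = 0.2·K + 50 kJ·mol⁻¹·Å⁻² for bond force constants,
0.05 Å for r_eq, 0.2·K + 20 kJ·mol⁻¹·rad⁻² for angle force constants,
0.1 rad for θ_eq, 0.5·V + 2 kJ/mol for barrier heights, π for phases.
Relative widths on force constants make a fixed fractional change cost the
same penalty across stiff and soft terms; the width function is a
parameter, so studies that want no prior (α = 0) still benefit from the
widths as natural optimizer scaling.

Optimization is quasi-Newton (L-BFGS-B) over width-scaled deviations from
the prior, with numerical gradients, force constants bounded below by zero,
and a relative objective tolerance of 10⁻⁸. Because only bonded parameters
move, internal coordinates (bond lengths, angles, torsions) and the
nonbonded energy of every training conformation are cached once, making an
objective evaluation a handful of vectorized array operations.

A practical conditioning point: X_U is normalized by Var(U^ref), so a few
steric-clash frames with energies thousands of kJ/mol above the minimum
flatten the objective and destroy parameter identifiability. Ensembles
drawn from a thermal sampler do not contain such frames; synthetic training
sets built from random torsions are therefore filtered to an energy window
(150 kJ/mol above the minimum in the recovery studies) before fitting.

## Conformer analysis

Rotamer labels use the half-open intervals [0°, 120°) → g+,
[120°, 240°) → t, [−120°, 0°) → g−, with any finite angle wrapped to
[−120°, 240°) first (so 240° and −120° both label g−). Conformer keys
string the role-torsion labels: χφ(ψ) for monofluoro species, χφ₁φ₂(ψ) for
difluoro species with the two φ labels in lexicographic order (the two
printed orderings are equivalent, so symmetric assignments merge under this
canonical form), and χ(ψ) for trifluoro species. Trajectory populations are
plain frame frequencies over these keys; Boltzmann populations are softmax
weights of relative Gibbs free energies at the table's temperature.
Intramolecular hydrogen bonds are flagged geometrically: donor-H to
acceptor distance < 2.5 Å in a representative (minimized) geometry, the
threshold being configurable since no standard value exists.

## Agreement metrics

ΔΔE measures each structure's model-vs-reference relative energy from the
reference-minimum structure, so global offsets in either column cancel; the
reference structure itself is excluded from summaries. Distribution
summaries report RMSE about zero and the mean. SAEP is the L1 distance
between population tables over the union of keys (missing keys read as 0),
bounded by [0, 2]. Superposition RMSD removes centroids and solves for the
optimal proper rotation by SVD of the covariance matrix with the
determinant sign correction, so mirror images are not superimposable —
physical chirality is preserved. Outlier filtering drops structure pairs
with RMSD above 0.3 Å by default and reports the count.

## J-coupling statistics

Ensemble-averaged couplings are ⟨J⟩ = Σ_i p_i J_i over conformer
populations. Agreement with experiment uses RMSE and squared Pearson
correlation. Experimental signs of through-hydrogen-bond OH···F couplings
are typically undetermined, so experiment-facing comparisons are made
magnitude against magnitude whenever any record's sign is unknown; this
convention reproduces the packaged dataset's printed summary rows exactly.
Comparisons between two computed columns (both signs known) are signed. A
comparison column with zero variance yields RMSE with an undefined-R²
warning (NaN) rather than an exception.

## Synthetic data

The generators provide ground truth for every stage and are pure functions
of their seeds:

- **Toy molecules**: a 4–8 carbon backbone; the "mono" pattern adds OH on
  C0, F on C2 and a symmetric H pair on C1, giving the three role torsions
  (χ = H-O-C0-C1, φ = O-C0-C1-C2, ψ = F-C2-C1-C0) and a symmetry group for
  the two-stage charge fit; the "chain" pattern is a bare carbon chain for
  parameter-recovery studies. Geometries are built by internal-coordinate
  placement (tetrahedral angles, staggered torsions); parameters are
  generic but realistic in magnitude (C–C K_b = 1100 kJ·mol⁻¹·Å⁻², angle
  K_θ ≈ 220–320 kJ·mol⁻¹·rad⁻², threefold torsions of 0.7–4 kJ/mol).
- **Surrogate reference potential**: the base force field with per-term
  force constants scaled by 1 + s·U(−1,1) (default s = 0.15) plus a cubic
  bond correction c₃·Σ(r − r_eq)³ (default c₃ = −150 kJ·mol⁻¹·Å⁻³). The
  cubic term cannot be represented by the class-I functional form, so
  refitting against this surrogate faces a genuine model-form gap: the
  fitted energy term plateaus above zero while still improving on the base
  parameters, giving a qualitative analogue of a retuned force field
  outperforming its parent without reaching the reference's accuracy.
- **Mixture trajectories**: each frame draws a conformer key from given
  weights and each role torsion from a von Mises distribution centered on
  that rotamer's well (60°, 180°, −60°) with concentration κ = 50, at which
  the wells overlap far below 1%, so realized key frequencies converge to
  the requested weights at the binomial rate.
- **ESP grids**: points sampled on shells at 1.4–2.0× the van der Waals
  radius around random atoms, rejecting points inside any atom's inner
  shell (and within 1 Å of any atom); values are the exact point-charge
  potential.

What the synthetic data does not emulate: real charge distributions are not
point charges (fitted charges absorb multipole effects), real reference
potentials differ from a force field in ways richer than smooth force
constant scaling plus a cubic term, and rotamer wells of real molecules are
skewed and coupled across torsions. Passing tests therefore demonstrate the
correctness of the machinery — estimators converge to known ground truth,
samplers target the right distributions, optimizers recover generating
parameters — not the chemical accuracy of any particular force field.

## Problem sizes and runtime

The default benchmark configuration scales the study design down by roughly
an order of magnitude — 2.5×10³ nested-MC-MC sweeps with 15-step inner
trajectories, 500/1500 train/test structures, 10⁵-frame population
trajectories only where binomial precision is needed — so a full pipeline
run completes in a few minutes on one CPU while every stage retains
statistical headroom. All sizes are configuration fields.

## Known limitations

- No periodic boundary conditions, Ewald summation, solvent boxes,
  thermostats or barostats: condensed-phase simulation is out of scope.
- Per-term (not per-atom-type) parameters mean no parameter sharing across
  chemically equivalent terms during refitting beyond what the priors
  impose.
- The reparametrization gradient is numerical; for much larger parameter
  sets an analytic Jacobian of the bonded terms would be the next step.
- Population tables are discrete over rotamer keys; continuous torsional
  heterogeneity within a well is not represented.
- The geometry builder covers mono-substituted and bare-chain patterns;
  di/tri-fluoro conformer keys are supported by the labelling and
  population machinery but no di/tri geometry generator ships.
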