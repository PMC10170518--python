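# fluorff

Force-field benchmarking and tuning machinery for conformational analysis of
small fluorinated molecules (γ-fluorohydrins and toy analogues).

Acyclic molecules carrying an OH and an F three bonds apart populate several
rotamer wells — labelled g+/t/g− per threefold torsion — whose relative
populations are set by a delicate balance of intramolecular hydrogen bonding
and sterics. Benchmarking a molecular model against a reference level of
theory for such systems requires a whole pipeline, which this package
implements as reusable, tested components:

- **Class-I force-field energetics** (`fluorff.forcefield`): harmonic bonds
  `Σ K_b (r − r_eq)²` and angles `Σ K_θ (θ − θ_eq)²`, cosine-series torsions
  `Σ (V_n/2)(1 + cos(nφ − γ_n))`, 12-6 Lennard-Jones and Coulomb terms with
  1-2/1-3 exclusions and scaled 1-4 interactions; analytic forces and L-BFGS
  minimization.
- **Two-stage RESP charge fitting** (`fluorff.resp`): restrained least-squares
  charges against ESP grids with hyperbolic regularization, exact total-charge
  and symmetry-equivalence constraints.
- **Hybrid and nested Markov chain Monte Carlo** (`fluorff.sampling`): an
  inner hybrid-MC chain on a cheap potential proposes states to an outer
  Metropolis test on an expensive target potential, recovering the target
  Boltzmann ensemble while paying for the expensive potential only at switch
  attempts.
- **Regularized bonded-parameter reoptimization** (`fluorff.reparam`):
  minimize `X_U + Θ` where `X_U = Σ_i ω_i (U_i^ref − U_i^MM − Δ̄)² / Var(U^ref)`
  is the mean-shifted, variance-normalized energy residual and
  `Θ = α Σ_m (p_m − p_m⁰)²/γ_m²` a Gaussian-prior penalty (α = 1/N_p by
  default).
- **Rotamer/conformer analysis** (`fluorff.conformers`): g+/t/g− labelling by
  half-open 120° intervals, conformer keys (χφ(ψ) and variants), trajectory
  clustering, and Boltzmann populations `p_i ∝ exp(−ΔG_i/RT)`.
- **Agreement metrics** (`fluorff.metrics`): relative-energy differences
  ΔΔE = (E_i^X − E_0^X) − (E_i^ref − E_0^ref), RMSE/mean summaries, the sum
  of absolute population errors (SAEP ∈ [0, 2]), and Kabsch superposition
  RMSD with reflections excluded.
- **Population-weighted NMR J-couplings** (`fluorff.jcoupling`):
  `⟨J⟩ = Σ_i p_i J_i` plus RMSE/R² agreement statistics and a packaged
  13-coupling experimental/computed reference dataset for ten
  γ-fluorohydrins in chloroform.
- **Synthetic ground truth** (`fluorff.synthetic`): toy molecules with full
  parameter coverage, surrogate "reference" potentials (smoothly perturbed
  force fields with a non-representable cubic bond term), von Mises mixture
  trajectories with known rotamer weights, and exact point-charge ESP grids —
  so every stage is testable end to end without quantum-chemistry engines.

## Worked example

```python
import numpy as np
from fluorff import MCSettings, nmcmc_run
from fluorff.sampling import make_ff_potential, masses_for
from fluorff.synthetic import (ToyMoleculeSpec, SurrogateReferenceSpec,
                               make_toy_molecule, make_surrogate_reference)

topo, params, conf = make_toy_molecule(ToyMoleculeSpec(n_heavy=4))
reference, _ = make_surrogate_reference(
    SurrogateReferenceSpec(base=params, perturbation_scale=0.15, seed=0), topo)

settings = MCSettings(T_low=350.0, T_target=300.0, n_leapfrog=15, sweeps=2000, seed=0)
report = nmcmc_run(make_ff_potential(topo, params), reference,
                   settings, conf.coords, masses_for(topo))
print(f"hMC acceptance    {report.hmc_acceptance:.3f}")
print(f"switch acceptance {report.switch_acceptance:.3f}")
```

prints

```
hMC acceptance    0.941
switch acceptance 0.789
```

i.e. the short inner MD trajectories conserve energy well enough for ~94% of
hybrid-MC moves to be accepted at 350 K, and ~79% of the inner-chain states
are promoted into the 300 K ensemble of the perturbed reference potential —
the two diagnostics that tell you the cheap potential is a good proposal
distribution for the expensive one.

The same pipeline is available from the shell:

```bash
fluorff benchmark --outdir out --seed 0      # full synthetic benchmark
fluorff jcoupling                            # reference-dataset statistics
fluorff synth --outdir fixtures              # emit toy fixtures
```

`fluorff benchmark` chains all stages — surrogate reference, nested MC-MC
ensemble, train/test split, bonded reparametrization, ΔΔE distributions,
rotamer populations and SAEP, J-coupling statistics — and writes CSV tables
plus a manifest with every seed and setting.

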