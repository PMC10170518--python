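"""Regularized reoptimization of bonded force-field parameters.

Bond, angle and dihedral parameters are tuned to reproduce a training set of
reference ("high-level") conformational energies by minimizing

    L(p) = X_U(p) + Theta(p)

where ``X_U`` is the variance-normalized, mean-shifted weighted squared
energy residual and ``Theta`` a harmonic (Gaussian-prior) penalty that keeps
each parameter near its initial value.  Nonbonded parameters (Lennard-Jones
and charges) are never touched.

Because only bonded parameters move, the internal coordinates and the
nonbonded energy of every training conformation are precomputed once, which
makes each objective evaluation a handful of vectorized array operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .forcefield import (
    FFParameters,
    batch_angles,
    batch_bond_lengths,
    batch_dihedrals,
    compute_energy,
)
from .topology import Conformation, MoleculeTopology

__all__ = [
    "TrainingSet",
    "ParamVector",
    "BondedEnergyModel",
    "energy_term_XU",
    "regularization_theta",
    "total_objective",
    "optimize_parameters",
    "split_train_test",
    "default_prior_widths",
]


@dataclass
class TrainingSet:
    """Conformations with reference energies and normalized weights."""

    conformations: list[Conformation]
    ref_energies: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ref_energies = np.asarray(self.ref_energies, dtype=float).ravel()
        if len(self.conformations) != len(self.ref_energies):
            raise ValueError("conformations and reference energies length mismatch")
        n = len(self.ref_energies)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if len(self.weights) != n:
                raise ValueError("weights length mismatch")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            s = self.weights.sum()
            if not np.isclose(s, 1.0):
                self.weights = self.weights / s

    @property
    def coords(self) -> np.ndarray:
        return np.stack([c.coords for c in self.conformations])

    def __len__(self) -> int:
        return len(self.ref_energies)


# ---------------------------------------------------------------------------
# Parameter flattening
# ---------------------------------------------------------------------------

_KIND_BOND_K = "bond_K"
_KIND_BOND_R = "bond_r_eq"
_KIND_ANGLE_K = "angle_K"
_KIND_ANGLE_T = "angle_theta_eq"
_KIND_DIH_V = "dihedral_V"
_KIND_DIH_G = "dihedral_gamma"


def default_prior_widths(kind: str, p0: float) -> float:
    """Prior width (Gaussian sigma) per parameter class.

    Force-constant widths scale with the initial value so that a fixed
    relative change costs the same penalty across stiff and soft terms;
    equilibrium values get absolute widths in their natural units.
    """
    if kind == _KIND_BOND_K:
        return 0.2 * abs(p0) + 50.0  # kJ/mol/A^2
    if kind == _KIND_BOND_R:
        return 0.05  # A
    if kind == _KIND_ANGLE_K:
        return 0.2 * abs(p0) + 20.0  # kJ/mol/rad^2
    if kind == _KIND_ANGLE_T:
        return 0.1  # rad
    if kind == _KIND_DIH_V:
        return 0.5 * abs(p0) + 2.0  # kJ/mol
    if kind == _KIND_DIH_G:
        return np.pi  # rad
    raise KeyError(kind)


@dataclass
class ParamVector:
    """Flat view of the bonded parameters with priors, widths and a mask."""

    values: np.ndarray
    priors: np.ndarray
    widths: np.ndarray
    mask: np.ndarray
    kinds: list[str]
    labels: list[str]
    alpha: Optional[float] = None  # None -> 1 / N_p

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.priors) == len(self.widths) == len(self.mask) == len(self.kinds) == n):
            raise ValueError("inconsistent vector lengths")
        if np.any(self.widths <= 0):
            raise ValueError("prior widths must be positive")

    @property
    def n_optimizable(self) -> int:
        return int(np.count_nonzero(self.mask))

    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 1.0 / max(self.n_optimizable, 1)


def flatten_bonded(
    params: FFParameters,
    optimize_phases: bool = False,
    alpha: Optional[float] = None,
    width_fn=default_prior_widths,
) -> ParamVector:
    """Flatten bond/angle/dihedral parameters into a :class:`ParamVector`.

    The mask marks bond force constants and equilibrium lengths, angle force
    constants and equilibrium angles, and dihedral barrier heights as
    optimizable; dihedral phases only when ``optimize_phases`` is set.
    """
    vals: list[float] = []
    kinds: list[str] = []
    labels: list[str] = []
    mask: list[bool] = []
    for key in sorted(params.bond):
        kb, req = params.bond[key]
        vals += [kb, req]
        kinds += [_KIND_BOND_K, _KIND_BOND_R]
        labels += [f"bond{key}.K", f"bond{key}.r_eq"]
        mask += [True, True]
    for key in sorted(params.angle):
        kt, teq = params.angle[key]
        vals += [kt, teq]
        kinds += [_KIND_ANGLE_K, _KIND_ANGLE_T]
        labels += [f"angle{key}.K", f"angle{key}.theta_eq"]
        mask += [True, True]
    for key in sorted(params.dihedral):
        for t, (v, n, gam) in enumerate(params.dihedral[key]):
            vals += [v, gam]
            kinds += [_KIND_DIH_V, _KIND_DIH_G]
            labels += [f"dihedral{key}[{t}].V", f"dihedral{key}[{t}].gamma"]
            mask += [True, optimize_phases]
    values = np.asarray(vals)
    widths = np.array([width_fn(k, p) for k, p in zip(kinds, values)])
    return ParamVector(
        values=values,
        priors=values.copy(),
        widths=widths,
        mask=np.asarray(mask, dtype=bool),
        kinds=kinds,
        labels=labels,
        alpha=alpha,
    )


def unflatten_bonded(params: FFParameters, values: np.ndarray) -> FFParameters:
    """Write a flat bonded-parameter vector back into a parameter copy."""
    out = params.copy()
    it = iter(values)
    for key in sorted(out.bond):
        out.bond[key] = (next(it), next(it))
    for key in sorted(out.angle):
        out.angle[key] = (next(it), next(it))
    for key in sorted(out.dihedral):
        terms = []
        for (_, n, _) in out.dihedral[key]:
            v, gam = next(it), next(it)
            terms.append((v, int(n), gam))
        out.dihedral[key] = terms
    return out


# ---------------------------------------------------------------------------
# Fast cached bonded energy model
# ---------------------------------------------------------------------------


class BondedEnergyModel:
    """Model energies of a fixed conformation set as a function of bonded
    parameters, with internal coordinates and nonbonded energy cached."""

    def __init__(self, topo: MoleculeTopology, params: FFParameters, training: TrainingSet):
        self.topo = topo
        coords = training.coords
        self.r = (
            batch_bond_lengths(coords, np.asarray(topo.bonds)) if topo.bonds else np.zeros((len(training), 0))
        )
        self.th = (
            batch_angles(coords, np.asarray(topo.angles)) if topo.angles else np.zeros((len(training), 0))
        )
        self.phi = (
            batch_dihedrals(coords, np.asarray(topo.dihedral_quads))
            if topo.dihedral_quads
            else np.zeros((len(training), 0))
        )
        # nonbonded energy never changes during bonded optimization
        nb_params = params.copy()
        nb_params.bond = {k: (0.0, v[1]) for k, v in nb_params.bond.items()}
        nb_params.angle = {k: (0.0, v[1]) for k, v in nb_params.angle.items()}
        nb_params.dihedral = {k: [(0.0, n, g) for (_, n, g) in v] for k, v in nb_params.dihedral.items()}
        self.e_nonbonded = np.array(
            [compute_energy(c, topo, nb_params).total for c in training.conformations]
        )
        self._dih_term_index = [
            (qi, len(params.dihedral[key]))
            for qi, key in enumerate(sorted(params.dihedral))
        ]

    def energies(self, params: FFParameters) -> np.ndarray:
        """Total model energy of every cached conformation."""
        e = self.e_nonbonded.copy()
        if self.r.shape[1]:
            kb, req = np.array([params.bond[k] for k in sorted(params.bond)]).T
            e += np.sum(kb * (self.r - req) ** 2, axis=1)
        if self.th.shape[1]:
            kt, teq = np.array([params.angle[k] for k in sorted(params.angle)]).T
            e += np.sum(kt * (self.th - teq) ** 2, axis=1)
        if self.phi.shape[1]:
            for qi, key in enumerate(sorted(params.dihedral)):
                for v, n, gam in params.dihedral[key]:
                    e += 0.5 * v * (1.0 + np.cos(n * self.phi[:, qi] - gam))
        return e


# ---------------------------------------------------------------------------
# Objective terms
# ---------------------------------------------------------------------------


def _xu_from_energies(u_ref: np.ndarray, u_mm: np.ndarray, weights: np.ndarray) -> float:
    var = float(np.var(u_ref))
    if var <= 0:
        raise ValueError("reference energies have zero variance; X_U is undefined")
    diff = u_ref - u_mm
    mean_shift = float(np.sum(weights * diff))
    return float(np.sum(weights * (diff - mean_shift) ** 2) / var)


def energy_term_XU(
    params: FFParameters,
    topo: MoleculeTopology,
    training: TrainingSet,
    model: Optional[BondedEnergyModel] = None,
) -> float:
    """Dimensionless energy-fitting term.

    ``X_U = sum_i w_i (U_i^ref - U_i^MM - dbar)^2 / Var(U^ref)`` with
    ``dbar`` the weighted mean residual (which makes X_U invariant to a
    constant shift of either energy column) and ``Var`` the unweighted
    population variance of the reference energies.
    """
    model = model if model is not None else BondedEnergyModel(topo, params, training)
    return _xu_from_energies(training.ref_energies, model.energies(params), training.weights)


def regularization_theta(p: ParamVector) -> float:
    """Harmonic prior penalty over the optimizable entries:
    ``Theta = alpha * sum_m (p_m - p_m0)^2 / gamma_m^2``."""
    m = p.mask
    dev = (p.values[m] - p.priors[m]) / p.widths[m]
    return float(p.effective_alpha() * np.sum(dev * dev))


def total_objective(
    params: FFParameters,
    topo: MoleculeTopology,
    training: TrainingSet,
    p: ParamVector,
    model: Optional[BondedEnergyModel] = None,
) -> float:
    """Objective minimized during reparametrization: ``X_U + Theta``."""
    return energy_term_XU(params, topo, training, model) + regularization_theta(p)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


def optimize_parameters(
    initial: FFParameters,
    topo: MoleculeTopology,
    training: TrainingSet,
    optimize_phases: bool = False,
    alpha: Optional[float] = None,
    width_fn=default_prior_widths,
    max_iter: int = 500,
) -> tuple[FFParameters, dict]:
    """Tune bonded parameters by local minimization of ``X_U + Theta``.

    Optimizes in prior-width units (each optimizable entry scaled by its
    width) with L-BFGS-B and numerical gradients; force constants are
    bounded below by zero.  When ``optimize_phases`` is false the dihedral
    phases are untouched; when true they are wrapped to [0, 2 pi) and a
    warning is emitted for phases away from {0, pi}, which break the
    energy equivalence of mirror-image conformers.

    Returns the tuned parameters and a trace dict with the initial/final
    objective and the optimizer status.
    """
    if len(training) == 0:
        raise ValueError("training set is empty")
    pvec = flatten_bonded(initial, optimize_phases=optimize_phases, alpha=alpha, width_fn=width_fn)
    model = BondedEnergyModel(topo, initial, training)
    midx = np.flatnonzero(pvec.mask)
    x0 = np.zeros(len(midx))  # scaled deviation from prior

    lower = np.full(len(midx), -np.inf)
    for pos, gi in enumerate(midx):
        kind = pvec.kinds[gi]
        if kind in (_KIND_BOND_K, _KIND_ANGLE_K):
            lower[pos] = -pvec.priors[gi] / pvec.widths[gi]  # K >= 0
        elif kind == _KIND_BOND_R:
            lower[pos] = (0.3 - pvec.priors[gi]) / pvec.widths[gi]  # r_eq > 0.3 A

    def assemble(x: np.ndarray) -> np.ndarray:
        vals = pvec.values.copy()
        vals[midx] = pvec.priors[midx] + x * pvec.widths[midx]
        return vals

    alpha_eff = pvec.effective_alpha()

    def fun(x: np.ndarray) -> float:
        vals = assemble(x)
        trial = unflatten_bonded(initial, vals)
        u_mm = model.energies(trial)
        xu = _xu_from_energies(training.ref_energies, u_mm, training.weights)
        theta = alpha_eff * float(np.sum(x * x))
        obj = xu + theta
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite objective during optimization")
        return obj

    obj0 = fun(x0)
    res = _scipy_minimize(
        fun,
        x0,
        method="L-BFGS-B",
        bounds=list(zip(lower, np.full(len(midx), np.inf))),
        options={"maxiter": max_iter, "ftol": 1e-8 * max(obj0, 1e-30), "gtol": 1e-10},
    )
    x_best = res.x if res.fun <= obj0 else x0
    if not res.success and res.fun > obj0:
        warnings.warn(f"parameter optimization did not converge: {res.message}", RuntimeWarning)
    final_vals = assemble(x_best)

    if optimize_phases:
        for gi in midx:
            if pvec.kinds[gi] == _KIND_DIH_G:
                final_vals[gi] = np.mod(final_vals[gi], 2.0 * np.pi)
                if min(
                    abs(final_vals[gi]), abs(final_vals[gi] - np.pi), abs(final_vals[gi] - 2 * np.pi)
                ) > 1e-3:
                    warnings.warn(
                        f"optimized phase {pvec.labels[gi]} = {np.degrees(final_vals[gi]):.1f} deg "
                        "leaves {0, 180}; conformational mirror symmetry is broken",
                        RuntimeWarning,
                    )

    tuned = unflatten_bonded(initial, final_vals)
    trace = {
        "initial_objective": obj0,
        "final_objective": float(min(res.fun, obj0)),
        "n_iterations": int(res.nit),
        "converged": bool(res.success),
        "n_optimizable": pvec.n_optimizable,
        "alpha": alpha_eff,
    }
    return tuned, trace


def split_train_test(
    ensemble: Sequence[Conformation],
    energies: Sequence[float],
    n_train: int,
    n_test: int,
    seed: int = 0,
) -> tuple[TrainingSet, TrainingSet]:
    """Disjoint uniform random train/test subsets, deterministic per seed."""
    energies = np.asarray(energies, dtype=float)
    if n_train + n_test > len(ensemble):
        raise ValueError(
            f"requested {n_train}+{n_test} structures from an ensemble of {len(ensemble)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ensemble))
    tr = perm[:n_train]
    te = perm[n_train : n_train + n_test]
    return (
        TrainingSet([ensemble[i] for i in tr], energies[tr]),
        TrainingSet([ensemble[i] for i in te], energies[te]),
    )
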