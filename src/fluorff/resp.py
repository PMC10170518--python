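"""Two-stage restrained electrostatic-potential (RESP) charge fitting.

Atomic partial charges are fit to reproduce an electrostatic potential
sampled on grids around one or more conformations, with a hyperbolic
restraint pulling charges toward zero, an exact total-charge constraint, and
optional equality constraints within symmetry groups.  Stage 1 fits all
atoms freely (restraint scale 0.01); stage 2 refits only the symmetry
equivalent atoms (scale 0.001), with equality enforced within each group and
all other atoms frozen at their stage-1 values.

The restrained problem is minimized exactly as written, ``|A q - b|^2 +
a * sum_j (sqrt(q_j^2 + w^2) - w)``, with the design matrix carrying the
Coulomb prefactor; the restraint scale ``a`` therefore acts on the same
scale as the squared-potential residual, and the conventional stage scales
(0.01 and 0.001) leave a well-determined fit essentially unbiased.  The
solver is iteratively reweighted least squares on the Karush-Kuhn-Tucker
system of the charge-constrained normal equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import COULOMB_CONSTANT
from .forcefield import SingularityError
from .topology import Conformation, MoleculeTopology

__all__ = ["ESPGrid", "RespStageSpec", "build_esp_system", "resp_stage", "two_stage_resp"]

logger = logging.getLogger(__name__)

#: width of the hyperbolic restraint well, elementary charges
DEFAULT_RESTRAINT_WIDTH = 0.1


@dataclass
class ESPGrid:
    """Electrostatic potential sampled at off-molecule grid points.

    ``points`` are M x 3 Cartesian positions (Angstrom); ``values`` the
    potential at each point in kJ/mol per elementary charge.
    """

    points: np.ndarray
    values: np.ndarray
    conformation_ref: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.points) != len(self.values):
            raise ValueError("points and values length mismatch")


@dataclass
class RespStageSpec:
    """Settings of one restrained-fit stage."""

    restraint_scale: float = 0.01
    restraint_width: float = DEFAULT_RESTRAINT_WIDTH
    frozen_charges: dict[int, float] = field(default_factory=dict)
    equivalence_groups: list[frozenset[int]] = field(default_factory=list)
    total_charge: float = 0.0

    def __post_init__(self) -> None:
        if self.restraint_scale < 0:
            raise ValueError("restraint scale must be >= 0")
        groups = [frozenset(g) for g in self.equivalence_groups]
        seen: set[int] = set()
        for g in groups:
            if g & seen:
                raise ValueError("equivalence groups must be disjoint")
            if g & self.frozen_charges.keys():
                raise ValueError("frozen atoms cannot appear in equivalence groups")
            seen |= g
        self.equivalence_groups = groups


def build_esp_system(
    grids: Sequence[ESPGrid], confs: Sequence[Conformation]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the multiconformational least-squares system.

    Returns ``(A, b)`` with ``A[m, i] = k_C / |r_m - x_i|`` so that ``A @ q``
    is the point-charge potential in kJ/mol/e at every grid point of every
    conformation.
    """
    if len(grids) != len(confs):
        raise ValueError("need exactly one ESP grid per conformation")
    blocks, targets = [], []
    for grid, conf in zip(grids, confs):
        d = np.linalg.norm(grid.points[:, None, :] - conf.coords[None, :, :], axis=2)
        if np.any(d < 1e-6):
            raise SingularityError("ESP grid point coincides with an atom")
        blocks.append(COULOMB_CONSTANT / d)
        targets.append(grid.values)
    return np.vstack(blocks), np.concatenate(targets)


def _reduction(n_atoms: int, spec: RespStageSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map free variables u to charges: q = S @ u + f (frozen offsets)."""
    frozen = spec.frozen_charges
    grouped = {a: gi for gi, g in enumerate(spec.equivalence_groups) for a in g}
    cols: dict[object, int] = {}
    for a in range(n_atoms):
        if a in frozen:
            continue
        key = ("g", grouped[a]) if a in grouped else ("a", a)
        cols.setdefault(key, len(cols))
    if not cols:
        raise ValueError("no varying charges after constraints")
    S = np.zeros((n_atoms, len(cols)))
    f = np.zeros(n_atoms)
    varying = np.zeros(n_atoms, dtype=bool)
    for a in range(n_atoms):
        if a in frozen:
            f[a] = frozen[a]
        else:
            key = ("g", grouped[a]) if a in grouped else ("a", a)
            S[a, cols[key]] = 1.0
            varying[a] = True
    return S, f, varying


def _restraint_value(q: np.ndarray, varying: np.ndarray, a: float, b: float) -> float:
    qv = q[varying]
    return float(a * np.sum(np.sqrt(qv * qv + b * b) - b))


def resp_objective(A: np.ndarray, b: np.ndarray, q: np.ndarray, spec: RespStageSpec) -> float:
    """Objective value: residual sum of squares plus hyperbolic restraint."""
    _, _, varying = _reduction(A.shape[1], spec)
    r = A @ q - b
    return float(r @ r) + _restraint_value(q, varying, spec.restraint_scale, spec.restraint_width)


def resp_stage(
    A: np.ndarray,
    b: np.ndarray,
    spec: RespStageSpec,
    q0: Optional[np.ndarray] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Solve one restrained fit stage; returns the full charge vector.

    Minimizes ``|A q - b|^2 + a * sum_j (sqrt(q_j^2 + w^2) - w)`` over the
    varying charges subject to the exact total-charge constraint
    and within-group equality, via iteratively reweighted linear KKT solves;
    converged when ``max |dq| < tol``.
    """
    n_atoms = A.shape[1]
    S, f, varying = _reduction(n_atoms, spec)
    H0 = S.T @ (A.T @ A) @ S
    g0 = S.T @ A.T @ (b - A @ f)
    c = S.T @ np.ones(n_atoms)
    qtot_free = spec.total_charge - float(f.sum())
    nu = S.shape[1]

    q = np.asarray(q0, dtype=float).copy() if q0 is not None else np.zeros(n_atoms)
    a, w = spec.restraint_scale, spec.restraint_width
    for _ in range(max_iter):
        # diagonal IRLS weights of the hyperbolic restraint, in q-space
        d = 0.5 * a / np.sqrt(q * q + w * w)
        d[~varying] = 0.0
        H = H0 + S.T @ (d[:, None] * S)
        kkt = np.zeros((nu + 1, nu + 1))
        kkt[:nu, :nu] = H
        kkt[:nu, nu] = c
        kkt[nu, :nu] = c
        rhs = np.concatenate([g0, [qtot_free]])
        sol = np.linalg.solve(kkt, rhs)
        q_new = S @ sol[:nu] + f
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new
    raise RuntimeError(
        f"restrained fit did not converge in {max_iter} iterations; last max charge "
        f"{np.max(np.abs(q)):.4f} e"
    )


def two_stage_resp(
    grids: Sequence[ESPGrid],
    confs: Sequence[Conformation],
    topo: MoleculeTopology,
    stage1_scale: float = 0.01,
    stage2_scale: float = 0.001,
    restraint_width: float = DEFAULT_RESTRAINT_WIDTH,
) -> np.ndarray:
    """Full two-stage restrained charge derivation.

    Stage 1 fits every atom with the stronger restraint and no equivalences;
    stage 2 refits only atoms in declared symmetry groups with within-group
    equality and a weaker restraint, every other atom frozen at its stage-1
    value.  Total charge equals the topology net charge in both stages.
    """
    A, b = build_esp_system(grids, confs)
    spec1 = RespStageSpec(
        restraint_scale=stage1_scale,
        restraint_width=restraint_width,
        total_charge=float(topo.net_charge),
    )
    q1 = resp_stage(A, b, spec1)
    if not topo.symmetry_groups:
        logger.info("no symmetry groups declared; stage 2 skipped")
        return q1
    sym_atoms = set().union(*topo.symmetry_groups)
    spec2 = RespStageSpec(
        restraint_scale=stage2_scale,
        restraint_width=restraint_width,
        frozen_charges={a: float(q1[a]) for a in range(topo.n_atoms) if a not in sym_atoms},
        equivalence_groups=list(topo.symmetry_groups),
        total_charge=float(topo.net_charge),
    )
    return resp_stage(A, b, spec2, q0=q1)
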