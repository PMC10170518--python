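"""Class-I force-field energetics: harmonic bonds and angles, cosine-series
dihedrals, 12-6 Lennard-Jones and Coulomb terms with 1-2/1-3 exclusions and
scaled 1-4 interactions.

The dihedral term uses the AMBER convention ``(V_n/2) * (1 + cos(n*phi -
gamma_n))``; Lennard-Jones cross terms use Lorentz-Berthelot combination
rules.  Energies are kJ/mol, lengths Angstrom; dihedral angles at the public
interface are degrees in ``[-180, 180)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .constants import COULOMB_CONSTANT
from .topology import Conformation, MoleculeTopology, _canon_angle, _canon_bond, _canon_dihedral

__all__ = [
    "FFParameters",
    "EnergyBreakdown",
    "ParameterLookupError",
    "SingularityError",
    "DegenerateGeometryError",
    "measure_dihedral",
    "set_dihedral",
    "compute_energy",
    "compute_forces",
    "minimize_conformation",
    "batch_bond_lengths",
    "batch_angles",
    "batch_dihedrals",
]


class ParameterLookupError(KeyError):
    """A topological term has no matching force-field parameter."""


class SingularityError(ValueError):
    """Two interacting particles (nearly) coincide."""


class DegenerateGeometryError(ValueError):
    """Three consecutive atoms of a torsion are collinear."""


@dataclass
class FFParameters:
    """All force-field parameters of one molecule, keyed by atom-index tuple.

    ``bond[(i,j)] = (K_b, r_eq)`` with K_b in kJ/mol/A^2; ``angle[(i,j,k)] =
    (K_theta, theta_eq)`` with K_theta in kJ/mol/rad^2 and theta_eq in rad;
    ``dihedral[(i,j,k,l)]`` is a list of ``(V_n, n, gamma_n)`` terms (V_n in
    kJ/mol, gamma_n in rad); ``lj[i] = (sigma_i, epsilon_i)``; ``charges[i]``
    in elementary charges.
    """

    bond: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    angle: dict[tuple[int, int, int], tuple[float, float]] = field(default_factory=dict)
    dihedral: dict[tuple[int, int, int, int], list[tuple[float, int, float]]] = field(default_factory=dict)
    lj: dict[int, tuple[float, float]] = field(default_factory=dict)
    charges: dict[int, float] = field(default_factory=dict)
    coulomb_constant: float = COULOMB_CONSTANT
    scale_14_lj: float = 0.5
    scale_14_coul: float = 1.0 / 1.2

    def __post_init__(self) -> None:
        self.bond = {_canon_bond(*k): tuple(v) for k, v in self.bond.items()}
        self.angle = {_canon_angle(k): tuple(v) for k, v in self.angle.items()}
        self.dihedral = {_canon_dihedral(k): [tuple(t) for t in v] for k, v in self.dihedral.items()}
        for key, (kb, _) in self.bond.items():
            if kb < 0:
                raise ValueError(f"negative bond force constant at {key}")
        for key, (kt, _) in self.angle.items():
            if kt < 0:
                raise ValueError(f"negative angle force constant at {key}")
        for i, (sig, eps) in self.lj.items():
            if sig <= 0 or eps < 0:
                raise ValueError(f"invalid LJ parameters for atom {i}: sigma={sig}, eps={eps}")

    def copy(self) -> "FFParameters":
        return FFParameters(
            bond={k: v for k, v in self.bond.items()},
            angle={k: v for k, v in self.angle.items()},
            dihedral={k: list(v) for k, v in self.dihedral.items()},
            lj=dict(self.lj),
            charges=dict(self.charges),
            coulomb_constant=self.coulomb_constant,
            scale_14_lj=self.scale_14_lj,
            scale_14_coul=self.scale_14_coul,
        )


@dataclass(frozen=True)
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    lj: float
    coulomb: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.lj + self.coulomb


# ---------------------------------------------------------------------------
# Internal coordinates (vectorized over a stack of frames)
# ---------------------------------------------------------------------------


def batch_bond_lengths(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bond lengths for a frame stack ``(F, N, 3)`` and index pairs ``(B, 2)``."""
    d = coords[..., idx[:, 1], :] - coords[..., idx[:, 0], :]
    return np.linalg.norm(d, axis=-1)


def batch_angles(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bond angles in radians for index triples ``(A, 3)``."""
    u = coords[..., idx[:, 0], :] - coords[..., idx[:, 1], :]
    v = coords[..., idx[:, 2], :] - coords[..., idx[:, 1], :]
    cu = np.linalg.norm(u, axis=-1)
    cv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("...ij,...ij->...i", u, v) / (cu * cv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def batch_dihedrals(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed torsions in radians, range ``[-pi, pi)``, for quads ``(D, 4)``.

    Sign follows the IUPAC right-hand convention about the 2-3 axis: looking
    down j->k, a clockwise rotation of the distal bond from syn is positive.
    """
    b1 = coords[..., idx[:, 1], :] - coords[..., idx[:, 0], :]
    b2 = coords[..., idx[:, 2], :] - coords[..., idx[:, 1], :]
    b3 = coords[..., idx[:, 3], :] - coords[..., idx[:, 2], :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.einsum("...ij,...ij->...i", n1, n2)
    y = np.einsum("...ij,...ij->...i", np.cross(n1, n2), b2) / b2n
    phi = np.arctan2(y, x)
    # map +pi to -pi so the anti boundary is canonical
    phi = np.where(phi >= np.pi - 1e-12, -np.pi, phi)
    return phi


def measure_dihedral(conf: Conformation, quad: Sequence[int]) -> float:
    """Signed torsion angle in degrees, range ``[-180, 180)``.

    Raises :class:`DegenerateGeometryError` when either bonded triple is
    collinear (the torsion is then undefined).
    """
    quad = tuple(quad)
    if len(set(quad)) != 4:
        raise ValueError(f"dihedral quadruple must have four distinct indices: {quad}")
    c = conf.coords[list(quad)]
    b1, b2, b3 = c[1] - c[0], c[2] - c[1], c[3] - c[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError(f"collinear atoms in dihedral {quad}")
    phi = float(batch_dihedrals(conf.coords[None], np.asarray([quad]))[0, 0])
    return float(np.degrees(phi))


def set_dihedral(
    conf: Conformation, topo: MoleculeTopology, quad: Sequence[int], angle_deg: float
) -> Conformation:
    """Return a copy with the torsion ``quad`` rotated to ``angle_deg``.

    All atoms on the distal (k, l) side of the rotatable j-k bond move
    rigidly; requires the j-k bond not to be part of a ring.
    """
    i, j, k, l = quad
    adj = topo.adjacency()
    # atoms reachable from k without crossing the j-k bond
    moving, stack = {k}, [k]
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if a == k and b == j:
                continue
            if b not in moving:
                moving.add(b)
                stack.append(b)
    if j in moving:
        raise ValueError(f"bond ({j},{k}) is in a ring; cannot drive dihedral {tuple(quad)}")
    current = measure_dihedral(conf, quad)
    delta = np.radians(angle_deg - current)
    axis = conf.coords[k] - conf.coords[j]
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(delta * axis)
    out = conf.coords.copy()
    mov = sorted(moving)
    out[mov] = rot.apply(out[mov] - conf.coords[k]) + conf.coords[k]
    return Conformation(out, tag=conf.tag)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------


def _lookup(table: dict, key, kind: str):
    try:
        return table[key]
    except KeyError:
        raise ParameterLookupError(f"missing {kind} parameter for term {key}") from None


def _lj_cross(params: FFParameters, i: int, j: int) -> tuple[float, float]:
    si, ei = _lookup(params.lj, i, "LJ")
    sj, ej = _lookup(params.lj, j, "LJ")
    return 0.5 * (si + sj), float(np.sqrt(ei * ej))


def _nonbonded_tables(topo: MoleculeTopology, params: FFParameters):
    """Precompute per-pair sigma/eps/qq products and 1-4 scale factors."""
    pairs, is14 = topo.nonbonded_pairs()
    if len(pairs) == 0:
        z = np.zeros(0)
        return pairs, z, z, z, z, z
    sig = np.empty(len(pairs))
    eps = np.empty(len(pairs))
    qq = np.empty(len(pairs))
    for m, (i, j) in enumerate(pairs):
        sig[m], eps[m] = _lj_cross(params, int(i), int(j))
        qi = _lookup(params.charges, int(i), "charge")
        qj = _lookup(params.charges, int(j), "charge")
        qq[m] = qi * qj
    slj = np.where(is14, params.scale_14_lj, 1.0)
    scoul = np.where(is14, params.scale_14_coul, 1.0)
    return pairs, sig, eps, qq, slj, scoul


def compute_energy(
    conf: Conformation, topo: MoleculeTopology, params: FFParameters
) -> EnergyBreakdown:
    """Evaluate the force-field energy of one conformation, by term."""
    if conf.n_atoms != topo.n_atoms:
        raise ValueError(f"conformation has {conf.n_atoms} atoms, topology {topo.n_atoms}")
    c = conf.coords[None]

    e_bond = 0.0
    if topo.bonds:
        idx = np.asarray(topo.bonds)
        r = batch_bond_lengths(c, idx)[0]
        kb, req = np.array([_lookup(params.bond, b, "bond") for b in topo.bonds]).T
        e_bond = float(np.sum(kb * (r - req) ** 2))

    e_angle = 0.0
    if topo.angles:
        idx = np.asarray(topo.angles)
        th = batch_angles(c, idx)[0]
        kt, teq = np.array([_lookup(params.angle, a, "angle") for a in topo.angles]).T
        e_angle = float(np.sum(kt * (th - teq) ** 2))

    e_dih = 0.0
    if topo.dihedral_quads:
        idx = np.asarray(topo.dihedral_quads)
        phi = batch_dihedrals(c, idx)[0]
        for m, q in enumerate(topo.dihedral_quads):
            for v, n, gam in _lookup(params.dihedral, q, "dihedral"):
                e_dih += 0.5 * v * (1.0 + np.cos(n * phi[m] - gam))
        e_dih = float(e_dih)

    pairs, sig, eps, qq, slj, scoul = _nonbonded_tables(topo, params)
    e_lj = e_coul = 0.0
    if len(pairs):
        r = batch_bond_lengths(c, pairs)[0]
        if np.any(r < 1e-6):
            bad = pairs[int(np.argmin(r))]
            raise SingularityError(f"atoms {tuple(bad)} overlap (r < 1e-6 A)")
        sr6 = (sig / r) ** 6
        e_lj = float(np.sum(slj * 4.0 * eps * (sr6 * sr6 - sr6)))
        e_coul = float(np.sum(scoul * params.coulomb_constant * qq / r))

    return EnergyBreakdown(e_bond, e_angle, e_dih, e_lj, e_coul)


# ---------------------------------------------------------------------------
# Analytic forces
# ---------------------------------------------------------------------------


def _dihedral_gradients(c: np.ndarray, quad: Sequence[int]):
    """d(phi)/d(r) for the four atoms of a torsion (phi in radians)."""
    i, j, k, l = quad
    b1 = c[j] - c[i]
    b2 = c[k] - c[j]
    b3 = c[l] - c[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = n1 @ n1
    n2sq = n2 @ n2
    b2n = np.linalg.norm(b2)
    if n1sq < 1e-20 or n2sq < 1e-20:
        raise DegenerateGeometryError(f"collinear atoms in dihedral {tuple(quad)}")
    g_i = -(b2n / n1sq) * n1
    g_l = (b2n / n2sq) * n2
    f1 = (b1 @ b2) / (b2n * b2n)
    f3 = (b3 @ b2) / (b2n * b2n)
    g_j = -(1.0 + f1) * g_i + f3 * g_l
    g_k = f1 * g_i - (1.0 + f3) * g_l
    return g_i, g_j, g_k, g_l


def compute_forces(
    conf: Conformation, topo: MoleculeTopology, params: FFParameters
) -> np.ndarray:
    """Analytic forces ``-dU/dx``, shape ``(N, 3)``, kJ/mol/A."""
    c = conf.coords
    grad = np.zeros_like(c)

    for (i, j) in topo.bonds:
        kb, req = _lookup(params.bond, (i, j), "bond")
        d = c[j] - c[i]
        r = np.linalg.norm(d)
        g = 2.0 * kb * (r - req) / r * d
        grad[i] -= g
        grad[j] += g

    for (i, j, k) in topo.angles:
        kt, teq = _lookup(params.angle, (i, j, k), "angle")
        u = c[i] - c[j]
        v = c[k] - c[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        th = np.arccos(cosang)
        sin = np.sqrt(max(1.0 - cosang * cosang, 1e-16))
        dth_di = (cosang * u / nu - v / nv) / (nu * sin)
        dth_dk = (cosang * v / nv - u / nu) / (nv * sin)
        pref = 2.0 * kt * (th - teq)
        grad[i] += pref * dth_di
        grad[k] += pref * dth_dk
        grad[j] -= pref * (dth_di + dth_dk)

    if topo.dihedral_quads:
        idx = np.asarray(topo.dihedral_quads)
        phi = batch_dihedrals(c[None], idx)[0]
        for m, q in enumerate(topo.dihedral_quads):
            dU = 0.0
            for v, n, gam in _lookup(params.dihedral, q, "dihedral"):
                dU += -0.5 * v * n * np.sin(n * phi[m] - gam)
            if dU == 0.0:
                continue
            gi, gj, gk, gl = _dihedral_gradients(c, q)
            for a, g in zip(q, (gi, gj, gk, gl)):
                grad[a] += dU * g

    pairs, sig, eps, qq, slj, scoul = _nonbonded_tables(topo, params)
    if len(pairs):
        d = c[pairs[:, 1]] - c[pairs[:, 0]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-6):
            bad = pairs[int(np.argmin(r))]
            raise SingularityError(f"atoms {tuple(bad)} overlap (r < 1e-6 A)")
        sr6 = (sig / r) ** 6
        dUdr = slj * 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        dUdr += -scoul * params.coulomb_constant * qq / r**2
        g = (dUdr / r)[:, None] * d
        np.add.at(grad, pairs[:, 1], g)
        np.add.at(grad, pairs[:, 0], -g)

    return -grad


def minimize_conformation(
    conf: Conformation,
    topo: MoleculeTopology,
    params: FFParameters,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> Conformation:
    """Local L-BFGS minimization; converged when the force max-norm <= tol.

    On non-convergence a warning is emitted and the best-so-far geometry is
    returned with tag suffix ``" unconverged"``.
    """
    n = conf.n_atoms

    def fun(x):
        cc = Conformation(x.reshape(n, 3))
        e = compute_energy(cc, topo, params).total
        g = -compute_forces(cc, topo, params)
        return e, g.ravel()

    e0 = compute_energy(conf, topo, params).total
    if not np.isfinite(e0):
        raise ValueError("starting energy is not finite")
    res = _scipy_minimize(
        fun,
        conf.coords.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 0.1 * tol, "ftol": 1e-14},
    )
    out = Conformation(res.x.reshape(n, 3), tag=conf.tag)
    gmax = float(np.max(np.abs(compute_forces(out, topo, params))))
    e1 = compute_energy(out, topo, params).total
    if e1 > e0:  # optimizer failed to improve; keep the start
        out, e1 = conf.copy(), e0
        gmax = float(np.max(np.abs(compute_forces(out, topo, params))))
    if gmax > tol:
        warnings.warn(
            f"minimization did not reach force tolerance {tol} (max |F| = {gmax:.3g}); "
            "returning best-so-far geometry",
            RuntimeWarning,
        )
        out.tag = (out.tag or "") + " unconverged"
    out.energy = e1
    return out
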