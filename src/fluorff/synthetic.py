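"""Synthetic ground-truth data generators.

Every pipeline stage can be exercised without quantum-chemical engines or
archived trajectories: this module builds toy fluorohydrin-like molecules
with full force-field parameter coverage, a surrogate "reference" potential
that perturbs the base force field smoothly (standing in for a higher level
of theory), dihedral trajectories drawn from circular mixtures with known
rotamer weights, and electrostatic-potential grids generated exactly from
known point charges.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .conformers import ROTAMER_CENTERS, parse_conformer_key
from .constants import COULOMB_CONSTANT, VDW_RADII
from .forcefield import (
    FFParameters,
    compute_energy,
    compute_forces,
    set_dihedral,
)
from .resp import ESPGrid
from .sampling import PotentialHandle
from .topology import Conformation, MoleculeTopology

__all__ = [
    "ToyMoleculeSpec",
    "SurrogateReferenceSpec",
    "make_toy_molecule",
    "make_surrogate_reference",
    "generate_dihedral_trajectory",
    "generate_esp_fixture",
    "perturb_conformations",
]

# ideal bond lengths (A) by element pair
_BOND_LENGTHS = {
    ("C", "C"): 1.53,
    ("C", "O"): 1.43,
    ("H", "O"): 0.96,
    ("C", "F"): 1.36,
    ("C", "H"): 1.09,
}
# bond force constants (kJ/mol/A^2)
_BOND_K = {
    ("C", "C"): 1100.0,
    ("C", "O"): 1300.0,
    ("H", "O"): 2300.0,
    ("C", "F"): 1500.0,
    ("C", "H"): 1400.0,
}
_TETRAHEDRAL = np.radians(109.471)
# per-element Lennard-Jones (sigma A, epsilon kJ/mol)
_LJ = {
    "C": (3.40, 0.36),
    "O": (3.00, 0.88),
    "F": (3.12, 0.26),
    "H": (2.47, 0.066),
}


@dataclass
class ToyMoleculeSpec:
    """Specification of a toy chain molecule.

    ``n_heavy`` backbone carbons (4-8); ``pattern`` selects the substituent
    layout: ``"mono"`` carries one OH (on C0) and one F (on C2) plus a
    symmetric H pair on C1, giving the three role torsions chi, phi, psi;
    ``"chain"`` is a bare carbon chain used for parameter-recovery studies.
    """

    n_heavy: int = 4
    pattern: str = "mono"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4 <= self.n_heavy <= 8:
            raise ValueError("n_heavy must be between 4 and 8")
        if self.pattern not in ("mono", "chain"):
            raise ValueError(f"unsupported pattern {self.pattern!r}")


def _place(b: np.ndarray, c: np.ndarray, d: np.ndarray, r: float, theta: float, phi: float) -> np.ndarray:
    """Place an atom at distance r from d, angle theta (a-d-c) and torsion
    phi about the c-d axis relative to b (natural extension reference frame)."""
    bc = c - b
    cd = d - c
    n = np.cross(bc, cd)
    n /= np.linalg.norm(n)
    cdn = cd / np.linalg.norm(cd)
    m = np.cross(n, cdn)
    d2 = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    return d + d2[0] * cdn + d2[1] * m + d2[2] * n


def make_toy_molecule(
    spec: ToyMoleculeSpec,
) -> tuple[MoleculeTopology, FFParameters, Conformation]:
    """Build topology, parameters and a staggered starting geometry."""
    n = spec.n_heavy
    elements: list[str] = ["C"] * n
    bonds: list[tuple[int, int]] = [(i, i + 1) for i in range(n - 1)]
    # (atom, parent, ref_angle_atoms..., torsion placement) handled below
    roles: dict[str, tuple[int, int, int, int]] = {}
    symmetry_groups: list[frozenset[int]] = []

    if spec.pattern == "mono":
        iO = n
        iHO = n + 1
        iF = n + 2
        iH1 = n + 3
        iH2 = n + 4
        elements += ["O", "H", "F", "H", "H"]
        bonds += [(0, iO), (iO, iHO), (2, iF), (1, iH1), (1, iH2)]
        roles = {
            "chi": (iHO, iO, 0, 1),  # hydroxyl torsion
            "phi": (iO, 0, 1, 2),  # O against the backbone
            "psi": (iF, 2, 1, 0),  # F against the backbone
        }
        symmetry_groups = [frozenset({iH1, iH2})]

    # --- geometry -----------------------------------------------------------
    coords = np.zeros((len(elements), 3))
    r_cc = _BOND_LENGTHS[("C", "C")]
    coords[0] = [0.0, 0.0, 0.0]
    coords[1] = [r_cc, 0.0, 0.0]
    coords[2] = coords[1] + [
        -r_cc * np.cos(_TETRAHEDRAL),
        r_cc * np.sin(_TETRAHEDRAL),
        0.0,
    ]
    for i in range(3, n):  # backbone anti zigzag
        coords[i] = _place(coords[i - 3], coords[i - 2], coords[i - 1], r_cc, _TETRAHEDRAL, np.pi)
    if spec.pattern == "mono":
        r_co = _BOND_LENGTHS[("C", "O")]
        r_oh = _BOND_LENGTHS[("H", "O")]
        r_cf = _BOND_LENGTHS[("C", "F")]
        r_ch = _BOND_LENGTHS[("C", "H")]
        # O on C0, anti to C2 about the C1-C0 axis
        coords[iO] = _place(coords[2], coords[1], coords[0], r_co, _TETRAHEDRAL, np.radians(180.0))
        # hydroxyl H, trans chi
        coords[iHO] = _place(coords[1], coords[0], coords[iO], r_oh, np.radians(107.0), np.radians(180.0))
        # F on C2, gauche psi
        coords[iF] = _place(coords[0], coords[1], coords[2], r_cf, _TETRAHEDRAL, np.radians(60.0))
        # symmetric H pair on C1
        coords[iH1] = _place(coords[iO], coords[0], coords[1], r_ch, _TETRAHEDRAL, np.radians(60.0))
        coords[iH2] = _place(coords[iO], coords[0], coords[1], r_ch, _TETRAHEDRAL, np.radians(-60.0))

    atoms = [(el, i) for i, el in enumerate(elements)]
    topo = MoleculeTopology(
        atoms=atoms,
        bonds=bonds,
        symmetry_groups=symmetry_groups,
        dihedral_roles=roles,
        net_charge=0,
    )

    # --- parameters ---------------------------------------------------------
    def bond_kind(i: int, j: int) -> tuple[str, str]:
        a, b = sorted((elements[i], elements[j]))
        return (a, b)

    bond_params = {}
    for (i, j) in topo.bonds:
        kind = bond_kind(i, j)
        bond_params[(i, j)] = (_BOND_K[kind], _BOND_LENGTHS[kind])
    angle_params = {}
    for (i, j, k) in topo.angles:
        teq = np.radians(107.0) if elements[j] == "O" else _TETRAHEDRAL
        kt = 320.0 if "H" not in (elements[i], elements[k]) else 220.0
        angle_params[(i, j, k)] = (kt, teq)
    dihedral_params = {}
    for q in topo.dihedral_quads:
        j, k = q[1], q[2]
        if elements[j] == "O" or elements[k] == "O":
            v = 1.2  # hydroxyl-type torsion, soft
        elif "H" in (elements[q[0]], elements[q[3]]):
            v = 0.7
        else:
            v = 4.0  # heavy-atom backbone torsion
        dihedral_params[q] = [(v, 3, 0.0)]
    lj = {i: _LJ[el] for i, el in enumerate(elements)}

    charges = {i: 0.0 for i in range(len(elements))}
    if spec.pattern == "mono":
        charges[iO] = -0.60
        charges[iHO] = 0.42
        charges[iF] = -0.32
        charges[0] = 0.22  # C-O carbon
        charges[2] = 0.30  # C-F carbon
        charges[iH1] = charges[iH2] = 0.05
        resid = -sum(charges.values())
        charges[1] += resid  # neutralize on the spacer carbon

    params = FFParameters(
        bond=bond_params,
        angle=angle_params,
        dihedral=dihedral_params,
        lj=lj,
        charges=charges,
    )
    conf = Conformation(coords, tag=f"toy-{spec.pattern}-{n}")
    return topo, params, conf


def perturb_conformations(
    conf: Conformation,
    topo: MoleculeTopology,
    n: int,
    coord_scale: float = 0.06,
    seed: int = 0,
    rotate_dihedrals: bool = True,
) -> list[Conformation]:
    """Diverse conformations for training: random rotatable-bond torsions
    plus small Gaussian Cartesian noise (``coord_scale`` Angstrom)."""
    rng = np.random.default_rng(seed)
    rotatable = [q for q in topo.dihedral_quads if len({q[0], q[3]}) == 2]
    # one representative quad per central bond
    seen: set[tuple[int, int]] = set()
    drivers = []
    for q in rotatable:
        jk = tuple(sorted(q[1:3]))
        if jk not in seen:
            seen.add(jk)
            drivers.append(q)
    out = []
    for i in range(n):
        c = conf
        if rotate_dihedrals:
            for q in drivers:
                c = set_dihedral(c, topo, q, rng.uniform(-180.0, 180.0))
        x = c.coords + rng.normal(scale=coord_scale, size=c.coords.shape)
        out.append(Conformation(x, tag=f"perturbed-{i}"))
    return out


@dataclass
class SurrogateReferenceSpec:
    """A smoothly perturbed copy of a base force field.

    Force constants (bond, angle, dihedral barrier heights) are scaled by
    independent factors ``1 + scale * u`` with ``u ~ U(-1, 1)`` per term,
    and an anharmonic cubic bond correction ``c3 * sum_b (r_b - r_eq)^3`` is
    added; the cubic term cannot be represented by the class-I functional
    form, so refitting against this surrogate faces a genuine model-form
    gap.  The correction is bounded below on the sampled domain as long as
    the harmonic terms dominate (|r - r_eq| well under K_b / |c3|).
    """

    base: FFParameters
    perturbation_scale: float = 0.15
    cubic_bond_coeff: float = -150.0  # kJ/mol/A^3
    seed: int = 0


def make_surrogate_reference(
    spec: SurrogateReferenceSpec, topo: MoleculeTopology
) -> tuple[PotentialHandle, FFParameters]:
    """Build the surrogate high-level potential; also returns the perturbed
    parameter set that generates its harmonic part (the recovery target)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.perturbation_scale
    pert = spec.base.copy()
    for key in sorted(pert.bond):
        kb, req = pert.bond[key]
        pert.bond[key] = (kb * (1.0 + s * rng.uniform(-1, 1)), req)
    for key in sorted(pert.angle):
        kt, teq = pert.angle[key]
        pert.angle[key] = (kt * (1.0 + s * rng.uniform(-1, 1)), teq)
    for key in sorted(pert.dihedral):
        pert.dihedral[key] = [
            (v * (1.0 + s * rng.uniform(-1, 1)), n, g) for (v, n, g) in pert.dihedral[key]
        ]

    bond_idx = np.asarray(topo.bonds) if topo.bonds else np.zeros((0, 2), dtype=int)
    req = np.array([pert.bond[b][1] for b in topo.bonds]) if topo.bonds else np.zeros(0)
    c3 = spec.cubic_bond_coeff

    def energy(x: np.ndarray) -> float:
        conf = Conformation(x)
        e = compute_energy(conf, topo, pert).total
        if len(bond_idx):
            d = x[bond_idx[:, 1]] - x[bond_idx[:, 0]]
            r = np.linalg.norm(d, axis=1)
            e += c3 * float(np.sum((r - req) ** 3))
        return e

    def forces(x: np.ndarray) -> np.ndarray:
        conf = Conformation(x)
        f = compute_forces(conf, topo, pert)
        if len(bond_idx):
            d = x[bond_idx[:, 1]] - x[bond_idx[:, 0]]
            r = np.linalg.norm(d, axis=1)
            g = (3.0 * c3 * (r - req) ** 2 / r)[:, None] * d
            np.add.at(f, bond_idx[:, 1], -g)
            np.add.at(f, bond_idx[:, 0], g)
        return f

    return PotentialHandle(energy=energy, forces=forces, label="surrogate-reference"), pert


def generate_dihedral_trajectory(
    topo: MoleculeTopology,
    base_conf: Conformation,
    weights: Mapping[str, float],
    kappa: float = 50.0,
    n_frames: int = 1000,
    seed: int = 0,
    molecule_class: str = "mono",
) -> list[Conformation]:
    """Trajectory whose role torsions follow a von Mises mixture.

    Each frame draws a conformer key from ``weights``, then each role
    torsion from a von Mises distribution centered on that rotamer's well
    (60, 180 or -60 degrees) with concentration ``kappa``.  At the default
    kappa the wells overlap by far less than 1%, so realized key
    frequencies converge to the requested weights.
    """
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    parsed = [parse_conformer_key(k, molecule_class) for k in keys]
    roles = sorted(parsed[0].keys()) if parsed else []
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(keys), size=n_frames, p=w)
    frames: list[Conformation] = []
    for f in range(n_frames):
        labels = parsed[choice[f]]
        conf = base_conf
        for role, lab in labels.items():
            center = np.radians(ROTAMER_CENTERS[lab])
            ang = np.degrees(rng.vonmises(center, kappa))
            conf = set_dihedral(conf, topo, topo.dihedral_roles[role], ang)
        frames.append(Conformation(conf.coords, tag=f"frame-{f}"))
    return frames


def generate_esp_fixture(
    topo: MoleculeTopology,
    charges: Mapping[int, float] | Sequence[float],
    confs: Sequence[Conformation],
    n_points: int = 800,
    seed: int = 0,
    shell_range: tuple[float, float] = (1.4, 2.0),
) -> list[ESPGrid]:
    """Exact point-charge ESP grids on van der Waals shells.

    Points are sampled on shells at ``shell_range`` times the element van
    der Waals radius around randomly chosen atoms; points closer than the
    inner shell of *any* atom are rejected, so no grid point lies inside
    the molecular surface (and none within 1 Angstrom of an atom).
    """
    q = np.array([charges[i] for i in range(topo.n_atoms)], dtype=float)
    radii = np.array([VDW_RADII[el] for el in topo.elements])
    rng = np.random.default_rng(seed)
    grids = []
    for conf in confs:
        pts = []
        while len(pts) < n_points:
            a = rng.integers(topo.n_atoms)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = radii[a] * rng.uniform(*shell_range)
            p = conf.coords[a] + rad * u
            d = np.linalg.norm(conf.coords - p, axis=1)
            if np.all(d >= shell_range[0] * radii) and np.all(d >= 1.0):
                pts.append(p)
        pts = np.asarray(pts)
        d = np.linalg.norm(pts[:, None, :] - conf.coords[None, :, :], axis=2)
        vals = COULOMB_CONSTANT * (1.0 / d) @ q
        grids.append(ESPGrid(points=pts, values=vals, conformation_ref=conf.tag or ""))
    return grids
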