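"""Molecular topology and conformation containers.

A :class:`MoleculeTopology` stores atoms and covalent connectivity; angle
triples, dihedral quadruples, 1-2/1-3 exclusions and scaled 1-4 pairs are all
derived from the bond list, so a topology is fully determined by its atoms,
bonds, declared symmetry groups and named dihedral roles.

Dihedral roles follow side-chain rotamer nomenclature: ``chi`` is the
hydroxyl H-O-C-C torsion, ``phi`` (or ``phi1``/``phi2`` for difluoro
species) the F/O backbone torsions, and ``psi`` the remaining backbone
torsion used in parentheses in conformer keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["MoleculeTopology", "Conformation", "derive_angles", "derive_dihedrals"]


def _canon_bond(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def _canon_angle(t: Sequence[int]) -> tuple[int, int, int]:
    i, j, k = t
    return (i, j, k) if i < k else (k, j, i)


def _canon_dihedral(q: Sequence[int]) -> tuple[int, int, int, int]:
    q = tuple(q)
    r = q[::-1]
    return q if q <= r else r


def derive_angles(bonds: Iterable[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All i-j-k triples with i-j and j-k bonded, canonicalized, sorted."""
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    out = set()
    for j, nbrs in adj.items():
        for i in nbrs:
            for k in nbrs:
                if i < k:
                    out.add((i, j, k))
    return sorted(out)


def derive_dihedrals(bonds: Iterable[tuple[int, int]]) -> list[tuple[int, int, int, int]]:
    """All proper i-j-k-l quadruples along bonded paths, canonicalized."""
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    out = set()
    for j, k in ((a, b) for a, b in adj.items() for b in adj[a]):
        for i in adj[j] - {k}:
            for l in adj[k] - {j}:
                if i != l:
                    out.add(_canon_dihedral((i, j, k, l)))
    return sorted(out)


@dataclass
class MoleculeTopology:
    """Atoms, connectivity and role annotations of one molecule.

    Parameters
    ----------
    atoms
        ``(element, index)`` pairs; indices must be ``0..N-1`` in order.
    bonds
        Covalent bonds as index pairs (stored canonically with ``i < j``).
    symmetry_groups
        Sets of atom indices declared chemically equivalent (used by the
        two-stage charge fit).
    dihedral_roles
        Map from role name (``chi``, ``phi``, ``phi1``, ``phi2``, ``psi``)
        to a dihedral quadruple.
    net_charge
        Total molecular charge in elementary charges.
    """

    atoms: list[tuple[str, int]]
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedral_quads: list[tuple[int, int, int, int]] = field(default_factory=list)
    symmetry_groups: list[frozenset[int]] = field(default_factory=list)
    dihedral_roles: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    net_charge: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for a, (el, idx) in enumerate(self.atoms):
            if idx != a:
                raise ValueError(f"atom indices must be consecutive from 0; got {idx} at position {a}")
        self.bonds = sorted({_canon_bond(*b) for b in self.bonds})
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) out of range or degenerate")
        if not self.angles:
            self.angles = derive_angles(self.bonds)
        else:
            self.angles = sorted({_canon_angle(a) for a in self.angles})
        if not self.dihedral_quads:
            self.dihedral_quads = derive_dihedrals(self.bonds)
        else:
            self.dihedral_quads = sorted({_canon_dihedral(q) for q in self.dihedral_quads})
        quadset = set(self.dihedral_quads)
        for role, quad in self.dihedral_roles.items():
            if _canon_dihedral(quad) not in quadset:
                raise ValueError(f"dihedral role {role!r} quadruple {quad} not among topology dihedrals")
        self.symmetry_groups = [frozenset(g) for g in self.symmetry_groups]
        self._derive_exclusions()

    def _derive_exclusions(self) -> None:
        bonded = {_canon_bond(*b) for b in self.bonds}
        excl_13 = {_canon_bond(i, k) for i, _, k in self.angles}
        pairs_14 = set()
        for i, _, _, l in self.dihedral_quads:
            p = _canon_bond(i, l)
            if p not in bonded and p not in excl_13:
                pairs_14.add(p)
        self.exclusions_12_13: set[tuple[int, int]] = bonded | excl_13
        self.pairs_14: set[tuple[int, int]] = pairs_14

    # -- convenience -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [el for el, _ in self.atoms]

    def nonbonded_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(pairs, is_14)``: all interacting pairs and a 1-4 mask."""
        n = self.n_atoms
        pairs, is14 = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in self.exclusions_12_13:
                    continue
                pairs.append((i, j))
                is14.append((i, j) in self.pairs_14)
        return np.asarray(pairs, dtype=int).reshape(-1, 2), np.asarray(is14, dtype=bool)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj


@dataclass
class Conformation:
    """One molecular geometry: Cartesian coordinates in Angstrom."""

    coords: np.ndarray
    energy: Optional[float] = None
    tag: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3); got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), self.energy, self.tag)
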