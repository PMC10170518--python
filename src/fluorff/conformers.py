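"""Rotamer labelling, conformer keys, and conformer populations.

Threefold torsions are classified into the side-chain rotamer wells

* ``g+`` for   0 deg <= angle < 120 deg,
* ``t``  for 120 deg <= angle < 240 deg,
* ``g-`` for -120 deg <= angle < 0 deg,

with any finite input wrapped into [-120, 240) first.  A conformer key
strings the labels of the named role torsions together: ``chi phi (psi)``
for monofluoro species, ``chi phi1 phi2 (psi)`` (with the two phi labels in
canonical lexicographic order, since the two printed orderings are
equivalent) for difluoro species, and ``chi (psi)`` for trifluoro species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import KB
from .forcefield import batch_dihedrals, measure_dihedral
from .topology import Conformation, MoleculeTopology

__all__ = [
    "ROTAMER_LABELS",
    "ROTAMER_CENTERS",
    "FreeEnergyTable",
    "label_rotamer",
    "conformer_key",
    "parse_conformer_key",
    "trajectory_populations",
    "boltzmann_populations",
    "has_imhb",
]

ROTAMER_LABELS = ("g+", "t", "g-")

#: well centers in degrees, used by the synthetic trajectory generator
ROTAMER_CENTERS = {"g+": 60.0, "t": 180.0, "g-": -60.0}

_ROLE_SETS = {
    "mono": ("chi", "phi", "psi"),
    "di": ("chi", "phi1", "phi2", "psi"),
    "tri": ("chi", "psi"),
}


def label_rotamer(angle_deg: float) -> str:
    """Rotamer well of a torsion angle (degrees, any finite value)."""
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    a = float(np.mod(angle_deg + 120.0, 360.0)) - 120.0  # wrap to [-120, 240)
    if 0.0 <= a < 120.0:
        return "g+"
    if 120.0 <= a < 240.0:
        return "t"
    return "g-"


def _assemble_key(labels: dict[str, str], molecule_class: str) -> str:
    if molecule_class == "mono":
        return f"{labels['chi']}{labels['phi']}({labels['psi']})"
    if molecule_class == "di":
        a, b = sorted([labels["phi1"], labels["phi2"]])
        return f"{labels['chi']}{a}{b}({labels['psi']})"
    if molecule_class == "tri":
        return f"{labels['chi']}({labels['psi']})"
    raise ValueError(f"unknown molecule class {molecule_class!r}")


def conformer_key(conf: Conformation, topo: MoleculeTopology, molecule_class: str = "mono") -> str:
    """Conformer key of one geometry from its role torsions."""
    roles = _ROLE_SETS.get(molecule_class)
    if roles is None:
        raise ValueError(f"unknown molecule class {molecule_class!r}")
    labels = {}
    for role in roles:
        if role not in topo.dihedral_roles:
            raise KeyError(f"topology lacks dihedral role {role!r} required for class {molecule_class!r}")
        labels[role] = label_rotamer(measure_dihedral(conf, topo.dihedral_roles[role]))
    return _assemble_key(labels, molecule_class)


def parse_conformer_key(key: str, molecule_class: str = "mono") -> dict[str, str]:
    """Invert a conformer key into per-role rotamer labels.

    For difluoro keys the canonical order is assigned to ``phi1 <= phi2``.
    """
    if "(" not in key or not key.endswith(")"):
        raise ValueError(f"malformed conformer key {key!r}")
    head, psi = key[:-1].split("(")
    tokens = []
    while head:
        for lab in ("g+", "g-", "t"):
            if head.startswith(lab):
                tokens.append(lab)
                head = head[len(lab) :]
                break
        else:
            raise ValueError(f"malformed conformer key {key!r}")
    roles = _ROLE_SETS[molecule_class]
    expected = len(roles) - 1
    if len(tokens) != expected:
        raise ValueError(f"key {key!r} has {len(tokens)} labels; class {molecule_class!r} needs {expected}")
    out = dict(zip([r for r in roles if r != "psi"], tokens))
    out["psi"] = psi
    return out


def trajectory_populations(
    traj: Sequence[Conformation],
    topo: MoleculeTopology,
    molecule_class: str = "mono",
) -> dict[str, float]:
    """Cluster every frame into its conformer and return key frequencies."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    roles = _ROLE_SETS[molecule_class]
    quads = np.asarray([topo.dihedral_roles[r] for r in roles])
    coords = np.stack([c.coords for c in traj])
    phi = np.degrees(batch_dihedrals(coords, quads))  # (F, n_roles)
    counts: dict[str, int] = {}
    for row in phi:
        labels = {role: label_rotamer(a) for role, a in zip(roles, row)}
        key = _assemble_key(labels, molecule_class)
        counts[key] = counts.get(key, 0) + 1
    n = len(traj)
    return {k: v / n for k, v in sorted(counts.items())}


@dataclass
class FreeEnergyTable:
    """Relative Gibbs free energies (kJ/mol) of conformers at temperature T."""

    values: dict[str, float]
    T: float = 298.15

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("free-energy table is empty")
        lo = min(self.values.values())
        # store relative to the minimum so the invariant min dG = 0 holds
        self.values = {k: float(v - lo) for k, v in self.values.items()}
        if self.T <= 0:
            raise ValueError("temperature must be positive")


def boltzmann_populations(fet: FreeEnergyTable) -> dict[str, float]:
    """Boltzmann weights ``p_i = exp(-dG_i / RT) / sum_j exp(-dG_j / RT)``."""
    keys = sorted(fet.values)
    dg = np.array([fet.values[k] for k in keys])
    w = np.exp(-(dg - dg.min()) / (KB * fet.T))
    w /= w.sum()
    return dict(zip(keys, w.tolist()))


def has_imhb(
    conf: Conformation,
    donor_h: int,
    acceptor: int,
    threshold: float = 2.5,
) -> bool:
    """Flag an intramolecular hydrogen bond by donor-H / acceptor distance.

    Default geometric criterion: H...acceptor distance below 2.5 Angstrom
    in the given (typically minimized) geometry.
    """
    d = float(np.linalg.norm(conf.coords[donor_h] - conf.coords[acceptor]))
    return d < threshold
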