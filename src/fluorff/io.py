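"""File formats: multi-frame XYZ, structured-text parameter files, CSV tables.

All formats are plain text, tolerate Windows and Unix line endings, and
round-trip their domain objects losslessly.  The parameter format stores one
block per term class with an explicit unit header and can optionally carry
the topology (atoms, bonds, symmetry groups, dihedral roles) so a single
file fully specifies a molecule.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .forcefield import FFParameters
from .topology import Conformation, MoleculeTopology

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_params",
    "write_params",
    "read_table",
    "write_table",
]

PathLike = Union[str, Path]

FORMAT_VERSION = "1"


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------


def write_xyz(path: PathLike, confs: Sequence[Conformation], elements: Sequence[str]) -> None:
    """Multi-frame XYZ; the comment line carries ``energy=`` and ``tag=``."""
    with open(path, "w") as fh:
        for conf in confs:
            if conf.n_atoms != len(elements):
                raise ValueError("conformation atom count does not match element list")
            fields = []
            if conf.energy is not None:
                fields.append(f"energy={conf.energy:.10g}")
            if conf.tag:
                fields.append(f"tag={conf.tag}")
            fh.write(f"{conf.n_atoms}\n{' '.join(fields)}\n")
            for el, (x, y, z) in zip(elements, conf.coords):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path: PathLike) -> tuple[list[Conformation], list[str]]:
    """Read a multi-frame XYZ file; returns conformations and element list."""
    lines = Path(path).read_text().replace("\r\n", "\n").split("\n")
    confs: list[Conformation] = []
    elements: Optional[list[str]] = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}") from None
        if i + 1 + n >= len(lines) + 1:
            raise ParseError(f"{path}:{i + 1}: truncated frame (expected {n} atoms)")
        comment = lines[i + 1]
        energy, tag = None, None
        for tok in comment.split():
            if tok.startswith("energy="):
                energy = float(tok[7:])
            elif tok.startswith("tag="):
                tag = tok[4:]
        frame_el, xyz = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: expected 'element x y z'")
            frame_el.append(parts[0])
            try:
                xyz.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise ParseError(f"{path}:{i + 3 + j}: non-numeric coordinate") from None
        if elements is None:
            elements = frame_el
        elif frame_el != elements:
            raise ParseError(f"{path}:{i + 1}: frame element list differs from the first frame")
        confs.append(Conformation(np.asarray(xyz), energy=energy, tag=tag))
        i += 2 + n
    if elements is None:
        raise ParseError(f"{path}: no frames found")
    return confs, elements


# ---------------------------------------------------------------------------
# Parameter / topology files
# ---------------------------------------------------------------------------


def write_params(
    path: PathLike, params: FFParameters, topo: Optional[MoleculeTopology] = None
) -> None:
    """Structured-text parameter file, one block per term class."""
    with open(path, "w") as fh:
        fh.write(f"# fluorff parameters v{FORMAT_VERSION}\n")
        fh.write("# units: kJ/mol, Angstrom, radians, elementary charges\n")
        fh.write("[nonbonded_settings]\n")
        fh.write(f"coulomb_constant {params.coulomb_constant!r}\n")
        fh.write(f"scale_14_lj {params.scale_14_lj!r}\n")
        fh.write(f"scale_14_coul {params.scale_14_coul!r}\n")
        fh.write("[bonds]\n# i j K_b r_eq\n")
        for (i, j), (kb, req) in sorted(params.bond.items()):
            fh.write(f"{i} {j} {float(kb)!r} {float(req)!r}\n")
        fh.write("[angles]\n# i j k K_theta theta_eq\n")
        for (i, j, k), (kt, teq) in sorted(params.angle.items()):
            fh.write(f"{i} {j} {k} {float(kt)!r} {float(teq)!r}\n")
        fh.write("[dihedrals]\n# i j k l V_n n gamma_n\n")
        for quad, terms in sorted(params.dihedral.items()):
            for v, n, g in terms:
                fh.write(f"{quad[0]} {quad[1]} {quad[2]} {quad[3]} {float(v)!r} {int(n)} {float(g)!r}\n")
        fh.write("[lj]\n# i sigma epsilon\n")
        for i, (sig, eps) in sorted(params.lj.items()):
            fh.write(f"{i} {float(sig)!r} {float(eps)!r}\n")
        fh.write("[charges]\n# i q\n")
        for i, q in sorted(params.charges.items()):
            fh.write(f"{i} {float(q)!r}\n")
        if topo is not None:
            fh.write("[atoms]\n# index element\n")
            for el, i in topo.atoms:
                fh.write(f"{i} {el}\n")
            fh.write("[topology_bonds]\n")
            for i, j in topo.bonds:
                fh.write(f"{i} {j}\n")
            fh.write("[symmetry_groups]\n")
            for g in topo.symmetry_groups:
                fh.write(" ".join(str(a) for a in sorted(g)) + "\n")
            fh.write("[dihedral_roles]\n")
            for role, quad in sorted(topo.dihedral_roles.items()):
                fh.write(f"{role} {quad[0]} {quad[1]} {quad[2]} {quad[3]}\n")
            fh.write(f"[net_charge]\n{topo.net_charge}\n")


def read_params(path: PathLike) -> tuple[FFParameters, Optional[MoleculeTopology]]:
    """Read a parameter file; returns (params, topology-or-None)."""
    lines = Path(path).read_text().replace("\r\n", "\n").split("\n")
    section = None
    data: dict[str, list[tuple[int, str]]] = {}
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            data.setdefault(section, [])
            continue
        if section is None:
            raise ParseError(f"{path}:{ln}: content before the first section header")
        data[section].append((ln, line))

    def fail(ln: int, msg: str):
        raise ParseError(f"{path}:{ln}: {msg}")

    params = FFParameters()
    for ln, line in data.get("nonbonded_settings", []):
        key, val = line.split(maxsplit=1)
        setattr(params, key, float(val))
    for ln, line in data.get("bonds", []):
        p = line.split()
        if len(p) != 4:
            fail(ln, "bond line needs 'i j K_b r_eq'")
        params.bond[(int(p[0]), int(p[1]))] = (float(p[2]), float(p[3]))
    for ln, line in data.get("angles", []):
        p = line.split()
        if len(p) != 5:
            fail(ln, "angle line needs 'i j k K_theta theta_eq'")
        params.angle[(int(p[0]), int(p[1]), int(p[2]))] = (float(p[3]), float(p[4]))
    for ln, line in data.get("dihedrals", []):
        p = line.split()
        if len(p) != 7:
            fail(ln, "dihedral line needs 'i j k l V_n n gamma_n'")
        quad = tuple(int(v) for v in p[:4])
        params.dihedral.setdefault(quad, []).append((float(p[4]), int(p[5]), float(p[6])))
    for ln, line in data.get("lj", []):
        p = line.split()
        if len(p) != 3:
            fail(ln, "LJ line needs 'i sigma epsilon'")
        params.lj[int(p[0])] = (float(p[1]), float(p[2]))
    for ln, line in data.get("charges", []):
        p = line.split()
        if len(p) != 2:
            fail(ln, "charge line needs 'i q'")
        params.charges[int(p[0])] = float(p[1])

    topo = None
    if "atoms" in data:
        atoms = []
        for ln, line in data["atoms"]:
            p = line.split()
            atoms.append((p[1], int(p[0])))
        atoms.sort(key=lambda t: t[1])
        bonds = [tuple(int(v) for v in line.split()) for _, line in data.get("topology_bonds", [])]
        groups = [
            frozenset(int(v) for v in line.split()) for _, line in data.get("symmetry_groups", [])
        ]
        roles = {}
        for ln, line in data.get("dihedral_roles", []):
            p = line.split()
            roles[p[0]] = tuple(int(v) for v in p[1:5])
        net = 0
        for ln, line in data.get("net_charge", []):
            net = int(line)
        topo = MoleculeTopology(
            atoms=atoms,
            bonds=bonds,
            symmetry_groups=groups,
            dihedral_roles=roles,
            net_charge=net,
        )
    return params, topo


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def write_table(path: PathLike, df: pd.DataFrame, units: str = "") -> None:
    """CSV with a one-line ``#`` units header."""
    with open(path, "w") as fh:
        fh.write(f"# fluorff table v{FORMAT_VERSION}; units: {units}\n")
        df.to_csv(fh, index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
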