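"""Force-field energetics: torsion measurement, energy terms, analytic
forces, minimization, and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fluorff.constants import COULOMB_CONSTANT
from fluorff.forcefield import (
    DegenerateGeometryError,
    FFParameters,
    ParameterLookupError,
    SingularityError,
    compute_energy,
    compute_forces,
    measure_dihedral,
    minimize_conformation,
    set_dihedral,
)
from fluorff.topology import Conformation, MoleculeTopology


def chain_topology(n):
    return MoleculeTopology(atoms=[("C", i) for i in range(n)], bonds=[(i, i + 1) for i in range(n - 1)])


def chain_params(topo, kb=1000.0, req=1.5, kt=300.0, teq=1.9, dih=((5.0, 3, 0.0),), q=0.0):
    n = topo.n_atoms
    return FFParameters(
        bond={b: (kb, req) for b in topo.bonds},
        angle={a: (kt, teq) for a in topo.angles},
        dihedral={d: list(dih) for d in topo.dihedral_quads},
        lj={i: (3.4, 0.3) for i in range(n)},
        charges={i: q * (-1) ** i for i in range(n)},
    )


# ---------------------------------------------------------------------------
# measure_dihedral
# ---------------------------------------------------------------------------


class TestMeasureDihedral:
    def test_planar_anti_reports_minus_180(self):
        conf = Conformation(np.array([[0, 1, 0], [1, 0, 0], [2, 0, 0], [3, -1, 0.0]]))
        assert measure_dihedral(conf, (0, 1, 2, 3)) == pytest.approx(-180.0)

    def test_planar_syn_reports_zero(self):
        conf = Conformation(np.array([[0, 1, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]]))
        assert measure_dihedral(conf, (0, 1, 2, 3)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("angle", [60.0, -60.0, 150.0, -179.0, 1.0])
    def test_explicit_rotation_from_syn(self, angle):
        # rotate the distal atom about the 2-3 axis by the right-hand rule
        syn = np.array([[0, 1, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        axis = np.array([1.0, 0.0, 0.0])
        p = syn.copy()
        p[3] = Rotation.from_rotvec(np.radians(angle) * axis).apply(p[3] - p[2]) + p[2]
        assert measure_dihedral(Conformation(p), (0, 1, 2, 3)) == pytest.approx(angle, abs=1e-9)

    def test_collinear_raises(self):
        conf = Conformation(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]]))
        with pytest.raises(DegenerateGeometryError):
            measure_dihedral(conf, (0, 1, 2, 3))

    def test_set_dihedral_roundtrip(self, toy_mono):
        topo, _, conf = toy_mono
        quad = topo.dihedral_roles["phi"]
        for target in (-120.0, 45.0, 179.0):
            moved = set_dihedral(conf, topo, quad, target)
            assert measure_dihedral(moved, quad) == pytest.approx(target, abs=1e-8)


# ---------------------------------------------------------------------------
# compute_energy
# ---------------------------------------------------------------------------


class TestComputeEnergy:
    def test_single_bond_closed_form(self):
        topo = chain_topology(2)
        params = FFParameters(bond={(0, 1): (1000.0, 1.5)}, lj={0: (3.4, 0.0), 1: (3.4, 0.0)}, charges={0: 0, 1: 0})
        conf = Conformation(np.array([[0, 0, 0], [1.6, 0, 0.0]]))
        e = compute_energy(conf, topo, params)
        assert e.bond == pytest.approx(10.0)  # K (r-r_eq)^2 = 1000 * 0.01
        assert e.total == pytest.approx(sum([e.bond, e.angle, e.dihedral, e.lj, e.coulomb]), rel=1e-9)

    def test_coulomb_pair_closed_form(self):
        # two unbonded atoms: unit opposite charges at 3 A
        topo = MoleculeTopology(atoms=[("C", 0), ("C", 1)], bonds=[])
        params = FFParameters(lj={0: (3.4, 0.0), 1: (3.4, 0.0)}, charges={0: 1.0, 1: -1.0})
        conf = Conformation(np.array([[0, 0, 0], [3.0, 0, 0.0]]))
        e = compute_energy(conf, topo, params)
        assert e.coulomb == pytest.approx(-COULOMB_CONSTANT / 3.0)
        assert e.coulomb == pytest.approx(-463.1182)

    def test_lj_minimum_is_minus_epsilon(self):
        topo = MoleculeTopology(atoms=[("C", 0), ("C", 1)], bonds=[])
        params = FFParameters(lj={0: (3.0, 0.5), 1: (3.0, 0.5)}, charges={0: 0.0, 1: 0.0})
        conf = Conformation(np.array([[0, 0, 0], [3.0 * 2 ** (1 / 6), 0, 0.0]]))
        assert compute_energy(conf, topo, params).lj == pytest.approx(-0.5)

    def test_missing_parameter_names_term(self):
        topo = chain_topology(3)
        params = chain_params(topo)
        del params.angle[(0, 1, 2)]
        conf = Conformation(np.array([[0, 0, 0], [1.5, 0, 0], [2.3, 1.2, 0.0]]))
        with pytest.raises(ParameterLookupError, match=r"angle.*\(0, 1, 2\)"):
            compute_energy(conf, topo, params)

    def test_overlapping_atoms_raise(self):
        topo = MoleculeTopology(atoms=[("C", 0), ("C", 1)], bonds=[])
        params = FFParameters(lj={0: (3.4, 0.3), 1: (3.4, 0.3)}, charges={0: 0.1, 1: 0.1})
        conf = Conformation(np.array([[0, 0, 0], [1e-8, 0, 0.0]]))
        with pytest.raises(SingularityError):
            compute_energy(conf, topo, params)

    def test_rigid_motion_invariance(self, toy_mono, rng):
        topo, params, conf = toy_mono
        e0 = compute_energy(conf, topo, params)
        rot = Rotation.from_rotvec(rng.normal(size=3))
        shifted = Conformation(rot.apply(conf.coords) + rng.normal(size=3) * 10.0)
        e1 = compute_energy(shifted, topo, params)
        for term in ("bond", "angle", "dihedral", "lj", "coulomb"):
            assert abs(getattr(e0, term) - getattr(e1, term)) < 1e-8


# ---------------------------------------------------------------------------
# compute_forces
# ---------------------------------------------------------------------------


class TestComputeForces:
    def test_zero_at_exact_minimum(self):
        # both bonds at r_eq, angle at theta_eq, no other terms
        topo = chain_topology(3)
        teq = 1.9
        params = FFParameters(
            bond={b: (1000.0, 1.5) for b in topo.bonds},
            angle={(0, 1, 2): (300.0, teq)},
            lj={i: (3.4, 0.0) for i in range(3)},
            charges={i: 0.0 for i in range(3)},
        )
        c = np.array(
            [[1.5 * np.cos(teq), 1.5 * np.sin(teq), 0.0], [0, 0, 0], [1.5, 0, 0.0]]
        )
        f = compute_forces(Conformation(c), topo, params)
        assert np.linalg.norm(f) < 1e-8

    def test_stretched_bond_closed_form(self):
        topo = chain_topology(2)
        params = FFParameters(bond={(0, 1): (1000.0, 1.5)}, lj={0: (3.4, 0.0), 1: (3.4, 0.0)}, charges={0: 0, 1: 0})
        conf = Conformation(np.array([[0, 0, 0], [1.7, 0, 0.0]]))
        f = compute_forces(conf, topo, params)
        # magnitude 2 K (r - r_eq) = 400 on each atom, opposite directions
        assert f[0, 0] == pytest.approx(400.0)
        assert f[1, 0] == pytest.approx(-400.0)

    def test_finite_difference_agreement(self, rng):
        topo = chain_topology(5)
        params = chain_params(topo, dih=((5.0, 3, 0.0), (1.0, 1, np.pi)), q=0.08)
        base = np.array([[i * 1.4, 0.3 * (i % 2), 0.05 * i * i] for i in range(5)])
        h = 1e-5
        for _ in range(100):
            x = base + rng.normal(scale=0.25, size=(5, 3))
            f = compute_forces(Conformation(x), topo, params)
            fd = np.zeros_like(f)
            for i in range(5):
                for k in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[i, k] += h
                    xm[i, k] -= h
                    fd[i, k] = -(
                        compute_energy(Conformation(xp), topo, params).total
                        - compute_energy(Conformation(xm), topo, params).total
                    ) / (2 * h)
            scale = max(np.max(np.abs(fd)), 1.0)
            assert np.max(np.abs(f - fd)) / scale < 1e-4


# ---------------------------------------------------------------------------
# minimize_conformation
# ---------------------------------------------------------------------------


class TestMinimize:
    def test_start_at_minimum_returns_input(self):
        topo = chain_topology(2)
        params = FFParameters(bond={(0, 1): (1000.0, 1.5)}, lj={0: (3.4, 0.0), 1: (3.4, 0.0)}, charges={0: 0, 1: 0})
        conf = Conformation(np.array([[0, 0, 0], [1.5, 0, 0.0]]))
        out = minimize_conformation(conf, topo, params, tol=1e-6)
        assert np.allclose(out.coords, conf.coords, atol=1e-6)

    def test_stretched_bond_relaxes_to_r_eq(self):
        topo = chain_topology(2)
        params = FFParameters(bond={(0, 1): (1000.0, 1.5)}, lj={0: (3.4, 0.0), 1: (3.4, 0.0)}, charges={0: 0, 1: 0})
        conf = Conformation(np.array([[0, 0, 0], [2.1, 0, 0.0]]))
        out = minimize_conformation(conf, topo, params, tol=1e-8)
        assert np.linalg.norm(out.coords[1] - out.coords[0]) == pytest.approx(1.5, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_energy_never_increases(self, toy_mono, seed):
        topo, params, conf = toy_mono
        rng = np.random.default_rng(seed)
        start = Conformation(conf.coords + rng.normal(scale=0.15, size=conf.coords.shape))
        e0 = compute_energy(start, topo, params).total
        out = minimize_conformation(start, topo, params, tol=1e-4)
        assert out.energy <= e0 + 1e-12


# ---------------------------------------------------------------------------
# exclusion bookkeeping
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n", [4, 5, 8])
def test_linear_chain_exclusion_counts(n):
    topo = chain_topology(n)
    assert len(topo.pairs_14) == n - 3
    assert len(topo.exclusions_12_13) == (n - 1) + (n - 2)
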