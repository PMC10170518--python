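"""Reparametrization: objective terms, regularization, optimization and
parameter recovery from energies generated by a known force field."""

import numpy as np
import pytest

from fluorff.forcefield import compute_energy
from fluorff.reparam import (
    ParamVector,
    TrainingSet,
    energy_term_XU,
    flatten_bonded,
    optimize_parameters,
    regularization_theta,
    split_train_test,
    total_objective,
    unflatten_bonded,
)
from fluorff.synthetic import ToyMoleculeSpec, make_toy_molecule, perturb_conformations
from fluorff.topology import Conformation


def training_from_ff(topo, params, conf, n, seed=0, coord_scale=0.06):
    confs = perturb_conformations(conf, topo, n, coord_scale=coord_scale, seed=seed)
    e = np.array([compute_energy(c, topo, params).total for c in confs])
    return TrainingSet(confs, e)


def fake_training(u_ref, u_mm_offset):
    """Trivial training set carrier for direct X_U arithmetic checks."""
    return np.asarray(u_ref, float), np.asarray(u_mm_offset, float)


class TestEnergyTermXU:
    def _xu(self, topo, params, training):
        return energy_term_XU(params, topo, training)

    def test_perfect_model_gives_zero(self, toy_chain):
        topo, params, conf = toy_chain
        training = training_from_ff(topo, params, conf, 40)
        assert self._xu(topo, params, training) == pytest.approx(0.0, abs=1e-20)

    def test_constant_shift_invariance(self, toy_chain):
        topo, params, conf = toy_chain
        training = training_from_ff(topo, params, conf, 40)
        shifted = TrainingSet(training.conformations, training.ref_energies + 57.3)
        assert self._xu(topo, params, shifted) == pytest.approx(0.0, abs=1e-16)

    def test_hand_computed_value(self):
        # U_ref = (0, 10, 20), U_model = (0, 10, 30), uniform weights:
        # residuals (0, 0, -10), mean residual -10/3, centered (10/3, 10/3, -20/3);
        # sum w (d - dbar)^2 = (1/3)(600/9) = 22.222; Var(U_ref) = 66.667
        # (population) -> X_U = 22.222 / 66.667 = 1/3
        from fluorff.reparam import _xu_from_energies

        u_ref = np.array([0.0, 10.0, 20.0])
        u_mm = np.array([0.0, 10.0, 30.0])
        w = np.full(3, 1 / 3)
        assert np.var(u_ref) == pytest.approx(66.667, abs=1e-3)
        assert _xu_from_energies(u_ref, u_mm, w) == pytest.approx(0.3333, abs=1e-4)

    def test_zero_variance_raises(self, toy_chain):
        topo, params, conf = toy_chain
        confs = perturb_conformations(conf, topo, 5, seed=1)
        training = TrainingSet(confs, np.full(5, 7.0))
        with pytest.raises(ValueError, match="variance"):
            energy_term_XU(params, topo, training)


class TestRegularization:
    def _pvec(self, dev=None, n=4, alpha=None):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        if dev is not None:
            values = values + dev
        return ParamVector(
            values=values,
            priors=np.array([1.0, 2.0, 3.0, 4.0]),
            widths=np.array([0.5, 1.0, 2.0, 4.0]),
            mask=np.ones(4, dtype=bool),
            kinds=["bond_K"] * 4,
            labels=[f"p{i}" for i in range(4)],
            alpha=alpha,
        )

    def test_zero_at_prior(self):
        assert regularization_theta(self._pvec()) == 0.0

    def test_one_width_deviation_with_alpha_one_over_np(self):
        # one parameter deviated by exactly its width, alpha = 1/4 -> 0.25
        p = self._pvec(dev=np.array([0.5, 0, 0, 0.0]))
        assert p.effective_alpha() == 0.25
        assert regularization_theta(p) == pytest.approx(0.25)

    def test_quadratic_scaling(self):
        p1 = self._pvec(dev=np.array([0, 1.0, 0, 0.0]), alpha=1.0)
        p2 = self._pvec(dev=np.array([0, 2.0, 0, 0.0]), alpha=1.0)
        assert regularization_theta(p2) == pytest.approx(4 * regularization_theta(p1))


class TestTotalObjective:
    def test_additivity_and_independent_recomputation(self, toy_chain, rng):
        topo, params, conf = toy_chain
        training = training_from_ff(topo, params, conf, 30)
        pvec = flatten_bonded(params)
        pvec.values[0] *= 1.1  # deviate one entry so Theta > 0
        deviated = unflatten_bonded(params, pvec.values)
        obj = total_objective(deviated, topo, training, pvec)
        xu = energy_term_XU(deviated, topo, training)
        th = regularization_theta(pvec)
        assert obj == pytest.approx(xu + th, rel=1e-12)
        assert th > 0

    def test_zero_at_perfect_fit_with_prior(self, toy_chain):
        topo, params, conf = toy_chain
        training = training_from_ff(topo, params, conf, 30)
        pvec = flatten_bonded(params)
        assert total_objective(params, topo, training, pvec) == pytest.approx(0.0, abs=1e-18)


def perturb_force_constants(params, frac, seed):
    rng = np.random.default_rng(seed)
    out = params.copy()
    for k in sorted(out.bond):
        kb, req = out.bond[k]
        out.bond[k] = (kb * (1 + frac * rng.choice([-1, 1])), req)
    for k in sorted(out.angle):
        kt, teq = out.angle[k]
        out.angle[k] = (kt * (1 + frac * rng.choice([-1, 1])), teq)
    for k in sorted(out.dihedral):
        out.dihedral[k] = [(v * (1 + frac * rng.choice([-1, 1])), n, g) for v, n, g in out.dihedral[k]]
    return out


def max_force_constant_error(tuned, truth):
    errs = []
    for k in truth.bond:
        errs.append(abs(tuned.bond[k][0] - truth.bond[k][0]) / truth.bond[k][0])
    for k in truth.angle:
        errs.append(abs(tuned.angle[k][0] - truth.angle[k][0]) / truth.angle[k][0])
    for k in truth.dihedral:
        for (vt, _, _), (vr, _, _) in zip(tuned.dihedral[k], truth.dihedral[k]):
            errs.append(abs(vt - vr) / abs(vr))
    return max(errs)


class TestOptimizeParameters:
    def test_self_generated_energies_leave_parameters_unchanged(self, toy_chain):
        topo, params, conf = toy_chain
        training = training_from_ff(topo, params, conf, 100)
        tuned, trace = optimize_parameters(params, topo, training)
        assert trace["final_objective"] <= trace["initial_objective"] + 1e-15
        assert trace["initial_objective"] == pytest.approx(0.0, abs=1e-15)
        assert max_force_constant_error(tuned, params) < 1e-6

    def test_recovery_from_perturbed_start(self, toy_chain):
        topo, truth, conf = toy_chain
        training = training_from_ff(topo, truth, conf, 500, seed=7)
        start = perturb_force_constants(truth, 0.20, seed=11)
        tuned, _ = optimize_parameters(start, topo, training, alpha=0.0)
        assert max_force_constant_error(tuned, truth) < 0.05
        test_set = training_from_ff(topo, truth, conf, 200, seed=8)
        assert energy_term_XU(tuned, topo, test_set) < 1e-3

    def test_tight_priors_pin_parameters(self, toy_chain):
        topo, truth, conf = toy_chain
        training = training_from_ff(topo, truth, conf, 80, seed=3)
        start = perturb_force_constants(truth, 0.2, seed=4)
        tight = lambda kind, p0: 1e-6 * (abs(p0) + 1.0)
        tuned, _ = optimize_parameters(start, topo, training, alpha=1e6, width_fn=tight)
        assert max_force_constant_error(tuned, start) < 1e-4

    def test_phases_untouched_by_default(self, toy_chain):
        topo, truth, conf = toy_chain
        training = training_from_ff(topo, truth, conf, 60, seed=5)
        start = perturb_force_constants(truth, 0.2, seed=6)
        tuned, _ = optimize_parameters(start, topo, training)
        for k in start.dihedral:
            for (_, _, g0), (_, _, g1) in zip(start.dihedral[k], tuned.dihedral[k]):
                assert g1 == g0
                assert g1 in (0.0, np.pi)


class TestSplitTrainTest:
    def test_disjoint_sizes_and_reproducibility(self, toy_chain):
        topo, params, conf = toy_chain
        confs = perturb_conformations(conf, topo, 50, seed=2)
        e = np.arange(50.0)
        tr1, te1 = split_train_test(confs, e, 20, 25, seed=42)
        tr2, te2 = split_train_test(confs, e, 20, 25, seed=42)
        assert len(tr1) == 20 and len(te1) == 25
        assert not (set(tr1.ref_energies) & set(te1.ref_energies))
        assert np.array_equal(tr1.ref_energies, tr2.ref_energies)
        assert np.array_equal(te1.ref_energies, te2.ref_energies)

    def test_oversubscription_raises(self, toy_chain):
        topo, params, conf = toy_chain
        confs = perturb_conformations(conf, topo, 10, seed=2)
        with pytest.raises(ValueError):
            split_train_test(confs, np.arange(10.0), 8, 5, seed=0)
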