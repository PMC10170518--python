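"""Samplers: leapfrog integrator properties, hybrid MC ergodicity on
analytic targets, and nested MC-MC recovery of the high-level ensemble."""

import numpy as np
import pytest

from fluorff.constants import FEMTOSECOND, KB
from fluorff.sampling import (
    MCSettings,
    PotentialHandle,
    hmc_chain,
    leapfrog,
    metropolis_chain,
    nmcmc_run,
)

T = 300.0


def harmonic(k):
    return PotentialHandle(
        energy=lambda x: 0.5 * k * float(np.sum(x * x)),
        forces=lambda x: -k * x,
        label=f"harmonic-{k}",
    )


def shifted(pot, c):
    return PotentialHandle(
        energy=lambda x: pot.energy(x) + c, forces=pot.forces, label=pot.label + "+c"
    )


def double_well(a=0.05, b=4.0):
    # U(x) = a (x^2 - b)^2, minima at +-2 when b = 4
    return PotentialHandle(
        energy=lambda x: a * float(np.sum((x * x - b) ** 2)),
        forces=lambda x: -4.0 * a * (x * x - b) * x,
        label="double-well",
    )


class TestLeapfrog:
    def test_free_particle_drifts_linearly(self):
        pot = PotentialHandle(energy=lambda x: 0.0, forces=lambda x: np.zeros_like(x))
        x0 = np.array([1.0, -2.0])
        p0 = np.array([3.0, 0.5])
        m = 2.0
        x1, p1 = leapfrog(x0, p0, pot, m, dt=1.0, n=50)
        assert x1 == pytest.approx(x0 + p0 / m * 50 * FEMTOSECOND)
        assert p1 == pytest.approx(p0)

    def test_harmonic_period_accuracy(self):
        # one full period of a 1-D oscillator returns near the start, O(dt^2)
        k, m = 100.0, 3.0
        omega = np.sqrt(k / m)
        period = 2 * np.pi / omega  # internal time units
        dt_fs = 0.5
        n = int(round(period / (dt_fs * FEMTOSECOND)))
        x0, p0 = np.array([0.7]), np.array([0.0])
        x1, p1 = leapfrog(x0, p0, harmonic(k), m, dt=dt_fs, n=n)
        # error bound: O(dt^2) in the step plus the period rounding remainder
        assert abs(x1[0] - x0[0]) < 5e-3

    def test_time_reversibility(self, rng):
        pot = double_well()
        x0 = rng.normal(size=4)
        p0 = rng.normal(size=4)
        x1, p1 = leapfrog(x0, p0, pot, 1.5, dt=2.0, n=37)
        x2, p2 = leapfrog(x1, -p1, pot, 1.5, dt=2.0, n=37)
        assert np.max(np.abs(x2 - x0)) < 1e-8
        assert np.max(np.abs(-p2 - p0)) < 1e-8


class TestHMC:
    def test_tiny_step_acceptance_near_one(self):
        chain, acc = hmc_chain(
            harmonic(50.0), T, np.array([0.2]), 5.0, dt=0.01, n_leapfrog=5, n_moves=200,
            rng=np.random.default_rng(0),
        )
        assert acc > 0.999

    def test_harmonic_variance_matches_kT_over_k(self):
        k, m = 50.0, 12.0
        n = 50_000
        chain, acc = hmc_chain(
            harmonic(k), T, np.array([0.0]), m, dt=1.0, n_leapfrog=20, n_moves=n,
            rng=np.random.default_rng(7),
        )
        xs = np.array([c[0] for c in chain])
        target = KB * T / k
        # 3 standard errors of the sample variance (weak autocorrelation at
        # full momentum refresh makes iid SE a fair scale)
        se = target * np.sqrt(2.0 / n) * 3
        assert abs(xs.var() - target) < max(se, 0.02 * target)

    def test_constant_shift_gauge_invariance(self):
        pot = harmonic(80.0)
        kwargs = dict(dt=1.0, n_leapfrog=10, n_moves=300)
        c1, a1 = hmc_chain(pot, T, np.array([0.3]), 4.0, rng=np.random.default_rng(3), **kwargs)
        c2, a2 = hmc_chain(
            shifted(pot, 123.4), T, np.array([0.3]), 4.0, rng=np.random.default_rng(3), **kwargs
        )
        assert a1 == a2
        assert np.array_equal(np.array(c1), np.array(c2))


class TestNestedMCMC:
    def test_identical_potentials_equal_temperatures_accept_all(self):
        pot = harmonic(60.0)
        settings = MCSettings(T_low=T, T_target=T, dt=1.0, n_leapfrog=10, sweeps=300, seed=5)
        rep = nmcmc_run(pot, pot, settings, np.array([0.1]), 8.0)
        assert rep.switch_acceptance == 1.0

    def test_high_level_moments_match_analytic(self):
        # low: soft harmonic; high: stiffer harmonic; same temperature;
        # leapfrog trajectories long enough to decorrelate the inner chain
        k1, k2 = 50.0, 120.0
        settings = MCSettings(T_low=T, T_target=T, dt=5.0, n_leapfrog=60, sweeps=50_000, seed=6)
        rep = nmcmc_run(harmonic(k1), harmonic(k2), settings, np.array([0.1]), 12.0)
        xs = np.array([e[0] for e in rep.ensemble])
        target = KB * T / k2
        # batch-means Monte Carlo standard errors (50 batches)
        batches = xs.reshape(50, -1)
        se_mean = batches.mean(axis=1).std(ddof=1) / np.sqrt(50)
        se_var = batches.var(axis=1).std(ddof=1) / np.sqrt(50)
        assert abs(xs.mean()) < 3 * se_mean
        assert abs(xs.var() - target) < 3 * se_var

    def test_double_well_histogram_matches_direct_metropolis(self):
        low = harmonic(1.0)
        high = double_well()
        settings = MCSettings(T_low=T, T_target=T, dt=8.0, n_leapfrog=60, sweeps=40_000, seed=8)
        rep = nmcmc_run(low, high, settings, np.array([2.0]), 2.0)
        xs = np.array([e[0] for e in rep.ensemble])
        chain, _ = metropolis_chain(high, T, step_size=0.9, n=200_000, seed=9, start=np.array([2.0]))
        ys = np.array([c[0] for c in chain])
        bins = np.linspace(-4, 4, 33)
        p, _ = np.histogram(xs, bins=bins, density=False)
        q, _ = np.histogram(ys, bins=bins, density=False)
        tv = 0.5 * np.sum(np.abs(p / p.sum() - q / q.sum()))
        assert tv < 0.05

    def test_switch_acceptance_decreases_with_perturbation(self):
        accs = []
        for k2 in (50.0, 80.0, 150.0):
            settings = MCSettings(T_low=T, T_target=T, dt=1.0, n_leapfrog=10, sweeps=3000, seed=11)
            rep = nmcmc_run(harmonic(50.0), harmonic(k2), settings, np.array([0.1]), 10.0)
            accs.append(rep.switch_acceptance)
        assert accs[0] == 1.0
        assert accs[0] > accs[1] > accs[2]

    def test_determinism_per_seed(self):
        settings = MCSettings(T_low=T, T_target=T, dt=1.0, n_leapfrog=8, sweeps=200, seed=13)
        rep1 = nmcmc_run(harmonic(40.0), harmonic(90.0), settings, np.array([0.2]), 5.0)
        rep2 = nmcmc_run(harmonic(40.0), harmonic(90.0), settings, np.array([0.2]), 5.0)
        assert np.array_equal(np.array(rep1.ensemble), np.array(rep2.ensemble))
        assert rep1.switch_acceptance == rep2.switch_acceptance


class TestMetropolis:
    def test_harmonic_variance(self):
        k = 70.0
        chain, acc = metropolis_chain(harmonic(k), T, step_size=0.5, n=100_000, seed=1, start=np.array([0.0]))
        xs = np.array([c[0] for c in chain])
        target = KB * T / k
        assert 0.0 < acc < 1.0
        assert abs(xs.var() - target) < 0.05 * target

    def test_constant_shift_invariance(self):
        pot = harmonic(70.0)
        c1, a1 = metropolis_chain(pot, T, 0.5, 500, seed=2, start=np.array([0.1]))
        c2, a2 = metropolis_chain(shifted(pot, 55.0), T, 0.5, 500, seed=2, start=np.array([0.1]))
        assert a1 == a2
        assert np.array_equal(np.array(c1), np.array(c2))
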