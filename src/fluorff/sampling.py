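"""Hybrid Monte Carlo and nested Markov chain Monte Carlo samplers.

The nested scheme runs a cheap inner chain (here hybrid MC on a low-level
potential at a boosted temperature) and periodically proposes its current
state to an outer Metropolis test against an expensive high-level potential
at the target temperature.  Accepted proposals enter the high-level
ensemble; on rejection the inner chain is reset to the last accepted
high-level state, which keeps the outer chain's invariant distribution equal
to the high-level Boltzmann distribution.

States are plain numpy arrays (any shape); molecular conformations pass
their ``(N, 3)`` coordinate arrays.  Masses broadcast against the state, so
one mass per atom serves all three Cartesian components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .constants import FEMTOSECOND, KB, mass_of
from .forcefield import FFParameters, compute_energy, compute_forces
from .topology import Conformation, MoleculeTopology

__all__ = [
    "PotentialHandle",
    "MCSettings",
    "SamplerReport",
    "make_ff_potential",
    "leapfrog",
    "hmc_chain",
    "nmcmc_run",
    "metropolis_chain",
]


class DivergenceError(FloatingPointError):
    """The integrator produced a non-finite energy (trajectory blow-up)."""


@dataclass
class PotentialHandle:
    """A potential energy surface: energy and forces as callables on a state."""

    energy: Callable[[np.ndarray], float]
    forces: Callable[[np.ndarray], np.ndarray]
    label: str = ""


def make_ff_potential(topo: MoleculeTopology, params: FFParameters, label: str = "FF") -> PotentialHandle:
    """Wrap a force field as a potential over raw coordinate arrays."""
    return PotentialHandle(
        energy=lambda x: compute_energy(Conformation(x), topo, params).total,
        forces=lambda x: compute_forces(Conformation(x), topo, params),
        label=label,
    )


@dataclass
class MCSettings:
    """Sampler settings.

    ``dt`` is the leapfrog time step in femtoseconds; ``switch_period`` is
    the number of inner hybrid-MC moves between promotion attempts to the
    high-level ensemble.
    """

    T_low: float = 350.0
    T_target: float = 300.0
    dt: float = 1.0
    n_leapfrog: int = 100
    sweeps: int = 25_000
    switch_period: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_low <= 0 or self.T_target <= 0:
            raise ValueError("temperatures must be positive")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.n_leapfrog < 1:
            raise ValueError("n_leapfrog must be >= 1")


@dataclass
class SamplerReport:
    ensemble: list = field(default_factory=list)
    energies: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hmc_acceptance: float = 0.0
    switch_acceptance: float = 0.0


def masses_for(topo: MoleculeTopology) -> np.ndarray:
    """Per-atom masses (amu), shaped to broadcast against (N, 3) coords."""
    return np.array([mass_of(el) for el in topo.elements])[:, None]


def leapfrog(
    x: np.ndarray,
    p: np.ndarray,
    potential: PotentialHandle,
    masses: np.ndarray | float,
    dt: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity-Verlet (kick-drift-kick) integration of n steps.

    Symplectic and time-reversible: integrating from ``(x', -p')`` returns
    to the start.  ``dt`` is in femtoseconds.
    """
    h = dt * FEMTOSECOND
    x = np.array(x, dtype=float)
    p = np.array(p, dtype=float)
    f = potential.forces(x)
    p = p + 0.5 * h * f
    for step in range(n):
        x = x + h * p / masses
        f = potential.forces(x)
        if not np.all(np.isfinite(f)):
            raise DivergenceError("non-finite forces during leapfrog integration")
        p = p + (h if step < n - 1 else 0.5 * h) * f
    e = potential.energy(x)
    if not np.isfinite(e):
        raise DivergenceError("non-finite energy at end of leapfrog trajectory")
    return x, p


def _kinetic(p: np.ndarray, masses) -> float:
    return float(np.sum(p * p / (2.0 * masses)))


def hmc_chain(
    potential: PotentialHandle,
    T: float,
    start: np.ndarray,
    masses: np.ndarray | float,
    dt: float = 1.0,
    n_leapfrog: int = 100,
    n_moves: int = 1000,
    rng: Optional[np.random.Generator] = None,
    record: bool = True,
) -> tuple[list[np.ndarray], float]:
    """Hybrid MC chain with full momentum refreshment each move.

    Momenta are resampled from the Maxwell distribution at ``T`` and the
    move is accepted with probability ``min(1, exp(-dH / kB T))``, giving an
    invariant distribution proportional to ``exp(-U / kB T)``.
    Returns the recorded chain (state after each move) and the acceptance
    fraction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    x = np.array(start, dtype=float)
    u = potential.energy(x)
    chain: list[np.ndarray] = []
    accepted = 0
    sigma_shape = np.broadcast_shapes(x.shape, np.shape(masses))
    for move in range(n_moves):
        p = rng.normal(size=sigma_shape) * np.sqrt(np.asarray(masses, dtype=float) * KB * T)
        h0 = u + _kinetic(p, masses)
        try:
            x_new, p_new = leapfrog(x, p, potential, masses, dt, n_leapfrog)
            u_new = potential.energy(x_new)
            h1 = u_new + _kinetic(p_new, masses)
            ok = np.isfinite(h1) and (np.log(rng.uniform()) < -(h1 - h0) / (KB * T))
        except DivergenceError:
            ok = False
        if ok:
            x, u = x_new, u_new
            accepted += 1
        if record:
            chain.append(x.copy())
        if move == 999 and accepted == 0 and n_moves >= 1000:
            raise RuntimeError("zero hybrid-MC acceptance over 1000 moves; check dt/potential")
    return chain, accepted / max(n_moves, 1)


def nmcmc_run(
    low: PotentialHandle,
    high: PotentialHandle,
    settings: MCSettings,
    start: np.ndarray,
    masses: np.ndarray | float,
) -> SamplerReport:
    """Nested MC-MC: inner hybrid-MC chain on ``low`` at ``T_low``, outer
    Metropolis promotion to ``high`` at ``T_target``.

    Every ``switch_period`` inner moves the inner state ``x'`` is proposed
    against the last accepted high-level state ``x`` and accepted with
    probability ``min(1, exp(-[U_high(x') - U_high(x)] / kB T_target
    + [U_low(x') - U_low(x)] / kB T_low))``; on rejection the inner chain is
    reset to ``x``.  The high-level ensemble records the retained state at
    every promotion attempt (so its histogram follows the high-level
    Boltzmann distribution at ``T_target``).
    """
    rng = np.random.default_rng(settings.seed)
    x_low = np.array(start, dtype=float)
    x_hi = x_low.copy()
    u_low_hi = low.energy(x_hi)  # low-level energy of the accepted high state
    u_hi = high.energy(x_hi)
    if np.shape(low.forces(x_low)) != np.shape(x_low):
        raise ValueError("low-level force shape does not match the state")

    ensemble: list[np.ndarray] = []
    energies: list[float] = []
    hmc_acc_total = 0.0
    n_inner_batches = 0
    switch_attempts = switch_accepts = 0

    n_attempts = settings.sweeps // settings.switch_period
    for _ in range(n_attempts):
        chain, acc = hmc_chain(
            low,
            settings.T_low,
            x_low,
            masses,
            dt=settings.dt,
            n_leapfrog=settings.n_leapfrog,
            n_moves=settings.switch_period,
            rng=rng,
            record=True,
        )
        x_low = chain[-1]
        hmc_acc_total += acc
        n_inner_batches += 1

        u_low_new = low.energy(x_low)
        u_hi_new = high.energy(x_low)
        log_alpha = -(u_hi_new - u_hi) / (KB * settings.T_target) + (u_low_new - u_low_hi) / (
            KB * settings.T_low
        )
        switch_attempts += 1
        if np.log(rng.uniform()) < log_alpha:
            x_hi, u_hi, u_low_hi = x_low.copy(), u_hi_new, u_low_new
            switch_accepts += 1
        else:
            x_low = x_hi.copy()
        ensemble.append(x_hi.copy())
        energies.append(u_hi)

    return SamplerReport(
        ensemble=ensemble,
        energies=np.asarray(energies),
        hmc_acceptance=hmc_acc_total / max(n_inner_batches, 1),
        switch_acceptance=switch_accepts / max(switch_attempts, 1),
    )


def metropolis_chain(
    potential: PotentialHandle,
    T: float,
    step_size: float,
    n: int,
    seed: int,
    start: np.ndarray,
) -> tuple[list[np.ndarray], float]:
    """Random-walk Metropolis reference sampler (test oracle).

    Isotropic Gaussian proposals of scale ``step_size``; returns the chain
    and acceptance fraction.
    """
    rng = np.random.default_rng(seed)
    x = np.array(start, dtype=float)
    u = potential.energy(x)
    chain, accepted = [], 0
    for _ in range(n):
        x_new = x + rng.normal(scale=step_size, size=x.shape)
        u_new = potential.energy(x_new)
        if np.isfinite(u_new) and np.log(rng.uniform()) < -(u_new - u) / (KB * T):
            x, u = x_new, u_new
            accepted += 1
        chain.append(x.copy())
    return chain, accepted / max(n, 1)
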