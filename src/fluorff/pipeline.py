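"""End-to-end benchmark orchestration.

``run_benchmark`` chains every stage on a synthetic study system with known
ground truth: build a toy molecule, construct a surrogate high-level
reference potential, generate a reference ensemble with the nested MC-MC
sampler, split it into train/test sets, retune the bonded parameters
against the training energies, compare base and tuned force fields by
relative-energy-difference distributions on the test set, sample rotamer
populations with both force fields and score them against the reference
ensemble populations by the sum of absolute population errors, and finally
summarize the packaged J-coupling dataset.  All outputs are CSV plus a
manifest recording seeds and settings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conformers import trajectory_populations
from .forcefield import compute_energy
from .io import write_params, write_table, write_xyz
from .jcoupling import (
    REFERENCE_SOURCES,
    compare_model_to_reference,
    compare_to_experiment,
    reference_jcoupling_records,
)
from .metrics import distribution_summary, saep
from .reparam import energy_term_XU, optimize_parameters, split_train_test
from .sampling import MCSettings, SamplerReport, hmc_chain, make_ff_potential, masses_for, nmcmc_run
from .synthetic import (
    SurrogateReferenceSpec,
    ToyMoleculeSpec,
    make_surrogate_reference,
    make_toy_molecule,
)
from .topology import Conformation

__all__ = ["RunConfig", "run_benchmark"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one benchmark run.

    Default problem sizes are chosen so a full run completes in a few
    minutes on one CPU while every stage still has enough data to be
    statistically meaningful; they scale down the study design (tens of
    thousands of sampler sweeps, 1e4/3e4 train/test structures) by roughly
    an order of magnitude.
    """

    outdir: str = "benchmark_out"
    seed: int = 0
    n_heavy: int = 4
    perturbation_scale: float = 0.15
    cubic_bond_coeff: float = -150.0
    mc: MCSettings = field(
        default_factory=lambda: MCSettings(
            T_low=350.0, T_target=300.0, dt=1.0, n_leapfrog=15, sweeps=2500, switch_period=1
        )
    )
    n_train: int = 500
    n_test: int = 1500
    sampling_moves: int = 2000
    optimize_phases: bool = False
    alpha: float | None = None  # None -> 1/N_p


def run_benchmark(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the report directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    rng_seed = int(config.seed)

    # -- study system -------------------------------------------------------
    topo, base_params, conf0 = make_toy_molecule(
        ToyMoleculeSpec(n_heavy=config.n_heavy, pattern="mono", seed=rng_seed)
    )
    write_params(out / "base_ff.params", base_params, topo)
    masses = masses_for(topo)

    surrogate, _ = make_surrogate_reference(
        SurrogateReferenceSpec(
            base=base_params,
            perturbation_scale=config.perturbation_scale,
            cubic_bond_coeff=config.cubic_bond_coeff,
            seed=rng_seed,
        ),
        topo,
    )
    base_pot = make_ff_potential(topo, base_params, label="base-FF")

    # -- reference ensemble via nested MC-MC --------------------------------
    t0 = time.time()
    mc = MCSettings(**{**asdict(config.mc), "seed": rng_seed + 1})
    report: SamplerReport = nmcmc_run(base_pot, surrogate, mc, conf0.coords, masses)
    ensemble = [
        Conformation(x, energy=float(e), tag=f"nmcmc-{i}")
        for i, (x, e) in enumerate(zip(report.ensemble, report.energies))
    ]
    logger.info(
        "nMC-MC: %d states, hMC acceptance %.3f, switch acceptance %.3f (%.1f s)",
        len(ensemble),
        report.hmc_acceptance,
        report.switch_acceptance,
        time.time() - t0,
    )
    write_xyz(out / "reference_ensemble.xyz", ensemble[:: max(len(ensemble) // 500, 1)], topo.elements)

    # -- train/test split and reparametrization -----------------------------
    t0 = time.time()
    train, test = split_train_test(
        ensemble, report.energies, config.n_train, config.n_test, seed=rng_seed + 2
    )
    tuned_params, trace = optimize_parameters(
        base_params,
        topo,
        train,
        optimize_phases=config.optimize_phases,
        alpha=config.alpha,
    )
    write_params(out / "tuned_ff.params", tuned_params, topo)
    xu = {
        "base_train": energy_term_XU(base_params, topo, train),
        "tuned_train": energy_term_XU(tuned_params, topo, train),
        "base_test": energy_term_XU(base_params, topo, test),
        "tuned_test": energy_term_XU(tuned_params, topo, test),
    }
    logger.info("reparametrization: %s; X_U %s (%.1f s)", trace, xu, time.time() - t0)

    # -- energetic agreement on the test set --------------------------------
    rows = []
    ref_e = test.ref_energies
    i0 = int(np.argmin(ref_e))
    for label, params in (("base", base_params), ("tuned", tuned_params)):
        model_e = np.array([compute_energy(c, topo, params).total for c in test.conformations])
        dde = (model_e - model_e[i0]) - (ref_e - ref_e[i0])
        dde = np.delete(dde, i0)
        rmse, mu = distribution_summary(dde)
        rows.append({"model": label, "rmse_kJ_mol": rmse, "mean_kJ_mol": mu, "n": len(dde)})
    dde_df = pd.DataFrame(rows)
    write_table(out / "delta_delta_E.csv", dde_df, units="kJ/mol")

    # -- sampling accuracy: populations and SAEP -----------------------------
    t0 = time.time()
    ref_pops = trajectory_populations(ensemble, topo, "mono")
    saep_rows = []
    pop_tables = {"reference": ref_pops}
    for label, params in (("base", base_params), ("tuned", tuned_params)):
        pot = make_ff_potential(topo, params, label)
        chain, acc = hmc_chain(
            pot,
            mc.T_target,
            conf0.coords,
            masses,
            dt=mc.dt,
            n_leapfrog=mc.n_leapfrog,
            n_moves=config.sampling_moves,
            rng=np.random.default_rng(rng_seed + 3),
        )
        pops = trajectory_populations([Conformation(x) for x in chain], topo, "mono")
        pop_tables[label] = pops
        saep_rows.append({"model": label, "saep": saep(pops, ref_pops), "hmc_acceptance": acc})
    keys = sorted(set().union(*pop_tables.values()))
    pop_df = pd.DataFrame(
        [{"conformer": k, **{m: t.get(k, 0.0) for m, t in pop_tables.items()}} for k in keys]
    )
    write_table(out / "populations.csv", pop_df, units="probability")
    write_table(out / "saep.csv", pd.DataFrame(saep_rows), units="dimensionless")
    logger.info("population sampling done (%.1f s)", time.time() - t0)

    # -- J-coupling statistics from the packaged dataset ---------------------
    records = reference_jcoupling_records()
    j_rows = []
    for source in REFERENCE_SOURCES:
        rmse, r2 = compare_to_experiment(records, source)
        j_rows.append({"source": source, "vs": "experiment", "rmse_Hz": rmse, "r2": r2})
    for source in ("GAFF.MOD", "ANI-2x"):
        rmse, r2 = compare_model_to_reference(records, source, "wB97X")
        j_rows.append({"source": source, "vs": "wB97X", "rmse_Hz": rmse, "r2": r2})
    write_table(out / "jcoupling_stats.csv", pd.DataFrame(j_rows), units="Hz")

    # -- manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {**asdict(config), "mc": asdict(mc)},
        "hmc_acceptance": report.hmc_acceptance,
        "switch_acceptance": report.switch_acceptance,
        "X_U": xu,
        "reparam_trace": trace,
        "runtime_s": time.time() - t_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("benchmark complete in %.1f s -> %s", time.time() - t_start, out)
    return out
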