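"""Population-weighted NMR J-coupling averaging and agreement statistics.

A through-hydrogen-bond coupling ``1hJ(OH...F)`` is computed per conformer
and averaged over conformer populations; agreement with experiment is
summarized by RMSE and the squared Pearson correlation.  Experimental signs
of these couplings are typically undetermined, so comparisons against
experiment are made magnitude vs magnitude; comparisons between two computed
columns (both signs known) are made on the signed values.

The packaged reference dataset holds the experimental couplings of ten
gamma-fluorohydrins in chloroform (13 couplings; three molecules contribute
two inequivalent couplings each) together with the couplings predicted from
the conformer populations of two quantum-chemical levels (MP2 and the
wB97X functional), two force fields (GAFF and its retuned variant GAFF.MOD)
and the ANI-2x neural network potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JRecord",
    "REFERENCE_SOURCES",
    "reference_jcoupling_table",
    "reference_jcoupling_records",
    "ensemble_average_j",
    "compare_to_experiment",
    "compare_model_to_reference",
]

REFERENCE_SOURCES = ("MP2", "wB97X", "GAFF", "GAFF.MOD", "ANI-2x")

# (molecule, coupling id, exptl |J| in Hz, MP2, wB97X, GAFF, GAFF.MOD, ANI-2x)
_REFERENCE_ROWS = [
    ("syn-A", "syn-A", 6.6, -7.6, -16.5, -5.6, -16.1, -19.6),
    ("anti-A", "anti-A", 1.9, -1.1, -7.4, -2.6, -9.9, -13.0),
    ("B", "B", 2.2, -2.2, -9.2, -1.6, -10.8, -13.6),
    ("C", "C", 1.7, -1.2, -6.6, -1.1, -2.2, -5.8),
    ("D", "D", 1.4, -1.3, -6.7, -0.85, -5.4, -10.7),
    ("E", "E-1", 3.5, -3.2, -11.3, -7.7, -9.0, -5.3),
    ("E", "E-2", 1.4, -1.7, -1.0, -0.7, -0.6, -3.0),
    ("F", "F-1", 0.6, -0.6, -1.8, -0.25, -0.4, -0.3),
    ("F", "F-2", 0.6, -0.7, -2.8, -0.9, -4.1, -7.9),
    ("G", "G-1", 0.4, -0.1, -1.1, -0.06, -2.2, -2.7),
    ("G", "G-2", 0.4, -0.3, -2.0, -0.11, -2.3, -3.624),
    ("H", "H", 0.7, -0.8, -0.8, -0.92, -1.46, -2.68),
    ("I", "I", 0.3, -0.4, -1.0, 0.39, -1.29, -1.765),
]


@dataclass
class JRecord:
    """One coupling: experimental value plus per-source computed values."""

    molecule: str
    coupling_id: str
    experimental: float
    sign_known: bool = False
    computed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.computed:
            raise ValueError("at least one computed source is required")
        if not self.sign_known and self.experimental < 0:
            raise ValueError("sign-unknown experimental values are stored as magnitudes (>= 0)")


def reference_jcoupling_table() -> pd.DataFrame:
    """The packaged 13-row reference dataset as a DataFrame (values in Hz)."""
    return pd.DataFrame(
        _REFERENCE_ROWS, columns=["molecule", "coupling", "exptl", *REFERENCE_SOURCES]
    )


def reference_jcoupling_records() -> list[JRecord]:
    """The packaged reference dataset as :class:`JRecord` objects."""
    return [
        JRecord(
            molecule=mol,
            coupling_id=cid,
            experimental=expt,
            sign_known=False,
            computed=dict(zip(REFERENCE_SOURCES, vals)),
        )
        for mol, cid, expt, *vals in _REFERENCE_ROWS
    ]


def ensemble_average_j(js: Mapping[str, float], pops: Mapping[str, float]) -> float:
    """Population-weighted coupling ``sum_i p_i J_i`` in Hz.

    Every populated conformer must have a coupling value; conformers with a
    coupling but zero population are allowed.
    """
    missing = [k for k, p in pops.items() if p > 0 and k not in js]
    if missing:
        raise KeyError(f"no J value for populated conformer(s): {missing}")
    return float(sum(p * js[k] for k, p in pops.items() if k in js))


def _rmse_r2(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.var(a) <= 0 or np.var(b) <= 0:
        warnings.warn("zero variance in a comparison column; R^2 undefined", RuntimeWarning)
        return rmse, float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return rmse, r * r


def compare_to_experiment(records: Sequence[JRecord], source: str) -> tuple[float, float]:
    """``(RMSE in Hz, R^2)`` of one computed column against experiment.

    When any record's experimental sign is undetermined the comparison is
    made between magnitudes of the computed values and experimental
    magnitudes (the convention for sign-undetermined couplings); otherwise
    signed values are compared directly.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a meaningful comparison")
    comp = np.array([r.computed[source] for r in records], dtype=float)
    expt = np.array([r.experimental for r in records], dtype=float)
    if not all(r.sign_known for r in records):
        comp = np.abs(comp)
        expt = np.abs(expt)
    return _rmse_r2(comp, expt)


def compare_model_to_reference(
    records: Sequence[JRecord], source_a: str, source_b: str
) -> tuple[float, float]:
    """``(RMSE, R^2)`` between two computed columns, signed values."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a meaningful comparison")
    a = np.array([r.computed[source_a] for r in records], dtype=float)
    b = np.array([r.computed[source_b] for r in records], dtype=float)
    return _rmse_r2(a, b)
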