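"""Energetic, geometric and sampling agreement metrics.

* Relative energy differences (Delta Delta E) of a model against a
  reference, measured from each side's energy of the reference-minimum
  structure, so any global offset of either column cancels.
* Distribution summaries (RMSE about zero and mean).
* The sum of absolute population errors (SAEP), a total-variation-style
  divergence between two conformer population tables, bounded by [0, 2].
* Minimum atomic-position RMSD over rigid superposition (Kabsch algorithm
  with the determinant correction that forbids reflections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PairedEnergies",
    "delta_delta_E",
    "distribution_summary",
    "saep",
    "superposition_rmsd",
    "outlier_filter",
]


@dataclass
class PairedEnergies:
    """Per-structure model and reference energies (kJ/mol).

    ``reference_id`` names the structure with the lowest reference energy;
    relative energies of both columns are measured from it.
    """

    ids: list
    model: np.ndarray
    reference: np.ndarray
    reference_id: Optional[object] = None

    def __post_init__(self) -> None:
        self.model = np.asarray(self.model, dtype=float).ravel()
        self.reference = np.asarray(self.reference, dtype=float).ravel()
        if not (len(self.ids) == len(self.model) == len(self.reference)):
            raise ValueError("ids and energy columns must have equal length")
        if self.reference_id is None:
            self.reference_id = self.ids[int(np.argmin(self.reference))]
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not among ids")


def delta_delta_E(pe: PairedEnergies) -> dict:
    """Per-structure ``(E_i^X - E_0^X) - (E_i^ref - E_0^ref)`` in kJ/mol.

    The reference structure itself (identically zero) is excluded from the
    returned map, matching the practice of dropping the reference point from
    error summaries.  Warns when the declared reference is not the
    reference-energy minimum.
    """
    i0 = pe.ids.index(pe.reference_id)
    if pe.reference[i0] > pe.reference.min() + 1e-12:
        warnings.warn(
            "declared reference structure is not the reference-energy minimum",
            RuntimeWarning,
        )
    dde = (pe.model - pe.model[i0]) - (pe.reference - pe.reference[i0])
    return {pid: float(v) for pid, v in zip(pe.ids, dde) if pid != pe.reference_id}


def distribution_summary(values: Sequence[float]) -> tuple[float, float]:
    """``(RMSE about zero, mean)`` of an error sample."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return float(np.sqrt(np.mean(v * v))), float(np.mean(v))


def saep(p_model: Mapping[str, float], p_ref: Mapping[str, float]) -> float:
    """Sum of absolute population errors over the union of conformer keys.

    Keys present in only one table are read as zero population in the
    other; the result lies in [0, 2], with 2 for disjoint supports.
    """
    keys = set(p_model) | set(p_ref)
    return float(sum(abs(p_model.get(k, 0.0) - p_ref.get(k, 0.0)) for k in keys))


def superposition_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum RMSD (Angstrom) between two structures over rigid motions.

    Centroids are removed and the optimal proper rotation is obtained from
    the SVD of the covariance matrix, with the sign of the smallest singular
    direction flipped when the raw optimum is a reflection.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate shapes must match and be (N, 3); got {A.shape} vs {B.shape}")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Ac @ R.T - Bc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def outlier_filter(
    pairs: Sequence[tuple], rmsd_threshold: float = 0.3, rmsd_index: int = 1
) -> tuple[list, int]:
    """Drop items whose RMSD entry exceeds the threshold (default 0.3 A).

    ``pairs`` is a sequence of tuples with the RMSD at ``rmsd_index``.
    Returns the retained items and the number removed; warns when nothing
    survives.
    """
    kept = [p for p in pairs if p[rmsd_index] <= rmsd_threshold]
    removed = len(pairs) - len(kept)
    if pairs and not kept:
        warnings.warn("all items exceeded the RMSD threshold; empty result", RuntimeWarning)
    return kept, removed
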