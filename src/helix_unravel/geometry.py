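"""Superposition, RMSD, radius of gyration and distance time series.

RMSD follows the two-selection protocol used for the central-helix
analyses: every frame is first superposed onto the reference over a *fit*
selection (default: all heavy atoms of residues 13-26) by a least-squares
Kabsch rotation, then the deviation is measured over a *measure* selection
(default: backbone heavy atoms of the middle region 15-24).  RMSD is
mass-unweighted; the radius of gyration is mass-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Conformation
from .trajectory import (
    FIT_ALL_HEAVY,
    MEASURE_BACKBONE_MID,
    RG_ALL_MID,
    AtomSelection,
    Trajectory,
    select_atoms,
)

__all__ = [
    "TimeSeries",
    "DegenerateSelectionError",
    "kabsch",
    "superpose",
    "rmsd_series",
    "rg_series",
    "distance_series",
]


class DegenerateSelectionError(ValueError):
    """Fit selection is collinear or has fewer than three atoms."""


@dataclass
class TimeSeries:
    """Paired (time, value) samples with a unit tag."""

    times_ps: np.ndarray
    values: np.ndarray
    unit: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values = np.asarray(self.values)
        if self.times_ps.shape != self.values.shape[:1]:
            raise ValueError("times and values must have equal length")
        if len(self.times_ps) > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_ps)

    @property
    def times_ns(self) -> np.ndarray:
        return self.times_ps / 1000.0


def _check_nondegenerate(X: np.ndarray) -> None:
    if X.shape[0] < 3:
        raise DegenerateSelectionError("need at least 3 fit atoms")
    centered = X - X.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateSelectionError("fit atoms are collinear")


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping P onto Q (both (n, 3)).

    Returns ``(R, t)`` with ``R`` a proper rotation (det +1) minimising
    ``sum |R p + t - q|^2`` (mass-unweighted).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def _kabsch_batch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Kabsch: P is (T, n, 3) mobile, Q is (n, 3) reference."""
    pc = P.mean(axis=1, keepdims=True)
    qc = Q.mean(axis=0)
    H = np.einsum("tni,nj->tij", P - pc, Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("tij,tjk->tik",
                                        Vt.transpose(0, 2, 1),
                                        U.transpose(0, 2, 1))))
    D = np.repeat(np.eye(3)[None], len(P), axis=0)
    D[:, 2, 2] = d
    R = np.einsum("tij,tjk,tkl->til", Vt.transpose(0, 2, 1), D,
                  U.transpose(0, 2, 1))
    t = qc - np.einsum("tij,tj->ti", R, pc[:, 0])
    return R, t


def superpose(
    mobile: Conformation,
    reference: Conformation,
    fit_selection: AtomSelection = FIT_ALL_HEAVY,
) -> tuple[np.ndarray, np.ndarray, Conformation]:
    """Superpose ``mobile`` onto ``reference`` over a fit selection.

    Returns ``(rotation, translation, transformed_mobile)``; the transform
    is the Kabsch least-squares solution over the fit atoms and is applied
    to every atom of the mobile conformation.
    """
    idx_m = select_atoms(mobile.topology, fit_selection)
    idx_r = select_atoms(reference.topology, fit_selection)
    if len(idx_m) != len(idx_r):
        raise ValueError("fit selection resolves differently on the two topologies")
    P, Q = mobile.coords[idx_m], reference.coords[idx_r]
    _check_nondegenerate(P)
    _check_nondegenerate(Q)
    R, t = kabsch(P, Q)
    moved = Conformation(mobile.topology, mobile.coords @ R.T + t,
                         label=mobile.label)
    return R, t, moved


def rmsd_series(
    trajectory: Trajectory,
    reference: Conformation,
    fit_selection: AtomSelection = FIT_ALL_HEAVY,
    measure_selection: AtomSelection = MEASURE_BACKBONE_MID,
) -> TimeSeries:
    """Per-frame RMSD (Å) after superposition on the fit selection."""
    fit_idx = select_atoms(trajectory.topology, fit_selection)
    ref_fit_idx = select_atoms(reference.topology, fit_selection)
    meas_idx = select_atoms(trajectory.topology, measure_selection)
    ref_meas_idx = select_atoms(reference.topology, measure_selection)
    _check_nondegenerate(reference.coords[ref_fit_idx])

    P = trajectory.coords[:, fit_idx]
    R, t = _kabsch_batch(P, reference.coords[ref_fit_idx])
    M = np.einsum("tij,tnj->tni", R, trajectory.coords[:, meas_idx]) + t[:, None]
    diff = M - reference.coords[ref_meas_idx]
    values = np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))
    return TimeSeries(trajectory.times_ps, values, unit="A", label="RMSD")


def rg_series(
    trajectory: Trajectory,
    selection: AtomSelection = RG_ALL_MID,
) -> TimeSeries:
    """Mass-weighted radius of gyration (Å) per frame."""
    idx = select_atoms(trajectory.topology, selection)
    masses = trajectory.topology.parameter_arrays()["mass"][idx]
    X = trajectory.coords[:, idx]
    w = masses / masses.sum()
    com = np.einsum("n,tni->ti", w, X)
    d2 = np.sum((X - com[:, None]) ** 2, axis=-1)
    values = np.sqrt(np.einsum("n,tn->t", w, d2))
    return TimeSeries(trajectory.times_ps, values, unit="A", label="Rg")


def distance_series(
    trajectory: Trajectory,
    atom_a: tuple[int, str],
    atom_b: tuple[int, str],
) -> TimeSeries:
    """Euclidean distance (Å) between two named atoms per frame."""
    ia = trajectory.topology.atom_index(*atom_a)
    ib = trajectory.topology.atom_index(*atom_b)
    values = np.linalg.norm(trajectory.coords[:, ia] - trajectory.coords[:, ib],
                            axis=-1)
    label = f"{atom_a[0]}:{atom_a[1]}-{atom_b[0]}:{atom_b[1]}"
    return TimeSeries(trajectory.times_ps, values, unit="A", label=label)
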