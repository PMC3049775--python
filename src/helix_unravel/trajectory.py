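"""Time-stamped coordinate trajectories and atom selections.

A :class:`Trajectory` stores uniformly spaced frames for one topology.  The
frame-time convention follows the production-run bookkeeping used
throughout the package: the first stored frame sits at ``t = start_ps``
(default one stride after time zero), so a 20 ns run sampled every 10 ps
holds exactly 2000 frames and "the last 2 ns" are exactly the final 200
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Conformation, PeptideTopology

__all__ = ["Trajectory", "AtomSelection", "SelectionError", "select_atoms"]


class SelectionError(ValueError):
    """Raised when an atom selection cannot be resolved against a topology."""


@dataclass(frozen=True)
class AtomSelection:
    """Residue-range plus atom-class selection.

    ``cls`` is one of ``"backbone"`` (N, CA, C, O), ``"heavy"`` (all
    non-hydrogen atoms, including cap heavy atoms) or ``"all"``.  An
    explicit ``atoms`` list of ``(residue_number, atom_name)`` pairs
    overrides the range/class filter entirely.
    """

    first_res: int = 13
    last_res: int = 26
    cls: str = "all"
    atoms: tuple[tuple[int, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.cls not in ("backbone", "heavy", "all"):
            raise SelectionError(f"unknown atom class {self.cls!r}")


#: Default fit selection for superposition: all heavy atoms of the peptide.
FIT_ALL_HEAVY = AtomSelection(13, 26, "heavy")
#: Default RMSD measure selection: backbone heavy atoms of the middle region.
MEASURE_BACKBONE_MID = AtomSelection(15, 24, "backbone")
#: Default radius-of-gyration selection: all atoms of the middle region.
RG_ALL_MID = AtomSelection(15, 24, "all")

_BACKBONE_NAMES = ("N", "CA", "C", "O")


def select_atoms(topology: PeptideTopology, selection: AtomSelection) -> np.ndarray:
    """Resolve a selection to sorted flat atom indices.

    Deterministic pure function of ``(topology, selection)``.
    """
    if selection.atoms is not None:
        if not selection.atoms:
            raise SelectionError("explicit atom list is empty")
        idx = [topology.atom_index(r, a) for r, a in selection.atoms]
        return np.array(sorted(idx), dtype=int)
    if not (13 <= selection.first_res <= selection.last_res <= 26):
        raise SelectionError(
            f"residue range {selection.first_res}-{selection.last_res} "
            "outside 13-26"
        )
    idx = []
    for i, res, atom in topology.iter_atoms():
        if not selection.first_res <= res.number <= selection.last_res:
            continue
        if selection.cls == "backbone" and not (
            atom.cls == "bb" and atom.name in _BACKBONE_NAMES
        ):
            continue
        if selection.cls == "heavy" and not atom.is_heavy:
            continue
        idx.append(i)
    if not idx:
        raise SelectionError(f"selection {selection} resolves to no atoms")
    return np.array(idx, dtype=int)


@dataclass
class Trajectory:
    """Uniformly time-stamped coordinate frames for one topology."""

    topology: PeptideTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    stride_ps: float = 10.0
    start_ps: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("coords must be (n_frames >= 1, n_atoms, 3)")
        if self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frame shape {self.coords.shape[1:]} does not match topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.stride_ps <= 0:
            raise ValueError("stride_ps must be positive")
        if self.start_ps is None:
            self.start_ps = self.stride_ps

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return self.start_ps + self.stride_ps * np.arange(self.n_frames)

    @property
    def duration_ns(self) -> float:
        return float(self.times_ps[-1]) / 1000.0

    def frame(self, i: int) -> Conformation:
        t_ns = self.times_ps[i] / 1000.0
        return Conformation(self.topology, self.coords[i],
                            label=f"frame t={t_ns:.2f} ns")

    def slice_ns(self, from_ns: float, to_ns: float) -> "Trajectory":
        """Frames with times in (from_ns, to_ns], keeping the time base."""
        t = self.times_ps / 1000.0
        mask = (t > from_ns) & (t <= to_ns)
        if not mask.any():
            raise ValueError(f"no frames in window ({from_ns}, {to_ns}] ns")
        first = int(np.argmax(mask))
        return Trajectory(self.topology, self.coords[mask],
                          stride_ps=self.stride_ps,
                          start_ps=float(self.times_ps[first]),
                          metadata=dict(self.metadata))
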