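"""Detection of the six α-helical backbone hydrogen bonds of region 15-24.

An α-helical backbone hydrogen bond (αHB) joins the carbonyl oxygen of
residue *i* to the amide hydrogen of residue *i+4*.  Six such bonds span
the middle region 15-24; they are numbered 1-6 starting with the 15→19
pair.  A bond is present when the acceptor-hydrogen distance is strictly
below 2.4 Å — a distance-only criterion, with no angle term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import TimeSeries
from .topology import Conformation, TopologyError
from .trajectory import Trajectory

__all__ = [
    "HBOND_CUTOFF",
    "HBondRecord",
    "MissingAtomError",
    "alpha_hbond_table",
    "hbond_distances",
    "hbond_count_series",
    "hbond_count_distribution",
]

#: Strict acceptor-hydrogen distance criterion (Å).
HBOND_CUTOFF = 2.4

#: (acceptor residue, donor residue) for αHB indices 1..6.
HBOND_PAIRS = tuple((14 + i, 18 + i) for i in range(1, 7))


class MissingAtomError(TopologyError):
    """A required O or HN atom is absent from the conformation's topology."""


@dataclass(frozen=True)
class HBondRecord:
    """One αHB assignment in one frame."""

    index: int  # 1..6
    acceptor_res: int  # carbonyl O of this residue
    donor_res: int  # amide HN of this residue
    distance: float  # Å, O...HN
    present: bool


def _pair_indices(topology) -> np.ndarray:
    idx = np.empty((6, 2), dtype=int)
    try:
        for k, (acc, don) in enumerate(HBOND_PAIRS):
            idx[k, 0] = topology.atom_index(acc, "O")
            idx[k, 1] = topology.atom_index(don, "HN")
    except TopologyError as exc:
        raise MissingAtomError(str(exc)) from exc
    return idx


def alpha_hbond_table(conformation: Conformation) -> list[HBondRecord]:
    """αHB table (exactly six records, indices 1-6) for one conformation."""
    idx = _pair_indices(conformation.topology)
    d = np.linalg.norm(conformation.coords[idx[:, 0]]
                       - conformation.coords[idx[:, 1]], axis=-1)
    return [
        HBondRecord(k + 1, HBOND_PAIRS[k][0], HBOND_PAIRS[k][1],
                    float(d[k]), bool(d[k] < HBOND_CUTOFF))
        for k in range(6)
    ]


def hbond_distances(trajectory: Trajectory) -> np.ndarray:
    """(n_frames, 6) array of O...HN distances in Å."""
    idx = _pair_indices(trajectory.topology)
    return np.linalg.norm(trajectory.coords[:, idx[:, 0]]
                          - trajectory.coords[:, idx[:, 1]], axis=-1)


def hbond_count_series(trajectory: Trajectory) -> TimeSeries:
    """Integer αHB count (0-6) per frame."""
    counts = (hbond_distances(trajectory) < HBOND_CUTOFF).sum(axis=1)
    return TimeSeries(trajectory.times_ps, counts.astype(int),
                      unit="count", label="aHB count")


def hbond_count_distribution(series: Sequence[TimeSeries] | TimeSeries) -> np.ndarray:
    """Frequency of n αHBs, n = 0..6, pooled over one or more count series.

    Frames are weighted equally across all trajectories; the returned
    frequencies are nonnegative and sum to one.
    """
    if isinstance(series, TimeSeries):
        series = [series]
    if not series:
        raise ValueError("need at least one count series")
    pooled = np.concatenate([np.asarray(s.values, dtype=int) for s in series])
    if pooled.size == 0:
        raise ValueError("count series are empty")
    if pooled.min() < 0 or pooled.max() > 6:
        raise ValueError("αHB counts must lie in 0..6")
    freq = np.bincount(pooled, minlength=7).astype(float)
    return freq / freq.sum()
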