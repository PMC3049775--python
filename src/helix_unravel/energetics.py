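"""Force-shifted nonbonded energies and residue-residue decomposition.

Nonbonded pair energies combine a Coulomb and a Lennard-Jones term, both
truncated with an atom-based force-shift at the cutoff r_c (12 Å default):
every term is multiplied by (1 − r/r_c)², which drives the energy *and*
its radial derivative smoothly to zero at the cutoff,

    V(r) = [ C q_i q_j / r  +  ε_ij ( (R_ij/r)^12 − 2 (R_ij/r)^6 ) ] (1 − r/r_c)²

for r ≤ r_c and 0 beyond, with C = 332.0716 kcal·Å·mol⁻¹·e⁻²,
ε_ij = √(ε_i ε_j) and R_ij = R_i/2 + R_j/2 (Lorentz-Berthelot).

Energies are decomposed into a symmetric residue-residue interaction
matrix (intra-residue pairs excluded).  E_p-p and E_np-np are the summed
interactions within the seven polar and seven nonpolar residues
respectively, each pair counted once — equivalently, half the sum of the
seven per-residue group energies ("divided by two to avoid double
counting").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TimeSeries
from .topology import (
    NONPOLAR_RESIDUES,
    POLAR_RESIDUES,
    Conformation,
    PeptideTopology,
)
from .trajectory import Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "DEFAULT_CUTOFF",
    "EnergyBreakdown",
    "pair_energy",
    "residue_interaction_matrix",
    "group_energy",
    "per_residue_group_energies",
    "energy_series",
    "energy_profile",
]

COULOMB_CONSTANT = 332.0716  # kcal Å / (mol e²)
DEFAULT_CUTOFF = 12.0  # Å

_RES_NUMBERS = tuple(range(13, 27))
_NP_COLS = np.array([n - 13 for n in NONPOLAR_RESIDUES])
_P_COLS = np.array([n - 13 for n in POLAR_RESIDUES])


def pair_energy(
    charge_i: float,
    charge_j: float,
    lj_i: tuple[float, float],
    lj_j: tuple[float, float],
    r: float | np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
):
    """Force-shifted nonbonded energy (kcal/mol) of one atom pair.

    ``lj_i``/``lj_j`` are ``(epsilon, rmin_half)`` pairs.  Works on scalars
    or arrays of distances; raises for any nonpositive distance.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("interatomic distance must be positive")
    eps = np.sqrt(lj_i[0] * lj_j[0])
    rmin = lj_i[1] + lj_j[1]
    with np.errstate(over="ignore"):
        x6 = (rmin / r_arr) ** 6
        plain = COULOMB_CONSTANT * charge_i * charge_j / r_arr + eps * (
            x6 * x6 - 2.0 * x6
        )
        shift = (1.0 - r_arr / cutoff) ** 2
        val = np.where(r_arr < cutoff, plain * shift, 0.0)
    return val if val.ndim else float(val)


class _PairTables:
    """Precomputed atom-pair parameter tables for one topology."""

    def __init__(self, topology: PeptideTopology):
        p = topology.parameter_arrays()
        q, eps, rmh = p["charge"], p["epsilon"], p["rmin_half"]
        self.qq = COULOMB_CONSTANT * np.outer(q, q)
        self.eps_ij = np.sqrt(np.outer(eps, eps))
        self.rmin_ij = rmh[:, None] + rmh[None, :]
        res = p["residue"]
        # excluded pairs: same residue, or within 3 covalent bonds (1-2/1-3/1-4)
        self.excluded = (res[:, None] == res[None, :]) | topology.exclusion_mask()
        # one-hot residue membership for matrix aggregation
        self.onehot = (res[:, None] == np.array(_RES_NUMBERS)[None, :]).astype(float)

        # condensed non-excluded upper-triangle pair list, sorted by
        # residue-pair id so per-frame aggregation is a single reduceat
        iu, ju = np.triu_indices(len(q), k=1)
        keep = ~self.excluded[iu, ju]
        iu, ju = iu[keep], ju[keep]
        pair_id = (res[iu] - 13) * 14 + (res[ju] - 13)
        order = np.argsort(pair_id, kind="stable")
        self.pi, self.pj = iu[order], ju[order]
        self.pair_qq = self.qq[self.pi, self.pj]
        self.pair_eps = self.eps_ij[self.pi, self.pj]
        self.pair_rmin = self.rmin_ij[self.pi, self.pj]
        sorted_id = pair_id[order]
        self.seg_starts = np.flatnonzero(
            np.r_[True, sorted_id[1:] != sorted_id[:-1]])
        self.seg_ids = sorted_id[self.seg_starts]


_TABLE_CACHE: dict[tuple[str, str], _PairTables] = {}


def _tables(topology: PeptideTopology) -> _PairTables:
    key = (topology.variant, topology.protonation)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _PairTables(topology)
    return _TABLE_CACHE[key]


def _matrices_for_coords(X: np.ndarray, tab: _PairTables,
                         cutoff: float) -> np.ndarray:
    """Residue interaction matrices (T, 14, 14) for coordinates (T, n, 3)."""
    diff = X[:, tab.pi, :] - X[:, tab.pj, :]
    d = np.sqrt(np.einsum("tpk,tpk->tp", diff, diff))
    np.maximum(d, 1e-9, out=d)
    with np.errstate(over="ignore"):
        inv = 1.0 / d
        x2 = (tab.pair_rmin * inv) ** 2
        x6 = x2 * x2 * x2
        plain = tab.pair_qq * inv + tab.pair_eps * (x6 * x6 - 2.0 * x6)
        e = plain * (1.0 - d / cutoff) ** 2
    e[d >= cutoff] = 0.0
    seg = np.add.reduceat(e, tab.seg_starts, axis=1)
    m = np.zeros((len(X), 14 * 14))
    m[:, tab.seg_ids] = seg
    m = m.reshape(len(X), 14, 14)
    return m + m.transpose(0, 2, 1)


def residue_interaction_matrix(
    conformation: Conformation, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Symmetric 14×14 residue-pair interaction matrix (kcal/mol).

    Entry (a, b) sums :func:`pair_energy` over all atom pairs with one atom
    in residue a and the other in residue b; the diagonal (intra-residue)
    is zero by construction and atom pairs within three covalent bonds
    (1-2/1-3/1-4 neighbours across the peptide bond) are excluded, as usual
    for nonbonded sums.  Rows/columns follow residues 13..26.
    """
    tab = _tables(conformation.topology)
    return _matrices_for_coords(conformation.coords[None], tab, cutoff)[0]


def group_energy(per_residue_terms) -> float:
    """Group energy from the seven per-residue interaction sums.

    Each member's interaction with the other six group members is summed
    and halved to undo double counting: E = ½ Σ terms.
    """
    terms = np.asarray(per_residue_terms, dtype=float)
    if terms.shape != (7,):
        raise ValueError("expected exactly 7 per-residue terms")
    return 0.5 * float(terms.sum())


def per_residue_group_energies(matrix: np.ndarray, group: str = "nonpolar"):
    """Per-residue interaction with the other six members of a polarity group.

    Returns a dict mapping residue number to kcal/mol for the seven
    residues of the requested group.
    """
    cols = _NP_COLS if group == "nonpolar" else _P_COLS
    numbers = NONPOLAR_RESIDUES if group == "nonpolar" else POLAR_RESIDUES
    sub = matrix[np.ix_(cols, cols)]
    return {num: float(sub[i].sum()) for i, num in enumerate(numbers)}


@dataclass
class EnergyBreakdown:
    """Per-frame nonbonded energy decomposition (kcal/mol)."""

    time_ps: float
    e_pp: float
    e_npnp: float
    e_total: float
    per_residue_npnp: dict[int, float]
    residue_matrix: np.ndarray


def _group_sums(matrices: np.ndarray):
    """E_pp, E_npnp and E_total (each pair once) from (T, 14, 14) matrices."""
    pp = matrices[:, _P_COLS[:, None], _P_COLS[None, :]].sum(axis=(1, 2)) / 2.0
    npnp = matrices[:, _NP_COLS[:, None], _NP_COLS[None, :]].sum(axis=(1, 2)) / 2.0
    total = matrices.sum(axis=(1, 2)) / 2.0
    return pp, npnp, total


def energy_series(
    trajectory: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    chunk: int = 200,
) -> list[EnergyBreakdown]:
    """One :class:`EnergyBreakdown` per frame."""
    tab = _tables(trajectory.topology)
    times = trajectory.times_ps
    out: list[EnergyBreakdown] = []
    for lo in range(0, trajectory.n_frames, chunk):
        X = trajectory.coords[lo:lo + chunk]
        m = _matrices_for_coords(X, tab, cutoff)
        pp, npnp, total = _group_sums(m)
        for k in range(len(X)):
            out.append(
                EnergyBreakdown(
                    time_ps=float(times[lo + k]),
                    e_pp=float(pp[k]),
                    e_npnp=float(npnp[k]),
                    e_total=float(total[k]),
                    per_residue_npnp=per_residue_group_energies(m[k], "nonpolar"),
                    residue_matrix=m[k],
                )
            )
    return out


def energy_profile(
    trajectory: Trajectory, cutoff: float = DEFAULT_CUTOFF, chunk: int = 200
) -> dict[str, TimeSeries]:
    """E_pp, E_npnp and E_total as :class:`TimeSeries` (lighter than
    :func:`energy_series`; no per-frame matrices are retained)."""
    tab = _tables(trajectory.topology)
    pps, npnps, totals = [], [], []
    for lo in range(0, trajectory.n_frames, chunk):
        m = _matrices_for_coords(trajectory.coords[lo:lo + chunk], tab, cutoff)
        pp, npnp, total = _group_sums(m)
        pps.append(pp)
        npnps.append(npnp)
        totals.append(total)
    t = trajectory.times_ps
    unit = "kcal/mol"
    return {
        "e_pp": TimeSeries(t, np.concatenate(pps), unit, "E_p-p"),
        "e_npnp": TimeSeries(t, np.concatenate(npnps), unit, "E_np-np"),
        "e_total": TimeSeries(t, np.concatenate(totals), unit, "E_total"),
    }
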