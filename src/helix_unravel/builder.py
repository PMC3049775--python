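"""Internal-coordinate construction of peptide conformations.

Coordinates are generated by sequential natural-extension placement: each
atom is positioned from three previously placed atoms using a bond length,
a bond angle and a torsion angle.  Backbone torsions (φ, ψ) are free
parameters; the peptide bond is kept trans (ω = 180°) and amide hydrogens
are placed in the peptide plane trans to the carbonyl oxygen.  Sidechains
use standard bond geometry at extended rotamers, with the first sidechain
torsion (χ₁) overridable per residue.

All placement routines are vectorised over a leading "frame" axis so that a
whole trajectory of scripted conformations is built in one pass.
"""

from __future__ import annotations

import numpy as np

from .topology import Conformation, PeptideTopology

__all__ = ["build_ideal_helix", "build_frames", "DihedralError"]

# Standard backbone geometry (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_N_H = 1.000
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_CA_C_O = 120.8
_A_C_N_H = 119.0
_OMEGA = 180.0

# Sidechain z-matrix entries: (atom, (ref_a, ref_b, ref_c), bond, angle,
# value, kind).  kind None: the torsion is the fixed value; kind "chi1" or
# "chi2": the torsion is the residue's χ₁/χ₂ plus the value (an offset).
# References are atom names within the residue.
_SIDE_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None)],
    "VAL": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, 0.0, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -122.0, "chi1"),
    ],
    "LEU": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG", ("N", "CA", "CB"), 1.53, 115.0, 0.0, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.53, 110.5, 0.0, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.53, 110.5, -122.0, "chi2"),
    ],
    "PHE": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, 0.0, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.40, 120.0, 0.0, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.40, 120.0, 180.0, "chi2"),
        ("CE1", ("CB", "CG", "CD1"), 1.40, 120.0, 180.0, None),
        ("CE2", ("CB", "CG", "CD2"), 1.40, 120.0, 180.0, None),
        ("CZ", ("CG", "CD1", "CE1"), 1.40, 120.0, 0.0, None),
    ],
    "SER": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("OG", ("N", "CA", "CB"), 1.42, 110.5, 0.0, "chi1"),
    ],
    "GLN": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG", ("N", "CA", "CB"), 1.53, 113.8, 0.0, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.5, 0.0, "chi2"),
        ("OE1", ("CB", "CG", "CD"), 1.23, 121.5, 0.0, None),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, 180.0, None),
    ],
    "LYS": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG", ("N", "CA", "CB"), 1.53, 113.8, 0.0, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.53, 111.0, 0.0, "chi2"),
        ("CE", ("CB", "CG", "CD"), 1.53, 111.0, 180.0, None),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.0, 180.0, None),
    ],
    "GLU": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG", ("N", "CA", "CB"), 1.53, 113.8, 0.0, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.5, 0.0, "chi2"),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.0, 0.0, None),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.0, 180.0, None),
    ],
    "ASP": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG", ("N", "CA", "CB"), 1.52, 112.5, 0.0, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, 0.0, "chi2"),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, 180.0, "chi2"),
    ],
    "HIP": [
        ("CB", ("N", "C", "CA"), 1.53, 110.5, -122.68, None),
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, 0.0, "chi1"),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.0, 0.0, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.36, 129.0, 180.0, "chi2"),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0, None),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0, None),
    ],
}
_SIDE_TEMPLATES["HIE"] = _SIDE_TEMPLATES["HIP"]

#: Default χ₁/χ₂ (degrees) per template; extended rotamers.
_DEFAULT_CHI1 = {
    "VAL": 175.0, "LEU": 180.0, "PHE": 180.0, "SER": 180.0, "GLN": 180.0,
    "LYS": 180.0, "GLU": 180.0, "ASP": 180.0, "HIP": 180.0, "HIE": 180.0,
}
_DEFAULT_CHI2 = {
    "LEU": 175.0, "PHE": 90.0, "GLN": 180.0, "LYS": 180.0, "GLU": 180.0,
    "ASP": 0.0, "HIP": 90.0, "HIE": 90.0,
}


class DihedralError(ValueError):
    """Raised when a torsion angle is outside (−180°, 180°]."""


def _check_dihedral(value: np.ndarray | float, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= -180.0) or np.any(arr > 180.0):
        raise DihedralError(f"{name} must lie in (-180, 180] degrees")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d bonded to c with angle(b,c,d) and torsion(a,b,c,d).

    All of ``a, b, c`` are arrays of shape (..., 3); angles in degrees may be
    scalars or arrays broadcastable to the leading shape.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    lead = c.shape[:-1]
    theta = np.broadcast_to(np.deg2rad(np.asarray(angle_deg, float)), lead)
    chi = np.broadcast_to(np.deg2rad(np.asarray(torsion_deg, float)), lead)
    bond = np.broadcast_to(np.asarray(bond, float), lead)

    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    chi = -chi  # measured torsions follow the IUPAC sign convention

    d = (
        c
        - (bond * np.cos(theta))[..., None] * bc
        + (bond * np.sin(theta))[..., None]
        * (np.cos(chi)[..., None] * m + np.sin(chi)[..., None] * n)
    )
    return d


def build_frames(
    topology: PeptideTopology,
    phi: np.ndarray,
    psi: np.ndarray,
    chi1: np.ndarray | None = None,
    chi2: np.ndarray | None = None,
) -> np.ndarray:
    """Build coordinates for many frames of scripted backbone torsions.

    Parameters
    ----------
    phi, psi:
        Arrays of shape (n_frames, 14) of backbone torsions in degrees for
        residues 13..26.  φ of residue 13 is taken about the acetyl C-N
        bond.
    chi1, chi2:
        Optional (n_frames, 14) arrays of first/second sidechain torsions;
        NaN entries fall back to the residue's default extended rotamer.

    Returns
    -------
    ndarray of shape (n_frames, n_atoms, 3).
    """
    phi = np.atleast_2d(np.asarray(phi, float))
    psi = np.atleast_2d(np.asarray(psi, float))
    T, n_res = phi.shape
    if psi.shape != (T, n_res) or n_res != 14:
        raise ValueError("phi and psi must both have shape (n_frames, 14)")
    _check_dihedral(phi, "phi")
    _check_dihedral(psi, "psi")
    for nm, arr in (("chi1", chi1), ("chi2", chi2)):
        if arr is not None:
            arr = np.atleast_2d(np.asarray(arr, float))
            if arr.shape != (T, n_res):
                raise ValueError(f"{nm} must have shape (n_frames, 14)")
            _check_dihedral(arr[np.isfinite(arr)], nm)
    chi1 = None if chi1 is None else np.atleast_2d(np.asarray(chi1, float))
    chi2 = None if chi2 is None else np.atleast_2d(np.asarray(chi2, float))

    coords = np.empty((T, topology.n_atoms, 3))
    # name -> coordinate block of the residue currently being built
    index_of: dict[str, int] = {}
    for i, res, atom in topology.iter_atoms():
        index_of[f"{res.number}:{atom.name}"] = i

    def idx(res_number: int, name: str) -> int:
        return index_of[f"{res_number}:{name}"]

    # --- acetyl cap: seed the chain deterministically in the xy plane
    i_cay, i_cy, i_oy = (idx(13, n) for n in ("CAY", "CY", "OY"))
    coords[:, i_cay] = (0.0, 0.0, 0.0)
    coords[:, i_cy] = (1.52, 0.0, 0.0)

    prev_c = i_cy
    prev_ca = i_cay  # torsion reference for ω about C-N
    prev_o = i_oy

    for r, res in enumerate(topology.residues):
        num = res.number
        i_n, i_hn = idx(num, "N"), idx(num, "HN")
        i_ca, i_c, i_o = idx(num, "CA"), idx(num, "C"), idx(num, "O")

        if num == 13:
            # N13 from the cap geometry; ψ-like torsion about CY is arbitrary
            ang = np.deg2rad(_A_CA_C_N)
            coords[:, i_n] = coords[:, i_cy] + _B_C_N * np.array(
                [-np.cos(ang), np.sin(ang), 0.0]
            )
            # acetyl carbonyl oxygen, planar, opposite the amide nitrogen
            coords[:, i_oy] = place_atom(
                coords[:, i_n], coords[:, i_cay], coords[:, i_cy],
                _B_C_O, 121.0, 180.0,
            )
        else:
            coords[:, i_n] = place_atom(
                coords[:, idx(num - 1, "N")], coords[:, prev_ca], coords[:, prev_c],
                _B_C_N, _A_CA_C_N, psi[:, r - 1],
            )

        coords[:, i_hn] = place_atom(
            coords[:, prev_o], coords[:, prev_c], coords[:, i_n],
            _B_N_H, _A_C_N_H, 180.0,
        )
        coords[:, i_ca] = place_atom(
            coords[:, prev_ca], coords[:, prev_c], coords[:, i_n],
            _B_N_CA, _A_C_N_CA, _OMEGA,
        )
        coords[:, i_c] = place_atom(
            coords[:, prev_c], coords[:, i_n], coords[:, i_ca],
            _B_CA_C, _A_N_CA_C, phi[:, r],
        )
        # carbonyl O trans to the next amide nitrogen: torsion ψ + 180
        o_torsion = np.where(psi[:, r] + 180.0 > 180.0,
                             psi[:, r] - 180.0, psi[:, r] + 180.0)
        coords[:, i_o] = place_atom(
            coords[:, i_n], coords[:, i_ca], coords[:, i_c],
            _B_C_O, _A_CA_C_O, o_torsion,
        )

        # sidechain
        d1 = _DEFAULT_CHI1.get(res.template, 0.0)
        d2 = _DEFAULT_CHI2.get(res.template, 0.0)
        if chi1 is not None:
            chi1_r = np.where(np.isfinite(chi1[:, r]), chi1[:, r], d1)
        else:
            chi1_r = np.full(T, d1)
        if chi2 is not None:
            chi2_r = np.where(np.isfinite(chi2[:, r]), chi2[:, r], d2)
        else:
            chi2_r = np.full(T, d2)
        for name, (ra, rb, rc), bond, angle, value, kind in _SIDE_TEMPLATES[
            res.template
        ]:
            if kind == "chi1":
                tors = chi1_r + value
            elif kind == "chi2":
                tors = chi2_r + value
            else:
                tors = np.full(T, value)
            # keep torsions in principal range for reproducibility
            tors = (tors + 180.0) % 360.0 - 180.0
            tors = np.where(tors == -180.0, 180.0, tors)
            coords[:, idx(num, name)] = place_atom(
                coords[:, idx(num, ra)], coords[:, idx(num, rb)],
                coords[:, idx(num, rc)], bond, angle, tors,
            )

        prev_c, prev_ca, prev_o = i_c, i_ca, i_o

    # --- C-terminal amide cap
    i_nt, i_ht1, i_ht2 = (idx(26, n) for n in ("NT", "HT1", "HT2"))
    i_n26, i_ca26, i_c26 = idx(26, "N"), idx(26, "CA"), idx(26, "C")
    coords[:, i_nt] = place_atom(
        coords[:, i_n26], coords[:, i_ca26], coords[:, i_c26],
        _B_C_N, _A_CA_C_N, psi[:, 13],
    )
    coords[:, i_ht1] = place_atom(
        coords[:, i_ca26], coords[:, i_c26], coords[:, i_nt], _B_N_H, 120.0, 0.0
    )
    coords[:, i_ht2] = place_atom(
        coords[:, i_ca26], coords[:, i_c26], coords[:, i_nt], _B_N_H, 120.0, 180.0
    )
    return coords


def build_ideal_helix(
    topology: PeptideTopology,
    phi_deg: float = -57.0,
    psi_deg: float = -47.0,
    label: str = "ideal helix",
) -> Conformation:
    """Build an ideal helical (or other uniform-torsion) conformation.

    With the default torsions (−57°, −47°) the result is a canonical
    α-helix: all six O(i)→HN(i+4) backbone hydrogen bonds of the middle
    region (15-24) satisfy the 2.4 Å acceptor-hydrogen criterion.
    """
    _check_dihedral(phi_deg, "phi")
    _check_dihedral(psi_deg, "psi")
    phi = np.full((1, 14), float(phi_deg))
    psi = np.full((1, 14), float(psi_deg))
    coords = build_frames(topology, phi, psi)
    return Conformation(topology, coords[0], label=label)
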