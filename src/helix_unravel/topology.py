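"""Topologies of the amyloid-beta(13-26) central-helix peptide and its variants.

The peptide studied here is the Aβ fragment spanning residues 13-26
(sequence HHQKLVFFAEDVGS in one-letter code) with neutral terminal caps:
an N-terminal acetyl group and a C-terminal amide.  Three sequence variants
are supported: the wild type (``WT``), the triple alanine replacement
V18A/F19A/F20A (``MA``) and the triple leucine replacement V18L/F19L/F20L
(``ML``).  The two histidines (H13, H14) can be modelled either protonated
(net peptide charge +1 e) or neutral, deprotonated at Nδ (net charge −1 e);
the protonation state only changes sidechain partial charges.

Atom detail is deliberately reduced: all heavy atoms are present, but the
only hydrogens kept are the backbone amide HN (needed for the α-helical
hydrogen-bond criterion) and the two C-terminal amide cap hydrogens.  Cap
atoms are carried by residues 13 (CAY/CY/OY) and 26 (NT/HT1/HT2).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "PeptideTopology",
    "Conformation",
    "TopologyError",
    "build_topology",
    "VARIANTS",
    "PROTONATIONS",
    "POLAR_RESIDUES",
    "NONPOLAR_RESIDUES",
]

VARIANTS = ("WT", "MA", "ML")
PROTONATIONS = ("+", "0")

#: Aβ residue numbers of the seven polar and seven nonpolar residues.
POLAR_RESIDUES = (13, 14, 15, 16, 22, 23, 26)
NONPOLAR_RESIDUES = (17, 18, 19, 20, 21, 24, 25)

_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008}

_ONE_TO_THREE = {
    "H": "HIS", "Q": "GLN", "K": "LYS", "L": "LEU", "V": "VAL",
    "F": "PHE", "A": "ALA", "E": "GLU", "D": "ASP", "G": "GLY", "S": "SER",
}

_WT_SEQUENCE = "HHQKLVFFAEDVGS"  # residues 13..26
_REPLACEMENT = {"WT": "VFF", "MA": "AAA", "ML": "LLL"}

# Covalent bonds per residue template (used to build the exclusion graph for
# nonbonded sums: pairs within 3 bonds are excluded).
_BACKBONE_BONDS = [("N", "HN"), ("N", "CA"), ("CA", "C"), ("C", "O")]
_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "HIP": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
}
_SIDECHAIN_BONDS["HIE"] = _SIDECHAIN_BONDS["HIP"]


class TopologyError(ValueError):
    """Raised for invalid variant/protonation requests or parameter lookups."""


@dataclass(frozen=True)
class Atom:
    """One atom with its nonbonded parameters.

    ``charge`` in elementary charges, ``epsilon`` (kcal/mol) and
    ``rmin_half`` (Å) are the Lennard-Jones well depth and half minimum
    distance, combined across pairs by Lorentz-Berthelot rules.
    ``cls`` is ``bb`` (backbone heavy), ``sc`` (sidechain/cap heavy) or
    ``h`` (hydrogen).
    """

    name: str
    element: str
    charge: float
    epsilon: float
    rmin_half: float
    cls: str

    @property
    def mass(self) -> float:
        return _MASSES[self.element]

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class Residue:
    number: int
    name: str  # three-letter code as written to PDB
    template: str  # parameter-table template (HIP/HIE for histidine)
    polarity: str  # "polar" | "nonpolar"
    atoms: tuple[Atom, ...]


@dataclass(frozen=True)
class PeptideTopology:
    """Aβ(13-26) variant topology with per-atom nonbonded parameters."""

    variant: str
    protonation: str
    residues: tuple[Residue, ...]

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if numbers != list(range(13, 27)):
            raise TopologyError("topology must hold residues 13..26 contiguously")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def iter_atoms(self) -> Iterator[tuple[int, Residue, Atom]]:
        """Yield (flat_index, residue, atom) in canonical order."""
        i = 0
        for res in self.residues:
            for atom in res.atoms:
                yield i, res, atom
                i += 1

    def residue(self, number: int) -> Residue:
        if not 13 <= number <= 26:
            raise TopologyError(f"residue number {number} outside 13..26")
        return self.residues[number - 13]

    def atom_index(self, res_number: int, atom_name: str) -> int:
        """Flat coordinate index of one atom, e.g. ``atom_index(16, 'NZ')``."""
        base = 0
        for res in self.residues:
            if res.number == res_number:
                for j, atom in enumerate(res.atoms):
                    if atom.name == atom_name:
                        return base + j
                valid = ", ".join(a.name for a in res.atoms)
                raise TopologyError(
                    f"residue {res_number} ({res.name}) has no atom "
                    f"{atom_name!r}; valid names: {valid}"
                )
            base += len(res.atoms)
        raise TopologyError(f"residue number {res_number} outside 13..26")

    @property
    def total_charge(self) -> float:
        return sum(a.charge for _, _, a in self.iter_atoms())

    def bonds(self) -> list[tuple[int, int]]:
        """Covalent bonds as flat atom-index pairs (incl. peptide/cap bonds)."""
        index: dict[tuple[int, str], int] = {}
        for i, res, atom in self.iter_atoms():
            index[(res.number, atom.name)] = i
        pairs: list[tuple[int, int]] = []
        for res in self.residues:
            for a, b in _BACKBONE_BONDS + _SIDECHAIN_BONDS[res.template]:
                pairs.append((index[(res.number, a)], index[(res.number, b)]))
            if res.number < 26:
                pairs.append((index[(res.number, "C")], index[(res.number + 1, "N")]))
        # acetyl cap on residue 13, amide cap on residue 26
        pairs += [
            (index[(13, "CAY")], index[(13, "CY")]),
            (index[(13, "CY")], index[(13, "OY")]),
            (index[(13, "CY")], index[(13, "N")]),
            (index[(26, "C")], index[(26, "NT")]),
            (index[(26, "NT")], index[(26, "HT1")]),
            (index[(26, "NT")], index[(26, "HT2")]),
        ]
        return pairs

    def exclusion_mask(self, max_bond_separation: int = 3) -> np.ndarray:
        """Boolean (n, n) mask of atom pairs within ``max_bond_separation``
        bonds of each other (1-2, 1-3 and 1-4 neighbours by default)."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import shortest_path

        n = self.n_atoms
        pairs = np.array(self.bonds())
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        dist = shortest_path(adj, method="D", directed=False, unweighted=True)
        return dist <= max_bond_separation

    # Cached flat parameter arrays used by the energy code ---------------
    def parameter_arrays(self) -> dict[str, np.ndarray]:
        n = self.n_atoms
        q = np.empty(n)
        eps = np.empty(n)
        rmh = np.empty(n)
        mass = np.empty(n)
        res_no = np.empty(n, dtype=int)
        for i, res, atom in self.iter_atoms():
            q[i] = atom.charge
            eps[i] = atom.epsilon
            rmh[i] = atom.rmin_half
            mass[i] = atom.mass
            res_no[i] = res.number
        return {"charge": q, "epsilon": eps, "rmin_half": rmh,
                "mass": mass, "residue": res_no}


@dataclass
class Conformation:
    """A single set of coordinates (Å) for one topology."""

    topology: PeptideTopology
    coords: np.ndarray  # (n_atoms, 3)
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


# ----------------------------------------------------------------------
# Parameter table loading

_PARAM_CACHE: dict[str, tuple[Atom, ...]] | None = None


def _load_templates() -> dict[str, tuple[Atom, ...]]:
    global _PARAM_CACHE
    if _PARAM_CACHE is None:
        templates: dict[str, list[Atom]] = {}
        text = (
            resources.files("helix_unravel.data")
            .joinpath("residue_params.tsv")
            .read_text()
        )
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tmpl, name, element, charge, epsi, rmh, cls = line.split("\t")
            templates.setdefault(tmpl, [])
            if name == "-":  # template with no sidechain atoms (glycine)
                continue
            templates[tmpl].append(
                Atom(name, element, float(charge), float(epsi), float(rmh), cls)
            )
        _PARAM_CACHE = {k: tuple(v) for k, v in templates.items()}
    return _PARAM_CACHE


def sequence_for(variant: str) -> str:
    """One-letter sequence of residues 13..26 for a variant."""
    if variant not in VARIANTS:
        raise TopologyError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return _WT_SEQUENCE[:5] + _REPLACEMENT[variant] + _WT_SEQUENCE[8:]


def build_topology(variant: str = "WT", protonation: str = "+") -> PeptideTopology:
    """Build the Aβ(13-26) topology for a sequence variant and His state.

    Parameters
    ----------
    variant:
        ``"WT"`` (V18/F19/F20), ``"MA"`` (A18/A19/A20) or ``"ML"``
        (L18/L19/L20).
    protonation:
        ``"+"`` for protonated H13/H14 (net charge +1 e) or ``"0"`` for
        histidines neutral at Nδ (net charge −1 e).
    """
    if variant not in VARIANTS:
        raise TopologyError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if protonation not in PROTONATIONS:
        raise TopologyError(
            f"unknown protonation {protonation!r}; expected '+' or '0'"
        )
    templates = _load_templates()
    backbone = templates["BB"]
    seq = sequence_for(variant)

    residues = []
    for offset, one in enumerate(seq):
        number = 13 + offset
        name = _ONE_TO_THREE[one]
        template = name
        if name == "HIS":
            template = "HIP" if protonation == "+" else "HIE"
        atoms = list(backbone) + list(templates[template])
        if number == 13:  # N-terminal acetyl cap atoms ride on residue 13
            atoms = list(templates["ACE"]) + atoms
        if number == 26:  # C-terminal amide cap atoms ride on residue 26
            atoms = atoms + list(templates["NH2"])
        polarity = "polar" if number in POLAR_RESIDUES else "nonpolar"
        residues.append(Residue(number, name, template, polarity, tuple(atoms)))

    return PeptideTopology(variant, protonation, tuple(residues))
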