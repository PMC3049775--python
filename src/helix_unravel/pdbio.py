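"""Reading and writing PDB files (single structures and multi-model trajectories).

Single conformations are written as fixed-width ATOM records (PDB v3.3
layout) with occupancy 1.00 and B-factor 0.00.  Trajectories use
MODEL/ENDMDL blocks; frame timing and provenance travel in ``REMARK 100``
records (``TIMESTEP_PS``, ``STARTTIME_PS``, plus free key/value metadata),
so a written trajectory file is self-describing.
"""

from __future__ import annotations

import os
from typing import TextIO

import numpy as np

from .topology import Conformation, PeptideTopology, build_topology
from .trajectory import Trajectory

__all__ = [
    "PDBFormatError",
    "PDBMismatchError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
]


class PDBFormatError(ValueError):
    """Malformed fixed-width record; message carries the line number."""


class PDBMismatchError(ValueError):
    """Parsed atoms do not match the expected topology."""


def _format_atom_line(serial: int, name: str, res_name: str, res_num: int,
                      xyz: np.ndarray, element: str) -> str:
    # Atom names of <=3 characters start in column 14 by PDB convention.
    field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {field:<4s} {res_name:<3s} A{res_num:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def _write_model(fh: TextIO, conf: Conformation) -> None:
    serial = 1
    for i, res, atom in conf.topology.iter_atoms():
        fh.write(
            _format_atom_line(serial, atom.name, res.name, res.number,
                              conf.coords[i], atom.element) + "\n"
        )
        serial += 1


def write_pdb(conformation: Conformation, path: str | os.PathLike) -> None:
    """Write a single conformation as a PDB file."""
    top = conformation.topology
    with open(path, "w") as fh:
        fh.write(f"REMARK 100 VARIANT {top.variant}\n")
        fh.write(f"REMARK 100 PROTONATION {top.protonation}\n")
        if conformation.label:
            fh.write(f"REMARK 100 LABEL {conformation.label}\n")
        _write_model(fh, conformation)
        fh.write("END\n")


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        res_num = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    return name, res_name, res_num, xyz


def _match_topology(records, topology: PeptideTopology):
    """Validate parsed atom records against a topology; return coordinates."""
    expected = [(res.number, res.name, atom.name)
                for _, res, atom in topology.iter_atoms()]
    got = [(rnum, rname, aname) for (aname, rname, rnum, _) in records]
    if got != expected:
        exp_set, got_set = set(expected), set(got)
        missing = sorted(exp_set - got_set)
        extra = sorted(got_set - exp_set)
        raise PDBMismatchError(
            f"atoms do not match {topology.variant}{topology.protonation} "
            f"topology; missing={missing[:8]} extra={extra[:8]}"
        )
    return np.array([xyz for (_, _, _, xyz) in records], dtype=float)


def _infer_topology(remarks: dict[str, str], records) -> PeptideTopology:
    variant = remarks.get("VARIANT")
    protonation = remarks.get("PROTONATION", "+")
    if variant is None:
        by_res = {rnum: rname for (_, rname, rnum, _) in records}
        names = tuple(by_res.get(n) for n in (18, 19, 20))
        variant = {("VAL", "PHE", "PHE"): "WT",
                   ("ALA", "ALA", "ALA"): "MA",
                   ("LEU", "LEU", "LEU"): "ML"}.get(names)
        if variant is None:
            raise PDBMismatchError(
                f"cannot infer sequence variant from residues 18-20 = {names}"
            )
    return build_topology(variant, protonation)


def _scan(path) -> tuple[dict[str, str], list[list]]:
    """Parse REMARK metadata and per-model atom records."""
    remarks: dict[str, str] = {}
    models: list[list] = [[]]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "REMARK" and line[7:10] == "100":
                parts = line.split(maxsplit=3)
                if len(parts) >= 4:
                    remarks[parts[2]] = parts[3].strip()
            elif rec == "MODEL ":
                if models[-1]:
                    models.append([])
            elif rec in ("ATOM  ", "HETATM"):
                models[-1].append(_parse_atom_line(line, lineno))
    if models and not models[-1]:
        models.pop()
    return remarks, models


def read_pdb(path: str | os.PathLike,
             topology: PeptideTopology | None = None) -> Conformation:
    """Read a single-structure PDB file.

    If the file holds several MODEL blocks only the first is read.  When
    ``topology`` is given the file must match it exactly (same residues and
    atom names in order); otherwise the variant is inferred from the
    ``REMARK 100`` header or from the residue names at positions 18-20.
    """
    remarks, models = _scan(path)
    if not models:
        raise PDBFormatError(f"no ATOM records found in {path}")
    records = models[0]
    if topology is None:
        topology = _infer_topology(remarks, records)
    coords = _match_topology(records, topology)
    return Conformation(topology, coords, label=remarks.get("LABEL", ""))


def write_trajectory(trajectory: Trajectory, path: str | os.PathLike,
                     fmt: str = "pdb") -> None:
    """Write a trajectory as a multi-model PDB file."""
    if fmt != "pdb":
        raise ValueError(f"unsupported trajectory format {fmt!r} (only 'pdb')")
    top = trajectory.topology
    with open(path, "w") as fh:
        fh.write(f"REMARK 100 VARIANT {top.variant}\n")
        fh.write(f"REMARK 100 PROTONATION {top.protonation}\n")
        fh.write(f"REMARK 100 TIMESTEP_PS {trajectory.stride_ps:g}\n")
        fh.write(f"REMARK 100 STARTTIME_PS {trajectory.start_ps:g}\n")
        for key, value in trajectory.metadata.items():
            fh.write(f"REMARK 100 META_{key.upper()} {value}\n")
        for t in range(trajectory.n_frames):
            fh.write(f"MODEL {t + 1:>8d}\n")
            _write_model(fh, trajectory.frame(t))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(path: str | os.PathLike,
                    topology: PeptideTopology | None = None,
                    fmt: str = "pdb") -> Trajectory:
    """Read a multi-model PDB trajectory written by :func:`write_trajectory`."""
    if fmt != "pdb":
        raise ValueError(f"unsupported trajectory format {fmt!r} (only 'pdb')")
    remarks, models = _scan(path)
    if not models:
        raise PDBFormatError(f"no ATOM records found in {path}")
    n0 = len(models[0])
    for m, records in enumerate(models):
        if len(records) != n0:
            raise PDBFormatError(
                f"model {m + 1} has {len(records)} atoms, expected {n0}"
            )
    if topology is None:
        topology = _infer_topology(remarks, models[0])
    coords = np.stack([_match_topology(records, topology) for records in models])
    stride = float(remarks.get("TIMESTEP_PS", 10.0))
    start = float(remarks.get("STARTTIME_PS", stride))
    metadata = {k[5:].lower(): v for k, v in remarks.items()
                if k.startswith("META_")}
    return Trajectory(topology, coords, stride_ps=stride, start_ps=start,
                      metadata=metadata)
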