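"""Readers and writers for GRO and PDB coordinate files.

GRO files store nanometres and are converted to Angstrom on read (and back
on write); PDB files are already in Angstrom.  Multi-frame GRO files (one
title/count/atoms/box block per frame) and multi-MODEL PDB files each yield
one :class:`~memthick.core.Frame` per block.  Only orthorhombic boxes are
accepted; triclinic input is rejected with a clear error.

The GRO dialect is parsed here directly because the block-per-frame layout
and line-numbered error reporting are part of this package's contract; the
PDB dialect is delegated to MDAnalysis, which also handles the >99,999-atom
serial-overflow policy on write.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np

from .core import (
    DEFAULT_CONVENTION,
    BeadRecord,
    Frame,
    LabeledEnsemble,
    NamingConvention,
)
from .errors import ParseError, StructureError

__all__ = ["read_coordinates", "write_coordinates"]

NM_TO_A = 10.0


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gro":
        return "gro"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # Content sniff: PDB files start with record keywords.
    with open(path) as fh:
        head = fh.readline()
    if head[:6].strip() in {"ATOM", "HETATM", "MODEL", "CRYST1", "REMARK", "HEADER", "TITLE"}:
        return "pdb"
    return "gro"


def read_coordinates(
    path: str | os.PathLike,
    dialect: str = "auto",
    convention: NamingConvention = DEFAULT_CONVENTION,
) -> LabeledEnsemble:
    """Read a (possibly multi-frame) GRO or multi-MODEL PDB file.

    Roles are assigned from bead/atom and residue names under *convention*.
    GRO coordinates are converted from nm to Angstrom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect == "gro":
        return _read_gro(path, convention)
    if dialect == "pdb":
        return _read_pdb(path, convention)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _parse_gro_time(title: str) -> float | None:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            return None
    return None


def _read_gro(path: Path, convention: NamingConvention) -> LabeledEnsemble:
    with open(path) as fh:
        lines = fh.read().splitlines()

    frames: list[Frame] = []
    topology: tuple[BeadRecord, ...] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():  # trailing blank lines
            i += 1
            continue
        frame_no += 1
        title = lines[i]
        if i + 1 >= len(lines):
            raise ParseError("truncated file: missing atom count", i + 2)
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise ParseError(
                f"expected atom count, got {lines[i + 1]!r}", i + 2
            ) from None
        if i + 2 + n_atoms >= len(lines) + 1 and i + 2 + n_atoms > len(lines):
            raise ParseError(
                f"truncated frame {frame_no}: expected {n_atoms} atom lines",
                len(lines),
            )
        records: list[BeadRecord] = []
        coords = np.empty((n_atoms, 3), dtype=np.float64)
        for j in range(n_atoms):
            ln = i + 2 + j
            line = lines[ln]
            try:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                name = line[10:15].strip()
                coords[j, 0] = float(line[20:28])
                coords[j, 1] = float(line[28:36])
                coords[j, 2] = float(line[36:44])
            except (ValueError, IndexError):
                raise ParseError(
                    f"malformed GRO atom line {line!r}", ln + 1
                ) from None
            if topology is None:
                records.append(
                    BeadRecord(
                        index=j,
                        name=name,
                        residue_name=resname,
                        residue_id=resid,
                        chain_id="",
                        role=convention.role_of(name, resname),
                    )
                )
        box_ln = i + 2 + n_atoms
        if box_ln >= len(lines):
            raise ParseError(f"frame {frame_no} is missing its box line", len(lines))
        box_fields = lines[box_ln].split()
        try:
            box_vals = [float(x) for x in box_fields]
        except ValueError:
            raise ParseError(
                f"malformed box line {lines[box_ln]!r}", box_ln + 1
            ) from None
        if len(box_vals) not in (3, 9):
            raise ParseError(
                f"box line must have 3 or 9 components, got {len(box_vals)}",
                box_ln + 1,
            )
        if len(box_vals) == 9 and any(abs(v) > 1e-9 for v in box_vals[3:]):
            raise StructureError(
                f"frame {frame_no}: triclinic box not supported "
                "(off-diagonal box components are nonzero)"
            )
        box = np.array(box_vals[:3]) * NM_TO_A

        if topology is None:
            topology = tuple(records)
        elif n_atoms != len(topology):
            raise StructureError(
                f"frame {frame_no} has {n_atoms} beads, frame 1 had {len(topology)}"
            )
        time = _parse_gro_time(title)
        frames.append(
            Frame(coords * NM_TO_A, box, float(frame_no - 1) if time is None else time)
        )
        i = box_ln + 1

    if topology is None:
        raise StructureError(f"no frames found in {path}")
    return LabeledEnsemble(topology, frames, source_format="gro")


def _write_gro(system: LabeledEnsemble, path: Path) -> None:
    with open(path, "w") as fh:
        for fr in system.frames:
            if not np.all(fr.box > 0):
                raise StructureError("GRO output requires a positive box")
            fh.write(f"memthick ensemble, t= {fr.time:.5f}\n")
            fh.write(f"{system.n_beads:5d}\n")
            for b, xyz in zip(system.topology, fr.coordinates):
                x, y, z = xyz / NM_TO_A
                fh.write(
                    f"{b.residue_id % 100000:5d}{b.residue_name:<5.5s}"
                    f"{b.name:>5.5s}{(b.index + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = fr.box / NM_TO_A
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB (via MDAnalysis)
# ---------------------------------------------------------------------------

def _parse_cryst1_records(path: Path) -> list[np.ndarray]:
    """All CRYST1 boxes in file order, as [a, b, c, alpha, beta, gamma].

    Parsed here because a CRYST1 record placed before the first MODEL (the
    usual layout for multi-MODEL files) is outside every frame's record
    range and therefore invisible to per-frame trajectory readers.
    """
    boxes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("CRYST1"):
                try:
                    vals = np.array(
                        [line[6:15], line[15:24], line[24:33],
                         line[33:40], line[40:47], line[47:54]],
                        dtype=float,
                    )
                except ValueError:
                    raise ParseError(f"malformed CRYST1 record {line!r}", ln) from None
                boxes.append(vals)
    return boxes


def _read_pdb(path: Path, convention: NamingConvention) -> LabeledEnsemble:
    import MDAnalysis as mda

    cryst = _parse_cryst1_records(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = u.atoms
        try:
            chains = atoms.chainIDs
        except AttributeError:
            chains = [""] * len(atoms)
        topology = tuple(
            BeadRecord(
                index=i,
                name=str(nm),
                residue_name=str(rn),
                residue_id=int(ri),
                chain_id=str(c).strip(),
                role=convention.role_of(str(nm), str(rn)),
            )
            for i, (nm, rn, ri, c) in enumerate(
                zip(atoms.names, atoms.resnames, atoms.resids, chains)
            )
        )
        frames: list[Frame] = []
        for k, ts in enumerate(u.trajectory):
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                dims = np.array(ts.dimensions, dtype=np.float64)
            elif cryst:
                dims = cryst[k] if len(cryst) == len(u.trajectory) else cryst[0]
            else:
                raise StructureError(
                    f"frame {k + 1}: PDB lacks a usable CRYST1 box record"
                )
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise StructureError(
                    f"frame {k + 1}: triclinic box not supported "
                    f"(angles {dims[3:]})"
                )
            frames.append(
                Frame(
                    np.array(atoms.positions, dtype=np.float64),
                    dims[:3].copy(),
                    float(ts.time),
                )
            )
    return LabeledEnsemble(topology, frames, source_format="pdb")


def _write_pdb(system: LabeledEnsemble, path: Path) -> None:
    import MDAnalysis as mda

    n = system.n_beads
    resids_seq = [b.residue_id for b in system.topology]
    # Build a residue index per bead (consecutive identical ids share one).
    resindex = np.zeros(n, dtype=int)
    ridx = 0
    for i in range(1, n):
        if (
            resids_seq[i] != resids_seq[i - 1]
            or system.topology[i].chain_id != system.topology[i - 1].chain_id
        ):
            ridx += 1
        resindex[i] = ridx
    n_res = ridx + 1
    first_of_res = np.searchsorted(resindex, np.arange(n_res))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=n_res, atom_resindex=resindex, trajectory=True
        )
        u.add_TopologyAttr("names", [b.name for b in system.topology])
        u.add_TopologyAttr(
            "resnames", [system.topology[i].residue_name for i in first_of_res]
        )
        u.add_TopologyAttr(
            "resids", [system.topology[i].residue_id for i in first_of_res]
        )
        u.add_TopologyAttr(
            "chainIDs", [b.chain_id or "X" for b in system.topology]
        )
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for fr in system.frames:
                u.atoms.positions = fr.coordinates
                u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_coordinates(
    system: LabeledEnsemble, path: str | os.PathLike, dialect: str | None = None
) -> Path:
    """Write *system* to *path* in the given dialect (inferred from the
    extension when omitted).  Round-tripping reproduces coordinates within
    format precision: 0.001 nm for GRO, 0.001 A for PDB."""
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower() or "gro"
    if dialect == "gro":
        _write_gro(system, path)
    elif dialect == "pdb":
        _write_pdb(system, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path
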