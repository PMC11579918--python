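"""Coordinate/topology data model and role-based bead selection.

The in-memory containers are deliberately small: a topology is a sequence of
:class:`BeadRecord`, a trajectory is a sequence of :class:`Frame`, and both
are bundled into a :class:`LabeledEnsemble`.  All internal lengths are in
Angstrom; unit conversion happens only at the I/O boundary (GRO files store
nanometres).  The membrane normal is the z-axis throughout.

Every bead is assigned exactly one :class:`Role` from its (name,
residue-name) pair under a configurable :class:`NamingConvention`; the
defaults cover Martini coarse-grained bead names (``PO4``, ``BB``, ``W``)
and all-atom PDB names (``P``, ``CA``, ``HOH``/``SOL``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptySelectionWarning, SelectionError, StructureError

__all__ = [
    "Role",
    "NamingConvention",
    "BeadRecord",
    "Frame",
    "LabeledEnsemble",
    "Selection",
    "select_beads",
    "parse_selection_query",
    "DEFAULT_CONVENTION",
]


class Role(str, Enum):
    """Functional role of a bead/atom, assigned purely from naming."""

    PROTEIN_BACKBONE = "protein_backbone"
    PROTEIN_OTHER = "protein_other"
    LIPID_PHOSPHATE = "lipid_phosphate"
    WATER = "water"
    OTHER = "other"


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "MSE",
}


@dataclass(frozen=True)
class NamingConvention:
    """Maps (bead name, residue name) pairs to roles.

    ``backbone_names`` covers both the Martini backbone bead (``BB``) and
    the all-atom C-alpha (``CA``); ``phosphate_names`` covers the Martini
    headgroup bead (``PO4``) and the atomistic phosphorus (``P``).
    """

    backbone_names: frozenset[str] = frozenset({"BB", "CA"})
    phosphate_names: frozenset[str] = frozenset({"PO4", "P"})
    water_names: frozenset[str] = frozenset({"W", "WN", "OW"})
    water_residues: frozenset[str] = frozenset({"W", "SOL", "HOH", "TIP3", "WAT"})
    protein_residues: frozenset[str] = frozenset(_AMINO_ACIDS)

    def role_of(self, name: str, residue_name: str) -> Role:
        name = name.strip().upper()
        residue_name = residue_name.strip().upper()
        if residue_name in self.water_residues or name in self.water_names:
            return Role.WATER
        if name in self.phosphate_names and residue_name not in self.protein_residues:
            return Role.LIPID_PHOSPHATE
        if name in self.backbone_names:
            return Role.PROTEIN_BACKBONE
        if residue_name in self.protein_residues:
            return Role.PROTEIN_OTHER
        return Role.OTHER


DEFAULT_CONVENTION = NamingConvention()


@dataclass(frozen=True)
class BeadRecord:
    index: int
    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    role: Role


@dataclass
class Frame:
    """One snapshot: coordinates in Angstrom, orthorhombic box, time in ps."""

    coordinates: np.ndarray  # (n_beads, 3) float64, Angstrom
    box: np.ndarray  # (3,) float64, Angstrom
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"frame coordinates must be (n, 3); got {self.coordinates.shape}"
            )
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise StructureError(f"box must be three positive lengths; got {self.box}")


@dataclass
class LabeledEnsemble:
    """Topology plus one or more frames sharing that topology."""

    topology: tuple[BeadRecord, ...]
    frames: list[Frame]
    source_format: str = "synthetic"  # gro | pdb | synthetic

    def __post_init__(self):
        self.topology = tuple(self.topology)
        if not self.frames:
            raise StructureError("an ensemble needs at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {i + 1} has {fr.coordinates.shape[0]} beads, "
                    f"topology has {n}"
                )

    @property
    def n_beads(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_beads, 3)."""
        return np.stack([fr.coordinates for fr in self.frames])

    def roles(self) -> np.ndarray:
        return np.array([b.role for b in self.topology], dtype=object)


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free set of bead indices with provenance."""

    bead_indices: tuple[int, ...]
    descriptor: str = ""

    def __post_init__(self):
        if len(set(self.bead_indices)) != len(self.bead_indices):
            raise SelectionError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.bead_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.bead_indices, dtype=np.intp)

    def coordinates(self, frame: Frame) -> np.ndarray:
        return frame.coordinates[self.indices]


def select_beads(
    system: LabeledEnsemble,
    role: Role | str | None = None,
    exclude_residues: Sequence[tuple[str | None, int, int]] = (),
    chain: str | None = None,
    include_residues: Sequence[tuple[str | None, int, int]] | None = None,
) -> Selection:
    """Role-based bead selection with inclusive residue-range exclusions.

    Parameters
    ----------
    role
        Keep only beads with this role (``None`` keeps all roles).
    exclude_residues
        Sequence of ``(chain_id_or_None, first, last)`` ranges; residue ids
        are matched against file numbering and both ends are inclusive,
        matching the ``resid a-b`` idiom of MD selection languages.
    chain
        Keep only beads on this chain.
    include_residues
        If given, keep only beads whose residue falls in one of these
        inclusive ranges (applied before exclusions).

    Selection order follows topology index order, so the operation is
    deterministic and idempotent.  An empty result raises
    :class:`EmptySelectionWarning` (as a warning) rather than passing
    silently.
    """
    if role is not None:
        role = Role(role)
        valid_roles = {b.role for b in system.topology}
        # A role absent from the system is a plausible typo worth flagging
        # only via the empty-selection warning below, not a hard error.

    def _in_ranges(b: BeadRecord, ranges) -> bool:
        for cid, lo, hi in ranges:
            if cid is not None and b.chain_id != cid:
                continue
            if min(lo, hi) <= b.residue_id <= max(lo, hi):
                return True
        return False

    kept: list[int] = []
    for b in system.topology:
        if role is not None and b.role != role:
            continue
        if chain is not None and b.chain_id != chain:
            continue
        if include_residues is not None and not _in_ranges(b, include_residues):
            continue
        if exclude_residues and _in_ranges(b, exclude_residues):
            continue
        kept.append(b.index)

    parts = []
    if role is not None:
        parts.append(f"role={role.value}")
    if chain is not None:
        parts.append(f"chain={chain}")
    for cid, lo, hi in exclude_residues:
        parts.append(f"exclude={cid or '*'}:{lo}-{hi}")
    descriptor = ",".join(parts) or "all"

    if not kept:
        warnings.warn(
            f"selection '{descriptor}' matched no beads", EmptySelectionWarning,
            stacklevel=2,
        )
    return Selection(tuple(kept), descriptor)


_QUERY_PART = re.compile(
    r"^(?:role=(?P<role>\w+)|chain=(?P<chain>\w+)|"
    r"exclude=(?P<xchain>[\w*]+):(?P<lo>\d+)-(?P<hi>\d+))$"
)


def parse_selection_query(query: str) -> dict:
    """Parse ``role=<r>[,chain=<c>][,exclude=<chain>:<a>-<b>...]`` into
    keyword arguments for :func:`select_beads`."""
    kwargs: dict = {"role": None, "chain": None, "exclude_residues": []}
    for part in filter(None, (p.strip() for p in query.split(","))):
        m = _QUERY_PART.match(part)
        if m is None:
            raise SelectionError(f"cannot parse selection term {part!r}")
        if m["role"]:
            kwargs["role"] = Role(m["role"])
        elif m["chain"]:
            kwargs["chain"] = m["chain"]
        else:
            cid = None if m["xchain"] == "*" else m["xchain"]
            kwargs["exclude_residues"].append((cid, int(m["lo"]), int(m["hi"])))
    return kwargs
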