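"""Synthetic bilayer, helix, and band-intensity generators with planted truth.

These generators provide ground-truth-bearing stand-ins for cluster-scale
coarse-grained simulations, so every downstream analysis (density profiles,
Gaussian thickness fits, TM-window selection, geometry, cleavage
statistics) can be validated by parameter recovery instead of by eye.

The bilayer model is intentionally minimal: one phosphate-like headgroup
bead per lipid, placed on a jittered square lattice in each leaflet, with
the local bilayer thickness following a smooth radial funnel around an
embedded protein cylinder,

    T(rho) = T_win + (T_bulk - T_win) * (1 - exp(-max(0, rho - r_p)^2 / (2 w^2)))

where ``rho`` is the lateral distance from the box-center axis, ``r_p`` the
protein radius and ``w`` the decay width.  At the protein surface the
bilayer is exactly ``T_win`` thick; far away it recovers ``T_bulk``.
Vertical Gaussian noise emulates thermal undulations; frames carry
independent noise (optionally AR(1)-correlated).  There are no lipid
tails, no dynamics and no flip-flop -- see docs/methods.md for what this
does and does not validate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BeadRecord, Frame, LabeledEnsemble, Role
from .errors import GeometryError

__all__ = [
    "ER_COMPOSITION",
    "BilayerSpec",
    "SyntheticTruth",
    "generate_bilayer",
    "generate_helix",
    "generate_band_table",
    "apportion_composition",
]

# Endoplasmic-reticulum model membrane composition (symmetric leaflets),
# after Monje-Galvan & Klauda; ratios 42:28:21:14:10:10:7:6:6:6.
ER_COMPOSITION: dict[str, float] = {
    "DYPC": 42, "YOPC": 28, "POPI": 21, "PYPI": 14, "DYPE": 10,
    "YOPE": 10, "ERGO": 7, "YOPA": 6, "YOPS": 6, "POPS": 6,
}


@dataclass(frozen=True)
class BilayerSpec:
    """Parameters of a synthetic two-leaflet bilayer with planted thickness.

    Lengths in Angstrom.  ``window_thickness == bulk_thickness`` together
    with ``protein_radius == 0`` gives a flat bilayer.  Defaults mirror a
    15 nm coarse-grained box with an ER-like lipid mixture.
    """

    bulk_thickness: float = 38.1
    window_thickness: float = 38.1
    window_radius: float = 16.0       # nominal extent of the thinned zone (metadata)
    decay_width: float = 25.0         # w of the radial funnel
    n_lipids_per_leaflet: int = 200
    area_per_lipid: float = 64.0      # A^2; sets the lattice constant
    z_noise_sigma: float = 1.0
    xy_jitter_sigma: float = 0.5
    n_frames: int = 100
    protein_radius: float = 0.0       # 0 -> no protein cylinder
    protein_half_height: float = 20.0
    n_protein_beads: int = 120
    water_slab: bool = False
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(ER_COMPOSITION)
    )
    seed: int = 0
    box_xy: float = 150.0
    box_z: float = 150.0
    ar1_coefficient: float = 0.0      # optional AR(1) memory of z-noise across frames

    def __post_init__(self):
        if not (0 < self.window_thickness <= self.bulk_thickness):
            raise ValueError(
                "require 0 < window_thickness <= bulk_thickness; got "
                f"{self.window_thickness} / {self.bulk_thickness}"
            )
        if self.window_radius < self.protein_radius:
            raise ValueError("window_radius must be >= protein_radius")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """The planted generator parameters plus realized per-species counts."""

    spec: BilayerSpec
    species_counts: dict[str, int]
    seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self.spec)
        d["composition"] = dict(d["composition"])
        return json.dumps(
            {"spec": d, "species_counts": self.species_counts, "seed": self.seed},
            indent=2,
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            spec=BilayerSpec(**d["spec"]),
            species_counts={k: int(v) for k, v in d["species_counts"].items()},
            seed=int(d["seed"]),
        )


def sidecar_path(coords_path: str | Path) -> Path:
    """Conventional location of the planted-truth sidecar for a coordinate file."""
    p = Path(coords_path)
    return p.with_suffix(p.suffix + ".truth.json")


def apportion_composition(
    composition: Mapping[str, float], n: int
) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` lipids among species ratios."""
    if n < 0:
        raise ValueError("n must be >= 0")
    total = float(sum(composition.values()))
    if total <= 0:
        raise ValueError("composition ratios must sum to > 0")
    quotas = {k: n * v / total for k, v in composition.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    # hand the leftover seats to the largest remainders, ties by name
    order = sorted(
        composition, key=lambda k: (-(quotas[k] - counts[k]), k)
    )
    for k in order[:short]:
        counts[k] += 1
    return counts


def local_thickness(
    rho: np.ndarray | float,
    bulk: float,
    window: float,
    protein_radius: float,
    decay_width: float,
) -> np.ndarray | float:
    """Planted thickness profile T(rho) of the radial funnel deformation."""
    d = np.maximum(0.0, np.asarray(rho, dtype=float) - protein_radius)
    return window + (bulk - window) * (1.0 - np.exp(-(d ** 2) / (2.0 * decay_width ** 2)))


def _protein_cylinder(spec: BilayerSpec, center: np.ndarray) -> np.ndarray:
    """Beads on the cylinder surface via a golden-angle spiral (static)."""
    n = spec.n_protein_beads
    k = np.arange(n)
    theta = k * (np.pi * (3.0 - np.sqrt(5.0)))
    z = -spec.protein_half_height + (2.0 * spec.protein_half_height) * (
        (k + 0.5) / n
    )
    xyz = np.column_stack(
        [
            center[0] + spec.protein_radius * np.cos(theta),
            center[1] + spec.protein_radius * np.sin(theta),
            z,
        ]
    )
    return xyz


def generate_bilayer(spec: BilayerSpec) -> tuple[LabeledEnsemble, SyntheticTruth]:
    """Generate a bilayer (+ optional protein cylinder and water slabs).

    Coordinates are membrane-centered: the bilayer midplane lies at z = 0
    and the box spans [-box/2, +box/2] in every direction.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = math.sqrt(spec.area_per_lipid)
    n_side = int(spec.box_xy // spacing)
    if n_side < 1:
        raise GeometryError("box too small for even one lipid lattice site")
    ax = (np.arange(n_side) - (n_side - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    has_protein = spec.protein_radius > 0 and spec.n_protein_beads > 0
    if has_protein:
        rho = np.hypot(sites[:, 0], sites[:, 1])
        sites = sites[rho >= spec.protein_radius]
    if len(sites) < spec.n_lipids_per_leaflet:
        raise GeometryError(
            f"lattice holds only {len(sites)} sites at {spec.area_per_lipid} "
            f"A^2/lipid in a {spec.box_xy} A box; cannot place "
            f"{spec.n_lipids_per_leaflet} lipids per leaflet"
        )
    chosen = sites[
        rng.choice(len(sites), size=spec.n_lipids_per_leaflet, replace=False)
    ]

    n_lip = spec.n_lipids_per_leaflet
    counts = apportion_composition(spec.composition, n_lip)
    species = np.repeat(
        [k for k in counts], [counts[k] for k in counts]
    )
    species = species[rng.permutation(n_lip)]

    records: list[BeadRecord] = []
    resid = 0
    for leaflet in ("U", "L"):
        for s in species:
            resid += 1
            records.append(
                BeadRecord(
                    index=len(records),
                    name="PO4",
                    residue_name=str(s),
                    residue_id=resid,
                    chain_id=leaflet,
                    role=Role.LIPID_PHOSPHATE,
                )
            )
    protein_xyz = None
    if has_protein:
        protein_xyz = _protein_cylinder(spec, np.zeros(2))
        for j in range(spec.n_protein_beads):
            resid += 1
            records.append(
                BeadRecord(
                    index=len(records),
                    name="BB",
                    residue_name="ALA",
                    residue_id=resid,
                    chain_id="P",
                    role=Role.PROTEIN_BACKBONE,
                )
            )
    water_xyz = None
    if spec.water_slab:
        w_spacing = 4.0
        z_lo = spec.bulk_thickness / 2.0 + 3.0
        z_hi = min(spec.box_z / 2.0 - 2.0, z_lo + 16.0)
        if z_hi <= z_lo:
            raise GeometryError("box_z too small to host a water slab")
        n_w_side = max(1, int(spec.box_xy // w_spacing))
        wax = (np.arange(n_w_side) - (n_w_side - 1) / 2.0) * w_spacing
        wz = np.arange(z_lo, z_hi, w_spacing)
        WX, WY, WZ = np.meshgrid(wax, wax, wz, indexing="ij")
        upper = np.column_stack([WX.ravel(), WY.ravel(), WZ.ravel()])
        water_xyz = np.vstack([upper, upper * np.array([1.0, 1.0, -1.0])])
        for j in range(len(water_xyz)):
            resid += 1
            records.append(
                BeadRecord(
                    index=len(records),
                    name="W",
                    residue_name="W",
                    residue_id=resid,
                    chain_id="W",
                    role=Role.WATER,
                )
            )

    box = np.array([spec.box_xy, spec.box_xy, spec.box_z])
    frames: list[Frame] = []
    prev_noise = None
    phi = spec.ar1_coefficient
    for f in range(spec.n_frames):
        jitter = (
            rng.normal(0.0, spec.xy_jitter_sigma, size=(2, n_lip, 2))
            if spec.xy_jitter_sigma > 0
            else np.zeros((2, n_lip, 2))
        )
        innov = rng.normal(0.0, spec.z_noise_sigma, size=(2, n_lip))
        if phi > 0 and prev_noise is not None:
            znoise = phi * prev_noise + math.sqrt(1.0 - phi ** 2) * innov
        else:
            znoise = innov
        prev_noise = znoise

        coords = []
        for li, sign in enumerate((+1.0, -1.0)):
            xy = chosen + jitter[li]
            rho = np.hypot(xy[:, 0], xy[:, 1])
            half_t = 0.5 * local_thickness(
                rho,
                spec.bulk_thickness,
                spec.window_thickness,
                spec.protein_radius,
                spec.decay_width,
            )
            z = sign * half_t + znoise[li]
            coords.append(np.column_stack([xy, z]))
        parts = coords
        if protein_xyz is not None:
            parts.append(protein_xyz)
        if water_xyz is not None:
            parts.append(water_xyz)
        frames.append(Frame(np.vstack(parts), box.copy(), time=float(f)))

    truth = SyntheticTruth(spec=spec, species_counts=counts, seed=spec.seed)
    return LabeledEnsemble(tuple(records), frames, source_format="synthetic"), truth


def generate_helix(
    n_residues: int,
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    rise_per_residue: float = 1.5,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    radius: float = 2.3,
    twist_deg: float = 100.0,
    phase_deg: float = 0.0,
) -> LabeledEnsemble:
    """Ideal backbone-bead helix along an arbitrary axis.

    One bead per residue at helix radius 2.3 A with a 100 degree/residue
    twist; the axial extent from bead i to bead j is (j - i) * rise.
    """
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues for axis estimation")
    axis = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise GeometryError("helix direction vector must be nonzero")
    axis = axis / norm
    # deterministic orthonormal frame perpendicular to the axis
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed_vec) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, seed_vec)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    k = np.arange(n_residues)
    ang = np.deg2rad(phase_deg + twist_deg * k)
    xyz = (
        np.asarray(origin, dtype=float)
        + np.outer(k * rise_per_residue, axis)
        + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )
    records = tuple(
        BeadRecord(
            index=i, name="BB", residue_name="ALA", residue_id=i + 1,
            chain_id="H", role=Role.PROTEIN_BACKBONE,
        )
        for i in range(n_residues)
    )
    span = np.ptp(xyz, axis=0).max() + 2 * radius + 20.0
    frame = Frame(xyz, np.full(3, max(span, 50.0)), 0.0)
    return LabeledEnsemble(records, [frame], source_format="synthetic")


def generate_band_table(
    true_cleavage: Sequence[float],
    n_lengths: Sequence[int] | None = None,
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
    strain: str = "WT",
    construct_prefix: str = "N",
    total_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Replicate band-intensity table with lognormal multiplicative noise.

    Each planted cleavage percentage p yields per-replicate cleaved and
    full-length intensities ``p/100 * I`` and ``(1 - p/100) * I``, each
    multiplied by an independent lognormal factor with unit mean and
    coefficient of variation ``cv``, emulating densitometry in arbitrary
    units.  With ``cv = 0`` the planted value is recovered exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    true_cleavage = np.asarray(true_cleavage, dtype=float)
    if np.any((true_cleavage < 0) | (true_cleavage > 100)):
        raise ValueError("true cleavage percentages must lie in [0, 100]")
    if n_lengths is None:
        n_lengths = list(range(len(true_cleavage)))
    if len(n_lengths) != len(true_cleavage):
        raise ValueError("n_lengths and true_cleavage lengths differ")
    rng = np.random.default_rng(seed)
    sigma2 = math.log(1.0 + cv ** 2)
    sigma = math.sqrt(sigma2)

    rows = []
    for nl, p in zip(n_lengths, true_cleavage):
        base_c = total_intensity * p / 100.0
        base_f = total_intensity * (1.0 - p / 100.0)
        factors = (
            np.exp(rng.normal(-sigma2 / 2.0, sigma, size=(n_replicates, 2)))
            if cv > 0
            else np.ones((n_replicates, 2))
        )
        for r in range(n_replicates):
            rows.append(
                {
                    "construct": f"{construct_prefix}{nl}",
                    "n_length": int(nl),
                    "strain": strain,
                    "replicate": r + 1,
                    "cleaved": base_c * factors[r, 0],
                    "full": base_f * factors[r, 1],
                }
            )
    return pd.DataFrame(rows)
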