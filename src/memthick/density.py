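"""Number-density profiles along the membrane normal and 3-D density maps.

The profile is the frame-averaged histogram of selected bead z-coordinates
divided by the slab volume (box_x * box_y * bin_width), in beads/A^3 --
the number-density analogue of the usual MD density tools.  The map is a
frame-averaged 3-D histogram on a uniform grid, optionally smoothed with a
periodic Gaussian kernel; smoothing preserves the integral.

Coordinates are taken as emitted (membrane-centered, in-box); an optional
wrap into the primary box is available at read time, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import Frame, LabeledEnsemble, Selection
from .errors import SelectionError

__all__ = [
    "DensityProfile",
    "DensityMap",
    "density_profile",
    "volumetric_map",
    "write_profile_tsv",
    "write_profile_xvg",
    "write_map_dx",
]


@dataclass
class DensityProfile:
    bin_edges: np.ndarray       # (n_bins + 1,) A, uniform
    density: np.ndarray         # (n_bins,) beads/A^3, frame-averaged
    n_frames: int
    selection_descriptor: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("density length must equal len(bin_edges) - 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class DensityMap:
    origin: np.ndarray          # (3,) A, corner of voxel (0,0,0)
    spacing: float              # A, cubic voxels
    density: np.ndarray         # (nx, ny, nz) beads/A^3, frame-averaged

    def total_count(self) -> float:
        """Integral of the map: mean number of selected beads per frame."""
        return float(self.density.sum() * self.spacing ** 3)


def density_profile(
    system: LabeledEnsemble,
    selection: Selection,
    bin_width: float = 1.0,
    z_range: tuple[float, float] | None = None,
    stride: int = 1,
) -> DensityProfile:
    """Frame-averaged number density of *selection* along z.

    ``z_range`` defaults to the membrane-centered box extent
    ``(-box_z/2, +box_z/2)`` of the first frame; beads outside it are
    ignored.  ``stride`` subsamples frames.
    """
    if len(selection) == 0:
        raise SelectionError("cannot compute a density profile of an empty selection")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    box0 = system.frames[0].box
    if bin_width >= box0[2]:
        raise ValueError(
            f"bin_width {bin_width} A is not smaller than the box height {box0[2]} A"
        )
    if z_range is None:
        z_range = (-box0[2] / 2.0, box0[2] / 2.0)
    lo, hi = map(float, z_range)
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)

    idx = selection.indices
    frames = system.frames[::stride]
    acc = np.zeros(n_bins, dtype=float)
    for fr in frames:
        z = fr.coordinates[idx, 2]
        counts, _ = np.histogram(z, bins=edges)
        acc += counts / (fr.box[0] * fr.box[1] * bin_width)
    acc /= len(frames)
    return DensityProfile(edges, acc, len(frames), selection.descriptor)


def volumetric_map(
    system: LabeledEnsemble,
    selection: Selection,
    spacing: float = 2.0,
    smoothing_sigma: float = 0.0,
    stride: int = 1,
) -> DensityMap:
    """Frame-averaged 3-D number-density map of *selection*.

    Before smoothing the integral of the map equals the mean number of
    selected beads that fall inside the grid; Gaussian smoothing uses
    periodic boundaries and therefore preserves that integral.
    """
    if len(selection) == 0:
        raise SelectionError("cannot compute a density map of an empty selection")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    box = system.frames[0].box
    if spacing > min(box) / 2.0:
        raise ValueError(
            f"spacing {spacing} A exceeds half the smallest box edge ({min(box) / 2} A)"
        )
    shape = np.maximum(1, np.round(box / spacing).astype(int))
    origin = -0.5 * box
    edges = [origin[d] + spacing * np.arange(shape[d] + 1) for d in range(3)]

    idx = selection.indices
    frames = system.frames[::stride]
    acc = np.zeros(shape, dtype=float)
    for fr in frames:
        h, _ = np.histogramdd(fr.coordinates[idx], bins=edges)
        acc += h
    acc /= len(frames) * spacing ** 3
    if smoothing_sigma > 0:
        acc = ndimage.gaussian_filter(acc, sigma=smoothing_sigma / spacing, mode="wrap")
    return DensityMap(origin=origin, spacing=float(spacing), density=acc)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: DensityProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# z_mid_A\tdensity_per_A3\n")
        for z, d in zip(profile.bin_centers, profile.density):
            fh.write(f"{z:.4f}\t{d:.8e}\n")
    return path


def write_profile_xvg(profile: DensityProfile, path: str | Path) -> Path:
    """Two-column xmgrace-style output, matching MD density-tool conventions."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write('@    title "Number density profile"\n')
        fh.write('@    xaxis  label "z (A)"\n')
        fh.write('@    yaxis  label "density (beads/A^3)"\n')
        fh.write(f'# selection: {profile.selection_descriptor}, '
                 f'frames: {profile.n_frames}\n')
        for z, d in zip(profile.bin_centers, profile.density):
            fh.write(f"{z:12.4f} {d:14.8e}\n")
    return path


def write_map_dx(dmap: DensityMap, path: str | Path) -> Path:
    """OpenDX scalar grid, readable by VMD and PyMOL."""
    path = Path(path)
    nx, ny, nz = dmap.density.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        ox, oy, oz = dmap.origin + dmap.spacing / 2.0
        fh.write(f"origin {ox:.4f} {oy:.4f} {oz:.4f}\n")
        fh.write(f"delta {dmap.spacing:.4f} 0 0\n")
        fh.write(f"delta 0 {dmap.spacing:.4f} 0\n")
        fh.write(f"delta 0 0 {dmap.spacing:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = dmap.density.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
    return path
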