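"""Rigid-body superposition, RMSD/RMSF validation metrics, and helix geometry.

Superposition uses the Kabsch SVD algorithm with the reflection guard, so
the returned rotation is always proper.  Helix axes follow the endpoint
convention common in membrane-protein work: the vector from the centroid
of the first *n_end* residues' backbone beads to the centroid of the last
*n_end* (default 3), oriented in sequence order.  Crossing angles between
two such axes are reported in [0, 180] degrees, optionally folded to
[0, 90] when the mutual orientation of the helices is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BeadRecord, Frame, LabeledEnsemble, Role, Selection
from .errors import GeometryError, SelectionError

__all__ = [
    "SuperpositionResult",
    "HelixAxis",
    "AngleSeries",
    "RMSFProfile",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "helix_axis",
    "helix_span",
    "cross_angle",
    "cross_angle_series",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3), proper (det = +1)
    translation: np.ndarray   # (3,)
    rmsd: float               # A, over the fitted selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class HelixAxis:
    start_centroid: np.ndarray
    end_centroid: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return self.end_centroid - self.start_centroid


@dataclass
class AngleSeries:
    per_frame_angle: np.ndarray  # degrees in [0, 180] (or [0, 90] if folded)
    mean: float
    sd: float


@dataclass
class RMSFProfile:
    per_residue_rmsf: np.ndarray   # A, one value per selected bead
    replicate_sd: np.ndarray       # A, SD across replicates (zeros if none)
    selection_descriptor: str = ""


def _fit_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch: proper rotation minimizing RMSD of centered clouds."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    # degenerate (collinear or coincident) clouds have rank < 2
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise GeometryError(
            "selection is collinear or degenerate; superposition is ill-defined"
        )
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cm, cr


def kabsch_superpose(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    selection: Selection | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    With a selection, only the selected beads define (and score) the fit.
    Requires at least 3 non-collinear beads.
    """
    mob = mobile.coordinates if isinstance(mobile, Frame) else np.asarray(mobile, float)
    ref = reference.coordinates if isinstance(reference, Frame) else np.asarray(reference, float)
    if selection is not None:
        mob = mob[selection.indices]
        ref = ref[selection.indices]
    if mob.shape != ref.shape:
        raise GeometryError("mobile and reference selections differ in size")
    if len(mob) < 3:
        raise GeometryError("superposition needs at least 3 beads")
    R, cm, cr = _fit_rotation(mob, ref)
    t = cr - cm @ R.T
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_series(
    ensemble: LabeledEnsemble,
    reference_frame: int | Frame = 0,
    selection: Selection | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (A) from a reference structure over a selection.

    With ``superpose=True`` (default) each frame is rigidly fitted to the
    reference on the same selection before scoring, as is standard for
    model-stability validation.
    """
    if selection is not None and len(selection) == 0:
        raise SelectionError("empty selection for RMSD")
    ref = (
        ensemble.frames[reference_frame]
        if isinstance(reference_frame, int)
        else reference_frame
    )
    ref_xyz = ref.coordinates if selection is None else selection.coordinates(ref)
    out = np.empty(ensemble.n_frames)
    for i, fr in enumerate(ensemble.frames):
        xyz = fr.coordinates if selection is None else selection.coordinates(fr)
        if np.array_equal(xyz, ref_xyz):  # exact zero for the reference itself
            out[i] = 0.0
        elif superpose:
            out[i] = kabsch_superpose(xyz, ref_xyz).rmsd
        else:
            out[i] = float(np.sqrt(((xyz - ref_xyz) ** 2).sum(axis=1).mean()))
    return out


def _single_rmsf(
    ensemble: LabeledEnsemble, selection: Selection | None, superpose_to_mean: bool
) -> np.ndarray:
    coords = ensemble.coordinate_array()
    if selection is not None:
        coords = coords[:, selection.indices, :]
    if superpose_to_mean:
        # two rounds: fit to frame 0, average, then fit to the running mean
        ref = coords[0]
        for _ in range(2):
            fitted = np.empty_like(coords)
            for i in range(coords.shape[0]):
                sp = kabsch_superpose(coords[i], ref)
                fitted[i] = sp.apply(coords[i])
            ref = fitted.mean(axis=0)
        coords = fitted
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf_profile(
    ensemble: LabeledEnsemble,
    selection: Selection | None = None,
    superpose_to_mean: bool = True,
    replicate_ensembles: Sequence[LabeledEnsemble] | None = None,
) -> RMSFProfile:
    """Per-bead root-mean-square fluctuation about the ensemble mean.

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) after (optional) superposition of each
    frame onto the ensemble mean.  With replicates, the profile is the mean
    across replicates and ``replicate_sd`` the sample SD across them.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ensembles = [ensemble] + list(replicate_ensembles or [])
    profiles = np.stack(
        [_single_rmsf(e, selection, superpose_to_mean) for e in ensembles]
    )
    if len(ensembles) > 1:
        sd = profiles.std(axis=0, ddof=1)
    else:
        sd = np.zeros(profiles.shape[1])
    return RMSFProfile(
        per_residue_rmsf=profiles.mean(axis=0),
        replicate_sd=sd,
        selection_descriptor=selection.descriptor if selection else "all",
    )


def helix_axis(
    frame: Frame,
    topology: Sequence[BeadRecord],
    residue_range: tuple[int, int],
    n_end: int = 3,
    chain: str | None = None,
) -> HelixAxis:
    """Endpoint-centroid helix axis over backbone beads of a residue range.

    The range is inclusive and taken against file numbering; giving it
    reversed (a > b) flips the vector.  ``n_end`` residues at each end
    define the centroids.
    """
    a, b = residue_range
    step = 1 if b >= a else -1
    resids = list(range(a, b + step, step))
    if len(resids) < 2 * n_end:
        raise GeometryError(
            f"range {a}-{b} holds {len(resids)} residues; need >= {2 * n_end}"
        )
    by_resid: dict[int, list[int]] = {}
    for bead in topology:
        if bead.role is not Role.PROTEIN_BACKBONE:
            continue
        if chain is not None and bead.chain_id != chain:
            continue
        by_resid.setdefault(bead.residue_id, []).append(bead.index)
    missing = [r for r in resids if r not in by_resid]
    if missing:
        raise SelectionError(f"no backbone beads for residues {missing}")

    def centroid(rs: list[int]) -> np.ndarray:
        idx = [i for r in rs for i in by_resid[r]]
        return frame.coordinates[idx].mean(axis=0)

    return HelixAxis(
        start_centroid=centroid(resids[:n_end]),
        end_centroid=centroid(resids[-n_end:]),
    )


def helix_span(n_residues: int, rise_per_residue: float = 1.5) -> float:
    """Axial span of an ideal alpha-helix: residues x 1.5 A canonical rise.

    A 14-residue transmembrane helix spans 21 A -- the hydrophobic
    matching argument for which membrane thickness a helix 'fits'.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return n_residues * rise_per_residue


def cross_angle(a: HelixAxis | np.ndarray, b: HelixAxis | np.ndarray,
                fold_to_90: bool = False) -> float:
    """Angle between two helix-axis vectors, degrees.

    In [0, 180] by default; ``fold_to_90`` maps antiparallel onto parallel
    (theta -> 180 - theta above 90) for analyses where helix directionality
    is irrelevant.
    """
    va = a.vector if isinstance(a, HelixAxis) else np.asarray(a, float)
    vb = b.vector if isinstance(b, HelixAxis) else np.asarray(b, float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        raise GeometryError("cross angle undefined for a zero vector")
    cosang = float(np.clip(va @ vb / (na * nb), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(cosang)))
    if fold_to_90 and ang > 90.0:
        ang = 180.0 - ang
    return ang


def cross_angle_series(
    ensemble: LabeledEnsemble,
    range_a: tuple[int, int],
    range_b: tuple[int, int],
    chain_a: str | None = None,
    chain_b: str | None = None,
    n_end: int = 3,
    fold_to_90: bool = False,
) -> AngleSeries:
    """Per-frame crossing angle between two helices defined by residue ranges."""
    angles = np.empty(ensemble.n_frames)
    for i, fr in enumerate(ensemble.frames):
        axis_a = helix_axis(fr, ensemble.topology, range_a, n_end, chain_a)
        axis_b = helix_axis(fr, ensemble.topology, range_b, n_end, chain_b)
        angles[i] = cross_angle(axis_a, axis_b, fold_to_90)
    return AngleSeries(
        per_frame_angle=angles,
        mean=float(angles.mean()),
        sd=float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
    )
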