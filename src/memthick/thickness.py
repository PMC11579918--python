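"""Local membrane-thickness estimation from phosphate density profiles.

Bilayer thickness is read off as the separation of the two leaflet peaks
in the number-density profile of phosphate headgroup beads along the
membrane normal.  Two regions are distinguished:

* ``bulk`` -- all phosphates of a protein-free reference membrane, fitted
  with a sum of two Gaussians (one per leaflet);
* ``tm_window`` -- only phosphates within a cutoff (default 6 A) of any
  protein bead, re-evaluated every frame because lipids exchange, fitted
  with a sum of three Gaussians.  The third, central component absorbs
  deeper-lying headgroups drawn into the thinned zone, so the thickness is
  always the separation of the two *outermost* component means -- the
  reading that reduces exactly to the two-Gaussian case.

Replicate simulations are aggregated as mean +/- SEM across replicates
(never across frames, which are autocorrelated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal
from scipy.spatial import cKDTree

from .core import Frame, LabeledEnsemble, Role, Selection, select_beads
from .density import DensityProfile
from .errors import FitError

__all__ = [
    "GaussianFitResult",
    "ThicknessResult",
    "tm_window_selection",
    "window_density_profile",
    "fit_leaflet_gaussians",
    "thickness_from_fit",
    "thickness_pipeline",
    "relative_thinning",
    "thickness_difference",
]


@dataclass
class GaussianFitResult:
    """K-component Gaussian fit A_k * exp(-(z - mu_k)^2 / (2 sigma_k^2)).

    Components are sorted by mean.  ``parameter_standard_errors`` mirrors
    ``components`` as (A, mu, sigma) triples from the covariance of the
    least-squares fit (NaN when unavailable).
    """

    components: list[tuple[float, float, float]]  # (amplitude, mean, sigma)
    parameter_standard_errors: list[tuple[float, float, float]]
    residual_norm: float
    r_squared: float
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])


@dataclass
class ThicknessResult:
    region: str                                # "bulk" | "tm_window"
    per_replicate_thickness: list[float]       # A
    mean: float
    sem: float
    method: str                                # "double" | "triple"
    n_replicates: int
    fits: list[GaussianFitResult] | None = None


def tm_window_selection(
    frame: Frame,
    protein_selection: Selection,
    phosphate_selection: Selection,
    cutoff: float = 6.0,
) -> Selection:
    """Phosphates within *cutoff* of any protein bead in this frame.

    The TM-window membrane patch is defined dynamically: the set of
    headgroups lining the protein changes frame to frame as lipids
    exchange.  Distances are plain Euclidean minima over all protein
    beads (boundary inclusive).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(protein_selection) == 0 or len(phosphate_selection) == 0:
        raise ValueError("both protein and phosphate selections must be non-empty")
    tree = cKDTree(protein_selection.coordinates(frame))
    d, _ = tree.query(phosphate_selection.coordinates(frame), k=1)
    keep = np.asarray(phosphate_selection.bead_indices)[d <= cutoff]
    return Selection(
        tuple(int(i) for i in keep),
        f"{phosphate_selection.descriptor} within {cutoff} A of protein",
    )


def window_density_profile(
    system: LabeledEnsemble,
    protein_selection: Selection,
    phosphate_selection: Selection,
    cutoff: float = 6.0,
    bin_width: float = 1.0,
    z_range: tuple[float, float] | None = None,
    stride: int = 1,
) -> DensityProfile:
    """Number density of TM-window phosphates, window re-selected per frame."""
    box0 = system.frames[0].box
    if z_range is None:
        z_range = (-box0[2] / 2.0, box0[2] / 2.0)
    lo, hi = map(float, z_range)
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)

    frames = system.frames[::stride]
    acc = np.zeros(n_bins, dtype=float)
    for fr in frames:
        sel = tm_window_selection(fr, protein_selection, phosphate_selection, cutoff)
        if len(sel) == 0:
            continue
        z = fr.coordinates[sel.indices, 2]
        counts, _ = np.histogram(z, bins=edges)
        acc += counts / (fr.box[0] * fr.box[1] * bin_width)
    acc /= len(frames)
    return DensityProfile(
        edges, acc, len(frames),
        f"tm_window(cutoff={cutoff} A) phosphates",
    )


def _gauss_sum(z: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(z, dtype=float)
    for k in range(len(params) // 3):
        a, mu, s = params[3 * k: 3 * k + 3]
        out += a * np.exp(-((z - mu) ** 2) / (2.0 * s ** 2))
    return out


def fit_leaflet_gaussians(
    profile: DensityProfile, n_components: int = 2, weighted: bool = False
) -> GaussianFitResult:
    """Nonlinear least-squares fit of K Gaussians to a density profile.

    Initialization places the two outer components on the two outermost
    local maxima of the profile and, for K = 3, the third at their
    midpoint.  Non-convergence is reported via ``converged=False``, never
    silently.  ``weighted=True`` weights residuals by sqrt(density)
    (Poisson-like); the default is unweighted.
    """
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    z = profile.bin_centers
    y = profile.density
    nonzero = np.count_nonzero(y)
    if nonzero < 2 * n_components + 1:
        raise FitError(
            f"profile '{profile.selection_descriptor}' has only {nonzero} nonzero "
            f"bins; need at least {2 * n_components + 1} for a {n_components}-"
            "component fit"
        )
    ymax = float(y.max())
    peaks, _ = signal.find_peaks(y, prominence=0.05 * ymax)
    if len(peaks) < 2:
        raise FitError(
            f"profile '{profile.selection_descriptor}' shows fewer than two "
            "detectable leaflet peaks; cannot initialize the fit"
        )
    left, right = int(peaks[0]), int(peaks[-1])
    bw = profile.bin_width
    sigma0 = max(2.0 * bw, 0.05 * (z[right] - z[left]))

    p0 = [y[left], z[left], sigma0]
    if n_components == 3:
        mid = 0.5 * (z[left] + z[right])
        mid_idx = int(np.argmin(np.abs(z - mid)))
        p0 += [max(y[mid_idx], 1e-3 * ymax), mid, sigma0]
    p0 += [y[right], z[right], sigma0]

    lower, upper = [], []
    for _ in range(n_components):
        lower += [0.0, z[0], 0.25 * bw]
        upper += [np.inf, z[-1], z[-1] - z[0]]

    sigma_w = None
    if weighted:
        sigma_w = 1.0 / np.sqrt(np.maximum(y, 1e-3 * ymax))

    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            _gauss_sum, z, y, p0=p0, sigma=sigma_w,
            bounds=(lower, upper), maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
    except (RuntimeError, optimize.OptimizeWarning):
        converged = False
        popt = np.asarray(p0, dtype=float)
        perr = np.full(len(p0), np.nan)
    if not np.all(np.isfinite(popt)):
        converged = False

    comps = sorted(
        [tuple(popt[3 * k: 3 * k + 3]) for k in range(n_components)],
        key=lambda c: c[1],
    )
    order = np.argsort([popt[3 * k + 1] for k in range(n_components)])
    errs = [tuple(perr[3 * k: 3 * k + 3]) for k in order]
    resid = y - _gauss_sum(z, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    return GaussianFitResult(
        components=[tuple(float(v) for v in c) for c in comps],
        parameter_standard_errors=[tuple(float(v) for v in e) for e in errs],
        residual_norm=float(np.sqrt(ss_res)),
        r_squared=r2,
        converged=converged,
    )


def thickness_from_fit(fit: GaussianFitResult, amplitude_floor: float = 0.01) -> float:
    """Peak-separation thickness: distance between the outermost means.

    Invariant to amplitude scaling and to any rigid z-shift of the profile;
    for the triple fit the central component is ignored by construction.
    Components whose amplitude has collapsed below ``amplitude_floor``
    times the largest amplitude are vestigial -- they carry essentially no
    density and their means are unconstrained by the data (this happens
    when a 3-component model is fitted to a profile with no mid-plane
    population) -- and are excluded before taking the outermost pair.
    """
    if not fit.converged:
        raise FitError("cannot extract thickness from an unconverged fit")
    amps = np.array([c[0] for c in fit.components])
    means = fit.means[amps >= amplitude_floor * amps.max()]
    if len(means) < 2:
        raise FitError(
            "fewer than two non-vestigial components; no leaflet separation"
        )
    return float(means.max() - means.min())


def thickness_pipeline(
    replicate_ensembles: Sequence[LabeledEnsemble],
    region: str = "bulk",
    protein_query: dict | None = None,
    cutoff: float = 6.0,
    bin_width: float = 1.0,
    n_components: int | None = None,
    stride: int = 1,
) -> ThicknessResult:
    """Select -> profile -> fit -> thickness for each replicate, then aggregate.

    ``region='bulk'`` uses every phosphate (double-Gaussian fit);
    ``region='tm_window'`` uses the dynamic 6 A window around the protein
    (triple-Gaussian fit).  Replicates whose fit does not converge are
    excluded with a warning.  SEM uses the n-1 sample SD over replicates;
    a single replicate yields SEM 0 with a warning.
    """
    if region not in ("bulk", "tm_window"):
        raise ValueError("region must be 'bulk' or 'tm_window'")
    if region == "tm_window" and protein_query is None:
        protein_query = {"role": Role.PROTEIN_BACKBONE}
    k = n_components or (3 if region == "tm_window" else 2)
    method = {2: "double", 3: "triple"}[k]

    values: list[float] = []
    fits: list[GaussianFitResult] = []
    for i, ens in enumerate(replicate_ensembles):
        phosphates = select_beads(ens, role=Role.LIPID_PHOSPHATE)
        if region == "tm_window":
            protein = select_beads(ens, **protein_query)
            profile = window_density_profile(
                ens, protein, phosphates, cutoff=cutoff,
                bin_width=bin_width, stride=stride,
            )
        else:
            from .density import density_profile

            profile = density_profile(ens, phosphates, bin_width=bin_width,
                                      stride=stride)
        try:
            fit = fit_leaflet_gaussians(profile, n_components=k)
        except FitError as exc:
            warnings.warn(
                f"replicate {i + 1}: fit could not be initialized ({exc}); "
                "replicate excluded"
            )
            continue
        if not fit.converged:
            warnings.warn(f"replicate {i + 1}: fit did not converge; excluded")
            continue
        fits.append(fit)
        values.append(thickness_from_fit(fit))

    if not values:
        raise FitError("no replicate produced a converged fit")
    arr = np.asarray(values)
    if len(arr) == 1:
        warnings.warn("single replicate: SEM reported as 0")
        sem = 0.0
    else:
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr)))
    return ThicknessResult(
        region=region,
        per_replicate_thickness=[float(v) for v in arr],
        mean=float(arr.mean()),
        sem=sem,
        method=method,
        n_replicates=len(arr),
        fits=fits,
    )


def relative_thinning(bulk: float, window: float) -> float:
    """Percent thinning of the window region relative to bulk.

    Negative values (thickening) are allowed but flagged with a warning.
    """
    if bulk <= 0:
        raise ValueError("bulk thickness must be > 0")
    value = (bulk - window) / bulk * 100.0
    if value < 0:
        warnings.warn(
            f"window ({window} A) thicker than bulk ({bulk} A): "
            "negative thinning (thickening)"
        )
    return value


def thickness_difference(a: ThicknessResult, b: ThicknessResult) -> dict[str, float]:
    """Difference of two thickness estimates with SEMs combined in quadrature."""
    return {
        "difference": a.mean - b.mean,
        "propagated_error": float(np.sqrt(a.sem ** 2 + b.sem ** 2)),
    }
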