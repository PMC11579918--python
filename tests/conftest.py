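import numpy as np
import pytest

from memthick import BilayerSpec, generate_bilayer
from memthick.core import BeadRecord, Frame, LabeledEnsemble, Role


@pytest.fixture
def flat_bilayer():
    """Noise-free flat bilayer: 50 lipids/leaflet, leaflets at +/-19.05 A."""
    spec = BilayerSpec(
        bulk_thickness=38.1, window_thickness=38.1, z_noise_sigma=0.0,
        xy_jitter_sigma=0.0, n_frames=1, n_lipids_per_leaflet=50,
        box_xy=80.0, seed=11,
    )
    ens, truth = generate_bilayer(spec)
    return ens, truth


@pytest.fixture
def window_bilayer():
    """Thinned-window bilayer with an embedded protein cylinder, mild noise."""
    spec = BilayerSpec(
        bulk_thickness=38.1, window_thickness=20.1, protein_radius=10.0,
        window_radius=16.0, z_noise_sigma=1.0, n_frames=30,
        n_lipids_per_leaflet=150, box_xy=120.0, seed=5,
    )
    ens, truth = generate_bilayer(spec)
    return ens, truth


def make_ensemble(coords_per_frame, box=(100.0, 100.0, 100.0), names=None,
                  resnames=None, resids=None, chain="A"):
    """Hand-build a LabeledEnsemble from raw coordinate arrays."""
    coords_per_frame = [np.asarray(c, dtype=float) for c in coords_per_frame]
    n = coords_per_frame[0].shape[0]
    names = names or ["BB"] * n
    resnames = resnames or ["ALA"] * n
    resids = resids or list(range(1, n + 1))
    from memthick.core import DEFAULT_CONVENTION

    topo = tuple(
        BeadRecord(i, names[i], resnames[i], resids[i], chain,
                   DEFAULT_CONVENTION.role_of(names[i], resnames[i]))
        for i in range(n)
    )
    frames = [Frame(c, np.asarray(box, float), float(t))
              for t, c in enumerate(coords_per_frame)]
    return LabeledEnsemble(topo, frames, source_format="synthetic")
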