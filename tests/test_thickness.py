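"""TM-window selection, Gaussian fits, and thickness extraction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memthick import (
    BilayerSpec,
    Role,
    fit_leaflet_gaussians,
    generate_bilayer,
    relative_thinning,
    select_beads,
    thickness_difference,
    thickness_from_fit,
    thickness_pipeline,
    tm_window_selection,
)
from memthick.core import Frame, Selection
from memthick.density import DensityProfile
from memthick.errors import FitError
from memthick.thickness import GaussianFitResult, ThicknessResult

from conftest import make_ensemble


def brute_force_window(frame, protein_sel, phosphate_sel, cutoff):
    """O(N*M) all-pairs distance oracle for the dynamic window selection."""
    prot = frame.coordinates[list(protein_sel.bead_indices)]
    keep = []
    for i in phosphate_sel.bead_indices:
        d = np.sqrt(((frame.coordinates[i] - prot) ** 2).sum(axis=1))
        if d.min() <= cutoff:
            keep.append(i)
    return tuple(keep)


class TestWindowSelection:
    def test_boundary_inclusive(self):
        coords = np.array([[0.0, 0.0, 0.0], [5.9, 0.0, 0.0], [6.1, 0.0, 0.0]])
        ens = make_ensemble([coords], names=["BB", "PO4", "PO4"],
                            resnames=["ALA", "DYPC", "DYPC"])
        prot = Selection((0,), "protein")
        phos = Selection((1, 2), "phosphates")
        sel = tm_window_selection(ens.frames[0], prot, phos, cutoff=6.0)
        assert sel.bead_indices == (1,)

    def test_monotone_in_cutoff(self, window_bilayer):
        ens, _ = window_bilayer
        prot = select_beads(ens, role=Role.PROTEIN_BACKBONE)
        phos = select_beads(ens, role=Role.LIPID_PHOSPHATE)
        s6 = set(tm_window_selection(ens.frames[0], prot, phos, 6.0).bead_indices)
        s8 = set(tm_window_selection(ens.frames[0], prot, phos, 8.0).bead_indices)
        assert s6 <= s8

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            coords = rng.uniform(-30, 30, (500, 3))
            names = ["BB"] * 60 + ["PO4"] * 440
            resnames = ["ALA"] * 60 + ["DYPC"] * 440
            ens = make_ensemble([coords], names=names, resnames=resnames)
            prot = Selection(tuple(range(60)), "protein")
            phos = Selection(tuple(range(60, 500)), "phos")
            cutoff = float(rng.uniform(3, 12))
            fast = tm_window_selection(ens.frames[0], prot, phos, cutoff)
            assert fast.bead_indices == brute_force_window(
                ens.frames[0], prot, phos, cutoff
            )

    def test_nonpositive_cutoff_rejected(self):
        ens = make_ensemble([np.zeros((2, 3))])
        with pytest.raises(ValueError):
            tm_window_selection(ens.frames[0], Selection((0,), "p"),
                                Selection((1,), "q"), cutoff=0.0)


def _profile_from(z, y):
    edges = np.append(z - 0.5, z[-1] + 0.5)
    return DensityProfile(edges, y, 1, "constructed")


def _gauss(z, a, mu, s):
    return a * np.exp(-((z - mu) ** 2) / (2 * s ** 2))


class TestGaussianFits:
    def test_two_component_self_consistency(self):
        z = np.arange(-40.0, 40.0) + 0.5
        y = _gauss(z, 1, -19.05, 1) + _gauss(z, 1, 19.05, 1)
        fit = fit_leaflet_gaussians(_profile_from(z, y), 2)
        assert fit.converged
        np.testing.assert_allclose(fit.means, [-19.05, 19.05], atol=0.01)
        assert fit.r_squared > 0.999

    def test_triple_beats_double_on_midplane_mixture(self):
        z = np.arange(-40.0, 40.0) + 0.5
        y = (_gauss(z, 1, -19.05, 1) + _gauss(z, 1, 19.05, 1)
             + _gauss(z, 0.1, 0.0, 8.0))
        prof = _profile_from(z, y)
        f3 = fit_leaflet_gaussians(prof, 3)
        f2 = fit_leaflet_gaussians(prof, 2)
        assert f3.converged and f2.converged
        outer3 = [f3.means.min(), f3.means.max()]
        np.testing.assert_allclose(outer3, [-19.05, 19.05], atol=0.05)
        sep3 = thickness_from_fit(f3)
        sep2 = thickness_from_fit(f2)
        true_sep = 38.1
        assert sep2 < true_sep  # double fit biased low by the mid-plane mass
        assert abs(sep3 - true_sep) < abs(sep2 - true_sep)

    def test_all_zero_profile_is_initialization_error(self):
        z = np.arange(-10.0, 10.0) + 0.5
        with pytest.raises(FitError):
            fit_leaflet_gaussians(_profile_from(z, np.zeros_like(z)), 2)

    def test_single_peak_profile_rejected(self):
        z = np.arange(-20.0, 20.0) + 0.5
        with pytest.raises(FitError, match="peaks"):
            fit_leaflet_gaussians(_profile_from(z, _gauss(z, 1, 0, 3)), 2)


class TestThicknessFromFit:
    def _fit(self, means, amps=None):
        amps = amps or [1.0] * len(means)
        comps = sorted(zip(amps, means, [1.0] * len(means)),
                       key=lambda c: c[1])
        return GaussianFitResult(
            components=[tuple(map(float, c)) for c in comps],
            parameter_standard_errors=[(0.0,) * 3] * len(means),
            residual_norm=0.0, r_squared=1.0, converged=True,
        )

    def test_outermost_separation(self):
        assert thickness_from_fit(self._fit([-19.05, 19.05])) == pytest.approx(38.1)
        assert thickness_from_fit(
            self._fit([-10.05, 0.0, 10.05])
        ) == pytest.approx(20.1)

    def test_vestigial_component_ignored(self):
        fit = self._fit([-10.05, 10.05, 25.0], amps=[1.0, 1.0, 1e-6])
        assert thickness_from_fit(fit) == pytest.approx(20.1)

    @given(shift=st.floats(-20, 20), scale=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_translation_and_amplitude_invariance(self, shift, scale):
        base = self._fit([-19.05, 0.0, 19.05])
        moved = self._fit([m + shift for m in (-19.05, 0.0, 19.05)],
                          amps=[scale] * 3)
        assert thickness_from_fit(moved) == pytest.approx(
            thickness_from_fit(base), abs=1e-9
        )

    def test_unconverged_fit_is_error(self):
        fit = self._fit([-19.05, 19.05])
        fit.converged = False
        with pytest.raises(FitError):
            thickness_from_fit(fit)


class TestPipeline:
    def test_bulk_recovery_small(self):
        specs = [
            BilayerSpec(n_frames=40, n_lipids_per_leaflet=150, box_xy=120.0,
                        z_noise_sigma=1.0, seed=s)
            for s in (21, 22, 23)
        ]
        ensembles = [generate_bilayer(s)[0] for s in specs]
        res = thickness_pipeline(ensembles, region="bulk")
        assert res.method == "double"
        assert res.mean == pytest.approx(38.1, abs=0.3)
        assert res.sem > 0

    def test_single_replicate_sem_zero_with_warning(self, flat_bilayer):
        ens, _ = flat_bilayer
        spec = BilayerSpec(n_frames=30, n_lipids_per_leaflet=100, box_xy=100.0,
                           z_noise_sigma=1.0, seed=31)
        with pytest.warns(UserWarning, match="single replicate"):
            res = thickness_pipeline([generate_bilayer(spec)[0]], region="bulk")
        assert res.sem == 0.0
        assert res.n_replicates == 1


class TestDerivedQuantities:
    def test_relative_thinning_printed_values(self):
        # 38.1 -> 20.1 A is ~47% thinner; 38.1 -> 23.1 A is ~39-40% thinner
        assert round(relative_thinning(38.1, 20.1)) == 47
        assert relative_thinning(38.1, 20.1) == pytest.approx(47.24, abs=0.01)
        assert relative_thinning(38.1, 23.1) == pytest.approx(39.37, abs=0.01)
        assert relative_thinning(30.0, 30.0) == 0.0

    def test_relative_thinning_complement_round_trip(self):
        b = 38.1
        for p in (0.0, 10.0, 47.2, 99.0):
            w = b * (1 - p / 100)
            assert relative_thinning(b, w) == pytest.approx(p, abs=1e-9)

    def test_thickening_flagged_not_fatal(self):
        with pytest.warns(UserWarning, match="thicker"):
            assert relative_thinning(20.0, 22.0) == pytest.approx(-10.0)

    def test_difference_and_quadrature_error(self):
        a = ThicknessResult("tm_window", [23.1], 23.1, 0.16, "triple", 5)
        b = ThicknessResult("tm_window", [20.1], 20.1, 0.54, "triple", 5)
        out = thickness_difference(a, b)
        assert out["difference"] == pytest.approx(3.0)
        assert out["propagated_error"] == pytest.approx(
            np.sqrt(0.54 ** 2 + 0.16 ** 2), abs=1e-9
        )
        same = thickness_difference(a, a)
        assert same["difference"] == 0.0
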