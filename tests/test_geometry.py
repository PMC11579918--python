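"""Superposition, RMSD/RMSF, and helix-geometry checks against oracles."""

import numpy as np
import pytest

from memthick import (
    cross_angle,
    generate_helix,
    helix_axis,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
)
from memthick.core import Selection
from memthick.errors import GeometryError

from conftest import make_ensemble


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def horn_quaternion_superpose(mobile, reference):
    """Independent quaternion-method (Horn) rigid superposition oracle."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    moved = P @ R.T
    return float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))


class TestKabsch:
    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(20, 3))
        R = random_rotation(rng)
        mobile = ref @ R.T + [3.0, -2.0, 7.0]
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd < 1e-8
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_identity_inputs_give_identity_transform(self):
        coords = np.random.default_rng(6).normal(size=(10, 3))
        res = kabsch_superpose(coords, coords)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-10)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ref = rng.normal(size=(10, 3))
            mobile = ref @ random_rotation(rng).T + rng.normal(size=3)
            mobile = mobile + rng.normal(scale=0.3, size=(10, 3))
            ours = kabsch_superpose(mobile, ref).rmsd
            oracle = horn_quaternion_superpose(mobile, ref)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(line + 0.0, line @ random_rotation(
                np.random.default_rng(8)).T)


class TestRmsd:
    def test_static_ensemble_all_zero(self):
        coords = np.random.default_rng(9).normal(size=(12, 3))
        ens = make_ensemble([coords] * 5)
        series = rmsd_series(ens, 0)
        np.testing.assert_allclose(series, 0.0, atol=1e-10)
        assert series[0] == 0.0

    def test_exclusion_changes_value_iff_excluded_residues_moved(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(10, 3)) * 5
        moved = base.copy()
        moved[[4, 5]] += [0.0, 0.0, 3.0]  # residues 5-6 move
        ens = make_ensemble([base, moved])
        full = rmsd_series(ens, 0, superpose=False)
        sel = Selection(tuple(i for i in range(10) if i not in (4, 5)),
                        "exclude resid 5-6")
        partial = rmsd_series(ens, 0, sel, superpose=False)
        assert full[1] > 0
        assert partial[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_kabsch_composition(self):
        rng = np.random.default_rng(11)
        frames = [rng.normal(size=(8, 3)) for _ in range(4)]
        ens = make_ensemble(frames)
        series = rmsd_series(ens, 0, superpose=True)
        for i, fr in enumerate(frames):
            assert series[i] == pytest.approx(
                kabsch_superpose(fr, frames[0]).rmsd, abs=1e-12
            )


class TestRmsf:
    def test_static_structure_zero(self):
        coords = np.random.default_rng(12).normal(size=(6, 3))
        prof = rmsf_profile(make_ensemble([coords] * 4))
        np.testing.assert_allclose(prof.per_residue_rmsf, 0.0, atol=1e-10)

    def test_isotropic_jitter_closed_form(self):
        rng = np.random.default_rng(13)
        base = rng.uniform(-10, 10, (5, 3))
        sigma = 0.8
        frames = base + rng.normal(0, sigma, size=(3000, 5, 3))
        ens = make_ensemble(list(frames))
        prof = rmsf_profile(ens, superpose_to_mean=False)
        assert prof.per_residue_rmsf.mean() == pytest.approx(
            sigma * np.sqrt(3), rel=0.03
        )

    def test_two_identical_replicates_zero_sd(self):
        rng = np.random.default_rng(14)
        frames = [rng.normal(size=(5, 3)) for _ in range(6)]
        a = make_ensemble(frames)
        b = make_ensemble(frames)
        prof = rmsf_profile(a, replicate_ensembles=[b])
        np.testing.assert_allclose(prof.replicate_sd, 0.0, atol=1e-12)

    def test_translation_invariant_with_superposition(self):
        rng = np.random.default_rng(15)
        frames = [rng.normal(size=(6, 3)) for _ in range(10)]
        shifted = [f + [100.0, -30.0, 12.0] for f in frames]
        a = rmsf_profile(make_ensemble(frames)).per_residue_rmsf
        b = rmsf_profile(make_ensemble(shifted)).per_residue_rmsf
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf_profile(make_ensemble([np.zeros((4, 3))]))


class TestHelixAxis:
    def test_reversed_range_flips_vector(self):
        ens = generate_helix(15)
        fwd = helix_axis(ens.frames[0], ens.topology, (1, 15))
        rev = helix_axis(ens.frames[0], ens.topology, (15, 1))
        np.testing.assert_allclose(fwd.vector, -rev.vector, atol=1e-12)

    def test_short_range_rejected(self):
        ens = generate_helix(10)
        with pytest.raises(GeometryError):
            helix_axis(ens.frames[0], ens.topology, (1, 5))

    def test_three_residue_endpoints_average_out_noise(self):
        # with noisy beads, 3-residue endpoint centroids beat single beads
        rng = np.random.default_rng(16)
        errs = {1: [], 3: []}
        for trial in range(40):
            ens = generate_helix(21)
            fr = ens.frames[0]
            fr.coordinates = fr.coordinates + rng.normal(0, 0.8, fr.coordinates.shape)
            for n_end in (1, 3):
                ax = helix_axis(fr, ens.topology, (1, 21), n_end=n_end)
                errs[n_end].append(cross_angle(ax, np.array([0.0, 0.0, 1.0])))
        assert np.mean(errs[3]) < np.mean(errs[1])


class TestCrossAngle:
    def test_identical_vectors_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cross_angle(v, v) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_constructed_helices(self):
        a = generate_helix(21, direction=(0, 0, 1))
        b = generate_helix(21, direction=(1, 0, 0))
        ax_a = helix_axis(a.frames[0], a.topology, (1, 21))
        ax_b = helix_axis(b.frames[0], b.topology, (1, 21))
        assert cross_angle(ax_a, ax_b) == pytest.approx(90.0, abs=0.5)

    def test_folding_semantics_antiparallel(self):
        v = np.array([0.0, 0.0, 1.0])
        assert cross_angle(v, -v) == pytest.approx(180.0)
        assert cross_angle(v, -v, fold_to_90=True) == pytest.approx(0.0)

    def test_invariant_under_joint_rigid_rotation(self):
        rng = np.random.default_rng(18)
        va = rng.normal(size=3)
        vb = rng.normal(size=3)
        base = cross_angle(va, vb)
        for _ in range(5):
            R = random_rotation(rng)
            assert abs(cross_angle(R @ va, R @ vb) - base) < 1e-6

    def test_zero_vector_rejected(self):
        with pytest.raises(GeometryError):
            cross_angle(np.zeros(3), np.array([1.0, 0.0, 0.0]))
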