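"""Projection library, alignment, Fourier reconstruction, symmetry, refinement."""

import numpy as np
import pytest

from picoem.core import ValidationError, VolumeMap
from picoem.geometry import AngularGrid, angular_distance_deg, euler_to_matrix
from picoem.postprocess import compute_fsc
from picoem.refine3d import (
    align_particle,
    apply_symmetry,
    make_projection_library,
    reconstruct,
    refine,
    rotate_image,
)
from picoem.simulator import (
    fourier_shift_image,
    render_model_density,
    simulate_particle_stack,
    simulate_projection,
)


class TestAngularGrid:
    def test_c2_grid_restricted_to_half_rot_range(self):
        grid = AngularGrid(15.0, "C2")
        arr = grid.as_array()
        assert (arr[:, 0] < 180.0).all()
        assert len(set(map(tuple, arr))) == len(arr)

    def test_grid_covers_asymmetric_unit(self, rng):
        """Quasi-uniform coverage oracle: every random direction of the C2
        asymmetric unit lies within ~one step of a grid direction."""
        step = 15.0
        grid = AngularGrid(step, "C2")
        arr = grid.as_array()

        def vec(rot, tilt):
            r, t = np.deg2rad(rot), np.deg2rad(tilt)
            return np.array([np.cos(r) * np.sin(t), np.sin(r) * np.sin(t), np.cos(t)])

        grid_vecs = np.stack([vec(r, t) for r, t in arr])
        for _ in range(500):
            rot, tilt = rng.uniform(0, 180), np.rad2deg(np.arccos(rng.uniform(-1, 1)))
            v = vec(rot, tilt)
            best = min(
                np.rad2deg(np.arccos(np.clip(np.abs(grid_vecs @ v), -1, 1))).min()
                for v in (v, np.array([-v[0], -v[1], v[2]]))
            )
            assert best <= step

    def test_density_matches_step_scaling(self):
        # halving the step roughly quadruples the direction count
        n15, n75 = len(AngularGrid(15.0, "C2")), len(AngularGrid(7.5, "C2"))
        assert 3.0 < n75 / n15 < 5.0


class TestProjectionLibrary:
    def test_c2_reference_projections_identical_under_rot_180(self, phantom64):
        _, vol = phantom64
        p1 = simulate_projection(vol, (30.0, 60.0, 0.0))
        p2 = simulate_projection(vol, (210.0, 60.0, 0.0))
        assert np.abs(p1 - p2).max() < 1e-3 * np.abs(p1).max()

    def test_spherical_reference_gives_identical_library(self):
        vol = render_model_density([(0.0, 0.0, 0.0, 1.0, 10.0)], 32, 5.6)
        lib = make_projection_library(vol, AngularGrid(30.0, "C1"))
        ref = lib.projections[0]
        assert np.abs(lib.projections - ref).max() < 1e-3 * ref.max()

    def test_empty_grid_and_noncubic_rejected(self, phantom64):
        _, vol = phantom64
        from picoem.core import SizingError

        with pytest.raises(SizingError):
            make_projection_library(
                VolumeMap(np.zeros((16, 16, 8)), 1.0), AngularGrid(30.0)
            )


class TestAlignParticle:
    @pytest.fixture(scope="class")
    def library(self, phantom64):
        _, vol = phantom64
        return make_projection_library(vol, AngularGrid(15.0, "C2"))

    def test_self_match_returns_own_direction_and_unit_score(self, library):
        j = 10
        rec = align_particle(library.projections[j], library, max_shift_px=4)
        assert (rec.rot, rec.tilt) == tuple(library.directions[j])
        assert rec.psi == 0.0 and rec.shift_x == 0.0 and rec.shift_y == 0.0
        assert rec.score == pytest.approx(1.0, abs=1e-6)

    def test_in_plane_rotation_recovered_within_one_psi_step(self, phantom64, library):
        _, vol = phantom64
        rot, tilt = library.directions[10]
        img = simulate_projection(vol, (rot, tilt, 23.0))
        rec = align_particle(img, library, max_shift_px=4, psi_step_deg=5.0)
        assert min(abs(rec.psi - 23.0), 360 - abs(rec.psi - 23.0)) <= 5.0

    def test_shift_recovered_within_half_pixel(self, library):
        img = fourier_shift_image(library.projections[10], (3.0, -2.0))
        rec = align_particle(img, library, max_shift_px=8)
        assert abs(rec.shift_x - 3.0) <= 0.5 and abs(rec.shift_y - (-2.0)) <= 0.5

    def test_rotate_image_matches_projector_psi_convention(self, phantom64):
        _, vol = phantom64
        direct = simulate_projection(vol, (40.0, 70.0, 33.0))
        composed = rotate_image(simulate_projection(vol, (40.0, 70.0, 0.0)), 33.0)
        assert np.abs(direct - composed).max() < 0.03 * np.abs(direct).max()

    def test_empty_library_rejected(self, rng):
        from picoem.refine3d import ProjectionLibrary

        empty = ProjectionLibrary(np.zeros((0, 2)), np.zeros((0, 64, 64)),
                                  AngularGrid(15.0, "C2"))
        with pytest.raises(ValidationError):
            align_particle(rng.normal(size=(64, 64)), empty)


def _stack_with_truth(vol, n, acq, seed, **kw):
    ps, gt = simulate_particle_stack(vol, n, acq, seed=seed, **kw)
    ps.metadata[["rot", "tilt", "psi"]] = gt.particles[["rot", "tilt", "psi"]]
    ps.metadata[["shift_x", "shift_y"]] = gt.particles[["shift_x", "shift_y"]].values
    return ps, gt


class TestReconstruct:
    def test_central_slice_theorem_single_particle(self, phantom32, acq56):
        _, vol = phantom32
        ps, gt = _stack_with_truth(vol, 1, acq56, seed=0, snr=None, apply_ctf=False,
                                   angles=[(0.0, 0.0, 0.0)])
        rec = reconstruct(ps, symmetry="C1", ctf_correction="none", wiener_frac=1e-4)
        n = vol.shape[0]
        c = n // 2
        centred = np.roll(rec.data, (-c, -c, -c), axis=(0, 1, 2))
        slab = np.fft.fftn(centred)[0]
        img = np.fft.fft2(np.roll(ps.images[0], (-c, -c), axis=(0, 1)))
        num = np.abs(slab * np.conj(img)).sum()
        den = np.sqrt((np.abs(slab) ** 2).sum() * (np.abs(img) ** 2).sum())
        assert num / den > 0.98

    def test_noiseless_fsc_against_phantom(self, phantom32, acq56):
        _, vol = phantom32
        ps, _ = _stack_with_truth(vol, 500, acq56, seed=1, snr=None, apply_ctf=False)
        rec = reconstruct(ps, symmetry="C2", ctf_correction="none")
        freqs, corrs = compute_fsc(rec, vol).shells()
        assert corrs[freqs <= 0.8 * vol.nyquist].min() >= 0.95

    def test_matches_real_space_backprojection_oracle(self, phantom32, acq56):
        """Independent oracle: unfiltered real-space back-projection on the
        periodic lattice (the direct-Fourier method is periodic); per-shell
        normalization in the FSC divides out its radial weighting."""
        from scipy.ndimage import map_coordinates

        _, vol = phantom32
        n = vol.shape[0]
        ps, gt = _stack_with_truth(vol, 500, acq56, seed=2, snr=None, apply_ctf=False)
        rec = reconstruct(ps, symmetry="C2", ctf_correction="none")

        c = n // 2
        idx = np.arange(n, dtype=float)
        zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij")
        pos = np.stack([xx - c, yy - c, zz - c])
        rot180 = np.diag([-1.0, -1.0, 1.0])
        bp = np.zeros((n, n, n))
        for i in range(len(ps)):
            r = euler_to_matrix(*gt.particles.loc[i, ["rot", "tilt", "psi"]])
            for g in (np.eye(3), rot180):            # same C2 averaging
                rp = np.tensordot((g @ r).T, pos, axes=1)   # projector adjoint
                bp += map_coordinates(
                    ps.images[i], [(rp[1] + c) % n, (rp[0] + c) % n],
                    order=1, mode="grid-wrap",
                )
        freqs, corrs = compute_fsc(rec, VolumeMap(bp, vol.voxel_size)).shells()
        assert corrs[freqs <= 0.8 * vol.nyquist].min() >= 0.95

    def test_amplitude_correction_beats_uncorrected(self, phantom32, acq56):
        _, vol = phantom32
        ps, _ = _stack_with_truth(vol, 200, acq56, seed=3, snr=None, apply_ctf=True,
                                  defocus_range_um=(1.7, 3.0))
        rec_amp = reconstruct(ps, acq56, symmetry="C2", ctf_correction="amplitude")
        rec_none = reconstruct(ps, acq56, symmetry="C2", ctf_correction="none")

        def corr(a):
            x, y = a.data - a.data.mean(), vol.data - vol.data.mean()
            return (x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum())

        assert corr(rec_amp) > corr(rec_none)

    def test_missing_orientation_and_bad_wiener_rejected(self, phantom32, acq56):
        _, vol = phantom32
        ps, _ = simulate_particle_stack(vol, 3, acq56, snr=None, apply_ctf=False)
        with pytest.raises(ValidationError):
            reconstruct(ps, symmetry="C1", ctf_correction="none")
        ps2, _ = _stack_with_truth(vol, 3, acq56, seed=0, snr=None, apply_ctf=False)
        with pytest.raises(ValidationError):
            reconstruct(ps2, symmetry="C1", ctf_correction="none", wiener_frac=0.0)


class TestApplySymmetry:
    def test_c2_volume_is_fixed_point(self, phantom64):
        _, vol = phantom64
        out = apply_symmetry(vol, "C2")
        assert np.abs(out.data - vol.data).max() < 1e-6 * vol.data.max()

    def test_idempotent_and_mass_preserving(self, rng):
        vol = VolumeMap(rng.normal(size=(32, 32, 32)), 2.0)
        once = apply_symmetry(vol, "C2")
        twice = apply_symmetry(once, "C2")
        assert np.abs(twice.data - once.data).max() < 1e-6 * np.abs(once.data).max()
        assert once.data.sum() == pytest.approx(vol.data.sum(), rel=1e-6)

    def test_off_axis_blob_splits_into_symmetric_pair(self):
        vol = render_model_density([(20.0, 10.0, 5.0, 1.0, 5.0)], 48, 2.0)
        out = apply_symmetry(vol, "C2")
        assert out.data.sum() == pytest.approx(vol.data.sum(), rel=1e-6)
        # centroid of each half plane matches the analytic rotation
        n, c, vox = 48, 24, 2.0
        coords = (np.arange(n) - c) * vox
        w = out.data
        x_cent = (w * coords[None, None, :]).sum(axis=(0, 1))
        # two equal-mass lobes at x = +-20 -> projected profile symmetric
        profile = w.sum(axis=(0, 1))
        assert profile[c + 10] == pytest.approx(profile[c - 10], rel=1e-6)
        assert (w * coords[None, None, :]).sum() == pytest.approx(0.0, abs=1e-9)

    def test_unsupported_group_rejected(self, phantom64):
        _, vol = phantom64
        with pytest.raises(ValidationError):
            apply_symmetry(vol, "D7")


class TestRefine:
    def test_zero_rounds_and_zero_particles_rejected(self, phantom32, acq56):
        _, vol = phantom32
        ps, _ = _stack_with_truth(vol, 2, acq56, seed=0, snr=None, apply_ctf=False)
        with pytest.raises(ValidationError):
            refine(ps, vol, rounds=0)

    def test_single_round_on_truth_close_to_reconstruct_at_truth(self, phantom32, acq56):
        """One alignment round starting from the phantom should not lose more
        than one FSC shell against the reconstruct-at-truth baseline."""
        _, vol = phantom32
        ps, gt = _stack_with_truth(vol, 150, acq56, seed=4, snr=None, apply_ctf=False)
        baseline = reconstruct(ps, symmetry="C2", ctf_correction="none")
        ps2 = ps.subset(np.arange(len(ps)))
        final, _ = refine(ps2, vol, rounds=1, grid_schedule=(10.0,), symmetry="C2",
                          ctf_mode="none", max_shift_px=4, align_lowpass_A=None)
        fb = compute_fsc(baseline, vol)
        fr = compute_fsc(final, vol)
        res_b = _crossing_shell(fb, 0.5)
        res_r = _crossing_shell(fr, 0.5)
        assert res_r >= res_b - 1

    def test_noiseless_angular_recovery_within_final_step(self, phantom32, acq56):
        _, vol = phantom32
        ps, gt = simulate_particle_stack(vol, 80, acq56, snr=None, apply_ctf=False,
                                         seed=5)
        final, log = refine(ps, vol, rounds=3, grid_schedule=(15, 10, 7.5),
                            symmetry="C2", ctf_mode="none", max_shift_px=4,
                            align_lowpass_A=None)
        errs = [
            angular_distance_deg(
                tuple(gt.particles.loc[i, ["rot", "tilt", "psi"]]),
                tuple(ps.metadata.loc[i, ["rot", "tilt", "psi"]]),
                "C2",
            )
            for i in range(len(ps))
        ]
        assert np.median(errs) <= 7.5


def _crossing_shell(curve, threshold):
    freqs, corrs = curve.shells()
    below = np.nonzero(corrs < threshold)[0]
    return below[0] if len(below) else len(corrs)
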