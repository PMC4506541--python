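"""Simulator: phantom symmetry, Gaussian rendering, projection, movies, stacks."""

import numpy as np
import pytest

from picoem.core import SizingError, ValidationError
from picoem.simulator import (
    PhantomSpec,
    build_phantom,
    fourier_shift_image,
    render_model_density,
    rot180_z,
    simulate_movie,
    simulate_particle_stack,
    simulate_projection,
)


class TestPhantom:
    def test_c2_density_exactly_invariant(self, phantom64):
        _, vol = phantom64
        dev = np.abs(vol.data - rot180_z(vol.data)).max()
        assert dev < 1e-6 * vol.data.max()

    def test_c2_atom_list_paired(self, phantom64):
        ph, _ = phantom64
        atoms = {(round(x, 6), round(y, 6), round(z, 6)) for x, y, z, _, _ in ph.atoms}
        for (x, y, z) in atoms:
            assert (round(-x, 6), round(-y, 6), round(z, 6)) in atoms

    def test_three_sites_per_half_doubled_by_c2(self):
        ph, _ = build_phantom(PhantomSpec(ligand_occupancies=(1.0, 1.0, 1.0)))
        assert len(ph.ligand_sites) == 6
        ids = {s.site_id for s in ph.ligand_sites}
        assert ids == {"beta1_a", "beta2_a", "beta5_a", "beta1_b", "beta2_b", "beta5_b"}

    def test_deterministic_under_spec(self):
        _, a = build_phantom(PhantomSpec(seed=7))
        _, b = build_phantom(PhantomSpec(seed=7))
        assert a.data.tobytes() == b.data.tobytes()

    def test_box_too_small_raises(self):
        with pytest.raises(SizingError):
            build_phantom(PhantomSpec(box_size=32, voxel_size=2.8))

    def test_bad_occupancy_rejected(self):
        with pytest.raises(ValidationError):
            build_phantom(PhantomSpec(ligand_occupancies=(1.2, 0.5, 0.5)))


class TestRenderModelDensity:
    def test_single_atom_grid_sum_matches_weight(self):
        vol = render_model_density([(0.0, 0.0, 0.0, 2.5, 5.0)], 48, 2.0)
        assert vol.data.sum() == pytest.approx(2.5, rel=0.01)

    def test_linearity_in_atoms(self):
        a1 = [(5.0, -3.0, 2.0, 1.0, 4.0)]
        a2 = [(-10.0, 6.0, -8.0, 2.0, 6.0)]
        both = render_model_density(a1 + a2, 48, 2.0)
        sep = render_model_density(a1, 48, 2.0).data + render_model_density(a2, 48, 2.0).data
        assert np.abs(both.data - sep).max() < 1e-10

    def test_one_voxel_shift_equivariance(self):
        base = render_model_density([(0.0, 0.0, 0.0, 1.0, 4.0)], 48, 2.0)
        shifted = render_model_density([(2.0, 0.0, 0.0, 1.0, 4.0)], 48, 2.0)
        assert np.abs(np.roll(base.data, 1, axis=2) - shifted.data).max() < 1e-12

    def test_out_of_bounds_atom_names_index(self):
        with pytest.raises(ValidationError, match="atom 1"):
            render_model_density(
                [(0.0, 0.0, 0.0, 1.0, 4.0), (500.0, 0.0, 0.0, 1.0, 4.0)], 48, 2.0
            )


class TestProjection:
    def test_spherically_symmetric_volume_projects_identically(self):
        vol = render_model_density([(0.0, 0.0, 0.0, 1.0, 12.0)], 32, 5.6)
        p1 = simulate_projection(vol, (0.0, 0.0, 0.0))
        p2 = simulate_projection(vol, (123.0, 67.0, 31.0))
        assert np.abs(p1 - p2).max() < 1e-3 * p1.max()

    @pytest.mark.parametrize("euler", [(0, 0, 0), (30, 60, 10), (200, 120, 300)])
    def test_mass_conservation(self, phantom64, euler):
        _, vol = phantom64
        p = simulate_projection(vol, euler)
        assert p.sum() == pytest.approx(vol.data.sum(), rel=0.005)

    def test_agrees_with_ray_integration_oracle(self, rng):
        """Naive trilinear ray-summation oracle vs the affine projector."""
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(rng.normal(size=(32, 32, 32)), 1.5)
        from picoem.core import VolumeMap
        from picoem.geometry import euler_to_matrix

        vol = VolumeMap(data, 1.0)

        def oracle(euler):
            r = euler_to_matrix(*euler)
            n, c = 32, 16
            idx = np.arange(n, dtype=float)
            zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij")
            pos = np.stack([xx - c, yy - c, zz - c])          # (3, n, n, n) in (x,y,z)
            rp = np.tensordot(r, pos, axes=1) + c             # sample v(R u)
            from scipy.ndimage import map_coordinates

            samples = map_coordinates(
                data, [rp[2], rp[1], rp[0]], order=1, mode="constant", cval=0.0
            )
            return samples.sum(axis=0)

        for _ in range(10):
            euler = tuple(rng.uniform(0, 360, 3))
            mine = simulate_projection(vol, euler, order=1)
            ref = oracle(euler)
            nrms = np.sqrt(((mine - ref) ** 2).mean()) / np.sqrt((ref**2).mean())
            assert nrms < 0.02

    def test_non_cubic_volume_rejected(self):
        from picoem.core import VolumeMap

        with pytest.raises(SizingError):
            simulate_projection(VolumeMap(np.zeros((16, 16, 8)), 1.0), (0, 0, 0))


class TestParticleStack:
    def test_identity_composition(self, phantom32, acq56):
        _, vol = phantom32
        ps, gt = simulate_particle_stack(
            vol, 1, acq56, snr=None, apply_ctf=False, angles=[(0.0, 0.0, 0.0)], seed=0
        )
        ref = simulate_projection(vol, (0.0, 0.0, 0.0))
        assert np.array_equal(ps.images[0], ref)

    def test_defocus_drawn_within_range(self, phantom32, acq56):
        _, vol = phantom32
        ps, gt = simulate_particle_stack(
            vol, 500, acq56, defocus_range_um=(1.7, 3.0), snr=None, seed=1
        )
        t = gt.particles
        assert ((t.defocus_u_um >= 1.7) & (t.defocus_u_um <= 3.0)).all()
        assert ((t.defocus_v_um >= 1.7) & (t.defocus_v_um <= 3.0)).all()
        assert (t.defocus_u_um >= t.defocus_v_um).all()

    def test_deterministic_under_seed(self, phantom32, acq56):
        _, vol = phantom32
        a, _ = simulate_particle_stack(vol, 5, acq56, snr=0.5, seed=9)
        b, _ = simulate_particle_stack(vol, 5, acq56, snr=0.5, seed=9)
        assert np.array_equal(a.images, b.images)

    def test_empty_defocus_range_rejected(self, phantom32, acq56):
        _, vol = phantom32
        with pytest.raises(ValidationError):
            simulate_particle_stack(vol, 2, acq56, defocus_range_um=(3.0, 1.7))


class TestMovie:
    def test_noiseless_driftless_dose_accumulation(self, phantom32, acq56):
        _, vol = phantom32
        movie, _ = simulate_movie(
            vol, 4, acq56, noise_level=0.0, drift=None, seed=2, shape=(160, 160)
        )
        total = movie.frames.sum(axis=0)
        single = movie.frames[0]
        assert np.abs(total - acq56.n_frames * single).max() <= 1e-6 * np.abs(total).max()

    def test_ground_truth_has_one_record_per_particle(self, phantom32, acq56):
        _, vol = phantom32
        movie, gt = simulate_movie(vol, 25, acq56, seed=3, shape=(320, 320))
        assert len(gt.particles) == 25
        assert gt.drift.shape == (acq56.n_frames, 2)

    def test_noise_variance_tracks_dose(self, phantom32, acq56):
        """Per-frame pixel variance of the noise follows the configured
        dose-proportional model within 5% (sample variance over repeats)."""
        _, vol = phantom32
        doses = [1.4, 2.8, 5.6, 2.8, 2.8] + [2.8] * 12
        level = 0.05
        resid2 = np.zeros(len(doses))
        n_rep = 40
        for rep in range(n_rep):
            movie, _ = simulate_movie(
                vol, 1, acq56, noise_level=level, seed=100 + rep,
                shape=(64, 64), doses=doses,
            )
            clean, _ = simulate_movie(
                vol, 1, acq56, noise_level=0.0, seed=100 + rep,
                shape=(64, 64), doses=doses,
            )
            resid2 += ((movie.frames - clean.frames) ** 2).mean(axis=(1, 2))
        measured = resid2 / n_rep
        expected = level**2 * np.array(doses) / acq56.dose_per_frame
        assert np.abs(measured / expected - 1.0).max() < 0.05

    def test_fourier_shift_inverse_on_band_limited_image(self, rng):
        # exact inversion holds away from the Nyquist components, which a
        # real-output Fourier shift must treat specially
        f = np.fft.fft2(rng.normal(size=(32, 32)))
        ky, kx = np.meshgrid(np.fft.fftfreq(32), np.fft.fftfreq(32), indexing="ij")
        f[np.hypot(ky, kx) > 0.35] = 0.0
        img = np.fft.ifft2(f).real
        back = fourier_shift_image(fourier_shift_image(img, (2.3, -1.1)), (-2.3, 1.1))
        assert np.abs(back - img).max() < 1e-10 * np.abs(img).max()
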