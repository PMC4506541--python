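"""FSC, resolution thresholds, sharpening, filtering, local resolution, sections."""

import numpy as np
import pytest

from picoem.core import SizingError, ValidationError, VolumeMap
from picoem.postprocess import (
    FSCCurve,
    compute_fsc,
    local_resolution,
    lowpass_map,
    model_map_fsc,
    render_sections,
    resolution_at_threshold,
    sharpen_map,
)
from picoem.simulator import PhantomSpec, build_phantom


class TestComputeFsc:
    def test_self_correlation_is_unity(self, phantom64):
        _, vol = phantom64
        _, corrs = compute_fsc(vol, vol).shells()
        assert np.abs(corrs - 1.0).max() < 1e-10

    def test_negated_map_gives_minus_one(self, phantom64):
        _, vol = phantom64
        neg = VolumeMap(-vol.data, vol.voxel_size)
        _, corrs = compute_fsc(vol, neg).shells()
        assert np.abs(corrs + 1.0).max() < 1e-10

    def test_independent_noise_maps_stay_inside_null_band(self):
        """Monte-Carlo null: |FSC| < 3/sqrt(shell voxel count) in >= 95% of
        shells across 20 seed pairs."""
        inside = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = VolumeMap(rng.normal(size=(32, 32, 32)), 2.0)
            b = VolumeMap(rng.normal(size=(32, 32, 32)), 2.0)
            curve = compute_fsc(a, b)
            corrs = curve.correlations[1:]
            counts = curve.counts[1:]
            inside += (np.abs(corrs) < 3.0 / np.sqrt(counts)).sum()
            total += len(corrs)
        assert inside / total >= 0.95

    def test_grid_mismatch_rejected(self, phantom64, rng):
        _, vol = phantom64
        with pytest.raises(SizingError):
            compute_fsc(vol, VolumeMap(rng.normal(size=(32, 32, 32)), 2.8))


class TestResolutionAtThreshold:
    def _step_curve(self):
        # shells every 0.02/A; value 1 below 0.2/A, 0.5 exactly at 0.2, 0 above
        freqs = np.arange(1, 16) * 0.02
        corrs = np.where(freqs < 0.2, 1.0, np.where(freqs == 0.2, 0.5, 0.0))
        return FSCCurve(freqs, corrs, np.full(len(freqs), 100), dc_included=False)

    def test_interpolated_crossing_of_step_curve(self):
        res, crossed = resolution_at_threshold(self._step_curve(), 0.5)
        assert crossed and res == pytest.approx(5.0)

    def test_curve_without_crossing_flags_nyquist(self):
        freqs = np.arange(1, 16) * 0.02
        curve = FSCCurve(freqs, np.ones(15), np.full(15, 100), dc_included=False)
        res, crossed = resolution_at_threshold(curve, 0.5)
        assert not crossed and res == pytest.approx(1.0 / freqs[-1])

    def test_threshold_ordering(self):
        rng = np.random.default_rng(1)
        freqs = np.arange(1, 30) * 0.01
        corrs = np.clip(1.0 - freqs * 4.0 + rng.normal(0, 0.01, len(freqs)), -1, 1)
        curve = FSCCurve(freqs, corrs, np.full(len(freqs), 50), dc_included=False)
        r143, _ = resolution_at_threshold(curve, 0.143)
        r500, _ = resolution_at_threshold(curve, 0.5)
        assert r143 <= r500

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            resolution_at_threshold(self._step_curve(), 1.0)


class TestModelMapFsc:
    def test_map_against_its_own_model_is_unity(self, phantom64):
        ph, vol = phantom64
        _, corrs = model_map_fsc(vol, ph.all_atoms()).shells()
        assert np.abs(corrs - 1.0).max() < 1e-9

    def test_band_limited_map_crosses_at_band_limit(self, phantom64):
        """The per-shell normalization makes FSC blind to smooth amplitude
        scaling, so the crossing sits at the frequency where the filter
        actually reaches zero, within one shell."""
        ph, vol = phantom64
        cut = 12.0
        limited = lowpass_map(vol, cut, edge_shells=2.0)
        curve = model_map_fsc(limited, ph.all_atoms())
        res, crossed = resolution_at_threshold(curve, 0.5)
        dk = 1.0 / (vol.shape[0] * vol.voxel_size)
        k_end = 1.0 / cut + 2.0 * dk          # filter identically zero beyond
        assert crossed and abs(1.0 / res - k_end) <= dk

    def test_unrelated_atoms_decorrelate_beyond_low_shells(self, phantom64):
        _, vol = phantom64
        other = [(25.0, -30.0, 18.0, 1.0, 5.0), (-25.0, 30.0, -18.0, 1.0, 5.0)]
        freqs, corrs = model_map_fsc(vol, other).shells()
        assert np.abs(corrs[freqs > 0.3 * vol.nyquist]).max() < 0.3


class TestSharpenMap:
    def test_zero_b_factor_is_identity(self, phantom64):
        _, vol = phantom64
        out = sharpen_map(vol, 0.0)
        assert np.abs(out.data - vol.data).max() < 1e-10

    def test_closed_form_amplitude_ratio_at_minus_50(self, phantom64):
        """B = -50 A^2 scales the amplitude at k = 1/3.4 1/A by
        exp(50 k^2 / 4) ~ 2.95 (closed form)."""
        _, vol = phantom64
        out = sharpen_map(vol, -50.0)
        fa = np.fft.fftn(vol.data)
        fb = np.fft.fftn(out.data)
        kz = np.fft.fftfreq(vol.shape[0], vol.voxel_size)
        k_target = 1.0 / 3.4
        i = int(np.argmin(np.abs(kz - k_target)))
        k_actual = kz[i]
        ratio = np.abs(fb[0, 0, i]) / np.abs(fa[0, 0, i])
        assert ratio == pytest.approx(np.exp(50.0 * k_actual**2 / 4.0), rel=1e-6)
        assert np.exp(50.0 * k_target**2 / 4.0) == pytest.approx(2.9489, abs=2e-3)

    def test_sharpen_then_blur_is_identity(self, phantom64):
        _, vol = phantom64
        out = sharpen_map(sharpen_map(vol, -50.0), 50.0)
        assert np.abs(out.data - vol.data).max() < 1e-8 * np.abs(vol.data).max()


class TestLowpassMap:
    def test_power_beyond_edge_is_negligible(self, phantom64):
        _, vol = phantom64
        out = lowpass_map(vol, 12.0, edge_shells=3.0)
        f = np.fft.fftn(out.data)
        kz, ky, kx = np.meshgrid(*[np.fft.fftfreq(vol.shape[0], vol.voxel_size)] * 3,
                                 indexing="ij")
        k = np.sqrt(kz**2 + ky**2 + kx**2)
        edge = 1.0 / 12.0 + 3.0 / (vol.shape[0] * vol.voxel_size)
        beyond = (np.abs(f[k >= edge]) ** 2).sum()
        assert beyond < 1e-6 * (np.abs(f) ** 2).sum()

    def test_dc_preserved_and_power_never_increases(self, phantom64):
        _, vol = phantom64
        out = lowpass_map(vol, 12.0)
        assert out.data.mean() == pytest.approx(vol.data.mean(), rel=1e-12)
        assert (out.data**2).sum() <= (vol.data**2).sum() * (1 + 1e-12)

    def test_nested_passbands_compose(self, phantom64):
        _, vol = phantom64
        once = lowpass_map(vol, 20.0)
        nested = lowpass_map(once, 6.8)
        assert np.abs(nested.data - once.data).max() < 1e-8 * np.abs(once.data).max()

    def test_cutoff_at_nyquist_rejected(self, phantom64):
        _, vol = phantom64
        with pytest.raises(ValidationError):
            lowpass_map(vol, 2.0 * vol.voxel_size)


class TestLocalResolution:
    def test_uniform_band_limited_pair_is_homogeneous(self):
        rng = np.random.default_rng(2)
        sig = lowpass_map(VolumeMap(rng.normal(size=(64, 64, 64)), 2.8), 12.0)
        sd = 0.3 * sig.data.std()
        a = VolumeMap(sig.data + rng.normal(0, sd, sig.shape), 2.8)
        b = VolumeMap(sig.data + rng.normal(0, sd, sig.shape), 2.8)
        res, cov = local_resolution(a, b, window_px=16, step_px=8, threshold=0.5)
        vals = res.data[cov]
        iqr = np.percentile(vals, 75) - np.percentile(vals, 25)
        assert iqr < 0.15 * np.median(vals)

    def test_blurred_region_scores_worse(self, phantom64):
        from scipy.ndimage import gaussian_filter

        _, vol = phantom64
        rng = np.random.default_rng(3)
        two = vol.data.copy()
        two[:, :, :32] = gaussian_filter(vol.data, 2.5)[:, :, :32]
        sd = 0.05 * vol.data.max()
        a = VolumeMap(two + rng.normal(0, sd, vol.shape), vol.voxel_size)
        b = VolumeMap(two + rng.normal(0, sd, vol.shape), vol.voxel_size)
        res, _ = local_resolution(a, b, window_px=16, step_px=8, threshold=0.5)
        prot = vol.data > 0.1 * vol.data.max()
        x = np.arange(64)[None, None, :]
        blurred = np.nanmedian(res.data[prot & (x < 28)])
        sharp = np.nanmedian(res.data[prot & (x >= 36)])
        assert blurred > sharp

    def test_small_window_rejected(self, phantom64):
        _, vol = phantom64
        with pytest.raises(SizingError):
            local_resolution(vol, vol, window_px=8)


class TestRenderSections:
    def test_full_thickness_gives_axis_mean(self, phantom64):
        _, vol = phantom64
        stack = render_sections(vol, vol.shape[0] * vol.voxel_size, axis=0)
        assert stack.raw.shape[0] == 1
        assert np.allclose(stack.raw[0], vol.data.mean(axis=0))

    def test_partition_identity(self, phantom64):
        _, vol = phantom64
        stack = render_sections(vol, 5.0, axis=0)
        recon = (stack.raw * stack.slab_counts[:, None, None]).sum(axis=0)
        proj = vol.data.sum(axis=0)
        assert np.abs(recon - proj).max() < 1e-6 * np.abs(proj).max()

    def test_one_angstrom_slabs_match_partition_oracle(self):
        _, vol = build_phantom(PhantomSpec())
        vol_104 = VolumeMap(vol.data, 1.04)
        stack = render_sections(vol_104, 1.0, axis=0)
        oracle = len({int(np.floor(i * 1.04 / 1.0)) for i in range(vol.shape[0])})
        assert stack.raw.shape[0] == oracle

    def test_normalization_is_global(self, phantom64):
        _, vol = phantom64
        stack = render_sections(vol, 10.0, axis=2)
        assert stack.normalized.min() == 0.0 and stack.normalized.max() == 1.0

    def test_sub_voxel_thickness_rejected(self, phantom64):
        _, vol = phantom64
        with pytest.raises(ValidationError):
            render_sections(vol, 0.3 * vol.voxel_size)
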