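"""Contrast transfer function: analytic model, estimation, screening, flipping.

Weak-phase CTF with positive-underfocus convention:

    CTF(k) = -[ sqrt(1 - A^2) sin(gamma) + A cos(gamma) ]
    gamma(k) = -pi lambda dz(theta) |k|^2 + (pi/2) Cs lambda^3 |k|^4

with dz(theta) the astigmatic defocus at azimuth theta, A the amplitude
contrast fraction and lambda the relativistic electron wavelength, so
CTF(0) = -A for every parameter set.

Defocus/astigmatism estimation correlates a background-subtracted, tile-
averaged power spectrum with |CTF|^2 over a defocus grid and refines the
optimum with a simplex search; Thon-ring isotropy compares per-sector
radial profiles of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import (
    AcquisitionParams,
    CTFParams,
    PicoemError,
    SizingError,
    ValidationError,
)

__all__ = [
    "PowerSpectrum",
    "CtfEstimationError",
    "ctf_value",
    "ctf_2d",
    "periodogram",
    "estimate_ctf",
    "thon_isotropy",
    "phase_flip",
]


class CtfEstimationError(PicoemError):
    """No usable Thon-ring signal: estimation failed rather than defaulted."""


@dataclass
class PowerSpectrum:
    """2D spectral power (FFT layout, DC at [0, 0]) with pixel size in A."""

    power: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2:
            raise ValidationError("power spectrum must be 2D")
        if np.any(self.power < 0):
            raise ValidationError("power spectrum must be non-negative")

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_size)

    def freq_grids(self):
        ky = np.fft.fftfreq(self.power.shape[0], d=self.pixel_size)[:, None]
        kx = np.fft.fftfreq(self.power.shape[1], d=self.pixel_size)[None, :]
        return ky, kx

    def radial_average(self, n_bins: int | None = None):
        """(frequency axis in 1/A, mean power per radial bin)."""
        ky, kx = self.freq_grids()
        k = np.hypot(ky, kx)
        n_bins = n_bins or self.power.shape[0] // 2
        edges = np.linspace(0.0, self.nyquist, n_bins + 1)
        idx = np.clip(np.digitize(k.ravel(), edges) - 1, 0, n_bins - 1)
        mask = (k.ravel() <= self.nyquist)
        sums = np.bincount(idx[mask], weights=self.power.ravel()[mask], minlength=n_bins)
        counts = np.bincount(idx[mask], minlength=n_bins)
        centres = 0.5 * (edges[:-1] + edges[1:])
        return centres, sums / np.maximum(counts, 1)


def ctf_value(
    params: CTFParams,
    acquisition: AcquisitionParams,
    kx: np.ndarray,
    ky: np.ndarray,
) -> np.ndarray:
    """Evaluate the CTF at spatial frequency vectors (kx, ky) in 1/A."""
    lam = acquisition.wavelength
    a = acquisition.amplitude_contrast
    cs = acquisition.cs_mm * 1e7          # mm -> A
    k2 = kx**2 + ky**2
    theta = np.arctan2(ky, kx)
    dz_mean = 0.5 * (params.defocus_u_um + params.defocus_v_um) * 1e4
    dz_diff = 0.5 * (params.defocus_u_um - params.defocus_v_um) * 1e4
    dz = dz_mean + dz_diff * np.cos(2.0 * (theta - np.deg2rad(params.astig_angle_deg)))
    gamma = -np.pi * lam * dz * k2 + 0.5 * np.pi * cs * lam**3 * k2**2
    return -(np.sqrt(1.0 - a**2) * np.sin(gamma) + a * np.cos(gamma))


def ctf_2d(
    params: CTFParams,
    acquisition: AcquisitionParams,
    shape: tuple[int, int],
    pixel_size: float,
    rfft: bool = False,
) -> np.ndarray:
    """CTF sampled on the (r)FFT frequency grid of an image of given shape.

    The sampled grid is symmetrized under k -> -k (which only touches the
    aliased Nyquist row/column, where the assignment of +-Nyquist is
    ambiguous) so that multiplying a real image's transform by it keeps the
    result exactly real.
    """
    ky = np.fft.fftfreq(shape[0], d=pixel_size)[:, None]
    kx = np.fft.fftfreq(shape[1], d=pixel_size)[None, :]
    c = ctf_value(params, acquisition, kx, ky)
    mirror = np.roll(np.flip(c, (0, 1)), 1, (0, 1))
    c = 0.5 * (c + mirror)
    if rfft:
        return c[:, : shape[1] // 2 + 1]
    return c


def periodogram(
    micrograph: np.ndarray, pixel_size: float, tile: int = 256, overlap: float = 0.5
) -> PowerSpectrum:
    """Tile-averaged power spectrum (Welch periodogram) of a micrograph."""
    h, w = micrograph.shape
    if min(h, w) < tile:
        raise SizingError(f"micrograph smaller than spectral tile {tile}")
    step = max(1, int(tile * (1.0 - overlap)))
    acc = np.zeros((tile, tile))
    count = 0
    for y0 in range(0, h - tile + 1, step):
        for x0 in range(0, w - tile + 1, step):
            patch = micrograph[y0 : y0 + tile, x0 : x0 + tile]
            patch = patch - patch.mean()
            acc += np.abs(np.fft.fft2(patch)) ** 2
            count += 1
    return PowerSpectrum(acc / count, pixel_size)


def _background_subtract(spec: PowerSpectrum, smooth_bins: int = 9, smooth_px: float = 1.5):
    """Remove the smooth radial baseline, keeping the oscillatory Thon part.

    The baseline is a median+Gaussian smoothed radial profile of log-power
    interpolated back onto the 2D grid; the residual is lightly smoothed in
    2D (isotropic, so ring positions are unbiased) to tame periodogram
    noise.
    """
    centres, prof = spec.radial_average()
    log_prof = np.log(np.maximum(prof, 1e-30))
    base = ndimage.median_filter(log_prof, size=smooth_bins, mode="nearest")
    base = ndimage.gaussian_filter1d(base, sigma=smooth_bins / 3.0, mode="nearest")
    ky, kx = spec.freq_grids()
    k = np.hypot(ky, kx)
    base2d = np.interp(k, centres, base, left=base[0], right=base[-1])
    resid = np.log(np.maximum(spec.power, 1e-30)) - base2d
    resid = ndimage.gaussian_filter(np.fft.fftshift(resid), smooth_px)
    resid = np.fft.ifftshift(resid)
    return resid, k


def _model_correlation(
    resid_band: np.ndarray,
    kxb: np.ndarray,
    kyb: np.ndarray,
    params: CTFParams,
    acquisition: AcquisitionParams,
) -> float:
    model = ctf_value(params, acquisition, kxb, kyb) ** 2
    a = resid_band - resid_band.mean()
    b = model - model.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_ctf(
    micrograph_or_spectrum,
    acquisition: AcquisitionParams,
    defocus_range_um: tuple[float, float] = (0.5, 5.0),
    pixel_size: float | None = None,
    coarse_step_um: float = 0.05,
    astig_max_um: float = 0.8,
    band: tuple[float, float] = (0.1, 0.9),
    quality_threshold: float = 0.2,
    tile: int = 512,
) -> tuple[CTFParams, float]:
    """Estimate defocus pair and astigmatism angle from Thon rings.

    Accepts a micrograph array (requires ``pixel_size``) or a PowerSpectrum.
    Returns ``(CTFParams, fit_quality)`` where quality is the correlation in
    [-1, 1] between |CTF|^2 and the background-subtracted spectrum over the
    fitting band (fractions of Nyquist).  The band's upper edge is capped
    where the spectral sampling stops resolving the Thon rings at the
    maximum search defocus (ring phase step <= pi/3 per spectral pixel).
    Raises CtfEstimationError when the best fit stays below
    ``quality_threshold`` (e.g. pure noise input).
    """
    if defocus_range_um[0] >= defocus_range_um[1]:
        raise ValidationError("defocus search range is empty")
    if isinstance(micrograph_or_spectrum, PowerSpectrum):
        spec = micrograph_or_spectrum
    else:
        if pixel_size is None:
            raise ValidationError("pixel_size required when passing a micrograph")
        mg = np.asarray(micrograph_or_spectrum)
        spec = periodogram(mg, pixel_size, tile=min(tile, min(mg.shape)))

    resid, k = _background_subtract(spec)
    ky, kx = spec.freq_grids()
    dk = 1.0 / (spec.power.shape[0] * spec.pixel_size)
    lam = acquisition.wavelength
    dz_hi_A = defocus_range_um[1] * 1e4
    k_resolve = 1.0 / (6.0 * lam * dz_hi_A * dk)
    k_lo = band[0] * spec.nyquist
    k_hi = min(band[1] * spec.nyquist, k_resolve)
    if k_hi <= k_lo:
        raise SizingError("spectral sampling too coarse to resolve Thon rings in band")
    band_mask = (k >= k_lo) & (k <= k_hi)
    resid_band = resid[band_mask]
    kxb = np.broadcast_to(kx, k.shape)[band_mask]
    kyb = np.broadcast_to(ky, k.shape)[band_mask]

    def score(dz_u, dz_v, ang):
        if dz_u < dz_v or dz_v <= 0:
            return -2.0
        try:
            p = CTFParams(dz_u, dz_v, ang % 180.0)
        except ValidationError:
            return -2.0
        return _model_correlation(resid_band, kxb, kyb, p, acquisition)

    # stage 1: round defocus grid
    lo, hi = defocus_range_um
    best = (-2.0, None)
    for dz in np.arange(lo, hi + 1e-9, coarse_step_um):
        s = score(dz, dz, 0.0)
        if s > best[0]:
            best = (s, (dz, dz, 0.0))
    if best[1] is None:
        raise CtfEstimationError("no defocus candidate scored")
    dz0 = best[1][0]

    # stage 2: coarse astigmatism around the round optimum
    candidates = [best]
    for astig in np.linspace(0.0, astig_max_um, 13):
        for ang in np.arange(0.0, 180.0, 10.0) if astig > 0 else [0.0]:
            s = score(dz0 + astig / 2, dz0 - astig / 2, ang)
            candidates.append((s, (dz0 + astig / 2, dz0 - astig / 2, ang)))
    candidates.sort(key=lambda c: -c[0])

    # stage 3: simplex refinement from the best coarse candidates (the
    # correlation surface has shallow side optima at high defocus)
    def neg(x):
        return -score(x[0], x[1], x[2])

    best = candidates[0]
    for s0, (u0, v0, a0) in candidates[:4]:
        res = optimize.minimize(
            neg, np.array([u0, v0, a0]), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
        )
        if -res.fun > best[0]:
            best = (-res.fun, tuple(res.x))
    u0, v0, a0 = best[1]
    quality = score(u0, v0, a0)
    if quality < quality_threshold:
        raise CtfEstimationError(
            f"fit quality {quality:.3f} below threshold {quality_threshold}: "
            "no detectable Thon-ring signal"
        )
    if u0 < v0:
        u0, v0 = v0, u0
        a0 += 90.0
    return CTFParams(float(u0), float(v0), float(a0 % 180.0)), float(quality)


def thon_isotropy(
    spectrum: PowerSpectrum,
    n_sectors: int = 8,
    threshold: float = 0.75,
    n_bins: int | None = None,
    window: int = 7,
) -> tuple[float, float]:
    """Highest frequency with isotropic Thon rings, plus an isotropy score.

    The azimuth range [0, pi) (Friedel-unique) is split into ``n_sectors``;
    per sector a radial profile of log-power is computed.  At each radial
    bin, sector profile segments (sliding window of bins) are compared to
    the all-sector mean segment with the concordance correlation, which
    penalizes ring-contrast loss in a sector (an anisotropy signature) and
    not only ring-position changes; the bin's isotropy score is the
    minimum over sectors.  Returned frequency is the end of the contiguous
    run of bins (from low frequency) whose score meets ``threshold`` —
    monotone non-increasing in the threshold by construction.  A threshold
    above every score returns the lowest usable bin frequency with score.
    """
    if n_sectors < 4:
        raise ValidationError("need at least 4 sectors")
    n = min(spectrum.power.shape)
    n_bins = n_bins or n // 4
    if n_bins < 8:
        raise SizingError("spectrum too small for radial binning")
    ky, kx = spectrum.freq_grids()
    k = np.hypot(ky, kx)
    theta = np.arctan2(ky, kx) % np.pi
    edges = np.linspace(0.0, spectrum.nyquist, n_bins + 1)
    sector_idx = np.minimum((theta / np.pi * n_sectors).astype(int), n_sectors - 1)
    bin_idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    valid = k <= spectrum.nyquist

    # linear power: ring-contrast loss in a sector must register in the score
    profiles = np.zeros((n_sectors, n_bins))
    for s in range(n_sectors):
        m = valid & (sector_idx == s)
        sums = np.bincount(bin_idx[m], weights=spectrum.power[m], minlength=n_bins)
        counts = np.bincount(bin_idx[m], minlength=n_bins)
        profiles[s] = sums / np.maximum(counts, 1)
    scale = np.abs(profiles).max()
    if scale > 0:
        profiles /= scale

    mean_prof = profiles.mean(axis=0)
    half = window // 2
    # the near-DC region has too few pixels per sector to score and carries
    # no Thon information; start above 6% of Nyquist
    min_bin = max(half, int(0.06 * n_bins) + 1)
    scores = np.full(n_bins, np.nan)
    for b in range(min_bin, n_bins - half):
        seg_mean = mean_prof[b - half : b + half + 1]
        worst = 1.0
        for s in range(n_sectors):
            seg = profiles[s, b - half : b + half + 1]
            a = seg - seg.mean()
            m = seg_mean - seg_mean.mean()
            var_a, var_m = (a * a).mean(), (m * m).mean()
            denom = var_a + var_m + (seg.mean() - seg_mean.mean()) ** 2
            if denom < 1e-18:
                r = 1.0
            else:
                r = float(2.0 * (a * m).mean() / denom)
            worst = min(worst, r)
        scores[b] = worst

    centres = 0.5 * (edges[:-1] + edges[1:])
    usable = np.nonzero(~np.isnan(scores))[0]
    last_ok = None
    for b in usable:
        if scores[b] >= threshold:
            last_ok = b
        else:
            break
    if last_ok is None:
        return float(centres[usable[0]]), float(scores[usable[0]])
    if last_ok == usable[-1]:
        return float(spectrum.nyquist), float(np.nanmin(scores))
    return float(centres[last_ok]), float(np.nanmin(scores[usable[0] : last_ok + 1]))


def phase_flip(
    image: np.ndarray,
    params: CTFParams,
    acquisition: AcquisitionParams,
    pixel_size: float,
) -> tuple[np.ndarray, CTFParams]:
    """Multiply Fourier coefficients by sign(CTF); amplitudes are untouched.

    Returns the corrected image and params with ``phase_flipped=True``.
    Raises on an already-flipped input to guard the bookkeeping (the raw
    operation is its own inverse; the flag is what prevents double use).
    """
    if params.phase_flipped:
        raise ValidationError("image already phase flipped (double flip attempted)")
    c2d = ctf_2d(params, acquisition, image.shape, pixel_size)
    sign = np.where(c2d < 0.0, -1.0, 1.0)
    flipped = np.fft.ifft2(np.fft.fft2(image) * sign).real
    return flipped, params.flipped()
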