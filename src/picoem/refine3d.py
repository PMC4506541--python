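"""Projection-matching refinement with CTF-amplitude-corrected reconstruction.

Each round: forward-project the current reference on a quasi-uniform
angular grid over the asymmetric unit, exhaustively match every particle
against the in-plane-rotated projections by normalized cross-correlation
(rotational search on a discrete psi grid, translational search over a
+-max_shift window via FFT correlation), then rebuild the map by Fourier
central-slice insertion with Wiener-style division by the accumulated
CTF^2 weights, averaging over the symmetry group during insertion.

Images and templates are normalized to zero mean and unit L2 norm under a
circular mask before correlation, so scores are comparable across
directions and bounded by 1 (reached at a perfect self-match).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy import ndimage

from .core import (
    AcquisitionParams,
    SizingError,
    ValidationError,
    VolumeMap,
)
from .ctf import ctf_2d
from .geometry import AngularGrid, euler_to_matrix, symmetry_matrices
from .particles import ParticleSet
from .simulator import rot180_z

__all__ = [
    "OrientationRecord",
    "ProjectionLibrary",
    "TemplateBank",
    "make_projection_library",
    "align_particle",
    "align_particles",
    "reconstruct",
    "apply_symmetry",
    "refine",
]


@dataclass
class OrientationRecord:
    particle_id: int
    rot: float
    tilt: float
    psi: float
    shift_x: float
    shift_y: float
    score: float
    round: int = 0


@dataclass
class ProjectionLibrary:
    """Forward projections of a reference on an angular grid."""

    directions: np.ndarray        # (D, 2) of (rot, tilt) degrees
    projections: np.ndarray       # (D, box, box)
    grid: AngularGrid

    def __len__(self) -> int:
        return len(self.directions)

    @property
    def box_size(self) -> int:
        return self.projections.shape[1]


def make_projection_library(
    reference: VolumeMap, grid: AngularGrid, order: int = 3
) -> ProjectionLibrary:
    """One forward projection per (rot, tilt) grid direction, psi = 0.

    For a C2 reference the grid covers rot in [0, 180) only, because the
    projections at rot and rot + 180 are identical.
    """
    if not reference.is_cubic:
        raise SizingError("reference must be cubic")
    if len(grid) == 0:
        raise ValidationError("empty angular grid")
    data = ndimage.spline_filter(reference.data, order=order) if order > 1 else reference.data
    vol = VolumeMap(data, reference.voxel_size)
    projs = np.empty((len(grid), reference.shape[0], reference.shape[0]))
    for i, (rot, tilt) in enumerate(grid.directions):
        r = euler_to_matrix(rot, tilt, 0.0)
        projs[i] = _rotate_project(vol.data, r, order)
    return ProjectionLibrary(grid.as_array(), projs, grid)


def _rotate_project(prefiltered: np.ndarray, r: np.ndarray, order: int) -> np.ndarray:
    n = prefiltered.shape[0]
    c = np.full(3, n // 2, dtype=float)
    m = r[::-1, ::-1]
    rotated = ndimage.affine_transform(
        prefiltered, m, offset=c - m @ c, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )
    return rotated.sum(axis=0)


def circular_mask(box: int, radius: float | None = None) -> np.ndarray:
    c = box // 2
    r = radius if radius is not None else box / 2.0 - 1.0
    yy, xx = np.mgrid[0:box, 0:box]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


def normalize_masked(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero mean, unit L2 norm under the mask; zero outside."""
    out = np.where(mask, image - image[mask].mean(), 0.0)
    norm = np.sqrt((out[mask] ** 2).sum())
    if norm > 0:
        out /= norm
    return out


def rotate_image(image: np.ndarray, psi_deg: float, order: int = 3) -> np.ndarray:
    """In-plane rotation consistent with the ZYZ psi convention:
    ``rotate_image(project(v, (rot, tilt, 0)), psi) == project(v, (rot, tilt, psi))``.
    """
    a = np.deg2rad(psi_deg)
    cs, sn = np.cos(a), np.sin(a)
    m = np.array([[cs, sn], [-sn, cs]])
    n = image.shape[0]
    c = np.full(2, n // 2, dtype=float)
    return ndimage.affine_transform(
        image, m, offset=c - m @ c, order=order, mode="constant", cval=0.0
    )


def lowpass_image(
    image: np.ndarray, cutoff_A: float, pixel_size: float, edge_shells: float = 3.0
) -> np.ndarray:
    """Cosine-edged 2D low-pass filter (same contract as the map filter)."""
    n = image.shape[0]
    ky = np.fft.fftfreq(image.shape[0], d=pixel_size)[:, None]
    kx = np.fft.fftfreq(image.shape[1], d=pixel_size)[None, :]
    k = np.hypot(ky, kx)
    k_c = 1.0 / cutoff_A
    width = edge_shells / (n * pixel_size)
    filt = np.ones_like(k)
    edge = (k > k_c) & (k < k_c + width)
    filt[edge] = 0.5 * (1.0 + np.cos(np.pi * (k[edge] - k_c) / width))
    filt[k >= k_c + width] = 0.0
    return np.fft.ifft2(np.fft.fft2(image) * filt).real


class TemplateBank:
    """Normalized, in-plane-rotated template FFTs for fast exhaustive matching.

    Templates are indexed (direction, psi); FFTs are stored as complex64 to
    bound memory for fine angular grids.  An optional alignment low-pass
    (``lowpass_A`` at the given pixel size) band-limits the matching — the
    matcher applies the same filter to the particle images, which boosts the
    effective correlation SNR when the noise is white but the signal is not.
    """

    def __init__(
        self,
        library: ProjectionLibrary,
        psi_step_deg: float,
        order: int = 3,
        lowpass_A: float | None = None,
        pixel_size: float = 1.0,
    ):
        if psi_step_deg <= 0:
            raise ValidationError("psi step must be positive")
        self.library = library
        self.psis = np.arange(0.0, 360.0, psi_step_deg)
        self.lowpass_A = lowpass_A
        self.pixel_size = pixel_size
        box = library.box_size
        self.mask = circular_mask(box)
        d, p = len(library), len(self.psis)
        self.fts = np.empty((d, p, box, box // 2 + 1), dtype=np.complex64)
        for i in range(d):
            proj = library.projections[i]
            if lowpass_A is not None:
                proj = lowpass_image(proj, lowpass_A, pixel_size)
            for j, psi in enumerate(self.psis):
                t = proj if psi == 0.0 else rotate_image(proj, psi, order)
                t = normalize_masked(t, self.mask)
                self.fts[i, j] = sfft.rfft2(t).astype(np.complex64)

    def prepare_image(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if self.lowpass_A is not None:
            img = lowpass_image(img, self.lowpass_A, self.pixel_size)
        return normalize_masked(img, self.mask)

    @property
    def box_size(self) -> int:
        return self.library.box_size


def _shift_window(box: int, max_shift: int):
    """Allowed shifts -max..+max (lexicographic) and their FFT-layout indices."""
    shifts = np.arange(-max_shift, max_shift + 1)
    idx = shifts % box
    return shifts, idx


def _match_one(
    image: np.ndarray,
    bank: TemplateBank,
    direction_subset: np.ndarray | None,
    max_shift: int,
    image_filter: np.ndarray | None = None,
):
    box = bank.box_size
    img_n = bank.prepare_image(image)
    f_img = sfft.rfft2(img_n).astype(np.complex64)
    fts = bank.fts if direction_subset is None else bank.fts[direction_subset]
    d, p = fts.shape[:2]
    if image_filter is not None:
        # matched filtering: Sum F_img (H F_t)* == Sum (H F_img) F_t* for real H,
        # so a per-particle transfer (e.g. |CTF|) is applied to the image once;
        # template norms must then include the transfer (Parseval on the rfft
        # grid, middle columns counted twice)
        f_img = f_img * image_filter
        colw = np.full(box // 2 + 1, 2.0, dtype=np.float32)
        colw[0] = 1.0
        if box % 2 == 0:
            colw[-1] = 1.0
        h2 = (image_filter.astype(np.float32) ** 2) * colw[None, :]
        norms = np.sqrt(
            np.maximum(((np.abs(fts) ** 2) * h2[None, None]).sum(axis=(2, 3)), 1e-12)
        )
    else:
        norms = None
    corr = sfft.irfft2(f_img[None, None] * np.conj(fts), s=(box, box))
    shifts, idx = _shift_window(box, max_shift)
    window = corr[:, :, idx[:, None], idx[None, :]]
    if norms is not None:
        window = window / norms[:, :, None, None]
    flat = int(np.argmax(window))
    di, pj, syi, sxi = np.unravel_index(flat, window.shape)
    score = float(window[di, pj, syi, sxi])
    dir_idx = int(di if direction_subset is None else direction_subset[di])
    rot, tilt = bank.library.directions[dir_idx]
    return dir_idx, float(rot), float(tilt), float(bank.psis[pj]), float(shifts[sxi]), float(shifts[syi]), score


def align_particle(
    image: np.ndarray,
    library: ProjectionLibrary,
    max_shift_px: int = 8,
    psi_step_deg: float = 15.0,
    bank: TemplateBank | None = None,
    particle_id: int = 0,
    round_index: int = 0,
    lowpass_A: float | None = None,
    pixel_size: float = 1.0,
) -> OrientationRecord:
    """Exhaustive (direction x psi x shift) normalized cross-correlation match.

    Returns the global maximum; ties break to the lowest (direction index,
    psi, shift) in scan order.  The correlation convention is
    ``image(u) ~ template(u - s)`` so the returned shift maps the library
    projection onto the particle.
    """
    if len(library) == 0:
        raise ValidationError("empty projection library")
    if image.shape != (library.box_size, library.box_size):
        raise ValidationError("image box does not match library box")
    if bank is None:
        bank = TemplateBank(library, psi_step_deg, lowpass_A=lowpass_A, pixel_size=pixel_size)
    _, rot, tilt, psi, sx, sy, score = _match_one(image, bank, None, max_shift_px)
    return OrientationRecord(particle_id, rot, tilt, psi, sx, sy, score, round_index)


def align_particles(
    particles: ParticleSet,
    library: ProjectionLibrary,
    max_shift_px: int = 8,
    psi_step_deg: float = 15.0,
    direction_subsets=None,
    round_index: int = 0,
    lowpass_A: float | None = None,
    use_ctf: bool = False,
    acquisition: AcquisitionParams | None = None,
) -> list[OrientationRecord]:
    """Batch alignment sharing one template bank; optional per-particle
    direction subsets implement local orientation search.

    With ``use_ctf=True`` each particle's |CTF| enters the matched filter
    (applied to the image transform, equivalent to CTF-modulating every
    template), which matters when CTF zeros cut through the band that
    discriminates orientations.
    """
    if use_ctf and acquisition is None:
        raise ValidationError("use_ctf requires acquisition parameters")
    bank = TemplateBank(
        library, psi_step_deg, lowpass_A=lowpass_A, pixel_size=particles.pixel_size
    )
    box = library.box_size
    records = []
    for i in range(len(particles)):
        subset = None if direction_subsets is None else direction_subsets[i]
        filt = None
        if use_ctf and not np.isnan(particles.metadata.iloc[i]["defocus_u_um"]):
            filt = np.abs(
                ctf_2d(particles.ctf_params(i), acquisition, (box, box),
                       particles.pixel_size, rfft=True)
            ).astype(np.float32)
        _, rot, tilt, psi, sx, sy, score = _match_one(
            particles.images[i], bank, subset, max_shift_px, image_filter=filt
        )
        records.append(OrientationRecord(i, rot, tilt, psi, sx, sy, score, round_index))
    return records


def records_to_metadata(particles: ParticleSet, records) -> None:
    """Write alignment records into the particle metadata in place."""
    for r in records:
        particles.metadata.loc[r.particle_id, ["rot", "tilt", "psi"]] = (r.rot, r.tilt, r.psi)
        particles.metadata.loc[r.particle_id, ["shift_x", "shift_y"]] = (r.shift_x, r.shift_y)
        particles.metadata.loc[r.particle_id, ["score", "round"]] = (r.score, r.round)


def reconstruct(
    particles: ParticleSet,
    acquisition: AcquisitionParams | None = None,
    symmetry: str = "C1",
    ctf_correction: str = "none",
    wiener_frac: float = 0.01,
) -> VolumeMap:
    """Direct Fourier inversion: insert each particle transform into its
    central slice with trilinear spreading and per-voxel weight accumulation.

    With ``ctf_correction='amplitude'`` the result is the Wiener-style ratio
    ``sum(CTF_i F_i) / (sum(CTF_i^2) + c)`` with ``c = wiener_frac x
    mean(sum CTF^2)``; phase-flipped particles contribute |CTF| in the
    numerator so the amplitude weighting stays consistent.  The symmetry
    group is averaged in Fourier space by inserting every particle once per
    group element.
    """
    if len(particles) < 1:
        raise ValidationError("reconstruction needs at least one particle")
    if ctf_correction not in ("none", "amplitude"):
        raise ValidationError(f"unknown ctf correction mode {ctf_correction!r}")
    if wiener_frac <= 0:
        raise ValidationError("wiener constant fraction must be positive")
    if not particles.has_orientations():
        raise ValidationError("every particle needs an assigned orientation")
    if ctf_correction == "amplitude" and acquisition is None:
        raise ValidationError("amplitude correction requires acquisition parameters")

    box = particles.box_size
    n3 = box**3
    num_re = np.zeros(n3)
    num_im = np.zeros(n3)
    den = np.zeros(n3)
    qy = np.fft.fftfreq(box) * box
    qx = np.fft.fftfreq(box) * box
    qxg, qyg = np.meshgrid(qx, qy)
    plane = np.stack([qxg.ravel(), qyg.ravel(), np.zeros(box * box)])  # (3, box^2)
    group = symmetry_matrices(symmetry)
    c0 = box // 2
    # rotation is about the box centre, not the FFT origin: re-centre the 2D
    # transform before insertion and un-centre the 3D transform afterwards
    centre_2d = np.exp(2j * np.pi * (qxg + qyg) * c0 / box).ravel()

    pend_idx, pend_re, pend_im, pend_w = [], [], [], []
    pending = 0
    for i in range(len(particles)):
        row = particles.metadata.iloc[i]
        f = np.fft.fft2(particles.images[i])
        sx, sy = row["shift_x"], row["shift_y"]
        if not (np.isnan(sx) or np.isnan(sy)) and (sx != 0 or sy != 0):
            f = ndimage.fourier_shift(f, shift=(-sy, -sx))
        if ctf_correction == "amplitude":
            c2d = ctf_2d(particles.ctf_params(i), acquisition, (box, box), particles.pixel_size)
            w2d = np.abs(c2d) if bool(row["phase_flipped"]) else c2d
        else:
            w2d = np.ones((box, box))
        f_w = (f * w2d).ravel() * centre_2d
        w2 = (w2d**2).ravel()
        r = euler_to_matrix(row["rot"], row["tilt"], row["psi"])
        for g in group:
            coords = (g @ r) @ plane            # (3, box^2) in (x, y, z) freq units
            idx, wts, sel = _trilinear_scatter(coords, box)
            pend_idx.append(idx)
            pend_re.append((wts * f_w.real[sel][None, :]).ravel())
            pend_im.append((wts * f_w.imag[sel][None, :]).ravel())
            pend_w.append((wts * w2[sel][None, :]).ravel())
            pending += idx.size
        if pending > 4_000_000 or i == len(particles) - 1:
            flat = np.concatenate([a.ravel() for a in pend_idx])
            num_re += np.bincount(flat, weights=np.concatenate(pend_re), minlength=n3)
            num_im += np.bincount(flat, weights=np.concatenate(pend_im), minlength=n3)
            den += np.bincount(flat, weights=np.concatenate(pend_w), minlength=n3)
            pend_idx, pend_re, pend_im, pend_w = [], [], [], []
            pending = 0

    c = wiener_frac * den.mean() if den.mean() > 0 else wiener_frac
    vol_ft = ((num_re + 1j * num_im) / (den + c)).reshape(box, box, box)
    kz = np.fft.fftfreq(box)[:, None, None] * box
    ky3 = np.fft.fftfreq(box)[None, :, None] * box
    kx3 = np.fft.fftfreq(box)[None, None, :] * box
    uncentre_3d = np.exp(-2j * np.pi * (kz + ky3 + kx3) * c0 / box)
    return VolumeMap(np.fft.ifftn(vol_ft * uncentre_3d).real, particles.pixel_size)


def _trilinear_scatter(coords, box):
    """Flattened grid indices (8, n) and trilinear weights (8, n) for points
    (x, y, z) in integer frequency units, wrapped modulo the box; points
    outside the Nyquist sphere are dropped (selection mask returned)."""
    half = box // 2
    kx, ky, kz = coords
    sel = kx**2 + ky**2 + kz**2 <= half**2
    kx, ky, kz = kx[sel], ky[sel], kz[sel]
    fx, fy, fz = np.floor(kx), np.floor(ky), np.floor(kz)
    tx, ty, tz = kx - fx, ky - fy, kz - fz
    idx_list, w_list = [], []
    for dz in (0, 1):
        wz = tz if dz else 1 - tz
        iz = (fz + dz).astype(np.int64) % box
        for dy in (0, 1):
            wy = ty if dy else 1 - ty
            iy = (fy + dy).astype(np.int64) % box
            for dx in (0, 1):
                wx = tx if dx else 1 - tx
                ix = (fx + dx).astype(np.int64) % box
                idx_list.append((iz * box + iy) * box + ix)
                w_list.append(wz * wy * wx)
    return np.stack(idx_list), np.stack(w_list), sel


def apply_symmetry(volume: VolumeMap, group: str = "C2") -> VolumeMap:
    """Average a volume over its point group (C2: exact 180-degree rotation
    about z on the grid).  Idempotent and mass-preserving."""
    mats = symmetry_matrices(group)
    if len(mats) == 1:
        return volume.copy()
    return VolumeMap(0.5 * (volume.data + rot180_z(volume.data)), volume.voxel_size)


def refine(
    particles: ParticleSet,
    initial_reference: VolumeMap,
    rounds: int = 3,
    grid_schedule=(15.0, 10.0, 7.5),
    symmetry: str = "C2",
    ctf_mode: str = "amplitude",
    acquisition: AcquisitionParams | None = None,
    max_shift_px: int = 8,
    start_lowpass_A: float = 20.0,
    local_search_factor: float = 2.0,
    wiener_frac: float = 0.01,
    align_lowpass_A: float | None = 15.0,
) -> tuple[VolumeMap, pd.DataFrame]:
    """Iterative projection-matching refinement.

    Round 1 searches the full asymmetric unit at the first schedule step;
    later rounds restrict each particle's direction search to a
    neighbourhood (``local_search_factor x`` previous step) of its previous
    assignment, with the psi/shift search always exhaustive.  The starting
    reference is low-pass filtered to ``start_lowpass_A`` before round 1,
    and matching is band-limited to ``align_lowpass_A`` (None = full band).
    Returns the final map and the per-round orientation log.
    """
    from .postprocess import lowpass_map

    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    if len(particles) == 0:
        raise ValidationError("no particles to refine")
    schedule = list(grid_schedule)
    while len(schedule) < rounds:
        schedule.append(schedule[-1])

    reference = lowpass_map(initial_reference, start_lowpass_A)
    logs = []
    prev_records = None
    prev_step = None
    for rnd in range(1, rounds + 1):
        step = float(schedule[rnd - 1])
        grid = AngularGrid(step, symmetry)
        library = make_projection_library(reference, grid)
        subsets = None
        if prev_records is not None:
            radius = local_search_factor * prev_step
            subsets = [
                grid.neighbours(r.rot, r.tilt, radius) for r in prev_records
            ]
            subsets = [s if len(s) else None for s in subsets]
        records = align_particles(
            particles, library, max_shift_px, psi_step_deg=step,
            direction_subsets=subsets, round_index=rnd, lowpass_A=align_lowpass_A,
            use_ctf=(ctf_mode == "amplitude"), acquisition=acquisition,
        )
        records_to_metadata(particles, records)
        reference = reconstruct(
            particles, acquisition=acquisition, symmetry=symmetry,
            ctf_correction=ctf_mode, wiener_frac=wiener_frac,
        )
        logs.append(pd.DataFrame([vars(r) for r in records]))
        prev_records, prev_step = records, step
    return reference, pd.concat(logs, ignore_index=True)
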