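"""Synthetic cryo-EM data generator with full ground-truth records.

The phantom emulates the architecture of a barrel-shaped protease complex
built from four stacked pseudo-seven-fold rings (alpha-beta-beta-alpha)
with overall C2 symmetry.  Because the C2 axis is fixed to z by package
convention, the barrel's long (pseudo-seven-fold) axis lies along x and
the two alpha/beta halves are exact 180-degree copies about z — the same
relationship the two halves of the real complex have.  The seven subunits
of each ring carry distinct weights (eukaryotic rings are built from seven
*different* subunits), which also removes the rotational degeneracy a
perfectly seven-fold ring would impose on orientation assignment.

Three designated "active sites" per half, attached to beta-ring subunits,
can carry ligand blobs whose weight scales with a per-site occupancy —
the synthetic analogue of an active-site inhibitor density.

All randomness flows through ``numpy.random.default_rng(seed)``; equal
seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    AcquisitionParams,
    CTFParams,
    SizingError,
    ValidationError,
    VolumeMap,
)
from .geometry import euler_to_matrix
from .movie import DoseLedger, MovieStack
from .particles import ParticleSet, empty_metadata

__all__ = [
    "PhantomSpec",
    "Phantom",
    "LigandSite",
    "GroundTruth",
    "build_phantom",
    "render_model_density",
    "simulate_projection",
    "fourier_shift_image",
    "rot180_z",
    "simulate_particle_stack",
    "simulate_micrograph",
    "simulate_movie",
    "simulate_thon_micrograph",
]


# ---------------------------------------------------------------------------
# phantom


@dataclass(frozen=True)
class LigandSite:
    site_id: str
    centre: tuple  # (x, y, z) Angstrom
    occupancy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(f"occupancy of {self.site_id} outside [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of the synthetic barrel phantom.

    Distances in Angstrom.  Defaults give a ~150 A long, ~110 A wide barrel
    in a 64-voxel box at 2.8 A/voxel, with enough margin that every blob's
    rendered support stays interior to the grid (keeps the C2 copy exact).
    """

    box_size: int = 64
    voxel_size: float = 2.8
    symmetry: str = "C2"
    n_subunits: int = 7
    alpha_x: float = 55.0          # axial centre of the outer (alpha) ring, one half
    beta_x: float = 20.0           # axial centre of the inner (beta) ring, one half
    alpha_radius: float = 42.0
    beta_radius: float = 45.0
    sigma: float = 6.5             # Gaussian width of a subunit blob
    alpha_weights: tuple = (1.0, 1.3, 0.75, 1.15, 0.9, 1.4, 0.6)
    beta_weights: tuple = (1.2, 0.7, 1.35, 0.95, 1.1, 0.65, 1.25)
    beta_phase_deg: float = 25.7   # stagger between alpha and beta rings
    ligand_subunits: tuple = (0, 2, 4)       # beta-ring subunits carrying sites
    ligand_names: tuple = ("beta1", "beta2", "beta5")
    ligand_occupancies: tuple = (1.0, 1.0, 1.0)
    ligand_sigma: float = 3.0
    ligand_weight: float = 0.6
    ligand_radial_inset: float = 15.0
    ligand_axial_inset: float = 8.0
    seed: int = 0


@dataclass
class Phantom:
    """Pseudo-atom ground-truth model: (x, y, z, weight, sigma) blobs."""

    atoms: list                    # list of (x, y, z, weight, sigma)
    symmetry: str
    ligand_sites: list             # list of LigandSite (both halves)
    seed: int
    ligand_sigma: float = 4.0
    ligand_weight: float = 1.0

    def all_atoms(self, include_ligands: bool = True, occupancy_override=None):
        """Protein blobs plus occupancy-weighted ligand blobs."""
        atoms = list(self.atoms)
        if include_ligands:
            for i, site in enumerate(self.ligand_sites):
                occ = site.occupancy if occupancy_override is None else occupancy_override[i]
                if occ > 0:
                    x, y, z = site.centre
                    atoms.append((x, y, z, self.ligand_weight * occ, self.ligand_sigma))
        return atoms


@dataclass
class GroundTruth:
    """Per-particle truth (angles, shifts, coordinates, CTF) plus movie drift."""

    particles: pd.DataFrame
    ctf: CTFParams | None = None
    drift: np.ndarray | None = None


def gaussian_peak(weight: float, sigma: float, voxel_size: float) -> float:
    """Peak grid value of a rendered Gaussian blob (weight / (2 pi s^2)^{3/2} v^3)."""
    return weight * (2.0 * np.pi * sigma**2) ** -1.5 * voxel_size**3


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[Phantom, VolumeMap]:
    """Construct the barrel phantom and render its density map.

    For C2, one half (rings at x > 0) is generated explicitly and the
    second half is its exact 180-degree rotation about z, so the atom list
    is invariant under the symmetry by construction.
    """
    if spec.box_size < 32:
        raise SizingError("box size must be at least 32 voxels")
    if spec.voxel_size <= 0:
        raise ValidationError("voxel size must be positive")
    if spec.symmetry.upper() not in ("C1", "C2"):
        raise ValidationError(f"unsupported symmetry {spec.symmetry!r}")
    if len(spec.ligand_occupancies) != len(spec.ligand_subunits):
        raise ValidationError("need one occupancy per ligand site")

    half_atoms: list[tuple] = []
    for ring_x, radius, weights, phase in (
        (spec.alpha_x, spec.alpha_radius, spec.alpha_weights, 0.0),
        (spec.beta_x, spec.beta_radius, spec.beta_weights, spec.beta_phase_deg),
    ):
        for j in range(spec.n_subunits):
            phi = np.deg2rad(phase + 360.0 * j / spec.n_subunits)
            w = weights[j % len(weights)]
            half_atoms.append(
                (ring_x, radius * np.cos(phi), radius * np.sin(phi), w, spec.sigma)
            )

    half_sites: list[LigandSite] = []
    for name, j, occ in zip(spec.ligand_names, spec.ligand_subunits, spec.ligand_occupancies):
        phi = np.deg2rad(spec.beta_phase_deg + 360.0 * j / spec.n_subunits)
        r = spec.beta_radius - spec.ligand_radial_inset
        x = spec.beta_x - spec.ligand_axial_inset
        half_sites.append(
            LigandSite(f"{name}_a", (x, r * np.cos(phi), r * np.sin(phi)), occ)
        )

    atoms = list(half_atoms)
    sites = list(half_sites)
    if spec.symmetry.upper() == "C2":
        for (x, y, z, w, s) in half_atoms:
            atoms.append((-x, -y, z, w, s))
        for site in half_sites:
            x, y, z = site.centre
            sites.append(
                LigandSite(site.site_id[:-2] + "_b", (-x, -y, z), site.occupancy)
            )

    half_extent = (spec.box_size // 2 - 1) * spec.voxel_size
    support = 3.0 * max(spec.sigma, spec.ligand_sigma)
    for (x, y, z, _, _) in atoms:
        if max(abs(x), abs(y), abs(z)) + support > half_extent:
            raise SizingError(
                "box too small to contain phantom at the requested voxel size"
            )

    phantom = Phantom(
        atoms=atoms,
        symmetry=spec.symmetry.upper(),
        ligand_sites=sites,
        seed=spec.seed,
        ligand_sigma=spec.ligand_sigma,
        ligand_weight=spec.ligand_weight,
    )
    volume = render_model_density(
        phantom.all_atoms(include_ligands=True), spec.box_size, spec.voxel_size
    )
    return phantom, volume


def render_model_density(atoms, box_size: int, voxel_size: float) -> VolumeMap:
    """Render pseudo-atoms as a sum of isotropic Gaussians on a cubic grid.

    Each atom contributes ``w * (2 pi s^2)^{-3/2} exp(-r^2 / 2 s^2) * v^3``
    so its plain grid sum approximates its weight.  Gaussians are evaluated
    on a local window of +-4.5 sigma (truncation error < 1e-4 of the weight).
    """
    if voxel_size <= 0:
        raise ValidationError("voxel size must be positive")
    n = int(box_size)
    c = n // 2
    data = np.zeros((n, n, n), dtype=np.float64)
    for idx, (x, y, z, w, sigma) in enumerate(atoms):
        if w <= 0:
            raise ValidationError(f"atom {idx}: weight must be positive")
        if sigma <= 0:
            raise ValidationError(f"atom {idx}: sigma must be positive")
        # fractional voxel position of the centre
        pos = np.array([z, y, x]) / voxel_size + c        # index order (z, y, x)
        if np.any(pos < 0) or np.any(pos > n - 1):
            raise ValidationError(f"atom {idx} lies outside the grid")
        r_vox = 4.5 * sigma / voxel_size
        lo = np.maximum(np.floor(pos - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(pos + r_vox).astype(int) + 1, n)
        zz = (np.arange(lo[0], hi[0]) - pos[0]) * voxel_size
        yy = (np.arange(lo[1], hi[1]) - pos[1]) * voxel_size
        xx = (np.arange(lo[2], hi[2]) - pos[2]) * voxel_size
        r2 = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        )
        amp = w * (2.0 * np.pi * sigma**2) ** -1.5 * voxel_size**3
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(-r2 / (2.0 * sigma**2))
    return VolumeMap(data, float(voxel_size))


# ---------------------------------------------------------------------------
# projection


def rot180_z(arr: np.ndarray) -> np.ndarray:
    """Exact 180-degree rotation about z through the centre voxel N//2.

    Works on images (y, x) and volumes (z, y, x); pure index permutation,
    no interpolation.
    """
    axes = (0, 1) if arr.ndim == 2 else (1, 2)
    n = arr.shape[axes[0]]
    shift = 2 * (n // 2) - n + 1
    return np.roll(np.flip(arr, axis=axes), shift, axis=axes)


def simulate_projection(
    volume: VolumeMap,
    euler: tuple[float, float, float],
    shift_px: tuple[float, float] = (0.0, 0.0),
    order: int = 3,
) -> np.ndarray:
    """Forward projection: rotate the volume by ZYZ Euler angles, integrate
    along z, then translate by ``shift_px = (sx, sy)``.

    The rotated volume samples ``v(R u)``; projection is the plain sum over
    the z axis (line integral in voxel units).
    """
    if not volume.is_cubic:
        raise SizingError("projection requires a cubic volume")
    if not np.all(np.isfinite(euler)):
        raise ValidationError("Euler angles must be finite")
    r = euler_to_matrix(*euler)
    rotated = _rotate_volume(volume.data, r, order=order)
    proj = rotated.sum(axis=0)
    if shift_px != (0.0, 0.0):
        proj = fourier_shift_image(proj, shift_px)
    return proj


def _rotate_volume(data: np.ndarray, r: np.ndarray, order: int = 3) -> np.ndarray:
    """Sample ``v(R u)`` on the same grid (centre at N//2, index order z,y,x)."""
    n = data.shape[0]
    c = np.array([n // 2, n // 2, n // 2], dtype=float)
    m = r[::-1, ::-1]              # (x,y,z) matrix re-expressed in (z,y,x) index order
    offset = c - m @ c
    return ndimage.affine_transform(
        data, m, offset=offset, order=order, mode="constant", cval=0.0, prefilter=order > 1
    )


def fourier_shift_image(image: np.ndarray, shift_px: tuple[float, float]) -> np.ndarray:
    """Translate an image by (sx, sy) pixels via Fourier phase ramps."""
    sx, sy = shift_px
    f = np.fft.fft2(image)
    f = ndimage.fourier_shift(f, shift=(sy, sx))
    return np.fft.ifft2(f).real


# ---------------------------------------------------------------------------
# particle stacks


def _draw_orientation(rng: np.random.Generator) -> tuple[float, float, float]:
    rot = rng.uniform(0.0, 360.0)
    psi = rng.uniform(0.0, 360.0)
    tilt = np.rad2deg(np.arccos(rng.uniform(-1.0, 1.0)))
    return rot, tilt, psi


def _draw_ctf(
    rng: np.random.Generator, defocus_range_um: tuple[float, float], astig_max_um: float
) -> CTFParams:
    lo, hi = defocus_range_um
    a = rng.uniform(0.0, min(astig_max_um, hi - lo)) if hi > lo else 0.0
    dv = rng.uniform(lo, hi - a) if hi - a > lo else lo
    return CTFParams(
        defocus_u_um=dv + a,
        defocus_v_um=dv,
        astig_angle_deg=rng.uniform(0.0, 180.0),
    )


def simulate_particle_stack(
    volume: VolumeMap,
    n: int,
    acquisition: AcquisitionParams,
    defocus_range_um: tuple[float, float] = (1.7, 3.0),
    snr: float | None = None,
    seed: int = 0,
    apply_ctf: bool = True,
    astig_max_um: float = 0.15,
    do_phase_flip: bool = False,
    shift_max_px: float = 0.0,
    angles=None,
    order: int = 3,
) -> tuple[ParticleSet, GroundTruth]:
    """Simulate boxed particles at random orientations with per-particle CTF.

    ``snr`` is clean-signal variance over noise variance (None = noiseless).
    ``do_phase_flip=True`` delivers flip-corrected particles (transfer |CTF|)
    with the metadata flag set, mimicking a stack that went through CTF
    phase correction.  Truth angles/shifts/CTF are returned separately.
    """
    from .ctf import ctf_2d

    if n < 1:
        raise ValidationError("need at least one particle")
    if defocus_range_um[0] > defocus_range_um[1]:
        raise ValidationError("empty defocus range")
    rng = np.random.default_rng(seed)
    box = volume.shape[0]
    images = np.empty((n, box, box))
    meta = empty_metadata(n)
    truth_rows = []
    for i in range(n):
        euler = tuple(angles[i]) if angles is not None else _draw_orientation(rng)
        shift = (
            (rng.uniform(-shift_max_px, shift_max_px), rng.uniform(-shift_max_px, shift_max_px))
            if shift_max_px > 0
            else (0.0, 0.0)
        )
        img = simulate_projection(volume, euler, shift, order=order)
        params = _draw_ctf(rng, defocus_range_um, astig_max_um)
        if apply_ctf:
            c2d = ctf_2d(params, acquisition, img.shape, volume.voxel_size)
            transfer = np.abs(c2d) if do_phase_flip else c2d
            img = np.fft.ifft2(np.fft.fft2(img) * transfer).real
        if snr is not None:
            sig_var = img.var()
            img = img + rng.normal(0.0, np.sqrt(sig_var / snr), img.shape)
        images[i] = img
        meta.loc[i, ["defocus_u_um", "defocus_v_um", "astig_angle_deg"]] = (
            params.defocus_u_um, params.defocus_v_um, params.astig_angle_deg,
        )
        meta.loc[i, "phase_flipped"] = bool(do_phase_flip and apply_ctf)
        truth_rows.append(
            {
                "particle_id": i,
                "rot": euler[0], "tilt": euler[1], "psi": euler[2],
                "shift_x": shift[0], "shift_y": shift[1],
                "defocus_u_um": params.defocus_u_um,
                "defocus_v_um": params.defocus_v_um,
                "astig_angle_deg": params.astig_angle_deg,
            }
        )
    particles = ParticleSet(images, volume.voxel_size, meta)
    return particles, GroundTruth(particles=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# micrographs and movies


def simulate_micrograph(
    volume: VolumeMap,
    n_particles: int,
    shape: tuple[int, int] = (768, 768),
    acquisition: AcquisitionParams = AcquisitionParams(),
    ctf: CTFParams | None = None,
    snr: float | None = None,
    seed: int = 0,
    min_separation_px: float | None = None,
    order: int = 3,
) -> tuple[np.ndarray, GroundTruth]:
    """Scatter randomly oriented projections over a field, then apply an
    optional micrograph-level CTF and additive Gaussian noise.

    The noise variance is set from the clean micrograph's variance over the
    whole field and the requested SNR.  Raises a placement error when the
    particle count cannot be placed at the requested separation.
    """
    rng = np.random.default_rng(seed)
    box = volume.shape[0]
    h, w = shape
    if box > min(h, w):
        raise SizingError("particle box larger than micrograph")
    sep = min_separation_px if min_separation_px is not None else 0.75 * box
    margin = box // 2
    coords: list[tuple[int, int]] = []
    tries = 0
    while len(coords) < n_particles:
        tries += 1
        if tries > 2000 * n_particles:
            raise ValidationError(
                f"cannot place {n_particles} particles at separation {sep} in {shape}"
            )
        x = int(rng.integers(margin, w - margin))
        y = int(rng.integers(margin, h - margin))
        if all((x - x0) ** 2 + (y - y0) ** 2 >= sep**2 for x0, y0 in coords):
            coords.append((x, y))

    clean = np.zeros(shape)
    rows = []
    for i, (x, y) in enumerate(coords):
        euler = _draw_orientation(rng)
        proj = simulate_projection(volume, euler, order=order)
        b0 = box // 2
        clean[y - b0 : y - b0 + box, x - b0 : x - b0 + box] += proj
        rows.append({"particle_id": i, "coord_x": x, "coord_y": y,
                     "rot": euler[0], "tilt": euler[1], "psi": euler[2]})

    if ctf is not None:
        from .ctf import ctf_2d

        c2d = ctf_2d(ctf, acquisition, shape, acquisition.pixel_size)
        clean = np.fft.ifft2(np.fft.fft2(clean) * c2d).real
    micrograph = clean
    if snr is not None:
        sig_var = clean.var()
        micrograph = clean + rng.normal(0.0, np.sqrt(sig_var / snr), shape)
    return micrograph, GroundTruth(particles=pd.DataFrame(rows), ctf=ctf)


def _drift_trajectory(
    n_frames: int, drift, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative per-frame drift (px).  ``drift`` may be None, an explicit
    (n_frames, 2) cumulative trajectory, or {'early_px': a, 'late_px': b}
    giving step magnitudes for frames 1-3 vs later (random directions)."""
    if drift is None:
        return np.zeros((n_frames, 2))
    if isinstance(drift, dict):
        traj = np.zeros((n_frames, 2))
        for f in range(1, n_frames):
            mag = drift.get("early_px", 0.0) if f <= 2 else drift.get("late_px", 0.0)
            ang = rng.uniform(0.0, 2 * np.pi)
            traj[f] = traj[f - 1] + mag * np.array([np.cos(ang), np.sin(ang)])
        return traj
    traj = np.asarray(drift, dtype=float)
    if traj.shape != (n_frames, 2):
        raise ValidationError(f"drift trajectory must be ({n_frames}, 2)")
    return traj


def simulate_movie(
    volume: VolumeMap,
    n_particles: int,
    acquisition: AcquisitionParams = AcquisitionParams(),
    ctf: CTFParams | None = None,
    noise_level: float = 0.0,
    drift=None,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    doses=None,
) -> tuple[MovieStack, GroundTruth]:
    """Dose-fractionated movie of a simulated field of particles.

    Each frame carries signal proportional to its dose (``dose_f / dose_per_frame``
    times the nominal clean field) and white Gaussian noise whose variance is
    proportional to its dose (``noise_level`` is the per-frame noise s.d. at
    nominal dose) — the standard Gaussian stand-in for shot noise.  Drift is
    applied as a cumulative whole-field translation.  ``doses`` overrides the
    uniform per-frame dose list from the acquisition parameters.
    """
    rng = np.random.default_rng(seed)
    clean, truth = simulate_micrograph(
        volume, n_particles, shape, acquisition, ctf=ctf, snr=None,
        seed=int(rng.integers(0, 2**31)),
    )
    nf = acquisition.n_frames
    dose_list = np.asarray(
        doses if doses is not None else [acquisition.dose_per_frame] * nf, dtype=float
    )
    if len(dose_list) != nf:
        raise ValidationError("per-frame dose list must match frame count")
    nominal = acquisition.dose_per_frame
    traj = _drift_trajectory(nf, drift, rng)
    frames = np.empty((nf,) + shape)
    for f in range(nf):
        sig = clean if np.allclose(traj[f], 0.0) else fourier_shift_image(clean, tuple(traj[f]))
        frames[f] = sig * (dose_list[f] / nominal)
        if noise_level > 0:
            sd = noise_level * np.sqrt(dose_list[f] / nominal)
            frames[f] = frames[f] + rng.normal(0.0, sd, shape)
    ledger = DoseLedger(tuple(dose_list), acquisition.frame_interval_s)
    movie = MovieStack(frames, ledger, acquisition.pixel_size)
    truth.drift = traj
    return movie, truth


def simulate_thon_micrograph(
    shape: tuple[int, int],
    acquisition: AcquisitionParams,
    ctf: CTFParams,
    snr: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """CTF-modulated amorphous-specimen image for Thon-ring work.

    White Gaussian specimen noise (a stand-in for the amorphous ice/carbon
    layer) filtered by the CTF, unit variance, plus additive white noise of
    variance 1/snr.
    """
    from .ctf import ctf_2d

    rng = np.random.default_rng(seed)
    specimen = rng.normal(0.0, 1.0, shape)
    c2d = ctf_2d(ctf, acquisition, shape, acquisition.pixel_size)
    signal = np.fft.ifft2(np.fft.fft2(specimen) * c2d).real
    signal /= signal.std()
    return signal + rng.normal(0.0, np.sqrt(1.0 / snr), shape)
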