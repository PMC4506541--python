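"""Active-site ligand-density scoring and occupancy-proxy ranking.

The visibility of extra density at a designated active site is made
quantitative with a z-score: mean density inside a spherical site mask
compared against the mean and spread of a surrounding background shell,

    z = (mean_mask - mean_shell) / sd_shell.

The statistic is invariant under any global affine rescaling of the map
(rho -> a rho + b with a > 0), so maps on different grey scales are
directly comparable; its expectation increases with the occupancy of a
ligand blob placed at the site.  Ranking sites by z is the synthetic
analogue of comparing inhibitor-density visibility across active sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PicoemError, ValidationError, VolumeMap

__all__ = [
    "SiteScore",
    "GeometryError",
    "site_density_score",
    "rank_sites",
    "DEFAULT_MASK_RADIUS_A",
    "DEFAULT_SHELL_RADII_A",
]

# standard site geometry for the synthetic phantom's ligand blobs: a compact
# core mask and a background shell that stays clear of the nearest subunit
DEFAULT_MASK_RADIUS_A = 4.0
DEFAULT_SHELL_RADII_A = (7.0, 14.0)


class GeometryError(PicoemError):
    """Mask/shell geometry invalid for this map."""


@dataclass
class SiteScore:
    site_id: str
    z_score: float
    mean_in_mask: float
    background_mean: float
    background_sd: float
    mask_voxels: int
    shell_voxels: int


def _radius_grid(volume: VolumeMap, centre_xyz_A) -> np.ndarray:
    n = volume.shape[0]
    c = n // 2
    coords = (np.arange(n) - c) * volume.voxel_size
    x0, y0, z0 = centre_xyz_A
    dz = coords[:, None, None] - z0
    dy = coords[None, :, None] - y0
    dx = coords[None, None, :] - x0
    return np.sqrt(dz**2 + dy**2 + dx**2)


def site_density_score(
    volume: VolumeMap,
    centre_xyz_A,
    mask_radius_A: float,
    shell_radii_A: tuple[float, float],
    site_id: str = "site",
) -> SiteScore:
    """Z-score of the density inside a spherical mask at a site centre
    against a disjoint spherical background shell around it.

    ``shell_radii_A = (inner, outer)`` must satisfy
    ``inner >= mask_radius`` (disjoint) and ``outer > inner``; everything
    must fit inside the grid.  A zero-variance background (e.g. an all-zero
    map) is flagged as degenerate geometry rather than returning inf.
    """
    inner, outer = shell_radii_A
    if mask_radius_A <= 0:
        raise GeometryError("mask radius must be positive")
    if inner < mask_radius_A:
        raise GeometryError("background shell overlaps the site mask")
    if outer <= inner:
        raise GeometryError("background shell is empty")
    n = volume.shape[0]
    half_extent = (n // 2 - 1) * volume.voxel_size
    if max(abs(c) for c in centre_xyz_A) + outer > half_extent + volume.voxel_size:
        raise GeometryError("site mask/shell extends outside the grid")
    r = _radius_grid(volume, centre_xyz_A)
    mask = r <= mask_radius_A
    shell = (r >= inner) & (r < outer)
    if mask.sum() == 0 or shell.sum() == 0:
        raise GeometryError("mask or shell contains no voxels at this voxel size")
    inside = volume.data[mask]
    bg = volume.data[shell]
    sd = float(bg.std(ddof=1))
    if sd == 0.0:
        raise GeometryError("degenerate background: zero standard deviation")
    z = (float(inside.mean()) - float(bg.mean())) / sd
    return SiteScore(
        site_id=site_id,
        z_score=float(z),
        mean_in_mask=float(inside.mean()),
        background_mean=float(bg.mean()),
        background_sd=sd,
        mask_voxels=int(mask.sum()),
        shell_voxels=int(shell.sum()),
    )


def rank_sites(volume: VolumeMap, sites) -> list[SiteScore]:
    """Score every site and return the full list sorted by descending
    z-score (ties broken by site id).

    ``sites`` is an iterable of dicts with keys ``site_id``, ``centre``
    (x, y, z in A), ``mask_radius`` and optional ``shell_radii``.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValidationError("ranking needs at least two sites")
    ids = [s["site_id"] for s in sites]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate site ids")
    scores = []
    for s in sites:
        shell = s.get("shell_radii", DEFAULT_SHELL_RADII_A)
        scores.append(
            site_density_score(
                volume, s["centre"], s["mask_radius"], shell, site_id=s["site_id"]
            )
        )
    return sorted(scores, key=lambda sc: (-sc.z_score, sc.site_id))


def scores_to_frame(scores) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])
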