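"""Boxed particle stacks with per-particle metadata.

A ParticleSet pairs an ``(n, box, box)`` image array with a pandas
DataFrame carrying one row per particle: CTF parameters, assigned Euler
angles (ZYZ, degrees), shifts (px), alignment score and refinement round.
Unassigned orientation fields are NaN until an aligner fills them in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CTFParams, ValidationError

ORIENTATION_COLUMNS = ["rot", "tilt", "psi", "shift_x", "shift_y", "score", "round"]

META_COLUMNS = [
    "particle_id", "micrograph_id", "coord_x", "coord_y",
    "defocus_u_um", "defocus_v_um", "astig_angle_deg", "phase_flipped",
] + ORIENTATION_COLUMNS


@dataclass
class ParticleSet:
    images: np.ndarray
    pixel_size: float
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValidationError("particle images must be (n, box, box)")
        if self.metadata is None:
            self.metadata = empty_metadata(len(self.images))
        if len(self.metadata) != len(self.images):
            raise ValidationError("metadata rows must match particle count")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box_size(self) -> int:
        return self.images.shape[1]

    def ctf_params(self, i: int) -> CTFParams:
        row = self.metadata.iloc[i]
        return CTFParams(
            defocus_u_um=float(row["defocus_u_um"]),
            defocus_v_um=float(row["defocus_v_um"]),
            astig_angle_deg=float(row["astig_angle_deg"]),
            phase_flipped=bool(row["phase_flipped"]),
        )

    def has_orientations(self) -> bool:
        return bool(self.metadata[["rot", "tilt", "psi"]].notna().all().all())

    def subset(self, indices) -> "ParticleSet":
        idx = np.asarray(indices)
        return ParticleSet(
            self.images[idx],
            self.pixel_size,
            self.metadata.iloc[idx].reset_index(drop=True),
        )


def empty_metadata(n: int) -> pd.DataFrame:
    df = pd.DataFrame({"particle_id": np.arange(n)})
    df["micrograph_id"] = 0
    df["coord_x"] = np.nan
    df["coord_y"] = np.nan
    df["defocus_u_um"] = np.nan
    df["defocus_v_um"] = np.nan
    df["astig_angle_deg"] = 0.0
    df["phase_flipped"] = False
    for c in ORIENTATION_COLUMNS:
        df[c] = np.nan
    return df
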