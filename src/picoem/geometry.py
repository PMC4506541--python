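"""Rotations, Euler conventions, angular grids and angular distances.

Euler convention: ZYZ intrinsic ``(rot, tilt, psi)`` in degrees,
``R = Rz(rot) @ Ry(tilt) @ Rz(psi)``.  A projection at these angles
samples the volume at ``R @ u`` (u in centre-origin coordinates) and
integrates along z, so for a C2 volume (two-fold about z)
``(rot, tilt, psi)`` and ``(rot + 180, tilt, psi)`` give the same image.
"""

from __future__ import annotations

import numpy as np

from .core import ValidationError

__all__ = [
    "rotation_z",
    "rotation_y",
    "euler_to_matrix",
    "angular_distance_deg",
    "symmetry_matrices",
    "AngularGrid",
    "make_angular_grid",
]


def rotation_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic rotation matrix, angles in degrees."""
    return rotation_z(rot) @ rotation_y(tilt) @ rotation_z(psi)


def symmetry_matrices(group: str) -> list[np.ndarray]:
    """Rotation matrices of a point group; C2 axis is z by convention."""
    g = group.upper()
    if g == "C1":
        return [np.eye(3)]
    if g == "C2":
        return [np.eye(3), rotation_z(180.0)]
    raise ValidationError(f"unsupported symmetry group: {group!r}")


def angular_distance_deg(
    euler_a: tuple[float, float, float],
    euler_b: tuple[float, float, float],
    symmetry: str = "C1",
) -> float:
    """Geodesic angle (degrees) between two orientations, modulo symmetry.

    Distance is min over group elements g of the rotation angle of
    ``Ra @ (g Rb)^T``; symmetry elements act on the volume, i.e. multiply
    the orientation matrix on the left.
    """
    ra = euler_to_matrix(*euler_a)
    rb = euler_to_matrix(*euler_b)
    best = 180.0
    for g in symmetry_matrices(symmetry):
        m = ra @ (g @ rb).T
        cos = (np.trace(m) - 1.0) / 2.0
        ang = np.rad2deg(np.arccos(np.clip(cos, -1.0, 1.0)))
        best = min(best, float(ang))
    return best


class AngularGrid:
    """Quasi-uniform (rot, tilt) directions covering the asymmetric unit.

    Directions are built on tilt rings with the number of rot samples per
    ring proportional to sin(tilt), so the angular spacing is roughly the
    requested step everywhere on the sphere.  For C2 the rot range is
    restricted to [0, 180) (half sphere per asymmetric unit).
    """

    def __init__(self, step_deg: float, symmetry: str = "C1"):
        if step_deg <= 0:
            raise ValidationError("angular step must be positive")
        symmetry_matrices(symmetry)  # validate group tag
        self.step_deg = float(step_deg)
        self.symmetry = symmetry.upper()
        rot_span = 180.0 if self.symmetry == "C2" else 360.0
        directions: list[tuple[float, float]] = []
        n_tilt = max(1, int(round(180.0 / step_deg)))
        for i in range(n_tilt + 1):
            tilt = 180.0 * i / n_tilt
            if tilt in (0.0, 180.0):
                directions.append((0.0, tilt))
                continue
            circumference = rot_span * np.sin(np.deg2rad(tilt))
            n_rot = max(1, int(round(circumference / step_deg)))
            for j in range(n_rot):
                directions.append((rot_span * j / n_rot, tilt))
        # unique directions only
        seen: set[tuple[float, float]] = set()
        uniq = []
        for d in directions:
            if d not in seen:
                seen.add(d)
                uniq.append(d)
        self.directions = uniq

    def __len__(self) -> int:
        return len(self.directions)

    def as_array(self) -> np.ndarray:
        return np.array(self.directions, dtype=float)

    def neighbours(self, rot: float, tilt: float, radius_deg: float) -> np.ndarray:
        """Indices of grid directions within an angular radius of (rot, tilt).

        Distance is measured between projection *directions* (the rotated z
        axis), modulo the grid's symmetry group.
        """
        def direction_vec(r, t):
            rr, tt = np.deg2rad(r), np.deg2rad(t)
            return np.array([np.cos(rr) * np.sin(tt), np.sin(rr) * np.sin(tt), np.cos(tt)])

        target = direction_vec(rot, tilt)
        targets = [target]
        if self.symmetry == "C2":
            targets.append(rotation_z(180.0) @ target)
        arr = self.as_array()
        vecs = np.stack([direction_vec(r, t) for r, t in arr])
        cos_r = np.cos(np.deg2rad(radius_deg))
        keep = np.zeros(len(arr), dtype=bool)
        for t in targets:
            keep |= vecs @ t >= cos_r - 1e-12
        return np.nonzero(keep)[0]


def make_angular_grid(step_deg: float, symmetry: str = "C1") -> AngularGrid:
    return AngularGrid(step_deg, symmetry)
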