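"""Automatic particle picking, manual curation bookkeeping, and extraction.

The picker is a matched filter: normalized cross-correlation against a
template when one is given, otherwise a Laplacian-of-Gaussian blob
response at the configured particle diameter.  Candidate maxima above the
score threshold are pruned greedily so no two picks are closer than the
minimum separation (higher score wins; exact ties go to the lower (y, x)).

Curation never deletes rows: removals are flagged so provenance survives,
manual additions are appended with their own provenance tag.

Coordinates are 0-based pixel positions, origin at the top-left of the
stored array (row y, column x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template

from .core import CTFParams, SizingError, ValidationError
from .particles import ParticleSet, empty_metadata

__all__ = ["PickTable", "autopick", "curate", "extract"]


@dataclass
class PickTable:
    """Per-pick rows: (micrograph_id, x, y, score, provenance, removed)."""

    table: pd.DataFrame
    micrograph_shape: tuple[int, int]

    def __post_init__(self) -> None:
        required = {"pick_id", "micrograph_id", "x", "y", "score", "provenance", "removed"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"pick table missing columns: {sorted(missing)}")
        h, w = self.micrograph_shape
        if ((self.table.x < 0) | (self.table.x >= w) | (self.table.y < 0) | (self.table.y >= h)).any():
            raise ValidationError("pick coordinates outside micrograph bounds")
        if not np.isfinite(self.table.score).all():
            raise ValidationError("pick scores must be finite")

    def active(self) -> pd.DataFrame:
        return self.table[~self.table.removed]

    def __len__(self) -> int:
        return int((~self.table.removed).sum())


def autopick(
    micrograph: np.ndarray,
    template: np.ndarray | None = None,
    diameter_px: float | None = None,
    threshold: float = 0.3,
    min_separation_px: float | None = None,
    micrograph_id: int = 0,
    invert: bool = False,
) -> PickTable:
    """Pick particles as pruned local maxima of a matched-filter response.

    Give either ``template`` (normalized cross-correlation) or
    ``diameter_px`` (Laplacian-of-Gaussian at sigma = d / 2 sqrt(2)).
    ``invert=True`` picks dark particles (negated contrast).
    """
    mg = np.asarray(micrograph, dtype=np.float64)
    if invert:
        mg = -mg
    if template is not None:
        t = np.asarray(template, dtype=np.float64)
        if invert:
            t = -t
        if t.shape[0] > mg.shape[0] or t.shape[1] > mg.shape[1]:
            raise SizingError("template larger than micrograph")
        response = match_template(mg, t, pad_input=True, mode="mean")
        diameter = float(min(t.shape))
    elif diameter_px is not None:
        sigma = diameter_px / (2.0 * np.sqrt(2.0))
        response = -ndimage.gaussian_laplace(mg, sigma) * sigma**2
        response /= max(response.std(), 1e-30)
        diameter = float(diameter_px)
    else:
        raise ValidationError("give a template or a blob diameter")
    sep = min_separation_px if min_separation_px is not None else 0.8 * diameter
    if sep <= 0:
        raise ValidationError("min separation must be positive")

    # local maxima above threshold
    footprint = np.ones((3, 3), dtype=bool)
    is_max = response == ndimage.maximum_filter(response, footprint=footprint, mode="nearest")
    ys, xs = np.nonzero(is_max & (response > threshold))
    scores = response[ys, xs]
    order = np.lexsort((xs, ys, -scores))  # score desc, then (y, x) asc
    picked: list[tuple[int, int, float]] = []
    for i in order:
        x, y, s = int(xs[i]), int(ys[i]), float(scores[i])
        if all((x - x0) ** 2 + (y - y0) ** 2 >= sep**2 for x0, y0, _ in picked):
            picked.append((x, y, s))

    # recentre each pick on the smoothed-intensity centroid (mean shift):
    # the raw matched-filter maximum sits on whichever density lobe is
    # strongest, while the particle's insertion point is its centroid
    r = max(4, int(round(0.7 * diameter)))
    smooth = ndimage.gaussian_filter(mg, max(1.0, diameter / 16.0))
    h, w = smooth.shape
    refined = []
    for (x, y, s) in picked:
        fx, fy = float(x), float(y)
        for _ in range(2):
            xi, yi = int(round(fx)), int(round(fy))
            y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
            x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
            patch = np.clip(smooth[y0:y1, x0:x1] - smooth[y0:y1, x0:x1].min(), 0, None)
            if patch.sum() <= 0:
                break
            yy, xx = np.mgrid[y0:y1, x0:x1]
            fx = (patch * xx).sum() / patch.sum()
            fy = (patch * yy).sum() / patch.sum()
        refined.append((min(max(int(round(fx)), 0), w - 1),
                        min(max(int(round(fy)), 0), h - 1), s))
    picked = refined

    df = pd.DataFrame(
        {
            "pick_id": np.arange(len(picked)),
            "micrograph_id": micrograph_id,
            "x": [p[0] for p in picked],
            "y": [p[1] for p in picked],
            "score": [p[2] for p in picked],
            "provenance": "auto",
            "removed": False,
        }
    )
    return PickTable(df, mg.shape)


def curate(picks: PickTable, removals=(), additions=()) -> PickTable:
    """Flag false positives as removed and append manual additions.

    ``removals`` is a list of pick ids (must exist and not be already
    removed); ``additions`` a list of (x, y) coordinates within bounds.
    Active count afterwards = auto - removed + added.
    """
    df = picks.table.copy()
    for pid in removals:
        match = df.index[df.pick_id == pid]
        if len(match) == 0:
            raise ValidationError(f"unknown pick id {pid}")
        if df.loc[match[0], "removed"]:
            raise ValidationError(f"pick id {pid} already removed")
        df.loc[match[0], "removed"] = True
    h, w = picks.micrograph_shape
    next_id = int(df.pick_id.max()) + 1 if len(df) else 0
    new_rows = []
    for (x, y) in additions:
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(f"manual addition ({x}, {y}) outside micrograph")
        new_rows.append(
            {"pick_id": next_id, "micrograph_id": df.micrograph_id.iloc[0] if len(df) else 0,
             "x": x, "y": y, "score": np.nan, "provenance": "manual-add", "removed": False}
        )
        next_id += 1
    if new_rows:
        add_df = pd.DataFrame(new_rows)
        add_df["score"] = add_df["score"].astype(float)
        df = pd.concat([df, add_df], ignore_index=True)
    df["score"] = df["score"].fillna(0.0)
    return PickTable(df, picks.micrograph_shape)


def extract(
    micrograph: np.ndarray,
    picks: PickTable,
    box_size: int,
    edge_policy: str = "skip",
    pixel_size: float = 1.0,
    ctf: CTFParams | None = None,
) -> tuple[ParticleSet, list[int]]:
    """Extract active picks into boxed particles centred on each coordinate.

    The box spans ``[c - box//2, c + box//2)`` on each axis.  With
    ``edge_policy='skip'`` out-of-bounds picks are dropped and their pick
    ids reported; with ``'clamp-pad'`` boxes are padded with the micrograph
    mean.  Boxes inherit the micrograph's CTF parameters when given.
    """
    if box_size % 2 != 0:
        raise ValidationError("box size must be even")
    if edge_policy not in ("skip", "clamp-pad"):
        raise ValidationError(f"unknown edge policy {edge_policy!r}")
    mg = np.asarray(micrograph, dtype=np.float64)
    h, w = mg.shape
    if box_size > min(h, w):
        raise SizingError("box size exceeds micrograph")
    b0 = box_size // 2
    fill = float(mg.mean())
    boxes, kept_rows, skipped = [], [], []
    for _, row in picks.active().iterrows():
        x, y = int(round(row.x)), int(round(row.y))
        y_lo, y_hi, x_lo, x_hi = y - b0, y - b0 + box_size, x - b0, x - b0 + box_size
        if y_lo < 0 or x_lo < 0 or y_hi > h or x_hi > w:
            if edge_policy == "skip":
                skipped.append(int(row.pick_id))
                continue
            box = np.full((box_size, box_size), fill)
            sy, sx = slice(max(y_lo, 0), min(y_hi, h)), slice(max(x_lo, 0), min(x_hi, w))
            box[sy.start - y_lo : sy.stop - y_lo, sx.start - x_lo : sx.stop - x_lo] = mg[sy, sx]
        else:
            box = mg[y_lo:y_hi, x_lo:x_hi].copy()
        boxes.append(box)
        kept_rows.append(row)

    n = len(boxes)
    meta = empty_metadata(n)
    for i, row in enumerate(kept_rows):
        meta.loc[i, "micrograph_id"] = row.micrograph_id
        meta.loc[i, "coord_x"] = row.x
        meta.loc[i, "coord_y"] = row.y
        if ctf is not None:
            meta.loc[i, ["defocus_u_um", "defocus_v_um", "astig_angle_deg"]] = (
                ctf.defocus_u_um, ctf.defocus_v_um, ctf.astig_angle_deg,
            )
            meta.loc[i, "phase_flipped"] = ctf.phase_flipped
    images = np.stack(boxes) if n else np.zeros((0, box_size, box_size))
    return ParticleSet(images, pixel_size, meta), skipped
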