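"""Dose accounting, frame-window selection, frame summation and drift measurement.

Frame indices are 1-based in every user-facing interface ("frames 3-10");
internal array storage is 0-based.  With the default acquisition protocol
(17 frames of 2.8 e/A^2), skipping the initial 5.6 e/A^2 and capping the
accumulated dose at 28 e/A^2 selects frames 3-10, i.e. 8 frames acquired
within 8 x 0.056 s = 0.448 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .core import PicoemError, ValidationError

__all__ = [
    "DoseLedger",
    "MovieStack",
    "EmptyWindowError",
    "accumulate_dose",
    "select_frame_window",
    "sum_frames",
    "measure_frame_drift",
]


class EmptyWindowError(PicoemError):
    """No frame satisfies the requested dose bounds."""


@dataclass(frozen=True)
class DoseLedger:
    """Per-frame doses (e/A^2) and frame timing."""

    doses: tuple
    frame_interval_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if any(d < 0 for d in self.doses):
            raise ValidationError("per-frame doses must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame interval must be positive")

    @classmethod
    def uniform(cls, n_frames: int, dose_per_frame: float, frame_interval_s: float) -> "DoseLedger":
        return cls((dose_per_frame,) * n_frames, frame_interval_s)

    @property
    def n_frames(self) -> int:
        return len(self.doses)

    def cumulative(self) -> np.ndarray:
        """Accumulated dose after each frame; index 0 is 'before frame 1' = 0."""
        return np.concatenate([[0.0], np.cumsum(self.doses)])


@dataclass
class MovieStack:
    """Dose-fractionated movie: (n_frames, H, W) array plus its dose ledger."""

    frames: np.ndarray
    ledger: DoseLedger
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError("movie frames must be a 3D (n, H, W) array")
        if self.frames.shape[0] != self.ledger.n_frames:
            raise ValidationError("frame count does not match dose ledger")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def accumulate_dose(ledger: DoseLedger, through_frame: int) -> float:
    """Accumulated dose (e/A^2) through a 1-based frame index (0 = none)."""
    if not (0 <= through_frame <= ledger.n_frames):
        raise ValidationError(
            f"frame index {through_frame} outside 0..{ledger.n_frames}"
        )
    return float(ledger.cumulative()[through_frame])


def select_frame_window(
    ledger: DoseLedger, skip_initial_dose: float, max_accumulated_dose: float
) -> tuple[int, int]:
    """Maximal contiguous frame window (1-based, inclusive) honouring dose bounds.

    The window starts at the first frame whose *preceding* accumulated dose
    is at least ``skip_initial_dose`` and ends at the last frame whose own
    accumulated dose does not exceed ``max_accumulated_dose``.
    """
    if skip_initial_dose >= max_accumulated_dose:
        raise ValidationError("skip dose must be below the accumulated-dose cap")
    cum = ledger.cumulative()
    start = None
    for f in range(1, ledger.n_frames + 1):
        if cum[f - 1] >= skip_initial_dose - 1e-12:
            start = f
            break
    end = None
    for f in range(ledger.n_frames, 0, -1):
        if cum[f] <= max_accumulated_dose + 1e-12:
            end = f
            break
    if start is None or end is None or start > end:
        raise EmptyWindowError(
            f"no frame window satisfies skip>={skip_initial_dose}, cap<={max_accumulated_dose}"
        )
    return start, end


def sum_frames(movie: MovieStack, window: tuple[int, int]):
    """Pixel-wise sum over a 1-based inclusive frame window.

    Returns ``(micrograph, info)`` where info carries the accumulated dose of
    the window and its acquisition time (frames x frame interval).
    """
    start, end = window
    if not (1 <= start <= end <= movie.n_frames):
        raise ValidationError(f"window {window} outside movie bounds 1..{movie.n_frames}")
    image = movie.frames[start - 1 : end].sum(axis=0)
    n = end - start + 1
    info = {
        "dose": float(sum(movie.ledger.doses[start - 1 : end])),
        "acquisition_time_s": n * movie.ledger.frame_interval_s,
        "n_frames": n,
        "window": (start, end),
    }
    return image, info


def measure_frame_drift(movie: MovieStack, upsample: int = 20) -> pd.DataFrame:
    """Frame-to-frame drift by phase cross-correlation of consecutive frames.

    Returns one row per frame with step and cumulative displacement vectors
    (px) plus a confidence score (normalized correlation peak of the aligned
    pair); frame 1 is the reference with zero displacement.  Low confidence
    (< 0.1) flags pure-noise movies where the drift estimate is meaningless.
    """
    if movie.n_frames < 2:
        raise ValidationError("drift measurement needs at least 2 frames")
    if np.allclose(movie.frames, 0.0):
        raise ValidationError("all-zero movie frames: drift is undefined")
    rows = [{"frame": 1, "step_x": 0.0, "step_y": 0.0, "cum_x": 0.0, "cum_y": 0.0,
             "confidence": 1.0}]
    cum = np.zeros(2)
    for f in range(1, movie.n_frames):
        ref, cur = movie.frames[f - 1], movie.frames[f]
        shift, _, _ = phase_cross_correlation(ref, cur, upsample_factor=upsample,
                                              normalization=None)
        # shift = displacement (dy, dx) that moves `cur` back onto `ref`;
        # the frame drifted by the opposite of that.
        step = -np.array([shift[1], shift[0]])
        cum = cum + step
        conf = _alignment_confidence(ref, cur, step)
        rows.append({"frame": f + 1, "step_x": step[0], "step_y": step[1],
                     "cum_x": cum[0], "cum_y": cum[1], "confidence": conf})
    df = pd.DataFrame(rows)
    df.attrs["max_cumulative_px"] = float(np.hypot(df.cum_x, df.cum_y).max())
    df.attrs["min_confidence"] = float(df.confidence.min())
    df.attrs["low_confidence"] = bool(df.confidence.min() < 0.1)
    return df


def _alignment_confidence(ref: np.ndarray, cur: np.ndarray, step: np.ndarray) -> float:
    """Normalized correlation of the two frames after undoing the drift step."""
    from scipy import ndimage

    aligned = ndimage.shift(cur, (-step[1], -step[0]), order=1, mode="constant",
                            cval=float(cur.mean()))
    a = ref - ref.mean()
    b = aligned - aligned.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)
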