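"""Frame-subtraction locomotor activity scoring.

The behavior (DIC) channel of a recording is scored by subtracting
consecutive frames.  A pixel "changed" between two frames if the absolute
intensity difference strictly exceeds a threshold calibrated from an
empty-chamber recording (pooled mean + 5 SD of subtracted pixel values).
A time point is *locomotor active* if the changed-pixel count strictly
exceeds a cutoff (100 pixels for microfluidic-chamber imaging).  In the
artificial-dirt plate variant, a time point is *quiescent* when the
changed-pixel count falls strictly below 1% of the worm's body size in
pixels.

Frame-alignment convention: N frames yield N-1 subtracted images; the
state of the pair (i, i+1) is assigned to frame i+1, and frame 0 inherits
frame 1's state, so the activity trace has the same length as the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import ForegroundNotFoundError

#: changed-pixel count above which a frame is locomotor active (chamber mode)
DEFAULT_PIXEL_COUNT_CUTOFF = 100
#: quiescence rule for artificial-dirt plates: changed pixels < 1% of body size
BODY_SIZE_QUIESCENCE_FRACTION = 0.01


@dataclass(frozen=True)
class CalibrationResult:
    """Pixel-difference threshold from an empty-chamber stack.

    ``pixel_threshold = mean + 5 * sd`` of all pixel values pooled over all
    subtracted images, with the population (ddof=0) standard deviation.
    """

    pixel_threshold: float
    n_frames_used: int
    mean: float
    sd: float
    frame_shape: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ActivityTrace:
    """Per-frame changed-pixel counts and binary locomotor state."""

    fps: float
    changed_pixels: np.ndarray = field(repr=False)
    active: np.ndarray = field(repr=False)
    body_size: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.changed_pixels) != len(self.active):
            raise ValueError("changed_pixels and active must have equal length")

    def __len__(self) -> int:
        return len(self.active)

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_s": np.arange(n) / self.fps,
                "changed_pixels": np.asarray(self.changed_pixels),
                "active": np.asarray(self.active, dtype=bool),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_stack(stack: np.ndarray, min_frames: int = 2) -> np.ndarray:
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a (frames, y, x) stack, got shape {arr.shape}")
    if arr.shape[0] < min_frames:
        raise ValueError(f"stack must contain at least {min_frames} frames")
    return arr


def calibrate_threshold(empty_stack) -> CalibrationResult:
    """Calibrate the changed-pixel threshold from a worm-free stack.

    Absolute differences of all consecutive frame pairs are pooled into a
    single sample of pixel values; the threshold is mean + 5 standard
    deviations (population SD) of that pooled sample.
    """
    arr = _validate_stack(empty_stack)
    diffs = np.abs(np.diff(arr, axis=0))
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=0))
    return CalibrationResult(
        pixel_threshold=mean + 5.0 * sd,
        n_frames_used=arr.shape[0],
        mean=mean,
        sd=sd,
        frame_shape=tuple(arr.shape[1:]),
    )


def classify_activity(
    stack,
    calib: CalibrationResult,
    pixel_count_cutoff: int = DEFAULT_PIXEL_COUNT_CUTOFF,
    fps: float = 10.0,
) -> ActivityTrace:
    """Score each frame as locomotor active or not by frame subtraction.

    For each consecutive pair, pixels whose absolute difference strictly
    exceeds ``calib.pixel_threshold`` are counted; the frame is active iff
    that count strictly exceeds ``pixel_count_cutoff`` (both inequalities
    read literally from "exceeded").
    """
    arr = _validate_stack(stack)
    if calib.frame_shape is not None and tuple(arr.shape[1:]) != tuple(calib.frame_shape):
        raise ValueError(
            f"stack frame shape {arr.shape[1:]} does not match calibration "
            f"frame shape {calib.frame_shape}"
        )
    diffs = np.abs(np.diff(arr, axis=0))
    counts = (diffs > calib.pixel_threshold).sum(axis=(1, 2))
    active_pairs = counts > pixel_count_cutoff
    # frame 0 inherits the state of the first subtracted pair
    changed = np.concatenate(([counts[0]], counts))
    active = np.concatenate(([active_pairs[0]], active_pairs))
    return ActivityTrace(fps=fps, changed_pixels=changed, active=active)


def quiescence_by_body_size(activity: ActivityTrace, body_size: float) -> ActivityTrace:
    """Re-score activity with the artificial-dirt 1%-of-body-size rule.

    A frame is quiescent iff its changed-pixel count is strictly below
    1% of ``body_size``; the returned trace's ``active`` is the negation.
    """
    if body_size <= 0:
        raise ValueError("body_size must be positive")
    counts = np.asarray(activity.changed_pixels)
    quiescent = counts < BODY_SIZE_QUIESCENCE_FRACTION * body_size
    return replace(activity, active=~quiescent, body_size=float(body_size))


def estimate_body_size(stack) -> float:
    """Estimate the worm's body size in pixels from a behavior stack.

    Each frame is thresholded with Otsu's method and the foreground pixel
    count recorded; the body size is the median count over frames.  A
    recording with no compact bright object (near-constant frames, or a
    "foreground" covering more than 25% of the image, as happens when Otsu
    bisects pure noise) raises :class:`ForegroundNotFoundError`.
    """
    arr = _validate_stack(stack, min_frames=1)
    counts = []
    for frame in arr:
        if np.ptp(frame) == 0:
            continue
        thr = threshold_otsu(frame)
        counts.append(int(np.count_nonzero(frame > thr)))
    if not counts:
        raise ForegroundNotFoundError("all frames are constant; no worm visible")
    size = float(np.median(counts))
    n_pixels = arr.shape[1] * arr.shape[2]
    if size == 0 or size > 0.25 * n_pixels:
        raise ForegroundNotFoundError(
            "no compact foreground object detected (empty chamber?)"
        )
    return size
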