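"""Ratiometric Ca2+ trace normalization and motion-active classification.

GCaMP fluorescence is divided by a co-expressed RFP reference to cancel
focus and motion artifacts; activity is expressed as the fractional change
of the ratio, dR/R0 = (R - R0)/R0, where R = GCaMP/RFP per frame and R0 is
the mean of R over the whole recording session.  By this definition the
session mean of dR/R0 is identically zero, so a neuron is classified as
*motion-active* when its mean dR/R0 over motion-bout frames exceeds the
session mean by a margin in absolute dR/R0 units (0.20 by default; a
multiplicative reading of "by 20%" is degenerate because the session mean
is zero by construction).

Frames with missing fluorescence (tracking dropouts, stored as NaN) are
excluded from every mean rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bout_segmentation import MOTION, BoutSeries
from .errors import AnalysisError

#: motion-active margin, in absolute dR/R0 units
DEFAULT_MOTION_ACTIVE_MARGIN = 0.20


@dataclass(frozen=True)
class RatioTrace:
    """Per-frame GCaMP/RFP ratio and its fractional change for one neuron."""

    fps: float
    R: np.ndarray = field(repr=False)
    R0: float = 0.0
    dr_over_r0: np.ndarray = field(repr=False, default=None)
    neuron_id: Optional[str] = None
    n_dropped_frames: int = 0

    def __len__(self) -> int:
        return len(self.R)

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_s": np.arange(n) / self.fps,
                "R": self.R,
                "dr_over_r0": self.dr_over_r0,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class MotionActivityResult:
    """Outcome of the motion-active classification for one neuron."""

    is_motion_active: bool
    motion_mean: float
    session_mean: float
    margin: float
    neuron_id: Optional[str] = None


def compute_ratio_trace(
    gcamp: Sequence,
    rfp: Sequence,
    fps: float,
    neuron_id: Optional[str] = None,
) -> RatioTrace:
    """Compute R = GCaMP/RFP and dR/R0 = (R - R0)/R0 with R0 = mean(R).

    NaN in either channel marks a tracking dropout: the frame is excluded
    from R0 and carries NaN in the outputs.  Non-positive RFP on a
    non-dropout frame is a data error and the offending frames are named.
    """
    g = np.asarray(gcamp, dtype=np.float64)
    r = np.asarray(rfp, dtype=np.float64)
    if g.shape != r.shape or g.ndim != 1:
        raise ValueError("gcamp and rfp must be 1-D arrays of equal length")
    if g.size < 2:
        raise ValueError("need at least 2 frames")
    if fps <= 0:
        raise ValueError("fps must be positive")

    dropout = np.isnan(g) | np.isnan(r)
    bad = np.flatnonzero(~dropout & (r <= 0))
    if bad.size:
        shown = ", ".join(map(str, bad[:10]))
        more = "" if bad.size <= 10 else f" (+{bad.size - 10} more)"
        raise ValueError(f"non-positive RFP at frames: {shown}{more}")

    R = np.where(dropout, np.nan, g / np.where(dropout, 1.0, r))
    R0 = float(np.nanmean(R))
    dr = (R - R0) / R0
    return RatioTrace(
        fps=fps,
        R=R,
        R0=R0,
        dr_over_r0=dr,
        neuron_id=neuron_id,
        n_dropped_frames=int(dropout.sum()),
    )


def classify_motion_active(
    trace: RatioTrace,
    bouts: BoutSeries,
    margin: float = DEFAULT_MOTION_ACTIVE_MARGIN,
) -> MotionActivityResult:
    """Classify a neuron as motion-active by the 20% enrichment rule.

    The neuron is motion-active iff its mean dR/R0 over all motion-bout
    frames strictly exceeds the whole-session mean plus ``margin`` (both
    means computed over non-dropout frames).
    """
    if len(trace) != bouts.n_frames:
        raise ValueError(
            f"trace length {len(trace)} does not match bout series "
            f"({bouts.n_frames} frames)"
        )
    motion_mask = np.zeros(bouts.n_frames, dtype=bool)
    for b in bouts.of_kind(MOTION):
        motion_mask[b.start_frame : b.end_frame] = True
    if not motion_mask.any():
        raise AnalysisError("no motion bouts in the series")

    dr = np.asarray(trace.dr_over_r0)
    with np.errstate(invalid="ignore"):
        motion_mean = float(np.nanmean(dr[motion_mask]))
        session_mean = float(np.nanmean(dr))
    return MotionActivityResult(
        is_motion_active=bool(motion_mean > session_mean + margin),
        motion_mean=motion_mean,
        session_mean=session_mean,
        margin=margin,
        neuron_id=trace.neuron_id,
    )
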