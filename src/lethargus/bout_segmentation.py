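"""Sleep/motion bout segmentation of binary locomotor traces.

A recording is scored frame-by-frame as locomotor active or non-active
(see :mod:`lethargus.motion_detection`).  A *sleep bout* is a maximal run
of non-active frames lasting strictly longer than a minimum duration
(6 s for imaging and plate behavior, 5 s in the optogenetics protocol);
everything else — active runs together with quiescent runs too short to
qualify — is merged into *motion bouts*.  The resulting bouts tile the
recording exactly and strictly alternate in kind.

Conventions
-----------
* Intervals are half-open ``[start, end)``; frames are 0-based; frame ``i``
  covers ``[i/fps, (i+1)/fps)`` seconds.
* "Lasts longer than X s" is read strictly: a quiescent run of exactly
  6.000 s (60 frames at 10 fps) is *not* a sleep bout.
* The 12-s bout filter is likewise strict by default: a bout of exactly
  12 s is dropped (``keep_equal=True`` flips this boundary, which the
  source text leaves ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SLEEP = "sleep"
MOTION = "motion"

#: minimum sleep-bout duration, seconds (imaging / plate behavior)
DEFAULT_MIN_SLEEP_S = 6.0
#: bouts at or below this duration are excluded from Ca2+ analyses, seconds
DEFAULT_MIN_BOUT_S = 12.0


@dataclass(frozen=True)
class Bout:
    """A typed interval of a recording, in frames plus derived seconds."""

    kind: str
    start_frame: int
    end_frame: int  # exclusive
    fps: float
    at_edge: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (SLEEP, MOTION):
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if self.end_frame <= self.start_frame:
            raise ValueError("bout end must be after its start")

    @property
    def start(self) -> float:
        return self.start_frame / self.fps

    @property
    def end(self) -> float:
        return self.end_frame / self.fps

    @property
    def duration(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class BoutSeries:
    """An alternating sequence of sleep/motion bouts tiling a recording."""

    bouts: tuple
    fps: float
    n_frames: int
    min_sleep_duration: float = DEFAULT_MIN_SLEEP_S

    @property
    def total_duration(self) -> float:
        return self.n_frames / self.fps

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def of_kind(self, kind: str) -> list:
        return [b for b in self.bouts if b.kind == kind]

    def to_state(self) -> np.ndarray:
        """Reconstruct the per-frame binary trace (True = active/motion)."""
        state = np.zeros(self.n_frames, dtype=bool)
        for b in self.bouts:
            if b.kind == MOTION:
                state[b.start_frame : b.end_frame] = True
        return state

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [b.kind for b in self.bouts],
                "start_s": [b.start for b in self.bouts],
                "end_s": [b.end for b in self.bouts],
                "duration_s": [b.duration for b in self.bouts],
                "at_edge": [b.at_edge for b in self.bouts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class QuiescenceSeries:
    """Fraction of non-active frames in consecutive non-overlapping windows."""

    window: float  # seconds (nominal; trailing window may be shorter)
    fps: float
    window_starts: np.ndarray = field(repr=False)  # seconds
    fraction: np.ndarray = field(repr=False)
    n_frames: np.ndarray = field(repr=False)  # frames actually in each window

    def __len__(self) -> int:
        return len(self.fraction)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start_s": self.window_starts,
                "fraction": self.fraction,
                "n_frames": self.n_frames,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _runs(x: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean vector into (start, end, value) triples."""
    edges = np.flatnonzero(np.diff(x.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(x)]))
    return [(int(s), int(e), bool(x[s])) for s, e in zip(bounds[:-1], bounds[1:])]


def segment_bouts(
    active: Sequence,
    fps: float,
    min_sleep_duration: float = DEFAULT_MIN_SLEEP_S,
) -> BoutSeries:
    """Partition a binary activity trace into sleep and motion bouts.

    Maximal runs of non-active frames strictly longer than
    ``min_sleep_duration`` seconds become sleep bouts; every other frame —
    active runs and sub-threshold quiescent runs alike — is merged into
    motion bouts, so motion segments separated only by a short quiescent
    run coalesce.

    Parameters
    ----------
    active
        Per-frame boolean locomotor state, True = active.
    fps
        Frame rate in frames per second.
    min_sleep_duration
        Strict lower duration bound for sleep bouts, in seconds.

    Returns
    -------
    BoutSeries
        Bouts tiling ``[0, len(active)/fps)`` with strictly alternating kinds.
    """
    arr = np.asarray(active, dtype=bool)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("activity trace must be a non-empty 1-D array")
    if fps <= 0:
        raise ValueError("fps must be positive")

    # mark frames belonging to qualifying sleep runs, then RLE that mask
    sleep_mask = np.zeros(arr.size, dtype=bool)
    for s, e, val in _runs(arr):
        if not val and (e - s) / fps > min_sleep_duration:
            sleep_mask[s:e] = True

    n = arr.size
    bouts = []
    for s, e, is_sleep in _runs(sleep_mask):
        bouts.append(
            Bout(
                kind=SLEEP if is_sleep else MOTION,
                start_frame=s,
                end_frame=e,
                fps=fps,
                at_edge=(s == 0 or e == n),
            )
        )
    return BoutSeries(
        bouts=tuple(bouts),
        fps=fps,
        n_frames=n,
        min_sleep_duration=min_sleep_duration,
    )


def filter_bouts(
    series: BoutSeries,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    drop_edges: bool = True,
    keep_equal: bool = False,
) -> list:
    """Return bouts passing the short-bout and edge exclusions.

    Bouts with ``duration > min_duration`` (strict by default; with
    ``keep_equal`` a bout of exactly ``min_duration`` is retained) and,
    if ``drop_edges``, not touching the start or end of the recording.
    The input series is not modified.
    """
    kept = []
    for b in series:
        if drop_edges and b.at_edge:
            continue
        if b.duration > min_duration or (keep_equal and b.duration == min_duration):
            kept.append(b)
    return kept


def fraction_of_quiescence(
    active: Sequence, fps: float, window: float
) -> QuiescenceSeries:
    """Fraction of non-active frames in non-overlapping windows.

    Windows are anchored at t = 0; the trailing partial window, if any, is
    reported with its own (shorter) frame count.
    """
    arr = np.asarray(active, dtype=bool)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("activity trace must be a non-empty 1-D array")
    if fps <= 0:
        raise ValueError("fps must be positive")
    wf = int(round(window * fps))
    if wf < 1:
        raise ValueError("window must cover at least one frame")

    starts = np.arange(0, arr.size, wf)
    fractions = np.empty(starts.size)
    counts = np.empty(starts.size, dtype=int)
    for i, s in enumerate(starts):
        chunk = arr[s : s + wf]
        counts[i] = chunk.size
        fractions[i] = np.count_nonzero(~chunk) / chunk.size
    return QuiescenceSeries(
        window=window,
        fps=fps,
        window_starts=starts / fps,
        fraction=fractions,
        n_frames=counts,
    )


def detect_lethargus(
    q: QuiescenceSeries,
    enter_threshold: float = 0.05,
    exit_threshold: float = 0.05,
    min_span: float = 1200.0,
) -> Optional[tuple[float, float]]:
    """Delimit lethargus as a sustained span of elevated quiescence.

    The longest contiguous run of windows with ``fraction >= enter_threshold``
    is extended outward while ``fraction >= exit_threshold``; the extended
    span is returned as ``(start_s, end_s)`` if it covers at least
    ``min_span`` seconds, else ``None``.

    Thresholds default to 0.05/0.05 and a 20-min minimum span; all three are
    deliberately configurable because the lethargus criterion in the
    literature is a convention rather than a measurement.
    """
    for name, t in (("enter_threshold", enter_threshold), ("exit_threshold", exit_threshold)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {t}")
    if len(q) == 0:
        raise ValueError("empty quiescence series")

    frac = np.asarray(q.fraction)
    core = frac >= enter_threshold
    if not core.any():
        return None

    best: Optional[tuple[int, int]] = None  # window index span, inclusive
    for s, e, val in _runs(core):
        if not val:
            continue
        lo, hi = s, e - 1
        while lo > 0 and frac[lo - 1] >= exit_threshold:
            lo -= 1
        while hi + 1 < frac.size and frac[hi + 1] >= exit_threshold:
            hi += 1
        if best is None or (hi - lo) > (best[1] - best[0]):
            best = (lo, hi)

    lo, hi = best
    start_s = float(q.window_starts[lo])
    end_s = float(q.window_starts[hi] + q.n_frames[hi] / q.fps)
    if end_s - start_s >= min_span:
        return (start_s, end_s)
    return None


def bout_series_from_frame(
    df: pd.DataFrame, fps: float, min_sleep_duration: float = DEFAULT_MIN_SLEEP_S
) -> BoutSeries:
    """Rebuild a :class:`BoutSeries` from its CSV/DataFrame representation."""
    bouts = []
    for row in df.itertuples(index=False):
        bouts.append(
            Bout(
                kind=row.kind,
                start_frame=int(round(row.start_s * fps)),
                end_frame=int(round(row.end_s * fps)),
                fps=fps,
                at_edge=bool(row.at_edge),
            )
        )
    n_frames = bouts[-1].end_frame if bouts else 0
    return BoutSeries(
        bouts=tuple(bouts),
        fps=fps,
        n_frames=n_frames,
        min_sleep_duration=min_sleep_duration,
    )
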