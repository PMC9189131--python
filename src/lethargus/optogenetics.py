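"""Stimulation-aligned behavioral analysis for optogenetic experiments.

Blue light is delivered for 3 s at the onset of a motion bout during
lethargus; the questions are (i) how long the stimulated motion bout lasts
before the next sleep bout (latency to the MS transition) and (ii) how
locomotor activity evolves around the stimulus.  In this protocol sleep
bouts are quiescent runs lasting strictly more than 5 s (not the 6-s rule
used for imaging).  The per-event summary statistic is the mean locomotor
activity over the 5 s after stimulation onset, computed on the raw
(unsmoothed) trace; the 2.5-s centered moving average is applied only to
the displayed/averaged traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bout_segmentation import SLEEP, segment_bouts
from .errors import AnalysisError

#: strict lower bound on sleep-bout duration in the optogenetics protocol, s
DEFAULT_OPTO_MIN_SLEEP_S = 5.0
#: stimulus duration by protocol, s
DEFAULT_STIM_DURATION_S = 3.0


@dataclass(frozen=True)
class StimEvent:
    """One optogenetic stimulation trial with its aligned behavior."""

    trial_id: int
    animal_id: int
    group: str  # "treated" (ATR+) or "control" (ATR-)
    stim_onset_s: float
    fps: float
    stim_duration_s: float = DEFAULT_STIM_DURATION_S
    latency_s: float = math.nan  # time from stim onset to first sleep bout
    censored: bool = False
    locomotion: Optional[np.ndarray] = field(default=None, repr=False)
    active: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass(frozen=True)
class LatencyResult:
    latency_s: float
    censored: bool


@dataclass(frozen=True)
class StimLocomotionResult:
    """Group-averaged stimulation-aligned locomotion and per-event summaries."""

    time_s: np.ndarray = field(repr=False)
    group_mean: dict = field(repr=False)
    group_sem: dict = field(repr=False)
    summaries: pd.DataFrame = field(repr=False)  # trial, group, post_mean
    p_value: float = math.nan  # unpaired t test between the two groups
    summary_window: float = 5.0
    n_excluded: int = 0


def latency_to_sleep(
    active: Sequence,
    fps: float,
    stim_onset_s: float,
    min_sleep_duration: float = DEFAULT_OPTO_MIN_SLEEP_S,
) -> LatencyResult:
    """Latency from stimulation onset to the first qualifying sleep bout.

    The post-stimulation trace is re-segmented under the 5-s sleep rule;
    the latency is the time from the stimulation onset to the start of the
    first sleep bout.  If no quiescent run after the stimulus lasts
    strictly more than ``min_sleep_duration`` s before the recording ends,
    the latency is right-censored.
    """
    arr = np.asarray(active, dtype=bool)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("activity trace must be a non-empty 1-D array")
    stim_frame = int(round(stim_onset_s * fps))
    if not 0 <= stim_frame < arr.size:
        raise ValueError("stimulation onset lies outside the recording")
    post = arr[stim_frame:]
    series = segment_bouts(post, fps, min_sleep_duration=min_sleep_duration)
    for b in series:
        if b.kind == SLEEP:
            return LatencyResult(latency_s=b.start, censored=False)
    return LatencyResult(latency_s=math.nan, censored=True)


def _moving_average(x: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered moving average with truncated (not padded) edges."""
    if window_frames <= 1:
        return np.asarray(x, dtype=float)
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(window_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _odd_window_frames(seconds: float, fps: float) -> int:
    w = max(1, int(round(seconds * fps)))
    return w if w % 2 == 1 else w + 1


def stim_triggered_locomotion(
    events: Sequence[StimEvent],
    window_pre: float = 10.0,
    window_post: float = 20.0,
    smooth: float = 2.5,
    summary_window: float = 5.0,
) -> StimLocomotionResult:
    """Average locomotion around stimulation onset, per group.

    Each event's locomotion trace is aligned at its stimulation onset and
    cropped to ``[-window_pre, window_post)``; events whose trace does not
    cover the full window are excluded (count reported).  Cropped traces
    are smoothed with a centered ``smooth``-second moving average and
    averaged within group.  The per-event summary is the raw-trace mean
    over ``[0, summary_window)`` s after onset; with exactly two groups an
    unpaired t test on the summaries is reported.
    """
    events = list(events)
    if not events:
        raise AnalysisError("no stimulation events")
    fps = events[0].fps
    if any(e.fps != fps for e in events):
        raise ValueError("all events must share one frame rate")

    pre_f = int(round(window_pre * fps))
    post_f = int(round(window_post * fps))
    sum_f = int(round(summary_window * fps))
    smooth_f = _odd_window_frames(smooth, fps)

    aligned: dict[str, list[np.ndarray]] = {}
    rows = []
    n_excluded = 0
    for e in events:
        if e.locomotion is None:
            n_excluded += 1
            continue
        loco = np.asarray(e.locomotion, dtype=float)
        s = int(round(e.stim_onset_s * fps))
        if s - pre_f < 0 or s + post_f > loco.size or s + sum_f > loco.size:
            n_excluded += 1
            continue
        win = loco[s - pre_f : s + post_f]
        aligned.setdefault(e.group, []).append(_moving_average(win, smooth_f))
        rows.append(
            {
                "trial": e.trial_id,
                "animal": e.animal_id,
                "group": e.group,
                "post_mean": float(loco[s : s + sum_f].mean()),
            }
        )
    if not rows:
        raise AnalysisError("no events with complete windows")

    time_s = (np.arange(-pre_f, post_f)) / fps
    group_mean, group_sem = {}, {}
    for grp, traces in aligned.items():
        mat = np.vstack(traces)
        group_mean[grp] = mat.mean(axis=0)
        group_sem[grp] = (
            mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
            if mat.shape[0] >= 2
            else np.full(mat.shape[1], np.nan)
        )

    summaries = pd.DataFrame(rows)
    p_value = math.nan
    groups = sorted(summaries["group"].unique())
    if len(groups) == 2:
        a = summaries.loc[summaries["group"] == groups[0], "post_mean"]
        b = summaries.loc[summaries["group"] == groups[1], "post_mean"]
        if len(a) >= 2 and len(b) >= 2:
            if np.ptp(np.concatenate([a, b])) == 0:
                p_value = 1.0  # all summaries identical
            else:
                p_value = float(stats.ttest_ind(a, b).pvalue)

    return StimLocomotionResult(
        time_s=time_s,
        group_mean=group_mean,
        group_sem=group_sem,
        summaries=summaries,
        p_value=p_value,
        summary_window=summary_window,
        n_excluded=n_excluded,
    )


def compare_latencies(events: Sequence[StimEvent]) -> dict:
    """Treated-vs-control comparison of latencies to the MS transition.

    Censored trials are excluded (their counts are reported).  Returns the
    two group medians, a Mann-Whitney U p-value, and a two-sample
    Kolmogorov-Smirnov p-value (the distributional comparison).
    """
    by_group: dict[str, list[float]] = {}
    censored: dict[str, int] = {}
    for e in events:
        if e.censored or math.isnan(e.latency_s):
            censored[e.group] = censored.get(e.group, 0) + 1
        else:
            by_group.setdefault(e.group, []).append(e.latency_s)
    if len(by_group) != 2:
        raise AnalysisError("need exactly two groups with uncensored latencies")
    (g1, x1), (g2, x2) = sorted(by_group.items())
    return {
        "groups": (g1, g2),
        "n": (len(x1), len(x2)),
        "n_censored": (censored.get(g1, 0), censored.get(g2, 0)),
        "median_s": (float(np.median(x1)), float(np.median(x2))),
        "mannwhitney_p": float(stats.mannwhitneyu(x1, x2).pvalue),
        "ks_p": float(stats.ks_2samp(x1, x2).pvalue),
    }
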