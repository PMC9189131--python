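"""Bout-aligned analysis of Ca2+ and locomotor signals.

Operations here take one or more *sessions*, each a pair
``(values, series)`` of a per-frame signal (typically dR/R0 from
:mod:`lethargus.calcium_traces`, or changed-pixel counts) and the
session's :class:`~lethargus.bout_segmentation.BoutSeries`.  Bouts are
pooled across sessions after the standard exclusions (duration strictly
greater than 12 s; bouts touching a recording edge dropped).

* :func:`align_and_average` — traces aligned at bout start on the native
  frame grid; time points supported by 10 or fewer bouts are omitted.
* :func:`normalized_profile` — each bout's duration is rescaled to 1 and
  the trace resampled onto a fixed grid; the mean over the first and
  fourth quartile of normalized time is returned per bout for a paired
  comparison (rising signals give Q4 > Q1).
* :func:`transition_triggered` — mean signal over the 12 s before vs
  after sleep-to-motion (SM) or motion-to-sleep (MS) transitions.
* :func:`peak_latency_correlation` — per-motion-bout peak of the 1-s
  moving-averaged signal against the latency from bout start, with an
  ordinary least-squares fit and 95% confidence intervals.
* :func:`cumulative_locomotor` — running sum of locomotor activity
  within each motion bout with a straight-line R^2 diagnostic.

The normalized-time grid uses cell midpoints ``(j + 0.5)/G`` so the four
quartiles receive equal numbers of grid points and quartile means of a
linear signal are exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bout_segmentation import (
    DEFAULT_MIN_BOUT_S,
    MOTION,
    SLEEP,
    Bout,
    BoutSeries,
    filter_bouts,
)
from .errors import AnalysisError
from .motion_detection import ActivityTrace
from .optogenetics import _moving_average, _odd_window_frames

#: time points supported by this many bouts or fewer are omitted
DEFAULT_MIN_SAMPLES = 10
#: transition window, seconds before/after
DEFAULT_TRANSITION_WINDOW_S = 12.0
#: smoothing window for peak detection, seconds
DEFAULT_PEAK_SMOOTH_S = 1.0
DEFAULT_GRID_SIZE = 100


# ---------------------------------------------------------------------------
# session plumbing
# ---------------------------------------------------------------------------

def _as_sessions(sessions) -> list[tuple[np.ndarray, BoutSeries]]:
    if isinstance(sessions, tuple) and len(sessions) == 2 and isinstance(sessions[1], BoutSeries):
        sessions = [sessions]
    out = []
    for values, series in sessions:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size != series.n_frames:
            raise ValueError(
                f"signal length {arr.size} does not match series "
                f"({series.n_frames} frames)"
            )
        out.append((arr, series))
    if not out:
        raise AnalysisError("no sessions supplied")
    fps = out[0][1].fps
    if any(s.fps != fps for _, s in out):
        raise ValueError("all sessions must share one frame rate")
    return out


def extract_bout_segments(
    sessions,
    kind: str,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    drop_edges: bool = True,
) -> tuple[list[np.ndarray], list[Bout], float]:
    """Pool per-bout signal segments of one kind across sessions.

    Applies the standard bout exclusions and returns the segments, the
    corresponding bouts, and the common frame rate.
    """
    sess = _as_sessions(sessions)
    fps = sess[0][1].fps
    segments, bouts = [], []
    for values, series in sess:
        for b in filter_bouts(series, min_duration=min_duration, drop_edges=drop_edges):
            if b.kind == kind:
                segments.append(values[b.start_frame : b.end_frame])
                bouts.append(b)
    return segments, bouts, fps


# ---------------------------------------------------------------------------
# aligned average
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedAverage:
    """Mean +/- SEM of bout-aligned traces on the native frame grid."""

    kind: str
    time_s: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)
    sem: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    min_samples: int = DEFAULT_MIN_SAMPLES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.time_s, "mean": self.mean, "sem": self.sem, "n": self.n}
        )


def align_and_average(
    sessions,
    kind: str,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    drop_edges: bool = True,
) -> AlignedAverage:
    """Align bout traces at bout start and average per time point.

    Time points contributed to by ``min_samples`` or fewer bouts are
    omitted (strict "10 or less" rule).  SEM is defined where n >= 2.
    """
    segments, _, fps = extract_bout_segments(sessions, kind, min_duration, drop_edges)
    if not segments:
        raise AnalysisError(f"no qualifying {kind} bouts")
    max_len = max(len(s) for s in segments)
    mean = np.full(max_len, np.nan)
    sem = np.full(max_len, np.nan)
    n = np.zeros(max_len, dtype=int)
    for k in range(max_len):
        vals = np.array([s[k] for s in segments if len(s) > k])
        n[k] = vals.size
        mean[k] = vals.mean()
        if vals.size >= 2:
            sem[k] = vals.std(ddof=1) / math.sqrt(vals.size)
    keep = n > min_samples
    return AlignedAverage(
        kind=kind,
        time_s=np.flatnonzero(keep) / fps,
        mean=mean[keep],
        sem=sem[keep],
        n=n[keep],
        min_samples=min_samples,
    )


# ---------------------------------------------------------------------------
# duration-normalized profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedProfile:
    """Duration-normalized average profile with per-bout quartile means."""

    kind: str
    grid: np.ndarray = field(repr=False)  # midpoints of G cells on [0, 1]
    mean: np.ndarray = field(repr=False)
    sem: np.ndarray = field(repr=False)
    q1: np.ndarray = field(repr=False)  # per-bout mean over [0, 0.25)
    q4: np.ndarray = field(repr=False)  # per-bout mean over [0.75, 1.0]
    p_q4_greater: float = math.nan  # one-sided Wilcoxon signed-rank
    n_bouts: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"normalized_time": self.grid, "mean": self.mean, "sem": self.sem})


def normalized_profile(
    sessions,
    kind: str,
    grid_size: int = DEFAULT_GRID_SIZE,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    drop_edges: bool = True,
) -> NormalizedProfile:
    """Average the signal along bout-duration-normalized time.

    Each bout's trace is linearly resampled onto ``grid_size`` cell
    midpoints over [0, 1].  Per-bout means over normalized time
    [0, 0.25) (Q1) and [0.75, 1.0] (Q4) are returned together with a
    paired one-sided Wilcoxon signed-rank p-value for Q4 > Q1.
    """
    segments, _, _ = extract_bout_segments(sessions, kind, min_duration, drop_edges)
    usable = []
    for seg in segments:
        if len(seg) < 2:
            warnings.warn("skipping a bout shorter than 2 frames", stacklevel=2)
            continue
        usable.append(seg)
    if not usable:
        raise AnalysisError(f"no qualifying {kind} bouts")

    grid = (np.arange(grid_size) + 0.5) / grid_size
    resampled = np.empty((len(usable), grid_size))
    for i, seg in enumerate(usable):
        xs = np.arange(len(seg)) / (len(seg) - 1)
        resampled[i] = np.interp(grid, xs, seg)

    q1 = resampled[:, grid < 0.25].mean(axis=1)
    q4 = resampled[:, grid >= 0.75].mean(axis=1)
    diffs = q4 - q1
    if np.allclose(diffs, 0.0):
        p = 1.0  # no enrichment anywhere; signed-rank test undefined
    else:
        p = float(stats.wilcoxon(q4, q1, alternative="greater").pvalue)

    n = resampled.shape[0]
    sem = (
        resampled.std(axis=0, ddof=1) / math.sqrt(n)
        if n >= 2
        else np.full(grid_size, np.nan)
    )
    return NormalizedProfile(
        kind=kind,
        grid=grid,
        mean=resampled.mean(axis=0),
        sem=sem,
        q1=q1,
        q4=q4,
        p_q4_greater=p,
        n_bouts=n,
    )


# ---------------------------------------------------------------------------
# transition-triggered windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionWindow:
    """Pre/post means of the signal around one SM or MS transition."""

    kind: str  # "SM" or "MS"
    time_s: float  # transition time
    pre_mean: float
    post_mean: float


def transition_triggered(
    sessions,
    kind: str = "MS",
    window: float = DEFAULT_TRANSITION_WINDOW_S,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    drop_edges: bool = True,
) -> tuple[list[TransitionWindow], dict]:
    """Mean signal in the ``window`` seconds before vs after transitions.

    A transition qualifies when both flanking bouts pass the standard
    exclusions and are long enough to contain the full window.  Returns
    the per-event windows and a paired summary (means and a paired t
    test), with the count of excluded transitions.
    """
    if kind not in ("SM", "MS"):
        raise ValueError("kind must be 'SM' or 'MS'")
    first, second = (SLEEP, MOTION) if kind == "SM" else (MOTION, SLEEP)
    sess = _as_sessions(sessions)
    fps = sess[0][1].fps
    wf = int(round(window * fps))

    events: list[TransitionWindow] = []
    n_excluded = 0
    for values, series in sess:
        for prev, cur in zip(series.bouts[:-1], series.bouts[1:]):
            if prev.kind != first or cur.kind != second:
                continue

            def ok(b: Bout) -> bool:
                if drop_edges and b.at_edge:
                    return False
                return b.duration > min_duration and b.n_frames >= wf

            if not (ok(prev) and ok(cur)):
                n_excluded += 1
                continue
            t = cur.start_frame
            events.append(
                TransitionWindow(
                    kind=kind,
                    time_s=cur.start,
                    pre_mean=float(np.nanmean(values[t - wf : t])),
                    post_mean=float(np.nanmean(values[t : t + wf])),
                )
            )
    if not events:
        raise AnalysisError(f"no qualifying {kind} transitions")

    pre = np.array([e.pre_mean for e in events])
    post = np.array([e.post_mean for e in events])
    if np.allclose(pre, post):
        p = 1.0
    else:
        p = float(stats.ttest_rel(post, pre).pvalue)
    summary = {
        "kind": kind,
        "n_events": len(events),
        "n_excluded": n_excluded,
        "pre_mean": float(pre.mean()),
        "post_mean": float(post.mean()),
        "paired_t_p": p,
    }
    return events, summary


# ---------------------------------------------------------------------------
# peak latency / intensity correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakEvent:
    """Peak of the smoothed signal within one motion bout."""

    bout_index: int
    peak: float
    latency_s: float  # from bout start; first frame on ties


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r: float
    p_value: float
    slope_ci: tuple
    intercept_ci: tuple
    n: int


def linear_fit(x: Sequence, y: Sequence) -> RegressionSummary:
    """Ordinary least squares of y on x with 95% CIs and Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    r, p = stats.pearsonr(x, y)
    return RegressionSummary(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r=float(r),
        p_value=float(p),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        n=int(x.size),
    )


def peak_latency_correlation(
    sessions,
    smooth: float = DEFAULT_PEAK_SMOOTH_S,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    drop_edges: bool = True,
) -> tuple[list[PeakEvent], Optional[RegressionSummary]]:
    """Peak signal intensity vs latency to peak across motion bouts.

    Each bout's trace is smoothed with a centered moving average
    (window = round(smooth * fps) frames, forced odd, edges truncated);
    the peak is the maximum (earliest frame on ties) and the latency is
    the time from bout start to the peak.  With at least 3 bouts and
    non-degenerate variance, an OLS fit of peak on latency is returned.
    """
    segments, _, fps = extract_bout_segments(sessions, MOTION, min_duration, drop_edges)
    if not segments:
        raise AnalysisError("no qualifying motion bouts")
    wf = _odd_window_frames(smooth, fps)

    peaks: list[PeakEvent] = []
    for i, seg in enumerate(segments):
        sm_seg = _moving_average(seg, wf)
        k = int(np.nanargmax(sm_seg))
        peaks.append(PeakEvent(bout_index=i, peak=float(sm_seg[k]), latency_s=k / fps))

    regression = None
    if len(peaks) >= 3:
        x = np.array([p.latency_s for p in peaks])
        y = np.array([p.peak for p in peaks])
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            regression = linear_fit(x, y)
    return peaks, regression


# ---------------------------------------------------------------------------
# cumulative locomotor activity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CumulativeBout:
    """Cumulative locomotor activity within one motion bout."""

    bout: Bout
    time_s: np.ndarray = field(repr=False)
    cumulative: np.ndarray = field(repr=False)
    r_squared: float = math.nan  # straight-line fit diagnostic


def cumulative_locomotor(
    activity: ActivityTrace,
    series: BoutSeries,
    min_duration: float = 0.0,
    drop_edges: bool = False,
) -> list[CumulativeBout]:
    """Running sum of changed-pixel counts within each motion bout.

    The R^2 of a straight-line fit of the cumulative curve against time
    is reported per bout; an essentially linear curve indicates a steady
    locomotion rate through the bout.  R^2 is NaN for a constant curve.
    """
    if len(activity) != series.n_frames:
        raise ValueError("activity trace and bout series lengths differ")
    counts = np.asarray(activity.changed_pixels, dtype=float)
    out = []
    for b in filter_bouts(series, min_duration=min_duration, drop_edges=drop_edges):
        if b.kind != MOTION:
            continue
        seg = counts[b.start_frame : b.end_frame]
        cum = np.cumsum(seg)
        t = np.arange(seg.size) / series.fps
        if np.ptp(cum) == 0:
            r2 = math.nan
        else:
            coef = np.polyfit(t, cum, 1)
            resid = cum - np.polyval(coef, t)
            r2 = 1.0 - float(np.sum(resid**2)) / float(np.sum((cum - cum.mean()) ** 2))
        out.append(CumulativeBout(bout=b, time_s=t, cumulative=cum, r_squared=r2))
    return out


# ---------------------------------------------------------------------------
# thin statistical wrappers (sample selection lives above; tests are scipy's)
# ---------------------------------------------------------------------------

def paired_wilcoxon(a, b, alternative: str = "two-sided") -> float:
    return float(stats.wilcoxon(a, b, alternative=alternative).pvalue)


def mann_whitney(a, b, alternative: str = "two-sided") -> float:
    return float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)


def paired_t(a, b) -> float:
    return float(stats.ttest_rel(a, b).pvalue)


def unpaired_t(a, b) -> float:
    return float(stats.ttest_ind(a, b).pvalue)


def ks_two_sample(a, b) -> float:
    return float(stats.ks_2samp(a, b).pvalue)
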