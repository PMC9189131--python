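"""Synthetic lethargus recordings with known ground truth.

Real inputs to this pipeline are video stacks of a single worm, dual-channel
fluorescence traces of the ALA interneuron, and optogenetic stimulation
logs.  This module generates statistically matched stand-ins:

* **Bout schedules** — alternating motion/sleep bouts, motion durations
  log-normal (positive and right-skewed, like observed bout-duration
  histograms), and a homeostatic coupling: expected sleep duration =
  ``sleep_base + homeostatic_gain x prior motion duration``.
* **Ca2+ traces** — a latent signal that ramps linearly during motion
  bouts (rate ``ramp_rate`` in dR/R0 units per second) and decays
  exponentially during sleep bouts (time constant ``decay_tau``),
  observed through noisy GCaMP and RFP channels.  This emulates ALA,
  whose Ca2+ gradually rises while the worm moves and rapidly decays at
  motion-to-sleep transitions.
* **Rendered video** — a worm-sized disc that jitters during motion bouts
  and is static during sleep bouts, plus a matched empty-chamber noise
  stack for threshold calibration.
* **Optogenetic trials** — each trial starts at a motion-bout onset with
  the stimulus at t = 0; the per-frame hazard of the motion-to-sleep
  transition is multiplied by ``stim_hazard_multiplier`` during the
  effect window in the treated group only.  Treated and control trials
  share common random numbers, so a multiplier of 1 reproduces the
  control group draw-for-draw.

Latent Ca2+ integration is forward Euler at the frame rate, evaluated
run-by-run in closed form (linear ramp / geometric decay), which is
algebraically identical to the per-frame update.

Every generator draws from one ``numpy`` Generator seeded from its
config's ``seed`` field (default 0), so identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .bout_segmentation import (
    DEFAULT_MIN_SLEEP_S,
    MOTION,
    SLEEP,
    BoutSeries,
    segment_bouts,
)
from .optogenetics import DEFAULT_STIM_DURATION_S, StimEvent

# rendering constants: absolute intensities are irrelevant to frame
# differencing because the threshold is calibrated per recording
BACKGROUND_LEVEL = 50.0
WORM_LEVEL = 150.0


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutScheduleConfig:
    """Generative parameters of the alternating bout schedule.

    ``motion_sigma`` is the log-scale SD of the log-normal motion-bout
    duration distribution; the distribution's arithmetic mean is
    ``motion_mean``.  Sleep durations are floored at ``min_bout`` so every
    simulated sleep bout is detectable under the 6-s rule by default.
    """

    total_duration: float = 600.0  # s
    fps: float = 10.0
    motion_mean: float = 30.0  # s
    motion_sigma: float = 0.6  # log-scale SD
    sleep_base: float = 10.0  # s
    homeostatic_gain: float = 0.5
    sleep_noise_sd: float = 2.0  # s
    min_bout: float = 7.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.motion_mean <= 0:
            raise ValueError("motion_mean must be positive")
        if self.motion_sigma < 0:
            raise ValueError("motion_sigma must be non-negative")
        if self.sleep_base < 0:
            raise ValueError("sleep_base must be non-negative")
        if self.sleep_noise_sd < 0:
            raise ValueError("sleep_noise_sd must be non-negative")
        if self.min_bout <= 0:
            raise ValueError("min_bout must be positive")


@dataclass(frozen=True)
class CaSimConfig:
    """Generative parameters of the ALA-like latent Ca2+ signal.

    Defaults give peak latent amplitudes around 3 dR/R0 units over a
    30-s motion bout — within the GCaMP6s dynamic range and comfortably
    above the 20% motion-active classification margin, as observed for
    ALA — and a fast decay upon sleep entry.
    """

    ramp_rate: float = 0.1  # dR/R0 units per second during motion
    decay_tau: float = 3.0  # s, exponential decay during sleep
    gcamp_gain: float = 100.0  # fluorescence units per latent unit
    gcamp_baseline: float = 100.0
    rfp_level: float = 100.0
    channel_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ramp_rate < 0:
            raise ValueError("ramp_rate must be non-negative")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.rfp_level <= 0:
            raise ValueError("rfp_level must be positive")
        if self.gcamp_baseline <= 0:
            raise ValueError("gcamp_baseline must be positive")
        if self.channel_noise_sd < 0:
            raise ValueError("channel_noise_sd must be non-negative")


@dataclass(frozen=True)
class VideoSimConfig:
    """Rendering parameters for the synthetic behavior video."""

    frame_shape: tuple = (128, 128)
    worm_area: int = 600  # pixels
    jitter_px: float = 4.0  # displacement per frame during motion
    pixel_noise_sd: float = 2.0
    n_frames: Optional[int] = None  # None: one frame per schedule frame
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.frame_shape
        if self.worm_area >= ny * nx:
            raise ValueError("worm_area must be smaller than the frame")
        if self.worm_area <= 0:
            raise ValueError("worm_area must be positive")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be non-negative")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be non-negative")
        if self.n_frames is not None and self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")


@dataclass(frozen=True)
class OptoSimConfig:
    """Generative parameters for optogenetic stimulation trials.

    ``baseline_hazard`` is the per-second probability of a motion-to-sleep
    transition; it is converted to a per-frame probability via
    ``p = 1 - (1 - h)**(1/fps)``.  During ``[0, stim_effect_window)`` the
    treated group's per-second hazard is multiplied by
    ``stim_hazard_multiplier`` (clamped at 1).  ``n_trials`` is per group;
    trials are assigned to animals in blocks of ``trials_per_animal``
    (at most 5 per animal, per protocol).
    """

    n_trials: int = 100
    baseline_hazard: float = 0.05  # per second
    stim_hazard_multiplier: float = 4.0
    stim_effect_window: float = 10.0  # s
    stim_duration: float = DEFAULT_STIM_DURATION_S  # s
    fps: float = 2.0
    trial_duration: float = 120.0  # s of post-stimulation recording
    pre_window: float = 10.0  # s of pre-stimulation (sleep) recording
    motion_level: float = 200.0  # mean changed-pixel count while moving
    motion_level_sd: float = 20.0
    quiescent_level_sd: float = 2.0
    trials_per_animal: int = 5
    #: share transition randomness between groups (treated trial i and
    #: control trial i see the same uniforms, so multiplier 1 reproduces
    #: the control group exactly); disable for independent-group draws,
    #: e.g. when calibrating a between-group test's type-I error
    common_random_numbers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if not 0 < self.baseline_hazard <= 1:
            raise ValueError("baseline_hazard must lie in (0, 1]")
        if self.stim_hazard_multiplier < 1:
            raise ValueError("stim_hazard_multiplier must be >= 1")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")
        if self.stim_effect_window < 0:
            raise ValueError("stim_effect_window must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 1 <= self.trials_per_animal <= 5:
            raise ValueError("trials_per_animal must lie in [1, 5]")


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduledBout:
    kind: str
    start: float  # s
    end: float  # s

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class GroundTruthSchedule:
    """A simulated bout schedule plus the parameters that generated it."""

    bouts: tuple
    state: np.ndarray = field(repr=False)  # per-frame, True = motion/active
    fps: float = 10.0
    total_duration: float = 600.0
    homeostatic_gain: float = 0.5
    ramp_rate: Optional[float] = None
    decay_tau: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return len(self.state)

    def motion_sleep_pairs(self) -> list[tuple[float, float]]:
        """(prior motion duration, sleep duration) for every adjacent
        motion->sleep pair, excluding the truncated final bout."""
        pairs = []
        last = self.bouts[-1] if self.bouts else None
        for prev, cur in zip(self.bouts[:-1], self.bouts[1:]):
            if prev.kind == MOTION and cur.kind == SLEEP and cur is not last:
                pairs.append((prev.duration, cur.duration))
        return pairs

    def to_bout_series(
        self, min_sleep_duration: float = DEFAULT_MIN_SLEEP_S
    ) -> BoutSeries:
        """Segment the ground-truth frame state into a :class:`BoutSeries`."""
        return segment_bouts(self.state, self.fps, min_sleep_duration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [b.kind for b in self.bouts],
                "start_s": [b.start for b in self.bouts],
                "end_s": [b.end for b in self.bouts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_bout_schedule(config: BoutScheduleConfig) -> GroundTruthSchedule:
    """Draw an alternating motion/sleep bout schedule with homeostatic coupling.

    The schedule starts with a motion bout.  Motion durations are
    log-normal with arithmetic mean ``motion_mean``; each following sleep
    duration is ``max(min_bout, sleep_base + homeostatic_gain * prior
    motion duration + N(0, sleep_noise_sd))``.  The last bout is truncated
    at ``total_duration``.  The per-frame binary state assigns frame ``i``
    the kind of the bout containing time ``i/fps``.
    """
    rng = np.random.default_rng(config.seed)
    mu = math.log(config.motion_mean) - config.motion_sigma**2 / 2.0

    bouts: list[ScheduledBout] = []
    t = 0.0
    kind = MOTION
    prev_motion = 0.0
    while t < config.total_duration:
        if kind == MOTION:
            d = float(rng.lognormal(mean=mu, sigma=config.motion_sigma))
            prev_motion = d
        else:
            d = (
                config.sleep_base
                + config.homeostatic_gain * prev_motion
                + float(rng.normal(0.0, config.sleep_noise_sd))
                if config.sleep_noise_sd > 0
                else config.sleep_base + config.homeostatic_gain * prev_motion
            )
            d = max(config.min_bout, d)
        end = min(t + d, config.total_duration)
        bouts.append(ScheduledBout(kind=kind, start=t, end=end))
        t = end
        kind = SLEEP if kind == MOTION else MOTION

    n_frames = int(round(config.total_duration * config.fps))
    times = np.arange(n_frames) / config.fps
    starts = np.array([b.start for b in bouts])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(bouts) - 1)
    kinds_motion = np.array([b.kind == MOTION for b in bouts])
    state = kinds_motion[idx]

    return GroundTruthSchedule(
        bouts=tuple(bouts),
        state=state,
        fps=config.fps,
        total_duration=config.total_duration,
        homeostatic_gain=config.homeostatic_gain,
    )


def _latent_calcium(state: np.ndarray, fps: float, ramp_rate: float, decay_tau: float) -> np.ndarray:
    """Latent Ca2+ by forward Euler at the frame rate, run-wise closed form.

    Each frame applies one update from the preceding value (C before the
    first frame is 0): motion frames add ``ramp_rate/fps``; sleep frames
    multiply by ``1 - 1/(fps*decay_tau)``.  A motion bout of L seconds
    therefore raises C by exactly ``ramp_rate * L``, peaking at the bout's
    final frame.
    """
    dt = 1.0 / fps
    if decay_tau <= dt:
        raise ValueError(
            f"decay_tau={decay_tau} must exceed the frame interval {dt} "
            "for a stable forward-Euler decay"
        )
    decay = 1.0 - dt / decay_tau
    C = np.empty(state.size, dtype=np.float64)
    c0 = 0.0
    pos = 0
    edges = np.flatnonzero(np.diff(state.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [state.size]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        m = e - s
        if state[s]:  # motion: linear ramp
            C[s:e] = c0 + ramp_rate * dt * np.arange(1, m + 1)
        else:  # sleep: geometric decay
            C[s:e] = c0 * decay ** np.arange(1, m + 1)
        c0 = C[e - 1]
        pos = e
    assert pos == state.size
    return C


def simulate_calcium(
    schedule: GroundTruthSchedule, config: CaSimConfig
) -> pd.DataFrame:
    """Simulate dual-channel fluorescence of an ALA-like neuron.

    Returns a DataFrame with columns ``frame``, ``time_s``, ``gcamp``,
    ``rfp``, and the ground-truth latent signal ``true_ca`` (dropped when
    written as an observed-trace CSV).
    """
    state = np.asarray(schedule.state, dtype=bool)
    if state.size < 2:
        raise ValueError("schedule must cover at least 2 frames")
    rng = np.random.default_rng(config.seed)
    C = _latent_calcium(state, schedule.fps, config.ramp_rate, config.decay_tau)
    n = state.size
    gcamp = (
        config.gcamp_baseline
        + config.gcamp_gain * C
        + rng.normal(0.0, config.channel_noise_sd, n)
    )
    rfp = config.rfp_level + rng.normal(0.0, config.channel_noise_sd, n)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / schedule.fps,
            "gcamp": gcamp,
            "rfp": rfp,
            "true_ca": C,
        }
    )


def write_traces_csv(traces: pd.DataFrame, path) -> None:
    """Write the observed-channel columns (frame, time_s, gcamp, rfp)."""
    traces[["frame", "time_s", "gcamp", "rfp"]].to_csv(path, index=False)


def _disc_mask(grids: tuple, center: tuple, area: int) -> np.ndarray:
    """Boolean mask of exactly ``area`` pixels nearest to ``center``."""
    yy, xx = grids
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    flat = d2.ravel()
    idx = np.argpartition(flat, area - 1)[:area]
    mask = np.zeros(flat.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(d2.shape)


def _reflect(v: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi]."""
    if hi <= lo:
        return lo
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (span - abs(v - span) if v > span else v)


def render_video(
    schedule: GroundTruthSchedule,
    config: VideoSimConfig,
    stack_path=None,
    empty_path=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the behavior stack and a matched empty-chamber noise stack.

    The worm is a filled disc of exactly ``worm_area`` pixels.  On each
    motion frame its center moves by ``jitter_px`` in a uniformly random
    direction, reflected at the borders so the worm never leaves the
    frame; directions whose reflected net displacement would be under
    three quarters of ``jitter_px`` are re-drawn (the worm slides along a
    wall rather than compressing into it), so a moving worm always moves
    visibly.  On sleep frames it is static, so consecutive-frame
    differences there contain pixel noise only.  The empty stack has the
    same shape and length and contains noise only.  Both are float32;
    pass paths to also write them as multi-page grayscale TIFFs.
    """
    state = np.asarray(schedule.state, dtype=bool)
    n = config.n_frames if config.n_frames is not None else state.size
    n = min(n, state.size)
    if n < 2:
        raise ValueError("need at least 2 frames to render")
    ny, nx = config.frame_shape
    rng = np.random.default_rng(config.seed)

    radius = math.sqrt(config.worm_area / math.pi)
    lo_y, hi_y = radius, ny - 1 - radius
    lo_x, hi_x = radius, nx - 1 - radius
    cy, cx = ny / 2.0, nx / 2.0
    grids = np.ogrid[:ny, :nx]

    stack = np.empty((n, ny, nx), dtype=np.float32)
    background = np.full((ny, nx), BACKGROUND_LEVEL, dtype=np.float32)
    mask = _disc_mask(grids, (cy, cx), config.worm_area)
    for i in range(n):
        if i > 0 and state[i] and config.jitter_px > 0:
            for _ in range(20):
                theta = rng.uniform(0.0, 2.0 * math.pi)
                ny_c = _reflect(cy + config.jitter_px * math.sin(theta), lo_y, hi_y)
                nx_c = _reflect(cx + config.jitter_px * math.cos(theta), lo_x, hi_x)
                if math.hypot(ny_c - cy, nx_c - cx) >= 0.75 * config.jitter_px:
                    break
            cy, cx = ny_c, nx_c
            mask = _disc_mask(grids, (cy, cx), config.worm_area)
        frame = background.copy()
        frame[mask] = WORM_LEVEL
        stack[i] = frame
    sd = np.float32(config.pixel_noise_sd)
    if config.pixel_noise_sd > 0:
        stack += rng.standard_normal(stack.shape, dtype=np.float32) * sd

    empty = np.full((n, ny, nx), BACKGROUND_LEVEL, dtype=np.float32)
    if config.pixel_noise_sd > 0:
        empty += rng.standard_normal(empty.shape, dtype=np.float32) * sd

    if stack_path is not None:
        tifffile.imwrite(stack_path, stack)
    if empty_path is not None:
        tifffile.imwrite(empty_path, empty)
    return stack, empty


def per_frame_hazard(hazard_per_s: float, fps: float) -> float:
    """Convert a per-second transition probability to a per-frame one."""
    return 1.0 - (1.0 - hazard_per_s) ** (1.0 / fps)


def simulate_optogenetics(config: OptoSimConfig) -> tuple[list[StimEvent], pd.DataFrame]:
    """Simulate treated (ATR+) and control (ATR-) stimulation trials.

    Each trial starts at a motion-bout onset with the stimulus at t = 0
    (after ``pre_window`` seconds of pre-stimulation sleep).  The frame of
    the motion-to-sleep transition is drawn from the per-frame hazard;
    during ``[0, stim_effect_window)`` the treated group's hazard is
    multiplied by ``stim_hazard_multiplier``.  Treated and control trial
    *i* share one uniform random stream (common random numbers), so a
    multiplier of 1 yields identical draws in both groups.  After the
    transition the worm stays quiescent to the end of the trial.

    Returns the list of :class:`StimEvent` (with per-frame locomotion and
    binary activity traces) and a stimulation-log DataFrame.
    """
    fps = config.fps
    pre_f = int(round(config.pre_window * fps))
    post_f = int(round(config.trial_duration * fps))
    window_f = int(round(config.stim_effect_window * fps))

    p_base = per_frame_hazard(config.baseline_hazard, fps)
    h_stim = min(1.0, config.baseline_hazard * config.stim_hazard_multiplier)
    p_stim = per_frame_hazard(h_stim, fps) if h_stim < 1.0 else 1.0

    events: list[StimEvent] = []
    rows = []
    for g_idx, group in enumerate(("control", "treated")):
        for i in range(config.n_trials):
            if config.common_random_numbers:
                # transition draws shared between groups
                rng_t = np.random.default_rng([int(config.seed), 7, i])
            else:
                rng_t = np.random.default_rng([int(config.seed), 7, g_idx, i])
            u = rng_t.random(post_f)
            p = np.full(post_f, p_base)
            if group == "treated":
                p[:window_f] = p_stim
            hits = np.flatnonzero(u < p)
            if hits.size:
                trans = int(hits[0])  # sleep starts at post frame trans+1
                latency = (trans + 1) / fps
                censored = False
                n_motion = trans + 1
            else:
                latency = math.nan
                censored = True
                n_motion = post_f

            rng_n = np.random.default_rng([int(config.seed), 11, g_idx, i])
            active = np.zeros(pre_f + post_f, dtype=bool)
            active[pre_f : pre_f + n_motion] = True
            loco = np.abs(rng_n.normal(0.0, config.quiescent_level_sd, pre_f + post_f))
            loco[active] = np.clip(
                rng_n.normal(config.motion_level, config.motion_level_sd, n_motion),
                0.0,
                None,
            )
            trial_id = g_idx * config.n_trials + i
            animal_id = trial_id // config.trials_per_animal
            events.append(
                StimEvent(
                    trial_id=trial_id,
                    animal_id=animal_id,
                    group=group,
                    stim_onset_s=config.pre_window,
                    fps=fps,
                    stim_duration_s=config.stim_duration,
                    latency_s=latency,
                    censored=censored,
                    locomotion=loco,
                    active=active,
                )
            )
            rows.append(
                {
                    "trial": trial_id,
                    "animal": animal_id,
                    "group": group,
                    "stim_onset_s": config.pre_window,
                    "latency_s": latency,
                    "censored": censored,
                }
            )
    return events, pd.DataFrame(rows)
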