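"""Bout-aligned averaging, normalized profiles, transitions, peaks, cumulative."""

import math

import numpy as np
import pytest

import lethargus as lg
from lethargus.bout_segmentation import MOTION, SLEEP
from lethargus.errors import AnalysisError


def make_series(kinds_and_frames, fps=10.0, edges="auto"):
    bouts, pos = [], 0
    total = sum(n for _, n in kinds_and_frames)
    for kind, n in kinds_and_frames:
        at_edge = (pos == 0 or pos + n == total) if edges == "auto" else False
        bouts.append(
            lg.Bout(kind=kind, start_frame=pos, end_frame=pos + n, fps=fps, at_edge=at_edge)
        )
        pos += n
    return lg.BoutSeries(bouts=tuple(bouts), fps=fps, n_frames=pos)


def pad_series(inner, fps=10.0):
    """Wrap (kind, frames) blocks with long edge bouts so the interior survives
    the 12-s/edge filters."""
    first = MOTION if inner[0][0] == SLEEP else SLEEP
    last = MOTION if inner[-1][0] == SLEEP else SLEEP
    return [(first, 200)] + inner + [(last, 200)]


# ---------------------------------------------------------------------------
# align_and_average
# ---------------------------------------------------------------------------

def test_identical_bouts_average_to_common_trace():
    blocks = pad_series([(MOTION, 150), (SLEEP, 150), (MOTION, 150)])
    series = make_series(blocks)
    ramp = np.arange(150, dtype=float)
    values = np.zeros(series.n_frames)
    for b in series.of_kind(MOTION):
        if not b.at_edge:
            values[b.start_frame : b.end_frame] = ramp
    out = lg.align_and_average((values, series), MOTION, min_samples=0)
    assert np.allclose(out.mean, ramp)
    assert np.allclose(out.sem, 0.0)
    assert np.all(out.n == 2)


def test_hand_assembled_two_bout_average():
    # bouts of 20 s and 30 s: output extends to 30 s, n drops 2 -> 1 at 20 s
    blocks = pad_series([(MOTION, 200), (SLEEP, 150), (MOTION, 300)])
    series = make_series(blocks)
    values = np.zeros(series.n_frames)
    m1, m2 = [b for b in series.of_kind(MOTION) if not b.at_edge]
    values[m1.start_frame : m1.end_frame] = 1.0
    values[m2.start_frame : m2.end_frame] = 3.0
    out = lg.align_and_average((values, series), MOTION, min_samples=0)
    assert len(out.mean) == 300
    assert np.all(out.n[:200] == 2) and np.all(out.n[200:] == 1)
    assert np.allclose(out.mean[:200], 2.0) and np.allclose(out.mean[200:], 3.0)
    assert np.all(np.isnan(out.sem[200:]))  # SEM undefined at n == 1


def test_min_samples_threshold_is_inclusive_drop():
    # 10 identical bouts and the "10 or less" rule: nothing survives
    inner = []
    for _ in range(10):
        inner += [(MOTION, 150), (SLEEP, 150)]
    series = make_series(pad_series(inner))
    values = np.zeros(series.n_frames)
    out = lg.align_and_average((values, series), MOTION, min_samples=10)
    assert len(out.mean) == 0
    # with an 11th bout the shared time points survive
    inner += [(MOTION, 150), (SLEEP, 150)]
    series = make_series(pad_series(inner))
    out = lg.align_and_average((np.zeros(series.n_frames), series), MOTION, min_samples=10)
    assert np.all(out.n == 11)


def test_no_qualifying_bouts_is_an_error():
    series = make_series([(MOTION, 50), (SLEEP, 100), (MOTION, 50)])
    with pytest.raises(AnalysisError):
        lg.align_and_average((np.zeros(series.n_frames), series), MOTION)


def test_min_samples_zero_conserves_counts():
    """n(t) equals the number of qualifying bouts at least t long."""
    rng = np.random.default_rng(0)
    inner = []
    lengths = []
    for _ in range(8):
        n = int(rng.integers(125, 400))
        lengths.append(n)
        inner += [(MOTION, n), (SLEEP, 130)]
    series = make_series(pad_series(inner))
    out = lg.align_and_average((np.zeros(series.n_frames), series), MOTION, min_samples=0)
    expected = [sum(1 for L in lengths if L > k) for k in range(max(lengths))]
    assert list(out.n) == expected


# ---------------------------------------------------------------------------
# normalized_profile
# ---------------------------------------------------------------------------

def test_constant_trace_flat_profile_q1_equals_q4():
    blocks = pad_series([(MOTION, 150), (SLEEP, 150), (MOTION, 220)])
    series = make_series(blocks)
    values = np.full(series.n_frames, 2.5)
    prof = lg.normalized_profile((values, series), MOTION)
    assert np.allclose(prof.mean, 2.5)
    assert np.allclose(prof.q1, prof.q4)


def test_linear_ramp_exact_quartile_means():
    # ramp 0 -> 1 over each bout: Q1 mean 0.125, Q4 mean 0.875 (closed form)
    inner = []
    for n in (150, 220, 300):
        inner += [(MOTION, n), (SLEEP, 150)]
    series = make_series(pad_series(inner))
    values = np.zeros(series.n_frames)
    for b in series.of_kind(MOTION):
        if not b.at_edge:
            values[b.start_frame : b.end_frame] = np.linspace(0.0, 1.0, b.n_frames)
    prof = lg.normalized_profile((values, series), MOTION, grid_size=100)
    assert np.allclose(prof.q1, 0.125, atol=1e-6)
    assert np.allclose(prof.q4, 0.875, atol=1e-6)
    assert np.allclose(prof.q4 - prof.q1, 0.75, atol=1e-6)
    # the profile itself is the identity line at grid midpoints
    assert np.allclose(prof.mean, prof.grid, atol=1e-6)


def test_warping_invariance_of_normalized_profile():
    """A monotone time re-parameterization of bout interiors leaves the
    duration-normalized profile unchanged at grid resolution."""
    f = lambda u: u**2  # the signal as a function of normalized time

    def session_for(lengths):
        inner = []
        for n in lengths:
            inner += [(MOTION, n), (SLEEP, 150)]
        series = make_series(pad_series(inner))
        values = np.zeros(series.n_frames)
        for b in series.of_kind(MOTION):
            if not b.at_edge:
                u = np.linspace(0.0, 1.0, b.n_frames)
                values[b.start_frame : b.end_frame] = f(u)
        return values, series

    a = lg.normalized_profile(session_for([200, 200]), MOTION)
    b = lg.normalized_profile(session_for([400, 1000]), MOTION)  # stretched bouts
    assert np.allclose(a.mean, b.mean, atol=5e-3)


def test_rising_signal_q4_exceeds_q1_significantly(session):
    values, series = session
    prof = lg.normalized_profile((values, series), MOTION)
    assert np.mean(prof.q4 > prof.q1) > 0.9
    assert prof.p_q4_greater < 0.05


# ---------------------------------------------------------------------------
# transition_triggered
# ---------------------------------------------------------------------------

def test_constant_trace_transitions_pre_equals_post():
    blocks = pad_series([(MOTION, 150), (SLEEP, 150), (MOTION, 150)])
    series = make_series(blocks)
    values = np.full(series.n_frames, 1.3)
    events, summary = lg.transition_triggered((values, series), "MS")
    assert events and all(e.pre_mean == e.post_mean for e in events)
    assert summary["paired_t_p"] == 1.0


def test_ms_transition_decay_matches_closed_form():
    """Noise-free ramp-then-decay: the post-window mean is below the
    pre-window mean for every event and both match closed-form means."""
    fps, a, tau = 10.0, 0.1, 3.0
    from tests_support_closed_form import window_means_oracle

    # interior motion/sleep bouts well over 12 s (edge bouts are excluded)
    from test_synthetic_data import constant_schedule

    blocks = [
        (True, 200), (False, 200), (True, 200), (False, 200),
        (True, 200), (False, 200), (True, 200),
    ]
    sched = constant_schedule(blocks, fps=fps)
    cfg = lg.CaSimConfig(ramp_rate=a, decay_tau=tau, channel_noise_sd=0.0)
    traces = lg.simulate_calcium(sched, cfg)
    series = sched.to_bout_series()
    gcamp = traces["gcamp"].to_numpy()

    events, summary = lg.transition_triggered((gcamp, series), "MS", window=12.0)
    assert len(events) == 2
    assert all(e.post_mean < e.pre_mean for e in events)

    # independent closed-form oracle for the window means
    expected_pre, expected_post = window_means_oracle(
        sched.state, fps, a, tau, cfg.gcamp_baseline, cfg.gcamp_gain, window=12.0
    )
    for e, pre, post in zip(events, expected_pre, expected_post):
        assert e.pre_mean == pytest.approx(pre, abs=1e-6)
        assert e.post_mean == pytest.approx(post, abs=1e-6)


def test_sm_change_small_relative_to_ms_drop(session):
    # the ramp restarts from a low baseline at SM, so any SM change is
    # modest next to the sharp drop from the activity peak at MS
    values, series = session
    sm_events, _ = lg.transition_triggered((values, series), "SM")
    ms_events, _ = lg.transition_triggered((values, series), "MS")
    sm = np.mean([e.post_mean - e.pre_mean for e in sm_events])
    ms = np.mean([e.post_mean - e.pre_mean for e in ms_events])
    assert ms < 0
    assert abs(sm) < abs(ms)


def test_symmetric_trace_has_equal_pre_post_means():
    blocks = pad_series([(MOTION, 240), (SLEEP, 240), (MOTION, 150)])
    series = make_series(blocks)
    values = np.zeros(series.n_frames)
    (sleep_bout,) = [b for b in series.of_kind(SLEEP) if not b.at_edge]
    t = sleep_bout.start_frame
    w = 120
    # mirror-symmetric about the boundary between frames t-1 and t
    values[t - w : t + w] = np.r_[np.arange(w)[::-1], np.arange(w)]
    events, _ = lg.transition_triggered((values, series), "MS", window=12.0)
    (e,) = events
    assert e.pre_mean == pytest.approx(e.post_mean)


# ---------------------------------------------------------------------------
# peak_latency_correlation
# ---------------------------------------------------------------------------

def test_degenerate_variance_reports_no_regression():
    inner = []
    for _ in range(4):
        inner += [(MOTION, 150), (SLEEP, 150)]
    series = make_series(pad_series(inner))
    values = np.zeros(series.n_frames)
    for b in series.of_kind(MOTION):
        if not b.at_edge:
            values[b.start_frame : b.end_frame] = np.linspace(0, 1, b.n_frames)
    peaks, reg = lg.peak_latency_correlation((values, series))
    assert len(peaks) == 4
    assert reg is None  # identical traces: zero variance in both coordinates


def test_noise_free_ramp_slope_equals_ramp_rate():
    # generator algebra: a bout ramping at rate a from zero peaks at its
    # final frame, and the truncated centered smoothing subtracts the same
    # constant from every bout, so OLS of peak on latency has slope a, r=1
    fps, a = 10.0, 0.1
    inner = []
    for n in (150, 200, 300, 400):
        inner += [(MOTION, n), (SLEEP, 200)]
    series = make_series(pad_series(inner), fps=fps)
    values = np.zeros(series.n_frames)
    for b in series.of_kind(MOTION):
        if not b.at_edge:
            values[b.start_frame : b.end_frame] = a * np.arange(1, b.n_frames + 1) / fps
    peaks, reg = lg.peak_latency_correlation((values, series))
    assert reg is not None
    assert reg.slope == pytest.approx(a, abs=1e-9)
    assert reg.r == pytest.approx(1.0, abs=1e-9)


def test_peak_ties_resolve_to_earliest_frame():
    blocks = pad_series([(MOTION, 200), (SLEEP, 150), (MOTION, 150)])
    series = make_series(blocks)
    values = np.zeros(series.n_frames)
    m = [b for b in series.of_kind(MOTION) if not b.at_edge][0]
    values[m.start_frame + 50 : m.end_frame] = 1.0  # plateau
    peaks, _ = lg.peak_latency_correlation((values, series), smooth=0.0)
    plateau_peak = [p for p in peaks if p.peak == 1.0][0]
    assert plateau_peak.latency_s == pytest.approx(5.0)


def test_noisy_replicates_recover_positive_correlation():
    positives = 0
    for rep in range(20):
        sched = lg.simulate_bout_schedule(
            lg.BoutScheduleConfig(total_duration=900.0, seed=100 + rep)
        )
        traces = lg.simulate_calcium(sched, lg.CaSimConfig(seed=200 + rep))
        ratio = lg.compute_ratio_trace(traces["gcamp"], traces["rfp"], sched.fps)
        _, reg = lg.peak_latency_correlation(
            (np.asarray(ratio.dr_over_r0), sched.to_bout_series())
        )
        if reg is not None and reg.r > 0:
            positives += 1
    assert positives >= 19


# ---------------------------------------------------------------------------
# cumulative locomotor activity
# ---------------------------------------------------------------------------

def test_constant_rate_gives_linear_cumulative():
    series = make_series([(MOTION, 100)])
    activity = lg.ActivityTrace(
        fps=10.0, changed_pixels=np.full(100, 7.0), active=np.ones(100, dtype=bool)
    )
    (out,) = lg.cumulative_locomotor(activity, series)
    assert out.r_squared == pytest.approx(1.0)
    assert out.cumulative[-1] == pytest.approx(700.0)


def test_zero_activity_gives_flat_curve():
    series = make_series([(MOTION, 50)])
    activity = lg.ActivityTrace(
        fps=10.0, changed_pixels=np.zeros(50), active=np.zeros(50, dtype=bool)
    )
    (out,) = lg.cumulative_locomotor(activity, series)
    assert np.all(out.cumulative == 0.0)
    assert math.isnan(out.r_squared)


def test_stationary_activity_is_essentially_linear():
    rng = np.random.default_rng(1)
    r2s = []
    for _ in range(40):
        n = int(rng.integers(150, 600))
        counts = rng.poisson(200.0, n).astype(float)
        series = make_series([(MOTION, n)])
        activity = lg.ActivityTrace(
            fps=10.0, changed_pixels=counts, active=np.ones(n, dtype=bool)
        )
        (out,) = lg.cumulative_locomotor(activity, series)
        r2s.append(out.r_squared)
    assert np.mean(np.asarray(r2s) >= 0.95) >= 0.95


# ---------------------------------------------------------------------------
# statistical wrappers
# ---------------------------------------------------------------------------

def test_wrappers_match_textbook_values():
    # classical paired example: scipy's own reference values are exact
    a = [125, 115, 130, 140, 140, 115, 140, 125, 140, 135]
    b = [110, 122, 125, 120, 140, 124, 123, 137, 135, 145]
    from scipy import stats

    assert lg.event_analysis.paired_wilcoxon(a, b) == pytest.approx(
        stats.wilcoxon(a, b).pvalue, abs=1e-12
    )
    x = [1.1, 2.3, 1.9, 3.8]
    y = [0.9, 1.2, 2.0, 1.7]
    assert lg.event_analysis.unpaired_t(x, y) == pytest.approx(
        stats.ttest_ind(x, y).pvalue, abs=1e-12
    )
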