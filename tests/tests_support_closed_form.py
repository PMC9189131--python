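"""Independent closed-form oracles used by the tests.

These compute expected values from the generative recursions' analytic
solutions (arithmetic series during motion runs, geometric series during
sleep runs) without calling the package's simulation or analysis code.
"""

import numpy as np


def latent_run_ends(state, fps, ramp_rate, decay_tau):
    """Per-run (start, end, is_motion, c_start, c_end) from closed forms."""
    dt = 1.0 / fps
    f = 1.0 - dt / decay_tau
    edges = np.flatnonzero(np.diff(np.asarray(state, dtype=np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(state)]))
    runs, c = [], 0.0
    for s, e in zip(bounds[:-1], bounds[1:]):
        m = e - s
        c_start = c
        c = c + ramp_rate * dt * m if state[s] else c * f**m
        runs.append((int(s), int(e), bool(state[s]), c_start, c))
    return runs


def window_means_oracle(state, fps, ramp_rate, decay_tau, baseline, gain, window):
    """Expected pre/post GCaMP means around interior MS transitions.

    Pre window = last w motion frames: C descends arithmetically from the
    peak, mean = peak - ramp_rate*dt*(w-1)/2.  Post window = first w sleep
    frames: C = peak * f^k for k = 1..w, mean = peak*f*(1-f^w)/(w*(1-f)).
    Transitions whose flanking runs touch a recording edge, fail the
    12-s rule, or cannot hold the full window are skipped, mirroring the
    analysis contract.
    """
    dt = 1.0 / fps
    f = 1.0 - dt / decay_tau
    w = int(round(window * fps))
    runs = latent_run_ends(state, fps, ramp_rate, decay_tau)
    n = len(state)

    pre_means, post_means = [], []
    for (s1, e1, m1, c1s, c1e), (s2, e2, m2, c2s, c2e) in zip(runs[:-1], runs[1:]):
        if not (m1 and not m2):  # MS only
            continue
        ok = (
            s1 != 0 and e2 != n
            and (e1 - s1) / fps > 12.0 and (e2 - s2) / fps > 12.0
            and (e1 - s1) >= w and (e2 - s2) >= w
        )
        if not ok:
            continue
        peak = c1e
        pre_c = peak - ramp_rate * dt * (w - 1) / 2.0
        post_c = peak * f * (1.0 - f**w) / (w * (1.0 - f))
        pre_means.append(baseline + gain * pre_c)
        post_means.append(baseline + gain * post_c)
    return pre_means, post_means
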