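import numpy as np
import pytest

import lethargus as lg


@pytest.fixture(scope="session")
def schedule():
    """A medium-length default-parameter bout schedule."""
    return lg.simulate_bout_schedule(lg.BoutScheduleConfig(total_duration=900.0, seed=11))


@pytest.fixture(scope="session")
def session(schedule):
    """(dR/R0 values, BoutSeries) for the default ALA-like simulation."""
    traces = lg.simulate_calcium(schedule, lg.CaSimConfig(seed=12))
    ratio = lg.compute_ratio_trace(traces["gcamp"], traces["rfp"], schedule.fps)
    return np.asarray(ratio.dr_over_r0), schedule.to_bout_series()


@pytest.fixture(scope="session")
def rendered_video():
    """A short rendered recording with its ground truth and empty stack."""
    sched = lg.simulate_bout_schedule(lg.BoutScheduleConfig(total_duration=60.0, seed=21))
    stack, empty = lg.render_video(sched, lg.VideoSimConfig(seed=22))
    return sched, stack, empty
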