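import numpy as np
import pytest

import turncycle as tc


@pytest.fixture(scope="session")
def fl_inside():
    return tc.get_preset("fl-inside")


@pytest.fixture(scope="session")
def steps_300(fl_inside):
    """300 FL inside step cycles, shared across phase-coupling tests."""
    return tc.make_steps(fl_inside, 300, seed=42)


@pytest.fixture(scope="session")
def load_inside_session():
    """A full load-stimulation session with ground truth (500 stimuli)."""
    preset = tc.get_preset("load-inside")
    gait = tc.make_steps(preset, 1001, seed=8)
    trial = tc.make_load_trial(gait, preset, seed=9, n_stim=500)
    cycles = tc.segment_steps(gait.touchdowns, gait.liftoffs)
    return preset, gait, trial, cycles


def spike_phases(train, gait):
    """Step-cycle phase of each spike in a train."""
    from turncycle.synthetic import _phase_of
    return _phase_of(train.times, gait.touchdowns.times)


@pytest.fixture(scope="session")
def phases_of():
    return spike_phases


def make_trace(values, fs=100.0, **kw):
    return tc.SampledTrace(np.asarray(values, dtype=float), fs, **kw)


@pytest.fixture(scope="session")
def trace_factory():
    return make_trace
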