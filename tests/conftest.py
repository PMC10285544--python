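"""Shared fixtures: steady-state reference runs are expensive (200 paced
cycles), so they are computed once per session and reused."""

import numpy as np
import pytest

import cardiopop.cell_model as cm


@pytest.fixture(scope="session")
def ref_config():
    return cm.SimulationConfig()


@pytest.fixture(scope="session")
def ref_trace(ref_config):
    """Reference (all-ones) model at 0.93 L_max, steady state."""
    tr = cm.simulate(cm.ScalingVector(), cm.MechanicalProtocol(), ref_config)
    assert tr.ok
    return tr


@pytest.fixture(scope="session")
def preload_traces(ref_config):
    """Steady-state isometric runs of the reference model at reduced lengths."""
    out = {}
    for L in (0.80, 0.85, 0.90):
        out[L] = cm.simulate(
            cm.ScalingVector(), cm.MechanicalProtocol(initial_length=L), ref_config)
    return out


@pytest.fixture(scope="session")
def afterloaded_traces(ref_trace, ref_config):
    """First afterloaded twitches of the reference model."""
    return {a: cm.afterloaded_twitch(cm.ScalingVector(), a, ref_config,
                                     baseline=ref_trace)
            for a in (0.25, 0.5, 0.75)}


def peak_force_last_cycle(trace):
    n = int(round(trace.cycle_length / trace.sample_dt))
    return float(trace.F_active[-(n + 1):].max())
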