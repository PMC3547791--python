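import numpy as np
import pytest

import repeatpull as rp


@pytest.fixture(scope="session")
def fast_free():
    """One free pull at the fast speed (cheap, reused across modules)."""
    return rp.simulate_pull(rp.SimParams(speed=0.05), 1)


@pytest.fixture(scope="session")
def slow_free():
    """One free pull at the slow speed (paper-style frame spacing)."""
    return rp.simulate_pull(rp.SimParams(speed=0.01), 1)


@pytest.fixture(scope="session")
def template7():
    return rp.make_native_template(7, 12, ligand_repeats=range(1, 7))


@pytest.fixture(scope="session")
def template7_free():
    return rp.make_native_template(7, 12)


@pytest.fixture(scope="session")
def bound_run(template7):
    """Bound pull plus its synthesized coordinate trajectory."""
    params = rp.SimParams(speed=0.01, ligand=True, ddg=4.0, q_whole=0.9)
    trace, truth = rp.simulate_pull(params, 3)
    traj = rp.synthesize_trajectory(truth, template7, 11)
    return trace, truth, traj


def tiny_trace(n=5, n_repeats=2, fz=100.0, dz=1.0):
    """Hand-built force trace: constant force fz along z, extension
    growing dz per frame, telescoping anchors splitting extension
    equally between repeats."""
    t = np.arange(n, dtype=float)
    force = np.zeros((n, 3))
    force[:, 2] = fz
    e2e = np.zeros((n, 3))
    e2e[:, 2] = dz * t
    anchors = np.zeros((n, n_repeats + 1, 3))
    for r in range(1, n_repeats + 1):
        anchors[:, r, 2] = e2e[:, 2] * r / n_repeats
    return rp.ForceTrace(time=t, force=force, end_to_end=e2e,
                         anchors=anchors)
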