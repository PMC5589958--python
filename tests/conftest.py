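"""Shared fixtures: test-bed systems and canonical surrogate states."""

from __future__ import annotations

import numpy as np
import pytest

from eadyn.pacing_sim import run_to_steady_state
from eadyn.testbed import (
    make_delayed_logistic_map,
    make_forced_linear,
    make_logistic_map,
    make_paced_surrogate_ap,
    make_sn_normal_form,
)

# canonical starting states inside each basin of the bistable surrogate
REST_START = np.array([-85.5, 0.999, 5.3, 2.0e-5])
PLATEAU_START = np.array([0.0, 0.30, 4.2, 1.0e-3])


@pytest.fixture
def logistic():
    return make_logistic_map(2.5)


@pytest.fixture
def delayed_logistic():
    return make_delayed_logistic_map(1.5)


@pytest.fixture
def sn_form():
    return make_sn_normal_form(-0.25)


@pytest.fixture
def forced_linear():
    return make_forced_linear(tau=1000.0, cycle_length=2000.0)


@pytest.fixture(scope="session")
def surrogate():
    """Bistable surrogate at mid-window %GKr, reference tolerances."""
    return make_paced_surrogate_ap(pct_gkr=40.0)


@pytest.fixture(scope="session")
def surrogate_fast():
    """Same surrogate with cheaper integration for settling-heavy tests."""
    return make_paced_surrogate_ap(pct_gkr=40.0, rtol=1e-8, atol=1e-10)


@pytest.fixture(scope="session")
def surrogate_attractors(surrogate):
    """Both period-1 attractors of the bistable surrogate at 40 %GKr."""
    fm = surrogate.system
    fm.set_param("pct_gkr", 40.0)
    short = run_to_steady_state(fm, REST_START, max_beats=300, tol=1e-8)
    lavo = run_to_steady_state(fm, PLATEAU_START, max_beats=300, tol=1e-8)
    assert short.converged and lavo.converged
    return {"short": short.state, "lavo": lavo.state}
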