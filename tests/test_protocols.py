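"""Sweep, census and clamp protocols on the test-bed systems."""

import numpy as np
import pytest

from eadyn.continuation import Branch
from eadyn.pacing_sim import run_to_steady_state
from eadyn.protocols import (
    default_init_bank,
    hysteresis_sweep,
    multistability_census,
    nai_fixed_analysis,
    perturb_and_settle,
    stable_overlap_windows,
    sweep_transitions,
)
from eadyn.shooting import FixedPoint
from eadyn.testbed import make_forced_linear, make_paced_surrogate_ap
from tests.conftest import PLATEAU_START, REST_START


def test_monostable_sweep_has_no_hysteresis(forced_linear):
    """Down and up sweeps of a monostable system retrace each other."""
    fm = forced_linear.system
    values_down = np.linspace(1500.0, 800.0, 8)
    down = hysteresis_sweep(fm, "tau", values_down, np.array([0.1]),
                            with_features=False)
    up = hysteresis_sweep(fm, "tau", values_down[::-1], down[-1].state,
                          with_features=False)
    assert sweep_transitions(down) == []
    assert sweep_transitions(up) == []
    for d, u in zip(down, up[::-1]):
        assert np.max(np.abs(d.state - u.state)) < 1e-8


def test_carry_over_is_the_hysteresis_mechanism(surrogate_fast,
                                                surrogate_attractors):
    """Inside the bistable window the outcome depends on the carried state:
    a LAVO-carried start stays LAVO while a fresh rest start gives the
    short AP -- deleting the carry-over changes the sweep outcome."""
    fm = surrogate_fast.system
    fm.set_param("pct_gkr", 40.0)
    carried = run_to_steady_state(fm, surrogate_attractors["lavo"],
                                  max_beats=100, tol=1e-8)
    fresh = run_to_steady_state(fm, REST_START, max_beats=300, tol=1e-8)
    assert carried.converged and fresh.converged
    assert np.max(np.abs(carried.state - fresh.state)) > 1.0


def test_census_finds_both_attractors(surrogate_fast):
    fm = surrogate_fast.system
    fm.set_param("pct_gkr", 40.0)
    bank = default_init_bank(8)
    entry = multistability_census(fm, bank, tol=1e-8, max_beats=300,
                                  polish=False)
    assert entry.order >= 2  # short AP + depolarised response (at least)
    assert entry.n_starts == 8


def test_census_monotone_in_bank_size(surrogate_fast):
    """Enlarging the init bank can only reveal more attractors."""
    fm = surrogate_fast.system
    fm.set_param("pct_gkr", 40.0)
    small = multistability_census(fm, default_init_bank(4), tol=1e-8,
                                  max_beats=300, polish=False)
    large = multistability_census(fm, default_init_bank(10), tol=1e-8,
                                  max_beats=300, polish=False)
    assert large.order >= small.order


def test_census_merges_same_basin_starts(surrogate_fast):
    fm = surrogate_fast.system
    fm.set_param("pct_gkr", 40.0)
    bank = [REST_START, REST_START + np.array([1.0, -0.01, 0.05, 1e-5])]
    entry = multistability_census(fm, bank, tol=1e-8, max_beats=300,
                                  polish=False)
    assert entry.order == 1
    assert entry.attractors[0].n_basin_hits == 2


def test_perturbation_identity(surrogate_fast, surrogate_attractors):
    fm = surrogate_fast.system
    fm.set_param("pct_gkr", 40.0)
    cls0, res0 = perturb_and_settle(fm, surrogate_attractors["short"], 0.0)
    assert res0.converged
    assert np.max(np.abs(res0.state - surrogate_attractors["short"])) < 1e-6
    assert cls0 == "noEAD"


def test_perturbation_crosses_basin_boundary(surrogate_fast,
                                             surrogate_attractors):
    """A large enough [Na+]i withdrawal kicks the short AP into the
    depolarised response's basin; verified against the brute-force
    attractor states."""
    fm = surrogate_fast.system
    fm.set_param("pct_gkr", 40.0)
    cls, res = perturb_and_settle(fm, surrogate_attractors["short"], -1.2,
                                  max_beats=400)
    assert res.converged
    assert np.max(np.abs(res.state - surrogate_attractors["lavo"])) < 1e-4
    assert cls in ("LAVO", "arrest")


def test_clamp_census_collapses_to_monostable(surrogate_fast):
    """Freezing [Na+]i removes the slow feedback and with it the
    coexistence: order drops to 1 at every clamp value."""
    base = surrogate_fast.system

    def factory(clamp):
        from eadyn.pacing_sim import PacedFlowMap

        params = base.params.copy(nai_clamp=clamp, pct_gkr=40.0)
        return PacedFlowMap(base.model, params, rtol=1e-8, atol=1e-10,
                            jac_method="fd")

    bank = default_init_bank(6)
    result = nai_fixed_analysis(factory, [5.2, 4.2], bank, tol=5e-8,
                                max_beats=300)
    for clamp, entry in result.items():
        assert entry.order == 1, f"clamp {clamp} not monostable"


def _fake_branch(params, stabilities):
    points = [
        FixedPoint(x=np.array([0.0]), k=1,
                   multipliers=np.array([0.5 if s else 1.5]),
                   residual=0.0, converged=True, n_iter=0)
        for s in stabilities
    ]
    return Branch(points, "p", list(params))


def test_stable_overlap_windows_from_constructed_branches():
    b1 = _fake_branch([0, 1, 2, 3, 4], [True, True, True, True, False])
    b2 = _fake_branch([2, 3, 4, 5], [True, True, True, True])
    assert stable_overlap_windows([b1]) == []
    windows = stable_overlap_windows([b1, b2])
    assert windows == [(2.0, 3.0)]


def test_overlap_window_bounds():
    b1 = _fake_branch([0, 1, 2, 3], [True] * 4)
    b2 = _fake_branch([2, 3, 4, 5], [True] * 4)
    assert stable_overlap_windows([b1, b2]) == [(2.0, 3.0)]
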