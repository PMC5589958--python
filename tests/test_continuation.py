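"""Branch continuation and bifurcation classification vs closed forms."""

import numpy as np
import pytest

from eadyn.continuation import (
    continue_branch,
    detect_crossings,
    find_bifurcations,
    localize_bifurcation,
    post_bifurcation_transition,
    refine_at_param,
)
from eadyn.shooting import newton_shoot
from eadyn.testbed import (
    make_delayed_logistic_map,
    make_forced_linear,
    make_logistic_map,
    make_sn_normal_form,
)


def logistic_branch(r0=2.5, r1=3.4, step=0.05):
    ts = make_logistic_map(r0)
    fp = newton_shoot(ts.system, np.array([0.4]))
    return ts, continue_branch(ts.system, "r", fp.x, (r0, r1), step)


def test_logistic_pd_localized_at_three():
    """The fixed-point multiplier 2 - r crosses -1 at exactly r = 3."""
    ts, br = logistic_branch()
    cands = detect_crossings(br)
    assert [c.kind for c in cands] == ["PD"]
    bp = localize_bifurcation(ts.system, br, cands[0])
    assert bp.kind == "PD"
    assert bp.param_value == pytest.approx(3.0, abs=1e-6)
    assert bp.critical_multiplier.real == pytest.approx(-1.0, abs=1e-6)


def test_branch_multipliers_match_closed_form():
    ts, br = logistic_branch()
    for fp, r in zip(br.points, br.params):
        assert fp.multipliers[0].real == pytest.approx(2.0 - r, abs=1e-9)
        assert fp.x[0] == pytest.approx(1.0 - 1.0 / r, abs=1e-9)


def test_delayed_logistic_ns_localized_at_two():
    """The complex pair modulus sqrt(r - 1) crosses 1 at r = 2."""
    ts = make_delayed_logistic_map(1.5)
    fp = newton_shoot(ts.system, np.array([0.3, 0.3]))
    assert abs(abs(fp.multipliers[0]) - np.sqrt(0.5)) < 1e-9
    br = continue_branch(ts.system, "r", fp.x, (1.5, 2.3), 0.05)
    cands = detect_crossings(br)
    assert any(c.kind == "NS" for c in cands)
    bp = localize_bifurcation(
        ts.system, br, next(c for c in cands if c.kind == "NS"))
    assert bp.param_value == pytest.approx(2.0, abs=1e-6)
    assert abs(bp.critical_multiplier.imag) > 1e-6
    assert abs(abs(bp.critical_multiplier) - 1.0) < 1e-6


def test_sn_fold_rounded_and_localized_at_zero():
    """Pseudo-arclength rounds the fold of x -> x + mu + x^2 and localizes
    it at mu = 0 to 1e-9; the branch continues onto the unstable side."""
    ts = make_sn_normal_form(-0.25)
    fp = newton_shoot(ts.system, np.array([-0.4]))
    assert fp.x[0] == pytest.approx(-0.5, abs=1e-10)
    br = continue_branch(ts.system, "mu", fp.x, (-0.25, 0.1), 0.02)
    stab = br.stability
    assert stab[0] and not stab[-1]  # rounded onto the unstable branch
    cands = detect_crossings(br)
    assert [c.kind for c in cands] == ["SN"]
    bp = localize_bifurcation(ts.system, br, cands[0])
    assert bp.param_value == pytest.approx(0.0, abs=1e-9)
    assert bp.critical_multiplier.real == pytest.approx(1.0, abs=1e-6)


def test_stability_flips_only_at_flagged_crossings():
    for builder, seed, rng_ in (
        (make_logistic_map, [0.4], (2.5, 3.4)),
        (make_sn_normal_form, [-0.4], (-0.25, 0.1)),
    ):
        ts = builder(rng_[0])
        fp = newton_shoot(ts.system, np.array(seed))
        br = continue_branch(ts.system, list(ts.system.params)[0], fp.x,
                             rng_, 0.03)
        flips = [i for i in range(len(br) - 1)
                 if br.stability[i] != br.stability[i + 1]]
        flagged = {c.index for c in detect_crossings(br)}
        assert all(i in flagged for i in flips)


def test_constant_multiplier_branch_has_no_crossings(forced_linear):
    """Continuing the forced linear system in tau: a straight branch whose
    multiplier never touches the unit circle."""
    fm = forced_linear.system
    fp = newton_shoot(fm, np.array([0.1]))
    br = continue_branch(fm, "tau", fp.x, (1000.0, 1500.0), 100.0,
                         tol=1e-9)
    assert detect_crossings(br) == []
    assert all(p.stable for p in br.points)


def test_backward_continuation_reproduces_pd():
    ts, br = logistic_branch(2.5, 3.4, 0.05)
    bp_fwd = find_bifurcations(ts.system, br)[0]
    ts2 = make_logistic_map(3.4)
    fp2 = newton_shoot(ts2.system, np.array([0.7]))
    br2 = continue_branch(ts2.system, "r", fp2.x, (3.4, 2.5), 0.05)
    bp_bwd = find_bifurcations(ts2.system, br2)[0]
    assert bp_fwd.kind == bp_bwd.kind == "PD"
    assert bp_fwd.param_value == pytest.approx(bp_bwd.param_value, abs=1e-6)


def test_post_sn_transition_diverges_in_normal_form():
    """Past the fold the normal form has no attractor: divergence flag."""
    ts = make_sn_normal_form(-0.25)
    fp = newton_shoot(ts.system, np.array([-0.4]))
    br = continue_branch(ts.system, "mu", fp.x, (-0.25, 0.1), 0.02)
    bp = find_bifurcations(ts.system, br)[0]
    res = post_bifurcation_transition(ts.system, bp, beyond=0.01,
                                      max_beats=200)
    assert res.diverged


def test_post_pd_transition_reaches_period_two():
    ts, br = logistic_branch()
    bp = find_bifurcations(ts.system, br)[0]
    res = post_bifurcation_transition(ts.system, bp, beyond=3.2,
                                      max_beats=500, tol=1e-10)
    assert not res.diverged
    assert res.settle.converged
    assert res.settle.period == 2


def test_refine_at_param_matches_closed_form():
    ts, br = logistic_branch()
    fp = refine_at_param(ts.system, br, 2.77, tol=1e-13)
    assert fp is not None
    assert fp.x[0] == pytest.approx(1.0 - 1.0 / 2.77, abs=1e-10)


def test_seed_must_converge():
    ts = make_sn_normal_form(0.2)  # no fixed point at the seed parameter
    with pytest.raises(ValueError, match="seed"):
        continue_branch(ts.system, "mu", np.array([0.0]), (0.2, 0.3), 0.01)
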