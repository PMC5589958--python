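"""Monodromy matrices, characteristic multipliers and Newton shooting."""

import math

import numpy as np
import pytest

from eadyn.pacing_sim import PacedFlowMap, run_to_steady_state
from eadyn.shooting import characteristic_multipliers, monodromy, newton_shoot
from eadyn.testbed import make_sn_normal_form
from eadyn.vm_model import PacingProtocol
from tests.conftest import REST_START


def test_multipliers_sorted_by_modulus():
    m = characteristic_multipliers(np.diag([0.5, -0.2]))
    assert m[0] == pytest.approx(0.5)
    assert m[1] == pytest.approx(-0.2)


def test_multipliers_of_scaled_rotation():
    r, theta = 0.8, 0.7
    M = r * np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
    m = characteristic_multipliers(M)
    assert abs(m[0]) == pytest.approx(r, rel=1e-12)
    assert abs(m[0].imag) == pytest.approx(r * math.sin(theta), rel=1e-12)
    assert m[1] == pytest.approx(np.conj(m[0]))


class _ZeroFieldModel:
    """dy/dt = 0: the cycle map is the identity."""

    state_names = ("a", "b")
    state_scales = np.ones(2)

    def rhs(self, t, y, params, istim=None):
        return np.zeros(2)

    def clamped_indices(self, params):
        return ()


class _ZeroParams:
    pacing = PacingProtocol(amplitude=1.0, duration=1.0, cycle_length=100.0)
    nai_clamp = None


def test_monodromy_of_zero_field_is_identity():
    fm = PacedFlowMap(_ZeroFieldModel(), _ZeroParams(), rtol=1e-10, atol=1e-12)
    x = np.array([0.3, -1.2])
    M_var = monodromy(fm, x, method="variational")
    M_fd = monodromy(fm, x, method="fd")
    assert np.allclose(M_var, np.eye(2), atol=1e-9)
    assert np.allclose(M_fd, np.eye(2), atol=1e-9)


def test_forced_linear_monodromy_closed_form(forced_linear):
    """The 1x1 monodromy is exp(-kT/tau), via the variational equations and
    (independently) via finite differences of the flow."""
    fm = forced_linear.system
    a = forced_linear.known_features["multiplier"]
    x = np.array([0.2])
    M1 = monodromy(fm, x, k=1, method="variational")
    M2 = monodromy(fm, x, k=2, method="variational")
    assert M1[0, 0] == pytest.approx(a, abs=1e-8)
    assert M2[0, 0] == pytest.approx(a * a, abs=1e-8)
    M_fd = fm.monodromy_fd(x)
    assert M_fd[0, 0] == pytest.approx(a, rel=1e-6)


def test_poincare_composition(forced_linear):
    fm = forced_linear.system
    x = np.array([0.7])
    assert fm.map(x, 2) == pytest.approx(fm.map(fm.map(x, 1), 1), abs=1e-9)


def test_newton_zero_iterations_at_fixed_point(forced_linear):
    fm = forced_linear.system
    xstar = forced_linear.known_features["fixed_point"]
    fp = newton_shoot(fm, np.array([xstar]), tol=1e-9)
    assert fp.converged
    assert fp.n_iter <= 1


def test_newton_one_step_on_affine_map(forced_linear):
    """Linearity makes the Newton model exact: any start converges in one
    iteration."""
    fm = forced_linear.system
    for x0 in (-5.0, 0.0, 12.0):
        fp = newton_shoot(fm, np.array([x0]), tol=1e-8)
        assert fp.converged
        assert fp.n_iter == (0 if abs(
            x0 - forced_linear.known_features["fixed_point"]) < 1e-9 else 1)


def test_newton_fails_when_no_fixed_point_exists():
    ts = make_sn_normal_form(0.1)  # past the fold: no fixed point
    fp = newton_shoot(ts.system, np.array([0.0]), tol=1e-10, max_iter=25)
    assert not fp.converged


def test_fd_and_variational_monodromy_agree_on_surrogate(surrogate):
    """The two Jacobian routes must agree to 1e-4 relative at assorted
    physiological states of the paced surrogate."""
    fm = surrogate.system
    fm.set_param("pct_gkr", 40.0)
    rng = np.random.default_rng(11)
    for _ in range(8):
        x = REST_START + rng.normal(size=4) * np.array([3.0, 3e-4, 0.3, 5e-6])
        M_var = fm.monodromy_variational(x)
        M_fd = fm.monodromy_fd(x)
        scale = max(np.max(np.abs(M_var)), 1e-12)
        assert np.max(np.abs(M_var - M_fd)) / scale < 1e-4


def test_stable_fixed_point_confirmed_by_forward_simulation(
    surrogate, surrogate_attractors
):
    """A fixed point reported stable really attracts: 50 beats from a
    perturbed start return to it within 1e-6 (mixed units)."""
    fm = surrogate.system
    fm.set_param("pct_gkr", 40.0)
    fp = newton_shoot(fm, surrogate_attractors["short"], tol=1e-9)
    assert fp.converged and fp.stable
    assert np.all(np.abs(fp.multipliers) < 1.0)  # no trivial +1 multiplier
    x = fp.x + 1e-6 * np.sign(np.arange(4) - 1.5)
    for _ in range(50):
        x = fm.map(x)
    assert np.max(np.abs(x - fp.x)) < 1e-6


def test_multipliers_invariant_under_state_reordering(surrogate):
    """Permuting the state variables must not change the multiplier set."""

    class Permuted:
        def __init__(self, model, perm):
            self.model = model
            self.perm = np.asarray(perm)
            self.inv = np.argsort(self.perm)
            self.state_names = tuple(model.state_names[i] for i in perm)
            self.state_scales = np.asarray(model.state_scales)[self.perm]

        def rhs(self, t, y, params, istim=None):
            return self.model.rhs(t, y[self.inv], params, istim=istim)[self.perm]

        def clamped_indices(self, params):
            return ()

    fm = surrogate.system
    fm.set_param("pct_gkr", 40.0)
    perm = [2, 0, 3, 1]
    pm = PacedFlowMap(Permuted(fm.model, perm), fm.params,
                      rtol=fm.rtol, atol=fm.atol, jac_method="fd")
    x = REST_START
    m_orig = np.sort(np.abs(characteristic_multipliers(fm.monodromy_fd(x))))
    m_perm = np.sort(np.abs(characteristic_multipliers(
        pm.monodromy_fd(x[perm]))))
    assert np.allclose(m_orig, m_perm, atol=1e-6)


def test_near_singular_shooting_matrix_reported(surrogate):
    """Close to the fold the shooting matrix becomes near-singular; this is
    reported as a detection signal, not raised."""
    fm = surrogate.system
    fm.set_param("pct_gkr", 35.6)
    res = run_to_steady_state(fm, REST_START, max_beats=400, tol=1e-8)
    fp = newton_shoot(fm, res.state, tol=1e-8)
    assert fp.converged
    assert fp.min_singular_value < 5e-2
    fm.set_param("pct_gkr", 40.0)
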