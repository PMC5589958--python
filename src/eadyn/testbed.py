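"""Synthetic test-bed systems with analytically known dynamical structure.

Every pipeline stage (shooting, monodromy, multiplier classification,
continuation, sweeps, census) is validated against these systems before it
is trusted on an ionic model:

* discrete maps with closed-form fixed points and multipliers (logistic,
  delayed logistic, saddle-node normal form) -- maps *are* their own
  Poincare maps, so they isolate the continuation/classification logic from
  integration error;
* a forced linear ODE whose stroboscopic map is affine with multiplier
  ``exp(-T/tau)`` known in closed form;
* the bundled paced-myocyte surrogate in a deliberately bistable (and a
  deliberately monostable) configuration.

Declared ``known_features`` are frozen constants; the test suite re-derives
each of them with the package's own machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .dynsys import MapSystem, StroboscopicSystem
from .pacing_sim import PacedFlowMap
from .vm_model import MinimalMyocyteModel, ModelParams, PacingProtocol

__all__ = [
    "TestSystem",
    "ForcedLinearModel",
    "make_logistic_map",
    "make_delayed_logistic_map",
    "make_sn_normal_form",
    "make_forced_linear",
    "make_paced_surrogate_ap",
    "SURROGATE_PACING",
    "SURROGATE_BISTABLE_WINDOW",
    "SURROGATE_SN_PCT",
    "SURROGATE_DESTAB_PCT",
]

#: pacing used by the surrogate (same pulse shape, shorter cycle)
SURROGATE_PACING = dict(amplitude=80.0, duration=1.0, cycle_length=1400.0)

#: %GKr window over which the bistable surrogate holds two stable period-1
#: responses (short AP vs depolarised long response); bounded below by the
#: SN fold of the short-AP branch and above by the destabilisation of the
#: long branch, where a real multiplier leaves the unit circle through +1
#: across a very sharp boundary layer.  A stable period-2 alternans orbit
#: additionally coexists over roughly 39-44.5 %GKr (tristability).
#: Re-derived by the census/continuation tests.
SURROGATE_BISTABLE_WINDOW = (35.42, 44.61)
SURROGATE_SN_PCT = 35.421  # fold of the short-AP branch (%GKr)
SURROGATE_DESTAB_PCT = 44.605  # stability loss of the long branch (%GKr)


@dataclass
class TestSystem:
    """A validation system plus its declared (closed-form or brute-force
    verified) dynamical features."""

    kind: str  # "map" | "forced_ode"
    name: str
    system: StroboscopicSystem
    known_features: dict = dc_field(default_factory=dict)
    model: object | None = None
    params: ModelParams | None = None


# ---------------------------------------------------------------------------
# discrete maps


def make_logistic_map(r: float = 2.5) -> TestSystem:
    """Logistic map ``x -> r x (1 - x)``.

    Fixed point ``x* = 1 - 1/r`` with multiplier ``2 - r``; period doubling
    where the multiplier reaches -1, at ``r = 3``.
    """

    def f(x, p):
        return np.array([p["r"] * x[0] * (1.0 - x[0])])

    def jac(x, p):
        return np.array([[p["r"] * (1.0 - 2.0 * x[0])]])

    sys = MapSystem(f, {"r": r}, 1, jac=jac, state_names=("x",), name="logistic")
    return TestSystem(
        kind="map",
        name="logistic",
        system=sys,
        known_features={
            "fixed_point": lambda r: 1.0 - 1.0 / r,
            "multiplier": lambda r: 2.0 - r,
            "pd_at": 3.0,
        },
    )


def make_delayed_logistic_map(r: float = 1.5) -> TestSystem:
    """Delayed logistic map ``(x, y) -> (r x (1 - y), x)``.

    Nontrivial fixed point ``(1 - 1/r, 1 - 1/r)``; its Jacobian has trace 1
    and determinant ``r - 1``, so for ``r > 1.25`` the multipliers are a
    complex pair of modulus ``sqrt(r - 1)`` -- a Neimark-Sacker bifurcation
    where the modulus reaches 1, at ``r = 2``.
    """

    def f(x, p):
        return np.array([p["r"] * x[0] * (1.0 - x[1]), x[0]])

    def jac(x, p):
        return np.array([[p["r"] * (1.0 - x[1]), -p["r"] * x[0]], [1.0, 0.0]])

    sys = MapSystem(f, {"r": r}, 2, jac=jac, state_names=("x", "y"),
                    name="delayed_logistic")
    return TestSystem(
        kind="map",
        name="delayed_logistic",
        system=sys,
        known_features={
            "fixed_point": lambda r: 1.0 - 1.0 / r,
            "multiplier_modulus": lambda r: math.sqrt(r - 1.0),
            "ns_at": 2.0,
        },
    )


def make_sn_normal_form(mu: float = -0.25) -> TestSystem:
    """Saddle-node normal form ``x -> x + mu + x^2``.

    For ``mu < 0`` the fixed points are ``x* = +/- sqrt(-mu)`` with
    multipliers ``1 + 2 x*``; they coalesce and annihilate in a fold at
    ``mu = 0`` (no fixed point for ``mu > 0``).
    """

    def f(x, p):
        return np.array([x[0] + p["mu"] + x[0] ** 2])

    def jac(x, p):
        return np.array([[1.0 + 2.0 * x[0]]])

    sys = MapSystem(f, {"mu": mu}, 1, jac=jac, state_names=("x",),
                    name="sn_normal_form")
    return TestSystem(
        kind="map",
        name="sn_normal_form",
        system=sys,
        known_features={
            "fixed_points": lambda mu: (
                (-math.sqrt(-mu), math.sqrt(-mu)) if mu <= 0 else ()
            ),
            "multiplier": lambda x: 1.0 + 2.0 * x,
            "sn_at": 0.0,
        },
    )


# ---------------------------------------------------------------------------
# forced linear ODE


class ForcedLinearModel:
    """``x' = -x / tau + Istim(t)``: the one-variable forced linear system.

    Its stroboscopic map is affine, ``P(x) = a x + c`` with
    ``a = exp(-T/tau)`` and
    ``c = A tau (1 - exp(-d/tau)) exp(-(T - d)/tau)`` for pulse amplitude
    ``A`` and duration ``d``; the unique fixed point ``c / (1 - a)`` is
    known in closed form, which makes this the primary integration oracle.
    """

    state_names = ("x",)
    state_scales = np.ones(1)

    def __init__(self, tau: float):
        self.tau = float(tau)

    def rhs(self, t, y, params, istim=None):
        if istim is None:
            istim = params.pacing.istim(t)
        return np.array([-y[0] / self.tau + istim])

    def clamped_indices(self, params):
        return ()

    # closed forms -----------------------------------------------------
    def strobe_affine(self, pacing: PacingProtocol) -> tuple[float, float]:
        a = math.exp(-pacing.cycle_length / self.tau)
        c = (
            pacing.amplitude
            * self.tau
            * (1.0 - math.exp(-pacing.duration / self.tau))
            * math.exp(-(pacing.cycle_length - pacing.duration) / self.tau)
        )
        return a, c

    def fixed_point(self, pacing: PacingProtocol) -> float:
        a, c = self.strobe_affine(pacing)
        return c / (1.0 - a)


@dataclass
class _LinearParams:
    pacing: PacingProtocol
    tau: float = 1000.0
    nai_clamp: None = None


def make_forced_linear(
    tau: float = 1000.0,
    cycle_length: float = 2000.0,
    amplitude: float = 1.0,
    duration: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> TestSystem:
    model = ForcedLinearModel(tau)
    pacing = PacingProtocol(amplitude=amplitude, duration=duration,
                            cycle_length=cycle_length)
    params = _LinearParams(pacing=pacing, tau=tau)
    # the closed-form oracle carries a full-precision Jacobian as well
    fm = PacedFlowMap(model, params, rtol=rtol, atol=atol, method="LSODA",
                      var_rtol=rtol, var_atol=atol)
    a, c = model.strobe_affine(pacing)
    return TestSystem(
        kind="forced_ode",
        name="forced_linear",
        system=fm,
        model=model,
        known_features={
            "multiplier": a,
            "offset": c,
            "fixed_point": model.fixed_point(pacing),
        },
    )


# ---------------------------------------------------------------------------
# paced surrogate myocyte


def make_paced_surrogate_ap(
    bistable: bool = True,
    pct_gkr: float = 40.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    nai_clamp: float | None = None,
    jac_method: str = "fd",
) -> TestSystem:
    """The bundled paced-myocyte surrogate.

    ``bistable=True`` uses the frozen :class:`MinimalMyocyteModel`
    constants, for which a short-AP and a depolarised long-response
    period-1 attractor coexist across ``SURROGATE_BISTABLE_WINDOW`` in
    ``pct_gkr`` (fold of the short branch at the lower edge; the long
    response destabilises at the upper edge).  ``bistable=False`` weakens
    the L-type window current (the inactivation midpoint is shifted 10 mV
    negative) which removes the steep [Na+]i feedback and with it the
    coexistence; the census then finds a single attractor across the same
    window.
    """
    if bistable:
        model = MinimalMyocyteModel()
    else:
        model = MinimalMyocyteModel(v_f_mid=-34.0)
    params = ModelParams(
        pct_gkr=pct_gkr,
        pacing=PacingProtocol(**SURROGATE_PACING),
        nai_clamp=nai_clamp,
    )
    fm = PacedFlowMap(model, params, rtol=rtol, atol=atol, method="LSODA",
                      jac_method=jac_method)
    # arclength metric sized to the branch-scale variation of each variable
    fm.continuation_weights_full = np.array([10.0, 1.0, 0.1, 1e-4])
    features = {
        "bistable": bistable,
        "window": SURROGATE_BISTABLE_WINDOW if bistable else None,
        "sn_pct": SURROGATE_SN_PCT if bistable else None,
        "destab_pct": SURROGATE_DESTAB_PCT if bistable else None,
        "param_name": "pct_gkr",
    }
    return TestSystem(
        kind="forced_ode",
        name="paced_surrogate_ap",
        system=fm,
        model=model,
        params=params,
        known_features=features,
    )
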