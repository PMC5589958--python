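"""Beat-by-beat integration of paced models and steady-state detection.

Integration is segmented at the stimulus-pulse edges so the square-pulse
discontinuity never falls inside an adaptive step.  Convergence of a paced
response is judged on the *stroboscopic samples* -- the state at each
stimulus onset -- using a maximum absolute component-wise difference across
consecutive (or period-k separated) beats, applied to the raw mixed-unit
state values with a default tolerance of 1e-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynsys import StroboscopicSystem
from .vm_model import CurrentSet, ModelParams

__all__ = [
    "BeatTrace",
    "SteadyStateResult",
    "IntegrationError",
    "integrate_cycle",
    "simulate_beats",
    "run_to_steady_state",
    "stroboscopic_sample",
    "PacedFlowMap",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_METHOD = "LSODA"


class IntegrationError(RuntimeError):
    """Integrator failure, annotated with the beat index and last valid state."""

    def __init__(self, message: str, beat_index: int | None = None, last_state=None):
        super().__init__(message)
        self.beat_index = beat_index
        self.last_state = last_state


@dataclass
class BeatTrace:
    """Sampled trajectory of one pacing cycle; ``t = 0`` is stimulus onset."""

    t: np.ndarray
    states: np.ndarray  # (n_samples, n_state)
    state_names: tuple[str, ...]
    beat_index: int = 0
    currents: pd.DataFrame | None = None

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    @property
    def vm(self) -> np.ndarray:
        return self.column("Vm")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, "t", self.t)
        df.insert(0, "beat_index", self.beat_index)
        return df


@dataclass
class SteadyStateResult:
    """Outcome of iterating the stroboscopic samples to convergence."""

    state: np.ndarray
    converged: bool
    beats_used: int
    residual: float
    period: int = 1
    merged_with: int | None = None
    residuals: list = field(default_factory=list)


def _segments(t0: float, pacing) -> list[tuple[float, float, float]]:
    """(start, stop, istim) integration segments covering one cycle."""
    return [
        (t0, t0 + pacing.duration, pacing.amplitude),
        (t0 + pacing.duration, t0 + pacing.cycle_length, 0.0),
    ]


def integrate_cycle(
    model,
    params: ModelParams,
    x0: np.ndarray,
    t0: float = 0.0,
    n_samples: int | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
    beat_index: int = 0,
) -> tuple[np.ndarray, BeatTrace | None]:
    """Integrate one pacing cycle; return the end state and optional trace.

    ``n_samples`` requests that many evenly spaced output samples across the
    cycle (the first at stimulus onset); ``None`` integrates endpoint-only.
    """
    x = np.asarray(x0, dtype=float)
    want_trace = n_samples is not None
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    T = params.pacing.cycle_length
    if want_trace:
        t_all = t0 + np.linspace(0.0, T, int(n_samples), endpoint=True)
    for a, b, amp in _segments(t0, params.pacing):
        t_eval = None
        if want_trace:
            mask = (t_all >= a) & (t_all < b) if b < t0 + T else (t_all >= a)
            t_eval = np.unique(np.concatenate(([a], t_all[mask], [b])))
        sol = solve_ivp(
            lambda t, y: model.rhs(t, y, params, istim=amp),
            (a, b),
            x,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed in [{a:g}, {b:g}] ms: {sol.message}",
                beat_index=beat_index,
                last_state=x,
            )
        x = sol.y[:, -1].copy()
        if want_trace:
            ts.append(sol.t)
            ys.append(sol.y.T)
    trace = None
    if want_trace:
        t_cat = np.concatenate(ts)
        y_cat = np.vstack(ys)
        keep = np.concatenate(([True], np.diff(t_cat) > 0))
        states = y_cat[keep]
        # pin the endpoints so the carried state and the trace agree bit
        # for bit (dense-output interpolation can differ in the last ulp)
        states[0] = np.asarray(x0, dtype=float)
        x = states[-1].copy()
        trace = BeatTrace(
            t=t_cat[keep] - t0,
            states=states,
            state_names=tuple(model.state_names),
            beat_index=beat_index,
        )
    return x, trace


def simulate_beats(
    model,
    params: ModelParams,
    x0: np.ndarray,
    n_beats: int,
    n_samples: int | None = None,
    with_currents: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> list[BeatTrace]:
    """Integrate ``n_beats`` consecutive paced cycles, returning their traces.

    The final state of beat ``k`` is, bit for bit, the initial state of beat
    ``k + 1``.  Sampling defaults to at least 2 kHz equivalent.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if n_samples is None:
        n_samples = max(int(math.ceil(params.pacing.cycle_length / 0.5)) + 1, 64)
    traces = []
    x = np.asarray(x0, dtype=float)
    for b in range(n_beats):
        x, trace = integrate_cycle(
            model, params, x, n_samples=n_samples,
            rtol=rtol, atol=atol, method=method, beat_index=b,
        )
        if with_currents:
            rows = [
                model.compute_currents(trace.states[i], trace.t[i], params)
                for i in range(len(trace.t))
            ]
            trace.currents = pd.DataFrame(
                {
                    name: [getattr(r, name) for r in rows]
                    for name in (*CurrentSet.FIELD_ORDER, "Istim", "inet",
                                 "jna_net", "jca_net")
                }
            )
        traces.append(trace)
    return traces


def stroboscopic_sample(trace: BeatTrace) -> np.ndarray:
    """State at stimulus onset (the Poincare-section sample of the beat)."""
    return trace.states[0].copy()


def run_to_steady_state(
    system: StroboscopicSystem,
    x0: np.ndarray,
    max_beats: int = 1000,
    tol: float = 1e-8,
    detect_periods: tuple[int, ...] = (1, 2, 4),
    stop_near: list[np.ndarray] | None = None,
    merge_tol: float = 1e-7,
) -> SteadyStateResult:
    """Iterate stroboscopic samples until the period-1 (or period-k) residual
    drops below ``tol``.

    Non-convergence within ``max_beats`` is *not* an error: alternans and
    quasiperiodic responses legitimately fail period-1 convergence and are
    returned with ``converged=False`` for period-k analysis.  A detected
    period k > 1 is reported in ``period`` (the k-beat residual met ``tol``
    while the 1-beat residual did not).

    ``stop_near`` (used by the multistability census) lets the iteration
    stop early once the sample comes within ``merge_tol`` of an already
    known attractor state; such a result carries ``merged_with`` and is not
    marked converged, since the 1e-8 criterion was not itself met.
    """
    if max_beats < 2:
        raise ValueError("max_beats must be >= 2")
    history = [np.asarray(x0, dtype=float)]
    residuals: list[float] = []
    x = history[0]
    pmax = max(detect_periods)
    for beat in range(1, max_beats + 1):
        x = system.map(x)
        history.append(x)
        if len(history) > pmax + 1:
            history.pop(0)
        res1 = float(np.max(np.abs(x - history[-2])))
        residuals.append(res1)
        if res1 < tol:
            return SteadyStateResult(x, True, beat, res1, 1, residuals=residuals)
        for p in detect_periods:
            if p > 1 and len(history) > p:
                resp = float(np.max(np.abs(x - history[-1 - p])))
                if resp < tol:
                    return SteadyStateResult(
                        x, True, beat, resp, p, residuals=residuals
                    )
        if stop_near is not None:
            for i, a in enumerate(stop_near):
                if float(np.max(np.abs(x - a))) < merge_tol:
                    return SteadyStateResult(
                        x, False, beat, res1, 1, merged_with=i,
                        residuals=residuals,
                    )
    return SteadyStateResult(x, False, max_beats, residuals[-1], 1,
                             residuals=residuals)


class PacedFlowMap(StroboscopicSystem):
    """Stroboscopic Poincare map of a paced ODE model.

    Wraps an ionic (or surrogate) model plus its :class:`ModelParams` and
    exposes the one-cycle flow as a discrete map in the model's *free*
    coordinates: when a variable is clamped (e.g. the [Na+]i-fixed system)
    it is removed from the map's state, so the monodromy matrix and the
    multiplier count reflect the effective dimension.

    The Jacobian of the map (monodromy matrix) is computed by integrating
    the variational equations alongside the flow, with the right-hand-side
    Jacobian obtained by central finite differences of the model ``rhs``
    using per-variable-class step scaling.
    """

    def __init__(
        self,
        model,
        params: ModelParams,
        rtol: float = DEFAULT_RTOL,
        atol: float = DEFAULT_ATOL,
        method: str = DEFAULT_METHOD,
        fd_rel: float = 1e-6,
        jac_method: str = "variational",
        fd_rel_map: float = 1e-3,
        var_rtol: float | None = None,
        var_atol: float | None = None,
    ):
        if jac_method not in ("variational", "fd"):
            raise ValueError("jac_method must be 'variational' or 'fd'")
        self.model = model
        self.params = params
        self.rtol = rtol
        self.atol = atol
        # the variational (Jacobian) integration needs far less accuracy
        # than the map itself; by default it is capped at 1e-8 relative
        self.var_rtol = max(rtol, 1e-8) if var_rtol is None else var_rtol
        self.var_atol = max(atol, 1e-10) if var_atol is None else var_atol
        self.method = method
        # rhs-level FD step factor (variational route); the map-level factor
        # must sit well above the integration noise floor, so it is larger
        self.fd_rel = fd_rel
        self.fd_rel_map = fd_rel_map
        self.jac_method = jac_method
        # optional full-space weights for the continuation arclength metric
        # (branch-scale variation, not absolute magnitude); None -> scales
        self.continuation_weights_full: np.ndarray | None = None

    # --- coordinate bookkeeping -------------------------------------
    @property
    def _n_full(self) -> int:
        return len(self.model.state_names)

    @property
    def active_indices(self) -> list[int]:
        clamped = set(self.model.clamped_indices(self.params))
        return [i for i in range(self._n_full) if i not in clamped]

    @property
    def dimension(self) -> int:
        return len(self.active_indices)

    @property
    def state_names(self) -> tuple[str, ...]:  # type: ignore[override]
        return tuple(self.model.state_names[i] for i in self.active_indices)

    @property
    def state_scales(self) -> np.ndarray:
        return np.asarray(self.model.state_scales, dtype=float)[self.active_indices]

    @property
    def continuation_weights(self) -> np.ndarray:
        if self.continuation_weights_full is None:
            return self.state_scales
        return np.asarray(self.continuation_weights_full, dtype=float)[
            self.active_indices
        ]

    def to_full(self, x: np.ndarray) -> np.ndarray:
        """Embed a free-coordinate vector into the full model state."""
        full = np.empty(self._n_full)
        full[self.active_indices] = x
        for i in self.model.clamped_indices(self.params):
            # clamped value supplied by params (single clamp: Nai)
            full[i] = self.params.nai_clamp
        return full

    def from_full(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float)[self.active_indices]

    # --- map interface ----------------------------------------------
    def map(self, x: np.ndarray, k: int = 1) -> np.ndarray:
        y = self.to_full(np.asarray(x, dtype=float))
        for _ in range(k):
            y, _ = integrate_cycle(
                self.model, self.params, y,
                rtol=self.rtol, atol=self.atol, method=self.method,
            )
        return self.from_full(y)

    def map_with_jacobian(
        self, x: np.ndarray, k: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        if self.jac_method == "fd":
            return self.map(x, k), self.jacobian_fd(x, k, rel_step=self.fd_rel_map)
        # the map at full precision, the Jacobian at the (looser)
        # variational tolerance -- residuals must be resolved tightly,
        # Jacobians need only a few significant digits
        return self.map(x, k), self.monodromy_variational(x, k)

    def monodromy_variational(self, x: np.ndarray, k: int = 1) -> np.ndarray:
        """Variational-equation monodromy regardless of ``jac_method``."""
        y = self.to_full(np.asarray(x, dtype=float))
        Phi = np.eye(self.dimension)
        for _ in range(k):
            y, M = self._variational_cycle(y)
            Phi = M @ Phi
        return Phi

    def monodromy_fd(self, x: np.ndarray, k: int = 1,
                     rel_step: float | None = None):
        """Finite-difference monodromy (independent cross-check route)."""
        return self.jacobian_fd(
            x, k, rel_step=self.fd_rel_map if rel_step is None else rel_step
        )

    # --- variational equations --------------------------------------
    def _rhs_jacobian(self, t: float, y: np.ndarray, istim: float) -> np.ndarray:
        """Jacobian of the model rhs w.r.t. the active variables (central FD)."""
        act = self.active_indices
        scales = np.asarray(self.model.state_scales, dtype=float)
        J = np.empty((len(act), len(act)))
        for col, j in enumerate(act):
            h = self.fd_rel * scales[j]
            yp = y.copy()
            ym = y.copy()
            yp[j] += h
            ym[j] -= h
            dp = self.model.rhs(t, yp, self.params, istim=istim)
            dm = self.model.rhs(t, ym, self.params, istim=istim)
            J[:, col] = (dp[act] - dm[act]) / (2.0 * h)
        return J

    def _variational_cycle(self, y0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nf = self._n_full
        na = self.dimension
        act = self.active_indices

        def aug_rhs(t, z, istim):
            y = z[:nf]
            dy = self.model.rhs(t, y, self.params, istim=istim)
            J = self._rhs_jacobian(t, y, istim)
            Phi = z[nf:].reshape(na, na)
            return np.concatenate([dy, (J @ Phi).ravel()])

        z = np.concatenate([y0, np.eye(na).ravel()])
        for a, b, amp in _segments(0.0, self.params.pacing):
            sol = solve_ivp(
                lambda t, zz: aug_rhs(t, zz, amp),
                (a, b), z, method=self.method,
                rtol=self.var_rtol, atol=self.var_atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"variational integration failed in [{a:g}, {b:g}] ms: "
                    f"{sol.message}", last_state=z[:nf],
                )
            z = sol.y[:, -1]
        return z[:nf].copy(), z[nf:].reshape(na, na).copy()

    # --- parameters ---------------------------------------------------
    def get_param(self, name: str) -> float:
        return float(getattr(self.params, name))

    def set_param(self, name: str, value: float) -> None:
        if not hasattr(self.params, name):
            raise KeyError(f"unknown parameter {name!r}")
        setattr(self.params, name, float(value))
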