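"""Predictor-corrector continuation of periodic responses and bifurcation
classification.

Branches of period-k fixed points of the stroboscopic map are traced in one
parameter with a secant predictor and pseudo-arclength corrector, so that
saddle-node folds are rounded and the unstable segments between folds are
computed -- the structure a natural-parameter sweep cannot reach.

Bifurcations are detected from the characteristic multipliers along the
branch and classified by how the unit circle is crossed:

* SN (saddle-node): a real multiplier crosses +1; the branch folds in the
  parameter and a stable/unstable pair coalesces and annihilates.
* PD (period-doubling): a real multiplier crosses -1; the response is
  destabilised and a period-doubled orbit is born nearby.
* NS (Neimark-Sacker): a complex-conjugate pair crosses the unit circle;
  a quasi-periodic response may appear.

Localization refines a detected crossing by bisection *along the branch*
(in arclength), which remains well-posed at folds where the parameter
itself is not monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynsys import StroboscopicSystem
from .shooting import FixedPoint, characteristic_multipliers
from .pacing_sim import run_to_steady_state, SteadyStateResult

__all__ = [
    "Branch",
    "BifurcationPoint",
    "CandidateBracket",
    "TransitionResult",
    "continue_branch",
    "detect_crossings",
    "localize_bifurcation",
    "post_bifurcation_transition",
    "find_bifurcations",
    "refine_at_param",
]

IMAG_TOL = 1e-6  # below this |Im|, a multiplier is treated as real


@dataclass
class Branch:
    """An ordered set of fixed points traced in one parameter."""

    points: list[FixedPoint]
    param_name: str
    param_values: list[float]
    k: int = 1

    def __len__(self) -> int:
        return len(self.points)

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.param_values, dtype=float)

    @property
    def stability(self) -> np.ndarray:
        return np.array([fp.stable for fp in self.points], dtype=bool)

    def stable_intervals(self) -> list[tuple[float, float]]:
        """Parameter intervals over which consecutive branch points are stable."""
        out: list[tuple[float, float]] = []
        lam = self.params
        st = self.stability
        i = 0
        while i < len(st):
            if st[i]:
                j = i
                while j + 1 < len(st) and st[j + 1]:
                    j += 1
                seg = lam[i : j + 1]
                out.append((float(seg.min()), float(seg.max())))
                i = j + 1
            else:
                i += 1
        return out


@dataclass
class CandidateBracket:
    """Two consecutive branch points between which a multiplier crossing
    (or parameter fold) was flagged."""

    index: int  # bracket is (index, index + 1)
    kind: str  # "SN" | "PD" | "NS"
    multiplier_before: complex
    multiplier_after: complex


@dataclass
class BifurcationPoint:
    param_value: float
    kind: str  # "SN" | "PD" | "NS"
    critical_multiplier: complex
    x: np.ndarray
    localization_width: float
    branch_param_name: str
    multipliers: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "param": self.branch_param_name,
            "param_value": float(self.param_value),
            "type": self.kind,
            "critical_multiplier": [
                float(self.critical_multiplier.real),
                float(self.critical_multiplier.imag),
            ],
            "x": [float(v) for v in self.x],
            "localization_width": float(self.localization_width),
        }


@dataclass
class TransitionResult:
    """Destination of the system after a bifurcation removes/destabilises
    the followed response (for the initial condition supplied -- under
    multistability other destinations exist)."""

    param_value: float
    diverged: bool
    settle: SteadyStateResult | None
    note: str = ""


# ---------------------------------------------------------------------------
# corrector machinery


def _state_weights(system: StroboscopicSystem) -> np.ndarray:
    """Arclength-metric weights: branch-scale variation per component.

    Systems may expose ``continuation_weights`` when their absolute state
    scales (mV, mM) are much larger than the variation along a branch --
    the metric must see the state move, or folds cannot be rounded.
    """
    w = getattr(system, "continuation_weights", None)
    if w is None:
        w = system.state_scales
    return np.asarray(w, dtype=float)


def _param_jacobian(system, x, lam, param_name, k, h):
    system.set_param(param_name, lam + h)
    pp = system.map(x, k)
    system.set_param(param_name, lam - h)
    pm = system.map(x, k)
    system.set_param(param_name, lam)
    return (pp - pm) / (2.0 * h)


def _corrector(
    system: StroboscopicSystem,
    param_name: str,
    u_pred: np.ndarray,
    tangent: np.ndarray,
    w: np.ndarray,
    k: int,
    tol: float,
    max_iter: int = 20,
):
    """Newton on [P^k(x;lam) - x ; tangent . (u - u_pred)/w] = 0.

    Returns ``(x, lam, J_map, residual)`` or ``None`` on failure.  ``u`` is
    the physical (state, param) vector; the hyperplane constraint is
    applied in scaled coordinates with weights ``w``.
    """
    n = system.dimension
    u = u_pred.copy()
    h_lam = 1e-6 * max(abs(u_pred[-1]), w[-1])
    for _ in range(max_iter):
        x, lam = u[:-1], float(u[-1])
        system.set_param(param_name, lam)
        try:
            Px, J = system.map_with_jacobian(x, k)
        except Exception:
            return None
        r = Px - x
        g = float(tangent @ ((u - u_pred) / w))
        rnorm = float(np.max(np.abs(r)))
        if rnorm < tol and abs(g) < 1e-12:
            return x, lam, J, rnorm
        dPdlam = _param_jacobian(system, x, lam, param_name, k, h_lam)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J - np.eye(n)
        A[:n, n] = dPdlam
        A[n, :] = tangent / w
        rhs = -np.concatenate([r, [g]])
        try:
            du = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(du)):
            return None
        u = u + du
    # final check
    x, lam = u[:-1], float(u[-1])
    system.set_param(param_name, lam)
    try:
        Px, J = system.map_with_jacobian(x, k)
    except Exception:
        return None
    r = Px - x
    rnorm = float(np.max(np.abs(r)))
    if rnorm < tol:
        return x, lam, J, rnorm
    return None


def _natural_point(system, param_name, lam, x_guess, k, tol):
    from .shooting import newton_shoot

    system.set_param(param_name, lam)
    fp = newton_shoot(system, x_guess, k=k, tol=tol)
    return fp if fp.converged else None


def _make_fp(system, x, J, lam, k, rnorm) -> FixedPoint:
    sv = np.linalg.svd(J - np.eye(len(x)), compute_uv=False)
    snapshot = {}
    params = getattr(system, "params", None)
    if isinstance(params, dict):
        snapshot = {kk: v for kk, v in params.items() if np.isscalar(v)}
    return FixedPoint(
        x=x.copy(),
        k=k,
        multipliers=characteristic_multipliers(J),
        residual=rnorm,
        converged=True,
        n_iter=0,
        min_singular_value=float(sv[-1]),
        param_snapshot=snapshot,
    )


# ---------------------------------------------------------------------------
# branch continuation


def continue_branch(
    system: StroboscopicSystem,
    param_name: str,
    x_seed: np.ndarray,
    param_range: tuple[float, float],
    initial_step: float,
    k: int = 1,
    tol: float = 1e-9,
    ds_min: float = 1e-4,
    ds_max: float = 1.0,
    max_points: int = 400,
    param_scale: float | None = None,
) -> Branch:
    """Trace a branch of period-k fixed points across ``param_range``.

    The seed is corrected at the *first* end of ``param_range``; stepping
    proceeds toward the second end.  Pseudo-arclength parametrisation lets
    the branch round folds onto its unstable side; the step is halved on
    corrector failure, grown by 1.3x after three consecutive successes and
    kept within ``[ds_min, ds_max]`` (measured in the scaled arclength).
    """
    lam0, lam1 = float(param_range[0]), float(param_range[1])
    direction = 1.0 if lam1 >= lam0 else -1.0
    if param_scale is None:
        param_scale = max(abs(initial_step), 1e-6)
    w = np.concatenate([_state_weights(system), [param_scale]])

    fp0 = _natural_point(system, param_name, lam0, np.asarray(x_seed, float), k, tol)
    if fp0 is None:
        raise ValueError("seed failed to converge at the start of the range")
    points = [fp0]
    lams = [lam0]
    xs = [fp0.x]

    # second point by a natural-parameter step (halved until it converges)
    step = direction * abs(initial_step)
    fp1 = None
    while abs(step) >= ds_min * param_scale * 1e-3:
        fp1 = _natural_point(system, param_name, lam0 + step, fp0.x, k, tol)
        if fp1 is not None:
            break
        step *= 0.5
    if fp1 is None:
        return Branch(points, param_name, lams, k)
    points.append(fp1)
    lams.append(lam0 + step)
    xs.append(fp1.x)

    u_prev = np.concatenate([xs[-2], [lams[-2]]])
    u_curr = np.concatenate([xs[-1], [lams[-1]]])
    ds = float(np.linalg.norm((u_curr - u_prev) / w))
    ds = min(max(ds, ds_min), ds_max)
    successes = 0
    lo, hi = min(lam0, lam1), max(lam0, lam1)

    while len(points) < max_points:
        secant = (u_curr - u_prev) / w
        nrm = np.linalg.norm(secant)
        if nrm == 0.0:
            break
        tangent = secant / nrm
        u_pred = u_curr + ds * tangent * w
        res = _corrector(system, param_name, u_pred, tangent, w, k, tol)
        if res is None:
            successes = 0
            ds *= 0.5
            if ds < ds_min:
                break
            continue
        x_new, lam_new, J_new, rnorm = res
        u_new = np.concatenate([x_new, [lam_new]])
        progress = np.linalg.norm((u_new - u_curr) / w)
        # no-progress guard (fold accumulation) and branch-jump guard: the
        # corrected point must stay commensurate with the predictor step,
        # otherwise the corrector slid onto a different (coexisting) branch
        if progress < ds * 1e-3 or progress > 4.0 * ds:
            successes = 0
            ds *= 0.5
            if ds < ds_min:
                break
            continue
        points.append(_make_fp(system, x_new, J_new, lam_new, k, rnorm))
        lams.append(lam_new)
        u_prev, u_curr = u_curr, u_new
        successes += 1
        if successes >= 3:
            ds = min(ds * 1.3, ds_max)
            successes = 0
        if not (lo - param_scale * 1e-9 <= lam_new <= hi + param_scale * 1e-9):
            break
    system.set_param(param_name, lams[-1])
    return Branch(points, param_name, lams, k)


# ---------------------------------------------------------------------------
# crossing detection


def _match_multipliers(m0: np.ndarray, m1: np.ndarray) -> list[tuple[complex, complex]]:
    """Pair multipliers of consecutive branch points by nearest neighbour."""
    from scipy.optimize import linear_sum_assignment

    m0 = np.asarray(m0)
    m1 = np.asarray(m1)
    cost = np.abs(m0[:, None] - m1[None, :])
    ri, ci = linear_sum_assignment(cost)
    return [(complex(m0[i]), complex(m1[j])) for i, j in zip(ri, ci)]


def _is_real(m: complex) -> bool:
    return abs(m.imag) <= IMAG_TOL * max(1.0, abs(m))


def detect_crossings(branch: Branch) -> list[CandidateBracket]:
    """Flag consecutive point pairs where a multiplier crosses the unit
    circle: through +1 (SN, co-detected with a parameter fold), through -1
    (PD), or as a complex pair by modulus (NS)."""
    out: list[CandidateBracket] = []
    lam = branch.params
    for i in range(len(branch) - 1):
        fp0, fp1 = branch.points[i], branch.points[i + 1]
        pairs = _match_multipliers(fp0.multipliers, fp1.multipliers)
        seen_ns = False
        for m0, m1 in pairs:
            if _is_real(m0) and _is_real(m1):
                if (m0.real - 1.0) * (m1.real - 1.0) < 0.0:
                    out.append(CandidateBracket(i, "SN", m0, m1))
                elif (m0.real + 1.0) * (m1.real + 1.0) < 0.0:
                    out.append(CandidateBracket(i, "PD", m0, m1))
            else:
                if (abs(m0) - 1.0) * (abs(m1) - 1.0) < 0.0 and not seen_ns:
                    if max(abs(m0.imag), abs(m1.imag)) > IMAG_TOL:
                        out.append(CandidateBracket(i, "NS", m0, m1))
                        seen_ns = True  # conjugate pair counted once
        # parameter fold without a flagged +1 crossing (coarse steps)
        if 0 < i and not any(b.index == i and b.kind == "SN" for b in out):
            d0 = lam[i] - lam[i - 1]
            d1 = lam[i + 1] - lam[i]
            if d0 * d1 < 0.0:
                lead0 = fp0.multipliers[np.argmin(np.abs(fp0.multipliers - 1.0))]
                lead1 = fp1.multipliers[np.argmin(np.abs(fp1.multipliers - 1.0))]
                out.append(CandidateBracket(i - 1 if abs(lead0 - 1) < abs(lead1 - 1)
                                            else i, "SN", complex(lead0),
                                            complex(lead1)))
    seen: set[tuple[int, str]] = set()
    unique = []
    for b in out:
        if (b.index, b.kind) not in seen:
            seen.add((b.index, b.kind))
            unique.append(b)
    return unique


def _crossing_value(multipliers: np.ndarray, kind: str) -> tuple[float, complex]:
    """Signed distance of the critical multiplier from its critical value."""
    m = np.asarray(multipliers)
    if kind == "SN":
        reals = m[np.abs(m.imag) <= IMAG_TOL * np.maximum(1.0, np.abs(m))]
        if len(reals) == 0:
            reals = m
        crit = reals[np.argmin(np.abs(reals - 1.0))]
        return float(crit.real - 1.0), complex(crit)
    if kind == "PD":
        reals = m[np.abs(m.imag) <= IMAG_TOL * np.maximum(1.0, np.abs(m))]
        if len(reals) == 0:
            reals = m
        crit = reals[np.argmin(np.abs(reals + 1.0))]
        return float(crit.real + 1.0), complex(crit)
    if kind == "NS":
        cplx = m[m.imag > IMAG_TOL * np.maximum(1.0, np.abs(m))]
        if len(cplx) == 0:
            cplx = m[np.argsort(-np.abs(m.imag))][:1]
        crit = cplx[np.argmin(np.abs(np.abs(cplx) - 1.0))]
        return float(abs(crit) - 1.0), complex(crit)
    raise ValueError(f"unknown bifurcation kind {kind!r}")


def localize_bifurcation(
    system: StroboscopicSystem,
    branch: Branch,
    bracket: CandidateBracket,
    tol_param: float = 1e-3,
    tol: float = 1e-9,
    max_bisect: int = 60,
    param_scale: float | None = None,
    s_tol: float = 1e-8,
) -> BifurcationPoint:
    """Refine a candidate crossing by bisection along the branch.

    The crossing function is the signed distance of the critical multiplier
    from its critical value (+1, -1, or unit modulus).  Bisection acts on
    the arclength between the bracketing branch points, which remains
    monotone through an SN fold where the parameter itself is not.
    """
    i = bracket.index
    fa, fb = branch.points[i], branch.points[i + 1]
    la, lb = branch.params[i], branch.params[i + 1]
    if param_scale is None:
        span = np.ptp(branch.params)
        param_scale = max(span / max(len(branch) - 1, 1), 1e-9)
    w = np.concatenate([_state_weights(system), [param_scale]])
    ua = np.concatenate([fa.x, [la]])
    ub = np.concatenate([fb.x, [lb]])
    ga, _ = _crossing_value(fa.multipliers, bracket.kind)
    gb, _ = _crossing_value(fb.multipliers, bracket.kind)
    ma, mb = fa.multipliers, fb.multipliers

    if ga * gb > 0.0:
        # widen once using the neighbouring points, then give up widening
        if i > 0:
            fa = branch.points[i - 1]
            ua = np.concatenate([fa.x, [branch.params[i - 1]]])
            ga, _ = _crossing_value(fa.multipliers, bracket.kind)
            ma = fa.multipliers
        if ga * gb > 0.0 and i + 2 < len(branch):
            fb = branch.points[i + 2]
            ub = np.concatenate([fb.x, [branch.params[i + 2]]])
            gb, _ = _crossing_value(fb.multipliers, bracket.kind)
            mb = fb.multipliers

    best_u, best_g, best_m = (ua, ga, ma) if abs(ga) < abs(gb) else (ub, gb, mb)
    for _ in range(max_bisect):
        if np.linalg.norm((ub - ua) / w) < s_tol:
            break
        secant = (ub - ua) / w
        nrm = np.linalg.norm(secant)
        if nrm == 0.0:
            break
        tangent = secant / nrm
        u_mid = 0.5 * (ua + ub)
        res = _corrector(system, branch.param_name, u_mid, tangent, w,
                         branch.k, tol)
        if res is None:
            break
        x_m, lam_m, J_m, _ = res
        # guard against sliding onto a coexisting branch during refinement
        if np.linalg.norm(
            (np.concatenate([x_m, [lam_m]]) - u_mid) / w
        ) > 2.0 * np.linalg.norm((ub - ua) / w):
            break
        mult = characteristic_multipliers(J_m)
        g_m, crit = _crossing_value(mult, bracket.kind)
        u_m = np.concatenate([x_m, [lam_m]])
        if abs(g_m) < abs(best_g):
            best_u, best_g, best_m = u_m, g_m, mult
        if ga * g_m <= 0.0:
            ub, gb = u_m, g_m
        else:
            ua, ga = u_m, g_m
    width = abs(float(ub[-1]) - float(ua[-1]))
    g_best, crit = _crossing_value(best_m, bracket.kind)
    return BifurcationPoint(
        param_value=float(best_u[-1]),
        kind=bracket.kind,
        critical_multiplier=crit,
        x=best_u[:-1].copy(),
        localization_width=width,
        branch_param_name=branch.param_name,
        multipliers=best_m,
    )


def find_bifurcations(
    system: StroboscopicSystem,
    branch: Branch,
    tol_param: float = 1e-3,
    **kwargs,
) -> list[BifurcationPoint]:
    """Detect and localize every multiplier crossing along a branch."""
    out = []
    for bracket in detect_crossings(branch):
        out.append(
            localize_bifurcation(system, branch, bracket,
                                 tol_param=tol_param, **kwargs)
        )
    return out


def refine_at_param(
    system: StroboscopicSystem,
    branch: Branch,
    lam: float,
    tol: float = 1e-9,
    stable_only: bool = True,
    max_iter: int = 30,
) -> FixedPoint | None:
    """Newton-correct the branch to an exact parameter value.

    Seeds from the branch point nearest in parameter (optionally among the
    stable points only) and shoots at ``lam``; used to compare a branch
    against quantities measured at parameters between its computed points.
    Returns ``None`` when no suitable seed exists or shooting fails.
    """
    from .shooting import newton_shoot

    lams = branch.params
    mask = branch.stability if stable_only else np.ones(len(branch), dtype=bool)
    if not np.any(mask):
        return None
    idx = np.flatnonzero(mask)
    j = idx[np.argmin(np.abs(lams[idx] - lam))]
    system.set_param(branch.param_name, float(lam))
    fp = newton_shoot(system, branch.points[j].x, k=branch.k, tol=tol,
                      max_iter=max_iter)
    return fp if fp.converged else None


# ---------------------------------------------------------------------------
# post-bifurcation transition


def post_bifurcation_transition(
    system: StroboscopicSystem,
    bif: BifurcationPoint,
    beyond: float,
    max_beats: int = 1000,
    tol: float = 1e-8,
    perturbation: float = 1e-6,
) -> TransitionResult:
    """Simulate forward just past a localized bifurcation and report the
    destination reached *from this initial condition*.

    The start is the critical orbit's state nudged by ``perturbation`` (in
    scaled units), the parameter set to ``beyond``.  A blow-up of the map is
    reported as divergence (the generic outcome past a fold with no
    coexisting attractor); non-convergence within ``max_beats`` is flagged
    as irregular.
    """
    system.set_param(bif.branch_param_name, beyond)
    x0 = bif.x + perturbation * np.asarray(system.state_scales, dtype=float)
    try:
        settle = run_to_steady_state(system, x0, max_beats=max_beats, tol=tol)
    except Exception as exc:
        return TransitionResult(beyond, True, None, note=str(exc))
    if not np.all(np.isfinite(settle.state)) or np.max(np.abs(settle.state)) > 1e8:
        return TransitionResult(beyond, True, settle, note="trajectory diverged")
    note = "" if settle.converged else "no periodic convergence (irregular)"
    return TransitionResult(beyond, False, settle, note=note)
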