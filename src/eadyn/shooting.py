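"""Newton shooting for periodic responses of the stroboscopic map.

A period-k paced response is a fixed point of ``P^k``, the k-cycle
stroboscopic map.  Its dynamical stability is decided by the characteristic
multipliers -- the eigenvalues of the monodromy matrix ``D P^k`` -- all of
which must lie strictly inside the unit circle for stability.  Because the
system is non-autonomous, no trivial multiplier is pinned at +1.

Newton shooting solves ``P^k(x) - x = 0`` with the monodromy-based Jacobian
``D P^k - I`` and step-halving damping; it converges to *unstable* fixed
points just as well as to stable ones, which is what makes the unstable
branches of the bifurcation diagrams computable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynsys import StroboscopicSystem

__all__ = [
    "FixedPoint",
    "characteristic_multipliers",
    "monodromy",
    "newton_shoot",
]


@dataclass
class FixedPoint:
    """A periodic response as a fixed point of ``P^k``."""

    x: np.ndarray
    k: int
    multipliers: np.ndarray  # complex, sorted by descending modulus
    residual: float
    converged: bool
    n_iter: int
    min_singular_value: float = np.inf
    param_snapshot: dict = field(default_factory=dict)
    message: str = ""

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(self.multipliers) < 1.0))

    @property
    def leading_multiplier(self) -> complex:
        return complex(self.multipliers[0])

    def to_dict(self) -> dict:
        return {
            "x": [float(v) for v in self.x],
            "k": int(self.k),
            "multipliers": [[float(m.real), float(m.imag)] for m in self.multipliers],
            "residual": float(self.residual),
            "converged": bool(self.converged),
            "stable": self.stable,
            "params": {k: float(v) for k, v in self.param_snapshot.items()},
        }


def characteristic_multipliers(monodromy_matrix: np.ndarray) -> np.ndarray:
    """Eigenvalues of the monodromy matrix, sorted by descending modulus."""
    mult = np.linalg.eigvals(np.asarray(monodromy_matrix, dtype=float))
    order = np.argsort(-np.abs(mult), kind="stable")
    return mult[order]


def monodromy(
    system: StroboscopicSystem,
    x: np.ndarray,
    k: int = 1,
    method: str = "variational",
) -> np.ndarray:
    """Jacobian of ``P^k`` at ``x``.

    ``method='variational'`` uses the system's own Jacobian route (for flow
    maps: the variational equations integrated along the orbit;
    for discrete maps: the chain-rule product of per-step Jacobians);
    ``method='fd'`` uses central finite differences of the map itself and
    serves as the independent cross-check.
    """
    if method == "variational":
        _, J = system.map_with_jacobian(x, k)
        return J
    if method == "fd":
        return system.jacobian_fd(x, k)
    raise ValueError(f"unknown monodromy method {method!r}")


def _snapshot(system: StroboscopicSystem) -> dict:
    params = getattr(system, "params", None)
    if isinstance(params, dict):
        return {k: v for k, v in params.items() if np.isscalar(v)}
    if params is not None:
        return {
            k: v
            for k, v in vars(params).items()
            if isinstance(v, (int, float)) and v is not None
        }
    return {}


def newton_shoot(
    system: StroboscopicSystem,
    x_guess: np.ndarray,
    k: int = 1,
    tol: float = 1e-9,
    max_iter: int = 30,
    max_halvings: int = 8,
) -> FixedPoint:
    """Damped Newton iteration on ``P^k(x) - x = 0``.

    Convergence is measured on the infinity norm of the residual in the raw
    mixed-unit state.  Near a bifurcation the shooting matrix ``D P^k - I``
    becomes singular; this is reported through ``min_singular_value`` (a
    detection signal) rather than raised.  Non-convergence returns the best
    iterate with ``converged=False``.
    """
    x = np.asarray(x_guess, dtype=float).copy()
    n = system.dimension
    eye = np.eye(n)

    Px, J = system.map_with_jacobian(x, k)
    r = Px - x
    rnorm = float(np.max(np.abs(r)))
    best = (x.copy(), J.copy(), rnorm)
    n_iter = 0
    message = ""
    for n_iter in range(1, max_iter + 1):
        if rnorm < tol:
            n_iter -= 1
            break
        A = J - eye
        try:
            dx = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(A, -r, rcond=None)[0]
        # damping trials evaluate the map only; the Jacobian is recomputed
        # once for the accepted iterate
        accepted = False
        lam = 1.0
        for _ in range(max_halvings + 1):
            x_new = x + lam * dx
            try:
                Px_new = system.map(x_new, k)
            except Exception as exc:  # divergence of the flow: reject step
                message = f"map evaluation failed during damping: {exc}"
                lam *= 0.5
                continue
            r_new = Px_new - x_new
            rnorm_new = float(np.max(np.abs(r_new)))
            if rnorm_new < rnorm or rnorm_new < tol:
                x, r, rnorm = x_new, r_new, rnorm_new
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            message = message or "damping failed to reduce the residual"
            break
        try:
            _, J = system.map_with_jacobian(x, k)
        except Exception as exc:
            message = f"Jacobian evaluation failed: {exc}"
            break
        if rnorm < best[2]:
            best = (x.copy(), J.copy(), rnorm)
    else:
        message = f"no convergence in {max_iter} iterations"

    if rnorm > best[2]:
        x, J, rnorm = best
    converged = rnorm < tol
    sv = np.linalg.svd(J - eye, compute_uv=False)
    return FixedPoint(
        x=x,
        k=k,
        multipliers=characteristic_multipliers(J),
        residual=rnorm,
        converged=converged,
        n_iter=n_iter,
        min_singular_value=float(sv[-1]),
        param_snapshot=_snapshot(system),
        message=message if not converged else "",
    )
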