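"""Discrete-time dynamical-system interface shared across the package.

A periodically paced myocyte is a non-autonomous ODE system with period equal
to the pacing cycle length.  Its periodic action-potential responses are fixed
points of the *stroboscopic map* -- the state-to-state map over one pacing
cycle, sampled at stimulus onset.  The shooting, continuation and protocol
layers all operate on that map, so they are agnostic to whether the underlying
system is a genuine ODE model (:class:`eadyn.pacing_sim.PacedFlowMap`) or an
analytically defined discrete map (:class:`MapSystem`) used as a validation
oracle.
"""

from __future__ import annotations

import abc
from typing import Callable

import numpy as np

__all__ = ["StroboscopicSystem", "MapSystem"]


class StroboscopicSystem(abc.ABC):
    """Abstract state-to-state map with named, tunable parameters.

    Subclasses provide :meth:`map` (and ideally an analytic or variational
    Jacobian via :meth:`map_with_jacobian`); a central finite-difference
    Jacobian with per-component step scaling is always available as a
    fallback and as an independent cross-check.
    """

    #: names of the state components, in order
    state_names: tuple[str, ...] = ()

    @property
    @abc.abstractmethod
    def dimension(self) -> int:
        """Number of free state variables."""

    @property
    def state_scales(self) -> np.ndarray:
        """Typical magnitude of each state component (mixed units).

        Used to scale finite-difference steps; defaults to ones.
        """
        return np.ones(self.dimension)

    @abc.abstractmethod
    def map(self, x: np.ndarray, k: int = 1) -> np.ndarray:
        """Apply the stroboscopic map ``k`` times."""

    def map_with_jacobian(
        self, x: np.ndarray, k: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(P^k(x), D P^k(x))``; default uses finite differences."""
        return self.map(x, k), self.jacobian_fd(x, k)

    def jacobian_fd(
        self, x: np.ndarray, k: int = 1, rel_step: float = 1e-6
    ) -> np.ndarray:
        """Central finite-difference Jacobian of ``P^k`` at ``x``.

        Step for component ``i`` is ``rel_step * state_scales[i]`` so that
        mV-, mM- and dimensionless-scaled variables are each perturbed by an
        appropriate amount.
        """
        x = np.asarray(x, dtype=float)
        n = self.dimension
        steps = rel_step * np.asarray(self.state_scales, dtype=float)
        J = np.empty((n, n))
        for i in range(n):
            h = steps[i]
            xp = x.copy()
            xm = x.copy()
            xp[i] += h
            xm[i] -= h
            J[:, i] = (self.map(xp, k) - self.map(xm, k)) / (2.0 * h)
        return J

    @abc.abstractmethod
    def get_param(self, name: str) -> float:
        """Read a named scalar parameter."""

    @abc.abstractmethod
    def set_param(self, name: str, value: float) -> None:
        """Set a named scalar parameter (mutates the system)."""


class MapSystem(StroboscopicSystem):
    """A discrete map used directly as its own Poincare map.

    Parameters
    ----------
    f : callable ``f(x, params) -> x'``
        One application of the map.
    params : dict
        Named scalar parameters, readable/settable by name.
    dimension : int
        State dimension.
    jac : callable ``jac(x, params) -> (n, n) array``, optional
        Analytic Jacobian of one application.  When absent the
        finite-difference fallback is used.
    """

    def __init__(
        self,
        f: Callable[[np.ndarray, dict], np.ndarray],
        params: dict,
        dimension: int,
        jac: Callable[[np.ndarray, dict], np.ndarray] | None = None,
        state_names: tuple[str, ...] | None = None,
        name: str = "map",
    ):
        self._f = f
        self.params = dict(params)
        self._dim = int(dimension)
        self._jac = jac
        self.state_names = state_names or tuple(
            f"x{i}" for i in range(dimension)
        )
        self.name = name

    @property
    def dimension(self) -> int:
        return self._dim

    def map(self, x: np.ndarray, k: int = 1) -> np.ndarray:
        y = np.asarray(x, dtype=float)
        for _ in range(k):
            y = np.asarray(self._f(y, self.params), dtype=float)
        return y

    def map_with_jacobian(
        self, x: np.ndarray, k: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        if self._jac is None:
            return self.map(x, k), self.jacobian_fd(x, k)
        y = np.asarray(x, dtype=float)
        J = np.eye(self._dim)
        for _ in range(k):
            J = np.asarray(self._jac(y, self.params), dtype=float) @ J
            y = np.asarray(self._f(y, self.params), dtype=float)
        return y, J

    def get_param(self, name: str) -> float:
        return self.params[name]

    def set_param(self, name: str, value: float) -> None:
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}")
        self.params[name] = float(value)
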