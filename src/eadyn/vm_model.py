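"""Paced ventricular-myocyte model layer.

The membrane-potential balance follows the standard current-clamp form

    dVm/dt = Istim - (ICaL + IKr + IKs + Ito + INa + IK1
                      + INab + ICab + INaK + INCX + IpCa)

with currents in pA/pF, voltages in mV, time in ms and concentrations in mM.
The delayed-rectifier conductances are expressed as a percentage of their
control values (gKs = 0.0257 nS/pF, gKr = 0.00738 nS/pF), which is the
parameter axis along which repolarisation reserve is attenuated.

The ionic right-hand side is a *pluggable provider*: any object with the
small model protocol documented on :class:`MinimalMyocyteModel` (``rhs``,
``compute_currents``, ``state_names``, ``state_scales``,
``clamped_indices``) can drive the pacing, shooting, continuation and
protocol layers.  The bundled :class:`MinimalMyocyteModel` is a
four-variable synthetic myocyte built around the same dynamical skeleton --
a fast excitable membrane, an L-type Ca channel with a slow inactivation
gate, and a slowly accumulating intracellular Na pool coupled through
Na/K-pump and Na/Ca-exchanger fluxes -- so that bistability between a
short-AP and a long-AP periodic response, its hysteresis, and its collapse
under an [Na+]i clamp can all be exercised in minutes on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PacingProtocol",
    "ModelParams",
    "CurrentSet",
    "MinimalMyocyteModel",
    "FARADAY_RTF",
]

#: RT/F at 37 C, in mV
FARADAY_RTF = 26.712338


@dataclass
class PacingProtocol:
    """Square current-pulse pacing train.

    Defaults follow the standard protocol: 80 pA/pF, 1 ms pulses at 0.5 Hz
    (pacing cycle length 2000 ms).  A depolarising stimulus is positive.
    """

    amplitude: float = 80.0  # pA/pF
    duration: float = 1.0  # ms
    cycle_length: float = 2000.0  # ms

    def __post_init__(self):
        if not self.duration < self.cycle_length:
            raise ValueError("pulse duration must be shorter than the cycle length")
        if self.duration <= 0 or self.cycle_length <= 0:
            raise ValueError("pulse duration and cycle length must be positive")

    def istim(self, t: float) -> float:
        """Stimulus density at absolute time ``t`` (ms); pulse at each cycle start."""
        phase = t % self.cycle_length
        return self.amplitude if phase < self.duration else 0.0


@dataclass
class ModelParams:
    """Conductance scalings, fixed concentrations and pacing for a run.

    ``pct_gkr``/``pct_gks`` scale the control conductances linearly:
    effective conductance = control x pct/100.  ``nai_clamp``, when set,
    freezes [Na+]i at the given value (the "[Na+]i-fixed system"), removing
    one dynamic variable.
    """

    pct_gkr: float = 100.0
    pct_gks: float = 100.0
    gkr_control: float = 0.00738  # nS/pF
    gks_control: float = 0.0257  # nS/pF
    cao: float = 2.0  # mM
    nao: float = 140.0  # mM
    ko: float = 5.4  # mM
    ki: float = 140.0  # mM, fixed
    pacing: PacingProtocol = field(default_factory=PacingProtocol)
    nai_clamp: float | None = None

    def __post_init__(self):
        if self.pct_gkr < 0 or self.pct_gks < 0:
            raise ValueError("conductance percentages must be non-negative")
        for name in ("cao", "nao", "ko", "ki"):
            if getattr(self, name) <= 0:
                raise ValueError(f"fixed concentration {name} must be positive")

    @property
    def gkr(self) -> float:
        """Effective IKr conductance (nS/pF)."""
        return self.gkr_control * self.pct_gkr / 100.0

    @property
    def gks(self) -> float:
        """Effective IKs conductance (nS/pF)."""
        return self.gks_control * self.pct_gks / 100.0

    @property
    def ek(self) -> float:
        """K+ Nernst potential (mV)."""
        return FARADAY_RTF * math.log(self.ko / self.ki)

    def copy(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass
class CurrentSet:
    """All membrane current densities (pA/pF) at one instant.

    ``inet`` is the parenthesised sum of the membrane balance, so that
    ``dVm/dt = istim - inet`` holds identically.  ``jna_net`` and
    ``jca_net`` are the net Na+ and Ca2+ fluxes in mM/ms (positive inward).
    """

    ICaL: float = 0.0
    IKr: float = 0.0
    IKs: float = 0.0
    Ito: float = 0.0
    INa: float = 0.0
    IK1: float = 0.0
    INab: float = 0.0
    ICab: float = 0.0
    INaK: float = 0.0
    INCX: float = 0.0
    IpCa: float = 0.0
    Istim: float = 0.0
    inet: float = 0.0
    jna_net: float = 0.0
    jca_net: float = 0.0

    FIELD_ORDER = (
        "ICaL", "IKr", "IKs", "Ito", "INa", "IK1",
        "INab", "ICab", "INaK", "INCX", "IpCa",
    )

    def sum_currents(self) -> float:
        return sum(getattr(self, name) for name in self.FIELD_ORDER)


def _sig(x: float) -> float:
    # numerically safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


class MinimalMyocyteModel:
    """Four-variable synthetic paced myocyte with Na-mediated bistability.

    State ``(Vm, f, Nai, Cai)``:

    * ``Vm`` -- membrane potential (mV);
    * ``f`` -- slow voltage-dependent inactivation gate of the L-type Ca
      current, in [0, 1];
    * ``Nai`` -- intracellular Na+ (mM), the slow variable whose beat-to-beat
      balance between pump extrusion (INaK, mostly during the AP) and
      exchanger/background loading (INCX, INab, mostly during diastole)
      carries the memory responsible for bistability and hysteresis;
    * ``Cai`` -- intracellular Ca2+ (mM), driven by ICaL influx and
      NCX/pump extrusion with a lumped uptake term standing in for
      sarcoplasmic-reticulum buffering.

    Currents carried: ICaL, IKr, IKs, IK1, INaK, INCX, INab, IpCa; the
    remaining inventory entries (Ito, INa, ICab) are present in the
    :class:`CurrentSet` with zero conductance in this minimal formulation
    (the stimulus pulse plays the role of the fast Na upstroke).

    Kinetic constants are frozen class attributes so every simulation is
    exactly reproducible; they are chosen (and verified at test time) so
    that a window of ``pct_gkr`` exists where a short-AP and a long-AP
    period-1 response coexist.
    """

    state_names = ("Vm", "f", "Nai", "Cai")

    def __init__(self, **overrides):
        """Optional keyword overrides shadow the frozen kinetic constants
        (used by the test bed to build deliberately monostable variants)."""
        for name, value in overrides.items():
            if not hasattr(type(self), name):
                raise TypeError(f"unknown kinetic constant {name!r}")
            setattr(self, name, float(value))

    # --- kinetic constants (frozen; verified by the test-bed census) ---
    e_ca = 60.0  # mV, effective ICaL reversal
    g_cal = 0.32  # nS/pF
    km_fca = 0.0015  # mM, Ca-dependent ICaL inactivation
    g_k1 = 0.2  # nS/pF
    g_nab = 0.0022  # nS/pF
    kr_gain = 3.0  # surrogate gain on IKr (gives %GKr real leverage here)
    k_nak = 2.5  # pA/pF, maximal Na/K pump density
    km_nai = 8.0  # mM, pump Na half-saturation
    h_nak = 4.0  # pump Hill coefficient
    k_ncx = 600.0  # pA/pF, exchanger scale
    gamma_ncx = 0.35  # exchanger energy-barrier position
    ca_ref_ncx = 1.2  # mM, exchanger Ca scaling
    g_pca = 0.06  # pA/pF, sarcolemmal Ca pump
    km_pca = 0.0005  # mM
    k_na_flux = 6.0e-4  # mM per (pA/pF * ms), Na current-to-flux factor
    k_ca_flux = 3.0e-6  # mM per (pA/pF * ms), Ca current-to-flux factor
    ca_rest = 0.00005  # mM, lumped uptake target
    tau_ca_up = 120.0  # ms, lumped uptake time constant
    tau_f_min = 25.0  # ms
    tau_f_plateau = 280.0  # ms, slow late-plateau inactivation
    tau_f_rest = 60.0  # ms-scale recovery (see tau_f)
    # gating midpoints/slopes (mV)
    v_d_mid = -12.0
    v_d_slope = 6.0
    v_f_mid = -24.0
    v_f_slope = 4.5
    v_tau_mid = -12.0
    v_tau_width = 18.0
    v_ks_mid = 25.0
    v_ks_slope = 14.0

    def state_scales_for(self, params: ModelParams) -> np.ndarray:
        full = np.array([100.0, 1.0, 10.0, 0.001])
        idx = [i for i in range(4) if i not in self.clamped_indices(params)]
        return full[idx] if params.nai_clamp is not None else full

    @property
    def state_scales(self) -> np.ndarray:
        return np.array([100.0, 1.0, 10.0, 0.001])

    def clamped_indices(self, params: ModelParams) -> tuple[int, ...]:
        """Indices of state variables held fixed under the current params."""
        return (2,) if params.nai_clamp is not None else ()

    def system_dimension(self, params: ModelParams) -> int:
        """Number of free (dynamic) state variables."""
        return 4 - len(self.clamped_indices(params))

    # --- gating steady states / time constants ---
    def d_inf(self, v: float) -> float:
        """Instantaneous ICaL activation."""
        return _sig((v - self.v_d_mid) / self.v_d_slope)

    def f_inf(self, v: float) -> float:
        return _sig(-(v - self.v_f_mid) / self.v_f_slope)

    def tau_f(self, v: float) -> float:
        # slow around the late-plateau window potentials, moderate at rest:
        # near-threshold APs linger in the window while robust ones push
        # through, which is what steepens APD as a function of [Na+]i
        return (
            self.tau_f_min
            + self.tau_f_plateau
            * math.exp(-(((v - self.v_tau_mid) / self.v_tau_width) ** 2))
            + self.tau_f_rest * _sig(-(v + 65.0) / 8.0)
        )

    @staticmethod
    def r_kr(v: float) -> float:
        """Instantaneous IKr activation x rectification."""
        return _sig((v + 20.0) / 7.0) * _sig(-(v - 45.0) / 24.0)

    def s_ks(self, v: float) -> float:
        return _sig((v - self.v_ks_mid) / self.v_ks_slope)

    @staticmethod
    def k1_inf(v: float) -> float:
        return _sig(-(v + 55.0) / 8.0)

    @staticmethod
    def f_v_nak(v: float) -> float:
        return 0.25 + 0.75 * _sig((v + 60.0) / 14.0)

    # --- currents ---
    def compute_currents(
        self,
        state: np.ndarray,
        t: float,
        params: ModelParams,
        istim: float | None = None,
    ) -> CurrentSet:
        """Evaluate every membrane current at ``state``; see Eq. contract.

        ``istim`` overrides the pacing-protocol stimulus when given (the
        integrator passes it per segment so the pulse edges are exact).
        """
        self._check_state(state)
        v, f, nai, cai = (float(s) for s in state)
        if params.nai_clamp is not None:
            nai = params.nai_clamp
        if istim is None:
            istim = params.pacing.istim(t)
        ek = params.ek
        ena = FARADAY_RTF * math.log(params.nao / nai)
        vhat = v / FARADAY_RTF

        f_ca = self.km_fca / (self.km_fca + cai)
        i_cal = self.g_cal * self.d_inf(v) * f * f_ca * (v - self.e_ca)
        i_kr = self.kr_gain * params.gkr * self.r_kr(v) * (v - ek)
        i_ks = params.gks * self.s_ks(v) * (v - ek)
        i_k1 = self.g_k1 * self.k1_inf(v) * (v - ek)
        i_nab = self.g_nab * (v - ena)
        h_na = nai**self.h_nak / (nai**self.h_nak + self.km_nai**self.h_nak)
        i_nak = self.k_nak * h_na * self.f_v_nak(v)
        # simplified electrogenic 3Na:1Ca exchanger; negative = forward mode
        # (Ca extrusion, Na loading)
        i_ncx = self.k_ncx * (
            math.exp(self.gamma_ncx * vhat) * (nai / params.nao) ** 3 * (params.cao / 2.0)
            - math.exp(-(1.0 - self.gamma_ncx) * vhat) * (cai / self.ca_ref_ncx)
        )
        i_pca = self.g_pca * cai / (cai + self.km_pca)

        cs = CurrentSet(
            ICaL=i_cal, IKr=i_kr, IKs=i_ks, IK1=i_k1,
            INab=i_nab, INaK=i_nak, INCX=i_ncx, IpCa=i_pca,
            Istim=float(istim),
        )
        cs.inet = cs.sum_currents()
        # net inward fluxes in mM/ms (positive = accumulation)
        cs.jna_net = -self.k_na_flux * (3.0 * i_nak + 3.0 * i_ncx + i_nab)
        cs.jca_net = -self.k_ca_flux * (i_cal - 2.0 * i_ncx + i_pca)
        return cs

    def rhs(
        self,
        t: float,
        state: np.ndarray,
        params: ModelParams,
        istim: float | None = None,
    ) -> np.ndarray:
        """Time derivative of the full state.

        Inlined hot path (no :class:`CurrentSet` allocation); agreement
        with :meth:`compute_currents` is asserted by the membrane-balance
        consistency test.
        """
        v = float(state[0])
        f = float(state[1])
        nai = float(state[2])
        cai = float(state[3])
        if params.nai_clamp is not None:
            nai = params.nai_clamp
        if istim is None:
            istim = params.pacing.istim(t)
        if not (math.isfinite(v) and math.isfinite(f)
                and math.isfinite(nai) and math.isfinite(cai)):
            self._check_state(state)  # raises with the offending component
        ek = params.ek
        ena = FARADAY_RTF * math.log(params.nao / nai)
        vhat = v / FARADAY_RTF

        f_ca = self.km_fca / (self.km_fca + cai)
        i_cal = self.g_cal * self.d_inf(v) * f * f_ca * (v - self.e_ca)
        i_kr = self.kr_gain * params.gkr * self.r_kr(v) * (v - ek)
        i_ks = params.gks * self.s_ks(v) * (v - ek)
        i_k1 = self.g_k1 * self.k1_inf(v) * (v - ek)
        i_nab = self.g_nab * (v - ena)
        h_na = nai**self.h_nak / (nai**self.h_nak + self.km_nai**self.h_nak)
        i_nak = self.k_nak * h_na * self.f_v_nak(v)
        i_ncx = self.k_ncx * (
            math.exp(self.gamma_ncx * vhat)
            * (nai / params.nao) ** 3 * (params.cao / 2.0)
            - math.exp(-(1.0 - self.gamma_ncx) * vhat) * (cai / self.ca_ref_ncx)
        )
        i_pca = self.g_pca * cai / (cai + self.km_pca)

        inet = i_cal + i_kr + i_ks + i_k1 + i_nab + i_nak + i_ncx + i_pca
        dv = istim - inet
        df = (self.f_inf(v) - f) / self.tau_f(v)
        dnai = (
            0.0
            if params.nai_clamp is not None
            else -self.k_na_flux * (3.0 * i_nak + 3.0 * i_ncx + i_nab)
        )
        dcai = (
            -self.k_ca_flux * (i_cal - 2.0 * i_ncx + i_pca)
            - (cai - self.ca_rest) / self.tau_ca_up
        )
        return np.array([dv, df, dnai, dcai])

    # spec-facing alias with the (state, t, params) argument order
    def derivatives(
        self, state: np.ndarray, t: float, params: ModelParams,
        istim: float | None = None,
    ) -> np.ndarray:
        return self.rhs(t, state, params, istim=istim)

    def rest_state(self, params: ModelParams, nai: float = 7.0) -> np.ndarray:
        """A physiologically sensible diastolic starting state."""
        if params.nai_clamp is not None:
            nai = params.nai_clamp
        v0 = params.ek + 2.0
        return np.array([v0, self.f_inf(v0), nai, self.ca_rest])

    @staticmethod
    def _check_state(state) -> None:
        arr = np.asarray(state, dtype=float)
        if arr.shape != (4,):
            raise ValueError(f"state must have 4 components, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            bad = [
                MinimalMyocyteModel.state_names[i]
                for i in range(4)
                if not math.isfinite(arr[i])
            ]
            raise ValueError(f"non-finite state component(s): {', '.join(bad)}")
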