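"""Per-beat action-potential measurements and response classification.

The quantities mirror what one-parameter bifurcation diagrams are built
from: APD90 (duration to 90% repolarisation), #TDMP (the number of
transiently depolarised membrane potentials -- EADs -- during AP phase
2-3), diastolic [Na+]i/[Ca2+]i sampled at stimulus onset, the [Ca2+]i
transient peak, and the diastolic interval.

Response classes:

* ``noEAD`` -- plain AP, no phase-2/3 re-depolarisations;
* ``EAD1``/``EAD2``/``EAD3``/``EADk`` -- APs with 1, 2, 3 or more
  transient depolarisations before repolarisation completes;
* ``LAVO`` -- low-amplitude voltage oscillation around plateau potential
  with repolarisation failure (the membrane never returns below the
  phase-2/3 floor before the next stimulus);
* ``irregular`` -- no periodic steady state detected within the beat cap.

The #TDMP detection rule (phase-2/3 floor at -40 mV, 1 mV prominence,
post-upstroke window) is an operational convention chosen to be robust to
integrator jitter; it is applied uniformly everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .pacing_sim import BeatTrace

__all__ = [
    "APFeatures",
    "apd90",
    "count_tdmp",
    "classify_response",
    "diastolic_and_peaks",
    "beat_features",
    "TDMP_FLOOR_MV",
    "TDMP_PROMINENCE_MV",
]

TDMP_FLOOR_MV = -40.0  # phase-2/3 floor for counting depolarised episodes
TDMP_PROMINENCE_MV = 1.0  # minimum net rise of a counted episode
MIN_AP_AMPLITUDE_MV = 10.0  # below this upstroke, no AP was elicited


@dataclass
class APFeatures:
    """Measurements of one steady (or candidate) beat."""

    apd90: float  # ms; NaN when repolarisation failed or no AP
    apd_status: str  # "ok" | "no_ap" | "repol_failure"
    n_tdmp: int
    response_class: str
    dia_nai: float
    dia_cai: float
    peak_cai: float
    di: float  # ms; NaN unless repolarisation completed
    period: int = 1


def apd90(trace: BeatTrace) -> tuple[float, str]:
    """AP duration at 90% repolarisation for one paced beat.

    The baseline is Vm at stimulus onset (per-beat, so drifting diastolic
    potentials are handled), the threshold is
    ``Vpeak - 0.9 (Vpeak - baseline)``, and the *last* downward crossing is
    used so that EAD re-depolarisations above the threshold extend the
    measured duration.  Returns ``(value, status)``; a NaN value carries
    status ``"no_ap"`` (no stimulated upstroke) or ``"repol_failure"``
    (Vm still above threshold at the end of the cycle).
    """
    vm = np.asarray(trace.vm, dtype=float)
    t = np.asarray(trace.t, dtype=float)
    baseline = vm[0]
    vpeak = float(vm.max())
    if vpeak - baseline < MIN_AP_AMPLITUDE_MV:
        return float("nan"), "no_ap"
    v90 = vpeak - 0.9 * (vpeak - baseline)
    above = vm >= v90
    if above[-1]:
        return float("nan"), "repol_failure"
    # last index where the trace sits at/above threshold
    last_above = int(np.nonzero(above)[0][-1])
    t0, t1 = t[last_above], t[last_above + 1]
    v0, v1 = vm[last_above], vm[last_above + 1]
    t_cross = t0 + (v90 - v0) / (v1 - v0) * (t1 - t0) if v1 != v0 else t1
    return float(t_cross - t[0]), "ok"


def count_tdmp(
    trace: BeatTrace,
    floor: float = TDMP_FLOOR_MV,
    prominence: float = TDMP_PROMINENCE_MV,
) -> int:
    """Count transiently depolarised membrane potentials after the upstroke.

    An episode is a local Vm maximum after the primary upstroke peak with
    net rise >= ``prominence`` occurring above the phase-2/3 ``floor``.
    The count is insensitive to uniform resampling at >= 2 kHz.
    """
    vm = np.asarray(trace.vm, dtype=float)
    i_peak = int(np.argmax(vm))
    seg = vm[i_peak:]
    if len(seg) < 3:
        return 0
    peaks, _ = find_peaks(seg, prominence=prominence, height=floor)
    return int(len(peaks))


def diastolic_and_peaks(trace: BeatTrace) -> tuple[float, float, float]:
    """Diastolic [Na+]i and [Ca2+]i (at stimulus onset) and the [Ca2+]i peak.

    Components absent from the model's state (e.g. a surrogate without a
    Ca pool) are reported as NaN.
    """
    def col(name):
        try:
            return trace.column(name)
        except ValueError:
            return None

    nai = col("Nai")
    cai = col("Cai")
    dia_nai = float(nai[0]) if nai is not None else float("nan")
    dia_cai = float(cai[0]) if cai is not None else float("nan")
    peak_cai = float(np.max(cai)) if cai is not None else float("nan")
    return dia_nai, dia_cai, peak_cai


def beat_features(trace: BeatTrace, period: int = 1) -> APFeatures:
    """All per-beat measurements for one trace (class set per single beat)."""
    value, status = apd90(trace)
    n = count_tdmp(trace)
    dia_nai, dia_cai, peak_cai = diastolic_and_peaks(trace)
    cycle = float(trace.t[-1] - trace.t[0])
    vm = np.asarray(trace.vm, dtype=float)
    failed_floor = bool(np.min(vm) > TDMP_FLOOR_MV) and status != "no_ap"
    if failed_floor or status == "repol_failure":
        cls = "LAVO" if n >= 1 else "arrest"
        value_out = float("nan")
        status = "repol_failure"
        di = float("nan")
    elif status == "no_ap":
        cls = "noAP"
        value_out, di = float("nan"), float("nan")
    else:
        cls = _class_from_count(n)
        value_out = value
        di = cycle - value
    return APFeatures(
        apd90=value_out,
        apd_status=status,
        n_tdmp=n,
        response_class=cls,
        dia_nai=dia_nai,
        dia_cai=dia_cai,
        peak_cai=peak_cai,
        di=di,
        period=period,
    )


def _class_from_count(n: int) -> str:
    if n <= 0:
        return "noEAD"
    if n <= 3:
        return f"EAD{n}"
    return "EADk"


def classify_response(
    features_sequence: list[APFeatures],
    converged: bool = True,
) -> str:
    """Classify a steady periodic response from its beats over one period.

    Repolarisation failure with plateau oscillation on any beat dominates
    (LAVO); otherwise the modal #TDMP over the period decides; a
    non-converged response is ``irregular``.
    """
    if not converged or not features_sequence:
        return "irregular"
    if any(f.apd_status == "repol_failure" for f in features_sequence):
        if any(f.n_tdmp >= 1 for f in features_sequence):
            return "LAVO"
        return "arrest"
    if all(f.apd_status == "no_ap" for f in features_sequence):
        return "noAP"
    counts = [f.n_tdmp for f in features_sequence if f.apd_status == "ok"]
    if not counts:
        return "irregular"
    values, freq = np.unique(counts, return_counts=True)
    modal = int(values[np.argmax(freq)])
    return _class_from_count(modal)
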