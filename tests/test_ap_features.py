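"""APD90 geometry, EAD counting and response classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eadyn.ap_features import (
    APFeatures,
    apd90,
    beat_features,
    classify_response,
    count_tdmp,
    diastolic_and_peaks,
)
from eadyn.pacing_sim import BeatTrace


def make_trace(t, vm, extra=None):
    cols = {"Vm": np.asarray(vm, dtype=float)}
    if extra:
        cols.update(extra)
    names = tuple(cols)
    states = np.column_stack([cols[n] for n in names])
    return BeatTrace(t=np.asarray(t, dtype=float), states=states,
                     state_names=names)


def trapezoid_ap(plateau=300.0, ramp=100.0, baseline=-85.0, peak=40.0,
                 cycle=1000.0, dt=0.25):
    """Instant upstroke, flat plateau, linear repolarisation ramp."""
    t = np.arange(0.0, cycle + dt / 2, dt)
    vm = np.full_like(t, baseline)
    vm[(t > 0) & (t <= plateau)] = peak
    ramp_mask = (t > plateau) & (t <= plateau + ramp)
    vm[ramp_mask] = peak + (baseline - peak) * (t[ramp_mask] - plateau) / ramp
    return make_trace(t, vm)


def test_apd90_trapezoid_geometry():
    """APD90 of a trapezoid AP is plateau + 0.9 x ramp (linear fall)."""
    value, status = apd90(trapezoid_ap(plateau=300.0, ramp=100.0))
    assert status == "ok"
    assert value == pytest.approx(390.0, abs=0.5)


@settings(max_examples=30, deadline=None)
@given(
    plateau=st.floats(50.0, 500.0),
    ramp=st.floats(20.0, 300.0),
)
def test_apd90_trapezoid_geometry_property(plateau, ramp):
    value, status = apd90(trapezoid_ap(plateau=plateau, ramp=ramp, cycle=1000.0))
    if plateau + ramp > 990.0:
        return  # ramp truncated by the cycle; geometry formula not applicable
    assert status == "ok"
    assert value == pytest.approx(plateau + 0.9 * ramp, abs=0.5)


def test_apd90_monotone_in_plateau():
    """Extending the plateau never shortens APD90."""
    values = []
    for plateau in (100.0, 200.0, 300.0, 400.0):
        v, _ = apd90(trapezoid_ap(plateau=plateau))
        values.append(v)
    assert all(b > a for a, b in zip(values[:-1], values[1:]))


def test_flat_trace_is_no_ap():
    t = np.linspace(0, 1000, 2001)
    value, status = apd90(make_trace(t, np.full_like(t, -85.0)))
    assert status == "no_ap"
    assert np.isnan(value)


def test_repolarisation_failure_flagged():
    t = np.linspace(0, 1000, 2001)
    vm = np.full_like(t, 0.0)
    vm[0] = -85.0  # stimulated from rest, never repolarises
    value, status = apd90(make_trace(t, vm))
    assert status == "repol_failure"
    assert np.isnan(value)


def ead_trace(n_bumps, amp=5.0, cycle=1000.0, dt=0.25):
    """AP with sinusoidal plateau bumps then full repolarisation."""
    t = np.arange(0.0, cycle + dt / 2, dt)
    vm = np.full_like(t, -85.0)
    up = (t > 0) & (t <= 400.0)
    vm[up] = 10.0
    if n_bumps:
        bump_zone = (t > 50.0) & (t <= 350.0)
        phase = (t[bump_zone] - 50.0) / 300.0 * n_bumps * 2 * np.pi
        vm[bump_zone] = 10.0 - amp + amp * np.cos(phase)
    ramp = (t > 400.0) & (t <= 500.0)
    vm[ramp] = 10.0 + (-85.0 - 10.0) * (t[ramp] - 400.0) / 100.0
    return make_trace(t, vm)


@pytest.mark.parametrize("n_bumps", [0, 1, 2, 3, 5])
def test_count_tdmp_counts_constructed_bumps(n_bumps):
    assert count_tdmp(ead_trace(n_bumps)) == n_bumps


def test_count_tdmp_resampling_invariant():
    """The count is unchanged between 2 kHz and 10 kHz equivalent sampling."""
    for n in (1, 2, 4):
        coarse = count_tdmp(ead_trace(n, dt=0.5))
        fine = count_tdmp(ead_trace(n, dt=0.1))
        assert coarse == fine == n


def test_count_ignores_subthreshold_bumps():
    """Oscillations below the -40 mV floor are not phase-2/3 EADs."""
    t = np.arange(0.0, 1000.0, 0.25)
    vm = np.full_like(t, -85.0)
    vm[(t > 0) & (t < 100)] = 10.0
    late = (t > 600) & (t < 800)
    vm[late] = -60.0 + 5.0 * np.sin((t[late] - 600) / 200 * 4 * np.pi)
    assert count_tdmp(make_trace(t, vm)) == 0


def test_classification_rules():
    mk = lambda n, status="ok": APFeatures(
        apd90=300.0 if status == "ok" else float("nan"), apd_status=status,
        n_tdmp=n, response_class="", dia_nai=7.0, dia_cai=1e-4,
        peak_cai=5e-4, di=700.0,
    )
    assert classify_response([mk(0)]) == "noEAD"
    assert classify_response([mk(1)]) == "EAD1"
    assert classify_response([mk(2), mk(2)]) == "EAD2"
    assert classify_response([mk(3)]) == "EAD3"
    assert classify_response([mk(5)]) == "EADk"
    assert classify_response([mk(1)], converged=False) == "irregular"
    assert classify_response([mk(2, status="repol_failure")]) == "LAVO"
    assert classify_response([mk(0, status="repol_failure")]) == "arrest"


def test_lavo_beat_features():
    """A plateau-oscillating, never-repolarising beat classifies as LAVO
    with undefined APD and DI."""
    t = np.arange(0.0, 1400.0, 0.5)
    vm = -10.0 + 8.0 * (1.0 - t / 5000.0) * np.sin(t / 1400 * 6 * np.pi)
    vm[0] = -22.0
    f = beat_features(make_trace(t, vm))
    assert f.response_class == "LAVO"
    assert np.isnan(f.apd90)
    assert np.isnan(f.di)
    assert f.n_tdmp >= 1


def test_diastolic_and_peaks_reads_state_columns():
    t = np.linspace(0.0, 1000.0, 101)
    nai = np.linspace(7.0, 7.1, 101)
    cai = 1e-4 + 5e-4 * np.sin(np.pi * t / 1000.0)
    tr = make_trace(t, np.full_like(t, -85.0),
                    extra={"Nai": nai, "Cai": cai})
    dia_nai, dia_cai, peak_cai = diastolic_and_peaks(tr)
    assert dia_nai == 7.0
    assert dia_cai == pytest.approx(1e-4)
    assert peak_cai == pytest.approx(6e-4, rel=1e-3)


def test_missing_concentrations_are_nan():
    t = np.linspace(0.0, 1000.0, 101)
    tr = make_trace(t, np.full_like(t, -85.0))
    dia_nai, dia_cai, peak_cai = diastolic_and_peaks(tr)
    assert np.isnan(dia_nai) and np.isnan(dia_cai) and np.isnan(peak_cai)


def test_di_complements_apd():
    f = beat_features(trapezoid_ap(plateau=300.0, ramp=100.0, cycle=1000.0))
    assert f.response_class == "noEAD"
    assert f.di == pytest.approx(1000.0 - f.apd90, abs=1e-9)
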