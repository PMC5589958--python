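"""Experiment protocols: hysteresis sweeps, multistability census,
[Na+]i perturbation/clamp analyses and bifurcation-diagram assembly.

These are the in-silico experiment designs that reveal the multistable
structure: a *sweep* carries the converged state of each parameter step
over as the initial condition of the next (the hysteresis mechanism); a
*census* settles a declared bank of initial conditions at a fixed
parameter and counts the distinct attractors reached (a lower bound on the
true multistability order, since the bank is finite); the *clamp* analysis
repeats the census with the slow Na pool frozen, which is the test of
whether the multistability is carried by [Na+]i dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ap_features import APFeatures, beat_features, classify_response
from .continuation import Branch, BifurcationPoint
from .pacing_sim import PacedFlowMap, run_to_steady_state, simulate_beats
from .shooting import newton_shoot

__all__ = [
    "SweepRecord",
    "Attractor",
    "CensusEntry",
    "hysteresis_sweep",
    "sweep_transitions",
    "multistability_census",
    "default_init_bank",
    "perturb_and_settle",
    "build_bifurcation_diagram",
    "stable_overlap_windows",
    "nai_fixed_analysis",
]

#: raw mixed-unit infinity-norm distance below which two stroboscopic
#: states are the same attractor
ATTRACTOR_DISTINCT_TOL = 1e-4
#: capture radius for early merging of census runs onto known attractors
#: (well inside any basin: inter-attractor distances are O(1) and larger)
CENSUS_MERGE_RADIUS = 0.02


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepRecord:
    param_value: float
    direction: str  # "down" | "up"
    state: np.ndarray  # stroboscopic steady (or last) state, map coordinates
    converged: bool
    period: int
    beats_used: int
    features: APFeatures | None = None
    response_class: str = ""


def _features_at(system: PacedFlowMap, state: np.ndarray, period: int = 1):
    """Features of the converged response (simulated over one period)."""
    model = system.model
    params = system.params
    traces = simulate_beats(
        model, params, system.to_full(state), max(period, 1),
        rtol=system.rtol, atol=system.atol, method=system.method,
    )
    feats = [beat_features(tr, period=period) for tr in traces]
    return feats


def hysteresis_sweep(
    system: PacedFlowMap,
    param_name: str,
    values,
    x0: np.ndarray,
    tol: float = 1e-8,
    max_beats: int = 300,
    with_features: bool = True,
) -> list[SweepRecord]:
    """Stepwise sweep with state carry-over.

    At each grid value the steady state is found starting from the
    *previous* step's converged state -- exactly the protocol that exposes
    hysteresis loops.  Non-convergence is recorded (``irregular``) and the
    last state is carried forward.
    """
    values = np.asarray(values, dtype=float)
    direction = "down" if values[-1] < values[0] else "up"
    records: list[SweepRecord] = []
    x = np.asarray(x0, dtype=float)
    for v in values:
        system.set_param(param_name, float(v))
        res = run_to_steady_state(system, x, max_beats=max_beats, tol=tol)
        x = res.state
        feats = None
        cls = "irregular"
        if with_features:
            feats = _features_at(system, x, period=res.period)
            cls = classify_response(feats, converged=res.converged)
        records.append(
            SweepRecord(
                param_value=float(v),
                direction=direction,
                state=x.copy(),
                converged=res.converged,
                period=res.period,
                beats_used=res.beats_used,
                features=feats[0] if feats else None,
                response_class=cls,
            )
        )
    return records


def sweep_transitions(
    records: list[SweepRecord],
    jump_tol: float = 2.0,
) -> list[tuple[float, float]]:
    """Grid cells ``(param_before, param_after)`` where the carried response
    changed attractor: a state jump larger than ``jump_tol`` (raw mixed
    units), a response-class change, or a convergence change."""
    out = []
    for a, b in zip(records[:-1], records[1:]):
        jumped = float(np.max(np.abs(b.state - a.state))) > jump_tol
        reclassified = (
            a.response_class != b.response_class
            and "" not in (a.response_class, b.response_class)
        )
        if jumped or reclassified or a.converged != b.converged:
            out.append((a.param_value, b.param_value))
    return out


# ---------------------------------------------------------------------------
# census


@dataclass
class Attractor:
    state: np.ndarray  # polished stroboscopic state (map coordinates)
    period: int
    response_class: str = ""
    n_basin_hits: int = 0
    settle_residual: float = float("nan")
    polish_shift: float = float("nan")  # |Newton polish - settled state|
    multipliers: np.ndarray | None = None


@dataclass
class CensusEntry:
    param_value: float
    attractors: list[Attractor] = field(default_factory=list)
    n_irregular: int = 0
    n_starts: int = 0

    @property
    def order(self) -> int:
        """Multistability order: number of distinct attractors found
        (a lower bound -- the init bank is finite)."""
        return len(self.attractors)

    @property
    def classes(self) -> set:
        return {a.response_class for a in self.attractors}


def default_init_bank(
    n: int = 22,
    nai_range: tuple[float, float] = (3.8, 5.8),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial-condition bank for the surrogate census (full coordinates).

    Half the bank pairs a [Na+]i grid with a resting membrane (polarised,
    recovered gate, low Ca load); half with a plateau membrane
    (depolarised, partly inactivated gate, high Ca load) -- the analogue of
    the low/high Ca-load split.  With ``rng`` given, states are jittered to
    make arbitrarily large banks.
    """
    n_each = max(n // 2, 1)
    nais = np.linspace(*nai_range, n_each)
    rest = [np.array([-85.5, 0.999, na, 5.0e-5]) for na in nais]
    plateau = [np.array([0.0, 0.30, na, 1.0e-3]) for na in nais]
    bank = np.array(rest + plateau)
    if rng is not None:
        jitter = rng.uniform(-1.0, 1.0, size=bank.shape)
        bank = bank + jitter * np.array([4.0, 0.05, 0.1, 2.0e-5])
        bank[:, 1] = np.clip(bank[:, 1], 0.0, 1.0)
        bank[:, 2:] = np.maximum(bank[:, 2:], 1.0e-6)
    return bank[:n] if len(bank) >= n else bank


def multistability_census(
    system: PacedFlowMap,
    init_bank,
    tol: float = 1e-8,
    max_beats: int = 250,
    merge_radius: float = CENSUS_MERGE_RADIUS,
    polish: bool = True,
    polish_rtol: float | None = None,
    with_features: bool = False,
) -> CensusEntry:
    """Settle every bank state and collect the distinct attractors reached.

    Runs merge early once they come within ``merge_radius`` (raw mixed
    units) of an attractor already found; the first run reaching a new
    attractor settles to the full ``tol`` criterion.  ``polish=True``
    additionally refines each attractor by Newton shooting (optionally on
    ``polish_system``, e.g. a tighter-tolerance copy) and records the
    polish displacement, so the census states are genuine fixed points.
    Non-converged runs are counted as irregular, not as attractors.
    """
    bank = [np.asarray(b, dtype=float) for b in init_bank]
    try:
        param_value = float(system.get_param("pct_gkr"))
    except (KeyError, AttributeError, TypeError):
        param_value = float("nan")
    entry = CensusEntry(param_value=param_value)
    entry.n_starts = len(bank)
    psys = system
    if polish and polish_rtol is not None:
        psys = PacedFlowMap(
            system.model, system.params, rtol=polish_rtol,
            atol=polish_rtol * 1e-2, method=system.method,
            jac_method=system.jac_method,
        )
    known: list[Attractor] = []
    # a period-k orbit is one attractor with k stroboscopic phases; runs
    # may converge onto any phase, so merging compares against all of them
    merge_states: list[np.ndarray] = []
    merge_owner: list[int] = []
    for x0 in bank:
        x = system.from_full(x0) if x0.shape[0] != system.dimension else x0
        res = run_to_steady_state(
            system, x, max_beats=max_beats, tol=tol,
            stop_near=merge_states or None,
            merge_tol=merge_radius,
        )
        if res.merged_with is not None:
            known[merge_owner[res.merged_with]].n_basin_hits += 1
            continue
        if not res.converged:
            entry.n_irregular += 1
            continue
        # de-alias the detected period: the k-beat residual criterion can
        # trigger at k > true period within integration noise, so the true
        # period is the smallest j whose j-beat excursion is negligible
        orbit = [res.state]
        for _ in range(res.period - 1):
            orbit.append(system.map(orbit[-1]))
        period = res.period
        for j in range(1, res.period):
            if res.period % j == 0:
                if float(np.max(np.abs(orbit[j] - orbit[0]))) < 1e-3:
                    period = j
                    orbit = orbit[:j]
                    break
        matched_known = None
        for st, owner in zip(merge_states, merge_owner):
            if float(np.max(np.abs(res.state - st))) < ATTRACTOR_DISTINCT_TOL:
                matched_known = owner
                break
        if matched_known is not None:
            known[matched_known].n_basin_hits += 1
            continue
        state = orbit[0]
        shift = float("nan")
        mult = None
        if polish:
            fp = newton_shoot(psys, state, k=period, tol=max(tol, 1e-8))
            if not fp.converged:
                # map-level FD Jacobians can fail near grazing orbits where
                # the map is extremely sensitive at the FD-step scale; the
                # variational route stays accurate there
                vsys = PacedFlowMap(
                    psys.model, psys.params, rtol=psys.rtol, atol=psys.atol,
                    method=psys.method, jac_method="variational",
                )
                fp = newton_shoot(vsys, state, k=period, tol=max(tol, 1e-8))
            if fp.converged:
                shift = float(np.max(np.abs(fp.x - state)))
                state = fp.x
                mult = fp.multipliers
                orbit = [state]
                for _ in range(period - 1):
                    orbit.append(system.map(orbit[-1]))
        att = Attractor(
            state=state,
            period=period,
            n_basin_hits=1,
            settle_residual=res.residual,
            polish_shift=shift,
            multipliers=mult,
        )
        if with_features:
            feats = _features_at(system, att.state, period=period)
            att.response_class = classify_response(feats, converged=True)
        idx = len(known)
        known.append(att)
        for st in orbit:
            merge_states.append(st)
            merge_owner.append(idx)
    entry.attractors = known
    return entry


# ---------------------------------------------------------------------------
# perturbation protocol


def perturb_and_settle(
    system: PacedFlowMap,
    state: np.ndarray,
    delta: float,
    var_name: str = "Nai",
    tol: float = 1e-8,
    max_beats: int = 300,
):
    """Instantaneously add ``delta`` to one state component at stimulus
    onset and settle; the tool for hopping between coexisting attractors."""
    idx = system.state_names.index(var_name)
    x = np.asarray(state, dtype=float).copy()
    x[idx] += delta
    res = run_to_steady_state(system, x, max_beats=max_beats, tol=tol)
    feats = _features_at(system, res.state, period=res.period)
    cls = classify_response(feats, converged=res.converged)
    return cls, res


# ---------------------------------------------------------------------------
# diagrams


def build_bifurcation_diagram(
    system: PacedFlowMap | None,
    branches: list[Branch],
    bif_points: list[BifurcationPoint] | None = None,
    with_features: bool = False,
) -> pd.DataFrame:
    """Tidy table of branch points: parameter, stability, multipliers and
    (optionally) per-orbit features -- the machine-readable twin of a
    one-parameter bifurcation diagram."""
    rows = []
    for bi, br in enumerate(branches):
        for fp, lam in zip(br.points, br.params):
            row = {
                "branch": bi,
                "param": br.param_name,
                "param_value": lam,
                "k": br.k,
                "stable": fp.stable,
                "leading_multiplier_mod": float(np.abs(fp.multipliers[0])),
                "residual": fp.residual,
            }
            for name, v in zip(_branch_state_names(system, fp), fp.x):
                row[name] = float(v)
            if with_features and system is not None and fp.stable:
                feats = _features_at(system_at(system, br.param_name, lam),
                                     fp.x, period=br.k)
                f0 = feats[0]
                row.update(
                    apd90=f0.apd90, n_tdmp=f0.n_tdmp,
                    response_class=classify_response(feats),
                    dia_nai=f0.dia_nai, dia_cai=f0.dia_cai,
                )
            rows.append(row)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(
            columns=["branch", "param", "param_value", "k", "stable",
                     "leading_multiplier_mod", "residual"]
        )
    if bif_points:
        df.attrs["bifurcations"] = [bp.to_dict() for bp in bif_points]
    return df


def _branch_state_names(system, fp):
    if system is not None:
        return system.state_names
    return tuple(f"x{i}" for i in range(len(fp.x)))


def system_at(system: PacedFlowMap, param_name: str, value: float):
    system.set_param(param_name, value)
    return system


def stable_overlap_windows(branches: list[Branch]) -> list[tuple[float, float]]:
    """Parameter intervals where >= 2 branches are simultaneously stable
    (the multistability windows shaded in bifurcation diagrams)."""
    intervals = []
    for br in branches:
        intervals.extend(br.stable_intervals())
    windows = []
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            lo = max(intervals[i][0], intervals[j][0])
            hi = min(intervals[i][1], intervals[j][1])
            if lo < hi:
                windows.append((lo, hi))
    windows.sort()
    merged: list[tuple[float, float]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# [Na+]i-fixed analysis


def nai_fixed_analysis(
    system_factory,
    nai_values,
    init_bank,
    tol: float = 1e-8,
    max_beats: int = 250,
) -> dict[float, CensusEntry]:
    """Census of the [Na+]i-clamped system at each clamp value.

    ``system_factory(nai_clamp)`` must return the clamped stroboscopic
    system.  The bank states are full-coordinate; the clamped component is
    dropped automatically.  Comparing the reported orders against the
    free-[Na+]i census answers whether the multistability is [Na+]i-driven.
    """
    out: dict[float, CensusEntry] = {}
    for clamp in nai_values:
        system = system_factory(float(clamp))
        entry = multistability_census(
            system, init_bank, tol=tol, max_beats=max_beats, polish=False,
        )
        entry.param_value = float(clamp)
        out[float(clamp)] = entry
    return out
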