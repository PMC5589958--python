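# eadyn

Bifurcation and multistability analysis of early afterdepolarisations
(EADs) in paced cardiac myocyte models.

Drug- or disease-induced loss of repolarisation reserve -- reduction of
the rapid (IKr) and slow (IKs) delayed-rectifier K+ currents -- can
prolong the ventricular action potential (AP) until EADs appear, a
trigger of lethal arrhythmias.  Viewed through dynamical-systems theory,
a paced myocyte is a periodically forced ODE system: each steady AP
response is a fixed point of the stroboscopic Poincare map `P` over one
pacing cycle, its stability is given by the characteristic multipliers
(eigenvalues of the monodromy matrix `DP`), and EAD onset, disappearance
and coexistence are organised by saddle-node (multiplier through +1),
period-doubling (through −1) and Neimark-Sacker (complex pair)
bifurcations as the conductance scalings %GKr/%GKs vary.  Because
several stable responses can coexist, conductance sweeps show hysteresis,
and the observed AP depends on the ionic history ([Na+]i above all) of
the cell.

The package provides, for any model implementing a small rhs-provider
protocol:

* segmented stiff integration of paced beats and the 1e-8 stroboscopic
  steady-state criterion, with period-2/4 flagging (`pacing_sim`);
* Newton shooting for stable *and unstable* period-k responses, with
  variational-equation and finite-difference monodromy routes
  (`shooting`);
* pseudo-arclength continuation that rounds folds, multiplier tracking,
  SN/PD/NS classification and bisection localization (`continuation`);
* per-beat AP measurements -- APD90, EAD count (#TDMP), diastolic
  [Na+]i/[Ca2+]i -- and response classification, including
  repolarisation-failure (LAVO) detection (`ap_features`);
* the experiment protocols: hysteresis sweeps with state carry-over,
  a brute-force multistability census over an initial-condition bank,
  [Na+]i perturbation hopping and the [Na+]i-clamped analysis
  (`protocols`);
* a validation test bed of systems with closed-form dynamics (logistic
  and delayed-logistic maps, saddle-node normal form, a forced linear
  ODE) plus a frozen four-variable paced-myocyte surrogate with verified
  bistability and hysteresis (`testbed`, `vm_model`);
* a YAML-configured CLI: `eadyn simulate | sweep | continue | census |
  clamp-scan | selftest` (`config`, `cli`, `io`).

## Worked example

Locate the fold that annihilates the surrogate's short-AP response and
the destabilisation of the coexisting depolarised response, then confirm
the hysteresis loop that stretches between them:

```python
import numpy as np
from eadyn import continue_branch, detect_crossings, localize_bifurcation
from eadyn import newton_shoot, run_to_steady_state
from eadyn.testbed import make_paced_surrogate_ap

ts = make_paced_surrogate_ap(pct_gkr=47.0)   # bistable frozen surrogate
fm = ts.system

# settle the short AP at 47 %GKr, then continue it down through its fold
rest = np.array([-85.5, 0.999, 5.3, 2e-5])
fp = newton_shoot(fm, run_to_steady_state(fm, rest, tol=1e-8).state, tol=1e-8)
short = continue_branch(fm, "pct_gkr", fp.x, (47.0, 34.0), 1.0,
                        tol=1e-8, ds_max=2.0, max_points=60)
sn = [localize_bifurcation(fm, short, c, tol=1e-8, s_tol=1e-5)
      for c in detect_crossings(short) if c.kind == "SN"][0]
print(f"short-AP branch folds at {sn.param_value:.3f} %GKr "
      f"(critical multiplier {sn.critical_multiplier.real:.6f})")
```

```
short-AP branch folds at 35.425 %GKr (critical multiplier 0.999996)
```

Below 35.4 %GKr the short AP no longer exists and the cell lands on the
depolarised, repolarisation-failing response; that response stays stable
up to 44.6 %GKr.  A 1 %-step down sweep therefore loses the short AP at
the 36 -> 35 step, while the up sweep only loses the depolarised response
at 44 -> 45 -- a hysteresis loop ten grid steps wide, carried by the slow
beat-to-beat [Na+]i balance: clamping [Na+]i collapses the census order
to 1.  (A stable period-2 alternans orbit additionally coexists over
roughly 39-44.5 %GKr, making the model tri-stable there.)

## Scope

The full mid-myocardial human ventricular myocyte model whose EAD
dynamics motivate this package is not bundled (its kinetic equations are
distributed as a PHML resource at physiodesigner.org); any model exposing
the documented rhs-provider protocol plugs into the same machinery.  See
`docs/methods.md` for the model contract, the numerical choices and the
verified structure of the bundled surrogate.
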