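# Methods

## The dynamical picture

A periodically paced ventricular myocyte is a non-autonomous ODE system

    dVm/dt = Istim(t) - (ICaL + IKr + IKs + Ito + INa + IK1
                          + INab + ICab + INaK + INCX + IpCa),

with gating variables and intracellular ion concentrations completing the
state, and a square stimulus pulse (default 80 pA/pF, 1 ms, cycle length
2000 ms) providing the forcing period T.  Every steady paced response --
normal APs, APs carrying early afterdepolarisations (EADs), and
low-amplitude plateau oscillations with repolarisation failure (LAVO) --
is a periodic orbit, i.e. a fixed point of the stroboscopic Poincare map
P that advances the state by one pacing cycle, sampled at stimulus onset.
A period-k response (e.g. alternans) is a fixed point of P^k.

Stability is decided by the characteristic multipliers: the eigenvalues
of the monodromy matrix DP^k evaluated on the orbit.  Because the system
is non-autonomous there is no trivial multiplier pinned at +1; a response
is stable iff all multipliers lie strictly inside the unit circle.  The
three generic ways a response is created, destroyed or destabilised are
read off how a multiplier exits the circle: through +1 (saddle-node, SN:
a stable/unstable pair coalesces and annihilates), through -1
(period-doubling, PD), or as a complex pair (Neimark-Sacker, NS:
quasi-periodicity).  Hysteresis and multistability arise when several
stable fixed points coexist over a window of a conductance parameter.

The conductance axis is repolarisation reserve: IKr and IKs are scaled
linearly as a percentage of their control conductances (0.00738 and
0.0257 nS/pF respectively), written %GKr and %GKs.

## Numerical machinery

**Integration.** Cycles are integrated with SciPy's adaptive solvers
(LSODA by default), segmented at the pulse edges so the stimulus
discontinuity never falls inside an adaptive step.  Default tolerances
are rtol 1e-8 / atol 1e-10; branch-structure computations on the bundled
surrogate use rtol 1e-10 / atol 1e-12 because Newton residuals must be
resolved below the map's evaluation roughness (an adaptive solver's step
sequence responds discontinuously to tiny changes in the initial state,
which sets a floor of roughly rtol x |Vm| on how smoothly P can be
evaluated).

**Steady-state criterion.** A paced run is converged when the maximum
absolute component-wise difference between the stroboscopic samples of
consecutive beats falls below 1e-8, applied to the raw mixed-unit state
(mV, mM, dimensionless) with no rescaling.  The residual is additionally
tested against the samples 2 and 4 beats apart, so alternans converges as
a flagged period-2 (or period-4) response instead of failing silently;
quasi-periodic responses legitimately fail and are flagged irregular.

**Monodromy.** Two routes are implemented and cross-checked against each
other (and against the closed-form forced linear system):

* *variational*: the linearised flow is integrated alongside the orbit,
  with the rhs Jacobian obtained by central differences of the model
  right-hand side using per-variable-class steps (1e-6 x a scale of
  100 mV / 1 / 10 mM / 1e-3 mM); the augmented (Jacobian) integration is
  capped at rtol 1e-8 while the map itself keeps the system tolerance --
  residuals must be resolved tightly, Jacobians only to a few digits;
* *finite differences of the map*: central differences of P itself with
  relative step 1e-3 per variable scale -- the step must sit well above
  the integration noise floor, which is why it is much larger than the
  rhs-level step.

The variational route is the reference and is also the robust choice for
*near-grazing* orbits -- the period-2 alternans beats and the marginal
saddle AP pass so close to the repolarisation threshold that the map
responds extremely sharply at the FD-step scale, making map-level
differences unusable there.  Away from grazing, the map-FD route is used
inside continuation loops where, at the surrogate's dimension (4), it is
cheaper.  Both must agree to 1e-4 relative on the surrogate (tested).

**Shooting.** Period-k responses are solved from P^k(x) - x = 0 by damped
Newton (step halving, at most 8 halvings) with the monodromy-based
Jacobian.  Newton converges to unstable fixed points as readily as to
stable ones, which is what makes the unstable branch segments computable.
Near a bifurcation the shooting matrix DP^k - I is near-singular; its
smallest singular value is reported as a detection signal rather than
raised as an error.  Default residual tolerance is 1e-9 (infinity norm,
raw mixed units); continuation on ODE systems uses 1e-8 because the
orbit-dependent evaluation roughness of the depolarised responses sits
just under that.

**Continuation.** Branches are traced with a secant predictor and a
pseudo-arclength Newton corrector (the hyperplane constraint is imposed
in scaled coordinates), so saddle-node folds are rounded onto their
unstable side -- a natural-parameter sweep cannot do this.  The step is
halved on corrector failure, grown by 1.3x after three consecutive
successes and kept within [1e-4, ds_max].  A corrected point whose
distance from the predictor exceeds four predictor steps is rejected:
without this guard the corrector can slide silently onto a *coexisting*
branch near a fold.  The arclength metric uses branch-scale weights
rather than absolute state magnitudes (for the surrogate: 10 mV, 1, 0.1
mM, 1e-4 mM): if the parameter direction dominates the metric, the
corrector hyperplane degenerates to "parameter = constant" and folds can
never be rounded.

**Detection and localization.** Multipliers of consecutive branch points
are paired by nearest-neighbour matching (so a real crossing of -1 is
never confused with a complex pair; a pair needs |Im| > 1e-6 to count as
complex).  Candidate crossings -- through +1 (SN, co-detected with a
parameter-direction reversal), through -1 (PD), or by modulus (NS) -- are
refined by bisection *along the branch* on the signed distance of the
critical multiplier from its critical value.  Bisection in arclength
remains well-posed at folds where the parameter itself is not monotone.
On the closed-form oracles this localizes the logistic PD at r = 3, the
delayed-logistic NS at r = 2 (both to 1e-6) and the saddle-node normal
form fold at mu = 0 to 1e-9.

**Per-beat measurements.** APD90 takes the per-beat baseline at stimulus
onset and the threshold at Vpeak - 0.9 (Vpeak - baseline), using the
*last* downward crossing so EAD re-depolarisations extend the measured
duration; repolarisation failure (still above threshold at cycle end, or
never below the -40 mV phase-2/3 floor) is flagged rather than measured.
The EAD count (#TDMP) is the number of local Vm maxima after the primary
upstroke peak with prominence >= 1 mV occurring above -40 mV; floor and
prominence are declared conventions chosen to be robust to integrator
jitter, and the count is invariant to resampling at or above 2 kHz
(tested).  Responses classify as noEAD / EAD1..EAD3 / EADk by the modal
count over the detected period, LAVO on repolarisation failure with
plateau oscillation, irregular without periodic convergence.

**Census.** The multistability census settles a declared bank of initial
conditions and counts distinct attractors (stroboscopic states differing
by more than 1e-4 in the raw mixed-unit norm).  It is a lower bound on
the true order, since the bank is finite.  Three refinements matter in
practice: runs merge early once within 0.02 of a known attractor (far
inside any basin here -- inter-attractor distances are O(10) in these
units); a detected period k is de-aliased by checking whether the j-beat
excursion (j | k) is below 1e-3, because the k-beat residual criterion
can trigger at an aliased multiple within integration noise; and a
period-k orbit's k stroboscopic phases are treated as one attractor.
Census attractors are optionally polished by Newton shooting at a tighter
integration tolerance, with the polish displacement recorded, so that
census states are genuine fixed points comparable to continuation output
at the 1e-6 level.

## The bundled surrogate myocyte

The full mid-myocardial ionic model this machinery is aimed at is not
bundled: its current-by-current kinetic formulation lives in its original
publication and in the PHML resource at physiodesigner.org, and
transcribing it is an (intended) plug-in exercise via the model-provider
protocol.  The bundled `MinimalMyocyteModel` is a four-variable synthetic
myocyte built to reproduce the *dynamical structure* the analysis
targets, not physiological quantities:

* fast membrane with ICaL (instantaneous activation, slow
  voltage-dependent inactivation gate f, Ca-dependent inactivation),
  IKr and IKs scaled by %GKr/%GKs, IK1, background Na current and a
  sarcolemmal Ca pump;
* a slow intracellular Na pool fed by the exchanger and background
  currents (mostly during diastole) and drained by the Na/K pump
  (mostly during the AP) -- the beat-to-beat memory variable;
* a Ca pool with a lumped uptake term standing in for
  sarcoplasmic-reticulum buffering.

An IKr gain constant (3x) gives the %GKr axis real leverage
while the control conductances keep their standard values.  The surrogate
is paced at 80 pA/pF, 1 ms, 1400 ms cycle length.  Its kinetic constants
are frozen in code (no randomness), and the resulting structure is
re-derived by the test suite:

* a short-AP branch that folds (SN, a real multiplier through +1) at
  about 35.4 %GKr;
* a depolarised long response (repolarisation failure with low-amplitude
  plateau oscillation, LAVO-like) stable from low %GKr up to about
  44.6 %GKr, where a real multiplier leaves the unit circle through +1
  across a very sharp boundary layer (the branch does not fold in the
  parameter there; past the layer the leading multiplier is O(10), and a
  -1 crossing follows on the already-unstable segment);
* between roughly 39 and 44.5 %GKr a stable period-2 alternans orbit
  additionally coexists, so the model is tri-stable there;
* 1%-step conductance sweeps with state carry-over reproduce the
  hysteresis loop: the short AP is lost at the fold on the way down
  (36 -> 35), the long response at its destabilisation on the way up
  (44 -> 45), about ten conductance-percent apart;
* clamping the Na pool (the [Na+]i-fixed system) removes the coexistence
  entirely -- the census order collapses to 1 -- identifying the slow Na
  balance as the carrier of the multistability.

What the surrogate does *not* emulate: physiological APD/conductance
magnitudes, the full EAD taxonomy (EAD2/EAD3 as separate branches),
sarcoplasmic-reticulum Ca cycling, and any quantitative bifurcation
location of the full ionic model.  Tests passing on the surrogate
demonstrate that the machinery -- shooting, monodromy, classification,
continuation, sweeps, census, clamp -- is correct on a system with the
same dynamical skeleton; they say nothing quantitative about a real
myocyte.

## Numerical choices and degenerate cases

* The saddle between the two basins is computable near the fold, but its
  unstable multiplier grows extremely fast along the branch (10 -> 150
  within one %GKr); beyond that, single shooting cannot meet a 1e-9
  residual (state would need accuracy below the integration noise floor)
  and the branch is truncated with a diagnostic.  Multiple shooting is
  deliberately out of scope.
* The long branch's upper stability boundary is a boundary-layer event:
  multipliers vary smoothly but over ~1e-4 in %GKr.  Localization by
  bisection lands on the layer; the reported critical multiplier is then
  not exactly on the unit circle and the localization width is the
  honest error bar.
* Period-doubled branches are continued on the P^2 map when seeded from a
  period-2 response found by simulation; automatic branch *switching* at
  a PD point is not implemented.
* A sweep step is called a transition when the carried steady state
  jumps by more than 2 raw mixed units between consecutive grid values
  (inter-attractor distances here are O(10-80), while drift of a single
  branch across a 1% step stays near or below 1).
* The [Na+]i clamp removes the Nai row/column from the map coordinates,
  so the multiplier count equals the effective dimension (3, not 4).

## Problem sizes

The test suite and the acceptance script run everything at the sizes
reported in their output: map-oracle branches of 20-70 points; surrogate
branches of 30-60 points; 1%-step sweeps over 33-47 %GKr; a 50-start
census at 20 parameter values (tests) or 5 values (acceptance script);
clamp censuses of 10 starts at two clamp values.  These sizes were chosen
so the full structure (two folds' worth of branches, the alternans
branch, the hysteresis loop and the census) is re-derived from scratch on
one CPU in minutes.
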