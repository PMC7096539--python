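# Methods

## The model

The package analyzes a phenomenological neural mass model of partial
seizures built from three coupled timescales:

- a **fast subsystem** (x1, y1) generating the fast discharges of the
  ictal state, with a cubic nullcline branch for x1 < 0 and a straight
  branch of slope m + 0.6(z−4)² for x1 ≥ 0 (in the full model the slope
  is additionally lowered by x2);
- a **spike-wave subsystem** (x2, y2) with its own cubic/piecewise-linear
  nullcline pair, relaxing on a timescale τ2;
- a **slow permittivity variable z**, which drifts at rate r ≪ 1 toward
  s(x1 − x0) and autonomously carries the system back and forth between
  the normal and ictal states.

The drive of the spike-wave subsystem is modulated by z and by a low-pass
filtered copy g of x1. The convolution defining g is integrated as the
equivalent ODE `g' = x1 − γ g` carried as a sixth state, which produces
the identical trajectory without storing history.

Two slow laws are implemented. The default ("modified") law adds a
−0.1 z⁷ term for z < 0, which stabilizes a large-amplitude fast-slow
limit cycle (LC) at negative z. The "original" law, linear in z for all
z, genuinely diverges when started below the saddle orbit separating the
seizure-like attractor from LC; the integrator truncates such runs and
flags them rather than raising, because that divergence is part of the
model's documented repertoire.

### The filter variable in equilibrium analysis

Whether the 0.002·g feedback enters the algebraic equilibrium system is
genuinely ambiguous: the published equilibrium **counts** (one saddle at
x0 = −1.6, three points at x0 = −0.9) require it omitted, while the
published **class** of the normal state at x0 = −2.5 (a stable node)
requires g at its stationary value x1/γ, which is also the honest
linearization of the six-state flow. Both conventions are exposed via
`ParameterSet.g_convention`:

- `"omit"` (default): matches the published 5×5 Jacobian and equilibrium
  counts; all reported values use this convention unless stated.
- `"stationary"`: substitutes g\* = x1/γ, adding 0.002/γ to the x2-row
  x1-column of the Jacobian.

Frozen-z *diagram* analysis (the continuation module) always carries the
stationary g drive, because only that choice reproduces the published
branch structure at Iext2 = 0.45 (normal-state branch of stable nodes,
ictal branch of unstable foci); its ensembles integrate g as a dynamic
fifth fast variable. The two choices are consistent where they overlap
and are documented at the call sites.

### Stability taxonomy

Classification follows the convention of the source analysis rather than
the strict textbook one for dimensions > 2: an equilibrium with mixed
eigenvalue signs is a **saddle** when at least one unstable eigenvalue is
real (a one-dimensional escape direction — the separatrix mechanism),
and an **unstable focus** when the only unstable directions are complex
pairs (the trajectory spirals out). All-stable and all-unstable spectra
split into node/focus by the imaginary parts. Eigenvalues with
|Re λ| < `real_tol` (default 1e−7) yield a MARGINAL flag instead of a
class, marking bifurcation proximity.

A second, *outer* family of equilibria exists beyond the outer fold of
the x1 ≥ 0 branch (z ≳ 7 at default parameters). It plays no role in the
model's repertoire and is excluded from default queries by the principal
analysis window z ∈ [−2, 6] (`z_window=None` reports everything).

## Numerics

- **Deterministic integration**: classical fixed-step RK4 with maximal
  step 0.01 (the step used for the published deterministic runs).
  Fixed-step rather than adaptive keeps event timing exactly
  reproducible. An overflow guard at |state| > 1e6 truncates and flags
  divergent runs.
- **Stochastic integration**: Euler–Maruyama with additive Gaussian
  white noise, default variance 0.0025 applied to the fast activity
  variables x1 and x2 (which equations carry noise is not specified in
  the source; the choice is configurable and affects only qualitative
  stochastic runs — every reported value is deterministic). Identical
  seeds give bitwise-identical trajectories.
- **Frozen-z ensembles**: the fast equations at many z values are
  integrated simultaneously (vectorized RK4 over the batch). The
  default step is 0.02; the averaged-curve computation uses 0.005
  because the large-amplitude relaxation cycles at negative z reach
  x1 ≈ −12, where the cubic branch has local decay rates of order 5·10²
  that a coarser fixed step cannot resolve stably.
- **Cycle detection**: after a 300-unit transient, the x1 series over a
  300–400-unit window gives peak/trough; peak-to-peak amplitude below
  1e−2 is treated as a point attractor, fewer than two upward midline
  crossings as a long-period ("long") cycle. The period is the mean
  spacing of upward crossings and ⟨x1⟩ the time average over the integer
  number of periods between the first and last crossing.

## Equilibrium solving

The piecewise-polynomial structure makes most equilibrium problems
exact: the fast subsystem reduces to a cubic (x1 < 0) plus a quadratic
(x1 ≥ 0), the spike-wave subsystem to two cubics, and the frozen-z full
fast system factorizes (the x2 cubic decouples from x1 under the "omit"
convention; under the stationary drive the weak 0.2·x1 coupling is
resolved by fixed-point seeding plus a 2-D Newton polish). Only the free
five-variable equilibrium problem needs a numeric solve: multi-start
damped Newton (`scipy.optimize.root`, hybr) with starts seeded from the
slow nullcline (which is strictly monotone in z, so z is unique per x1)
crossed with the x2-cubic roots, the z row scaled by 1/r for
conditioning, solutions deduplicated at 1e−8 and accepted only below a
residual of 1e−10.

Several closed forms whose radicals were lost in the source rendering
were re-derived from Tr(J) = 0 / Det(J) = 0 and are verified against
numeric eigenvalue sweeps in the test suite:

- upper-branch equilibria x1 = (R ± √δ⁺)/(2d), R = m + 0.6(z−4)²,
  δ⁺ = R² + 4d(c − z + Iext1);
- Hopf of the upper branch z(H) = 4 − √((5/3)(1−m)) for m ≤ 1;
- lower fold z(SN1) = Iext1 − 5/27 (extremum of the cubic branch at
  x1 = 2(b−d)/(3a) = −4/3);
- upper fold z(SN2) = c + Iext1 for m ≤ 0, else min(X) + 4 with X the
  real roots of X⁴ + pX² + qX + w (p = 10m/3, q = −500/9,
  w = (25/9)(m² + 20(Iext1 − 3)) at default c, d);
- spike-wave Det root x2 = −1/√3 and trace roots ±√((1 − 1/τ2)/3).

The printed SNIC drive expression is inconsistent in sign with the
stated value; the equilibrium condition I = x2³ − x2 + f2(x2) evaluated
at the Det root gives 2/(3√3) ≈ 0.385, which the root-count flip
confirms, and is the form implemented.

## Continuation and bifurcation detection

Diagrams are built by the stated grid procedure (solve at every z;
default 801 points over [−2, 6], tests use 41–401) rather than
pseudo-arclength: equilibria at neighboring grid points are linked by
nearest-x1 matching and the linked curves split into
stability-homogeneous branches. Folds are located by bisection on the
equilibrium count, Hopf points by bisection on the real part of the
tracked complex pair. Cycle terminations are tagged:

- **HOPF** — the focus the cycle surrounds flips stability across the
  termination (with no fold inside the cycle's x1 band), or the terminal
  amplitude falls below 3× the point threshold;
- **SNIC vs HOMOCLINIC** — both show period growth; they are separated
  by whether the newborn node–saddle pair lies on the cycle *and* the
  cycle dies exactly at the fold. The cycle's disappearance point is
  bisected by direct integration (1500-unit transients, long enough to
  pass the saddle-node ghost bottleneck) and compared with the fold
  location: coexistence beyond 0.006 z-units means the cycle died on a
  pre-existing saddle (homoclinic). Below that resolution the two
  scenarios merge into the saddle-node-loop codimension-2 point and the
  call is genuinely ambiguous — the fast subsystem at m = 2 terminates
  only 0.012 z-units past the fold and is resolved correctly.

`classify_sle` requires a unique saddle equilibrium (otherwise the
trajectory parks on a stable point and no autonomous seizure-like event
exists), takes onset as the lower fold SN1, and names the offset from
the fate of the upper attractor reached just below SN1: a cycle ending
in HOPF / SNIC / HOMOCLINIC gives fold/Hopf, fold/circle,
fold/homoclinic; a stable point gives fold/fold, subtyped as
depolarization block when the discharge-generating x1-block of the
Jacobian is a node (zero imaginary parts) rather than a focus. The
bistability interval is [SN1, HB] for homoclinic offsets and [SN1, SN2]
otherwise, with SN2 the refined end of the stable upper branch.

## Averaging

⟨x1⟩(z) is computed on a 400-point z grid over [−2.5, 4.25] (cycle
average where the upper fast attractor is a cycle, equilibrium value
where it is a point; grid points whose attractor is the lower branch are
masked). Because x0 enters the slow averaged nullcline linearly, one
curve serves every x0. Orbit roots are bracketed by sign changes on the
grid and refined by bisection on the interpolant to 1e−4 in z; stability
is the sign of the central-difference slope (one grid cell), since ⟨x1⟩
is itself a numerical estimate. Labels follow z-order: the lowest-z
stable root is the large fast-slow cycle LC, higher stable roots are
small cycles (SLC), unstable roots are saddle orbits S. SNPO points are
found by bisection in x0 on the root count (tolerance 1e−3 in the
module, 0.02 asserted in tests).

## Behavior atlas

`classify_behavior` labels one deterministic run by rules on the
stationary segment, in priority order: overflow → DIVERGENT; z dipping
below 0.5 → LC_RSE (the fast-slow cycle lives at low/negative z);
sustained alternation between low/high-x1 plateaus (30-time-unit
debounce, so neither individual discharges nor the short gaps of chaotic
spiking count) → the SLE/switch classes, subtyped by `classify_sle`;
quiet x1 in the terminal window (the last ≤ 800 units — z relaxes on the
1/r ≈ 3000-unit timescale, so rest states are judged from the end of the
run) → NORMAL_STATE / NONOSCILLATORY / DB by branch side and the
x1-block eigenstructure; otherwise sustained spiking → CHAOTIC when the
interspike-interval coefficient of variation exceeds 0.2, else
SLC_PERIODIC. Chaos is diagnosed by ISI irregularity only; no Lyapunov
exponents are computed. Thresholds (plateau debounce, spike threshold =
mid-range, CV cutoff) are keyword-exposed.

## Problem sizes and defaults

Reported computations use: 41–401-point continuation grids (the 801
default is kept in the API), 400-point averaged curves at dt = 0.005,
ensemble transients of 300–1500 time units, and full-model runs of
2000–8000 time units at dt = 0.01. The nonoscillatory rest state at
(m, x0) = (0, −0.9) needs ≈ 8000 units because z must traverse its own
1/r timescale before settling.

## Limitations

- Saddle cycles are established through the averaged slope, not Floquet
  multipliers; homoclinic/SNIC terminations within 0.006 z-units of a
  fold are reported as SNIC (the codimension-2 ambiguity above).
- Region boundaries in (m, x0) are resolved per grid point; no
  two-parameter continuation of codimension-2 curves is attempted.
- The behavior rules assume the run outlasts the slow transient; labels
  are stable under duration doubling once settled, but a too-short run
  of a slowly-converging rest state reads as its transient (documented
  in the atlas tests).
- No spatial coupling between multiple model instances, and no fitting
  to electrographic recordings.
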