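# epileptor

A dynamical-systems analysis toolkit for a slow-fast neural mass model
of epileptic seizures, refractory status epilepticus (RSE), and
depolarization block (DB).

## The scientific problem

Seizure-like events (SLEs) in a widely used phenomenological neural mass
model arise from a slow-fast structure: a fast discharge-generating
oscillator (x1, y1) and an intermediate spike-wave oscillator (x2, y2)
are both steered by a very slow permittivity variable z,

    x1' = y1 − f1(x1, x2) − z + Iext1
    y1' = c − d x1² − y1
    z'  = r (s (x1 − x0) − z − 0.1 z⁷·[z<0])
    x2' = −y2 + x2 − x2³ + Iext2 + 0.002 g − 0.3 (z − 3.5)
    y2' = (−y2 + f2(x2)) / τ2,     g' = x1 − γ g

with f1 cubic for x1 < 0 and linear of slope m + 0.6(z−4)² (minus x2 in
the full model) for x1 ≥ 0, and f2 piecewise linear. As z drifts, the
fast dynamics crosses bifurcations: seizures start at a fold (SN1) of
the normal-state branch and end — depending on m and Iext2 — at a
homoclinic, saddle-node-on-invariant-circle (SNIC), Hopf, or second fold
bifurcation, defining the burster classes fold/homoclinic, fold/circle,
fold/Hopf, and fold/fold. A stabilizing z⁷ term supports an additional
large-amplitude fast-slow limit cycle (LC, an RSE-like state), small
tonic-spiking cycles (SLC), depolarization block, and chaotic spiking.

The package implements, as tested library code plus a thin CLI:

- **systems / integrate** — the four systems (full model, uncoupled fast
  and spike-wave subsystems, fast-slow subsystem), analytic Jacobians,
  fixed-step RK4 (max step 0.01) and seeded Euler–Maruyama integration;
- **equilibria** — exact per-branch polynomial equilibrium solving,
  multi-start Newton for the full model, the eigenvalue stability
  taxonomy, closed-form fold/Hopf/SNIC locations, and the printed
  trace/determinant stability tables as executable checks;
- **continuation** — (z, x1) bifurcation diagrams by grid continuation,
  limit-cycle envelopes at frozen z, fold/Hopf detection, and
  onset/offset (burster class) classification;
- **averaging** — the Pontryagin averaging method: ⟨x1⟩(z), the slow
  averaged nullcline, periodic orbits LC/S/SLC with stability from
  d⟨ż⟩/dz, x0 sweeps and saddle-node-of-periodic-orbits (SNPO) location;
- **atlas** — per-point (m, x0) classification: equilibrium multisets,
  orbit sets, behavior labels (normal state, nonoscillatory, SLE
  classes, DB–NS switching, LC/RSE, SLC, chaos via interspike-interval
  irregularity);
- **presets** — a registry of caption-faithful figure configurations.

## Worked example

Classify the seizure offset at the default operating point and locate
the periodic orbits of the fast-slow subsystem:

```python
from epileptor import ParameterSet, SystemId, classify_sle, find_equilibria
from epileptor.averaging import AveragedCurve, find_periodic_orbits, locate_snpo

p = ParameterSet()                      # m=0, x0=-1.6, Iext2=0.45, ...

eqs = find_equilibria(SystemId.FULL, p)
print(len(eqs), eqs[0].stability.value)
# 1 saddle        -> the regime admits autonomous seizure-like events

res = classify_sle(p)
print(res.label, res.bistability)
# fold/circle (2.9148148148148145, 4.134495849609375)
#   onset at the fold z(SN1) = Iext1 - 5/27 = 2.9148, offset through a
#   SNIC; the system is bistable between those z values

curve = AveragedCurve.compute(SystemId.SUB1, p)          # <x1>(z), m=0
print([(r.label, round(r.z, 3)) for r in
       find_periodic_orbits(-1.6, SystemId.SUB1, p, curve).roots])
# [('LC', -1.736), ('S', 1.114)]
#   the large fast-slow cycle and the saddle orbit separating its basin
#   from the seizure-like attractor

print(round(locate_snpo(SystemId.SUB1, p, (-2.8, -2.3), curve), 3))
# -2.451   -> below x0 = -2.45 the LC and S orbits have merged and gone
```

The same operations are available from the shell:

```bash
epileptor classify --m 0.5                    # fold/homoclinic
epileptor diagram --system sub1 --out diag.csv --points-out points.json
epileptor preset run fig1 --seed 7 --out sle.csv
```

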