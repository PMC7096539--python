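"""Per-point classification over the (m, x0) parameter plane.

Three complementary views are combined: the multiset of equilibria (from
the root solver), the set of periodic orbits of the slow-fast structure
(from the averaging method), and a rule-based label for the behavior a
deterministic simulation actually exhibits from a given initial
condition.  Chaos is diagnosed from interspike-interval irregularity,
as the coefficient of variation of the post-transient ISI sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .averaging import AveragedCurve, find_periodic_orbits
from .continuation import classify_sle
from .equilibria import StabilityClass, find_equilibria, sub1_closed_form_points
from .integrate import Trajectory, drop_transient, integrate_deterministic
from .params import ParameterSet
from .systems import SystemId

#: closed vocabulary of behaviors reachable from standard initial conditions
BEHAVIOR_LABELS = (
    "NORMAL_STATE",        # rest on the lower (normal) branch
    "NONOSCILLATORY",      # rest at the upper stable focus
    "SLE_HOMOCLINIC",      # seizure-like events, fold/homoclinic class
    "SLE_CIRCLE",          # seizure-like events, fold/circle class
    "SLE_HOPF",            # seizure-like events, fold/Hopf class
    "SWITCH_NONOSC_NS",    # fold/fold switch between nonoscillatory and normal
    "SWITCH_DB_NS",        # fold/fold switch between depolarization block and normal
    "DB",                  # rest in depolarization block (upper stable node)
    "LC_RSE",              # the large-amplitude fast-slow limit cycle
    "SLC_PERIODIC",        # small-amplitude tonic spiking at stationary z
    "CHAOTIC",             # irregular ISI spiking
    "DIVERGENT",           # overflow (original z law below the separatrix)
)


@dataclass
class IsiSeries:
    """Interspike intervals of one trajectory component."""

    spike_times: np.ndarray
    intervals: np.ndarray

    @property
    def cv(self) -> float:
        """Coefficient of variation of the intervals (the chaos metric)."""
        return float(np.std(self.intervals) / np.mean(self.intervals))


def isi(
    traj: Trajectory,
    component: str = "x1",
    threshold: Optional[float] = None,
    transient_fraction: float = 0.25,
) -> IsiSeries:
    """Spike times as upward threshold crossings of ``component`` on the
    post-transient segment; default threshold is the signal mid-range."""
    traj = drop_transient(traj, transient_fraction, fraction=True)
    s = traj.component(component)
    if threshold is None:
        threshold = 0.5 * (np.max(s) + np.min(s))
    above = s > threshold
    ups = np.flatnonzero(~above[:-1] & above[1:])
    if ups.size < 3:
        raise ValueError(f"fewer than 3 spikes detected (got {ups.size})")
    times = traj.times[ups + 1]
    return IsiSeries(spike_times=times, intervals=np.diff(times))


@dataclass
class RegionDescriptor:
    """What exists at one (m, x0) point: equilibria, orbits, behavior."""

    m: float
    x0: float
    Iext2: float
    equilibria: List[StabilityClass]
    orbits: List[str]
    sle_label: Optional[str] = None
    behavior: Optional[str] = None

    @property
    def n_equilibria(self) -> int:
        return len(self.equilibria)


def equilibrium_region(
    m: float, x0: float, params: Optional[ParameterSet] = None
) -> RegionDescriptor:
    """Equilibrium multiset of the full model at this (m, x0)."""
    p = (params or ParameterSet()).with_(m=m, x0=x0)
    eqs = find_equilibria(SystemId.FULL, p)
    return RegionDescriptor(
        m=m, x0=x0, Iext2=p.Iext2,
        equilibria=sorted((e.stability for e in eqs), key=lambda s: s.value),
        orbits=[],
    )


def orbit_region(
    m: float,
    x0: float,
    params: Optional[ParameterSet] = None,
    curve: Optional[AveragedCurve] = None,
) -> List[str]:
    """Periodic-orbit labels {LC, S, SLC} at this (m, x0), from the
    averaging method on the full model.  Pass a precomputed
    ``AveragedCurve`` (which depends on m but not x0) when sweeping."""
    p = (params or ParameterSet()).with_(m=m, x0=x0)
    if curve is None:
        curve = AveragedCurve.compute(SystemId.FULL, p)
    orbits = find_periodic_orbits(x0, SystemId.FULL, p, curve)
    return orbits.labels


# ---------------------------------------------------------------------------
# behavior classification


def _plateau_transitions(x1: np.ndarray, t: np.ndarray, split: float,
                         debounce: float = 30.0) -> int:
    """Number of transitions between low-x1 and high-x1 episodes.

    The debounce (in time units) requires the new state to persist, so
    neither fast discharges nor the short silent gaps of chaotic spiking
    count as state switches — only genuine normal/ictal alternation."""
    hi = x1 > split
    dt = t[1] - t[0]
    win = max(int(debounce / dt), 1)
    state = hi[0]
    n_trans = 0
    i = 0
    while i < len(hi) - win:
        if np.all(hi[i : i + win] != state):
            state = not state
            n_trans += 1
            i += win
        else:
            i += 1
    return n_trans


def classify_behavior(
    params: ParameterSet,
    init: Sequence[float] = (0.0, -5.0, 3.0, 0.0, 0.0, 0.01),
    duration: float = 4000.0,
    dt: float = 0.01,
    transient_fraction: float = 0.4,
    z_flat_tol: float = 0.05,
    cv_chaos: float = 0.2,
) -> str:
    """Rule-based label for a deterministic run of the full model.

    The stationary segment (after discarding ``transient_fraction``) is
    classified from its z-range and x1 statistics: flat z with still x1
    is a rest state (normal / nonoscillatory / depolarization block by
    branch and eigenstructure), flat z with spiking is a small limit
    cycle or chaotic spiking by ISI regularity, a large z excursion into
    negative z is the fast-slow cycle, and alternation between distinct
    z-plateaus is the seizure-like or switching attractor, subtyped by
    the bifurcation-diagram classification.
    """
    p = params
    traj = integrate_deterministic(SystemId.FULL, init, duration, p, dt_max=dt)
    if traj.diverged:
        return "DIVERGENT"
    tail = drop_transient(traj, transient_fraction, fraction=True)
    z = tail.component("z")
    x1 = tail.component("x1")
    cf = sub1_closed_form_points(p)

    # the fast-slow cycle LC lives at low/negative z, far below the
    # Z-curve folds where the seizure-like attractor operates
    if float(np.min(z)) < 0.5:
        return "LC_RSE"

    # sustained alternation between normal and ictal plateaus
    n_trans = _plateau_transitions(x1, tail.times, split=cf.x1_fold)
    if n_trans >= 2:
        sle = classify_sle(p)
        if sle.has_sle:
            if sle.offset == "FOLD":
                return (
                    "SWITCH_DB_NS" if sle.ictal_state == "db"
                    else "SWITCH_NONOSC_NS"
                )
            return {
                "HOMOCLINIC": "SLE_HOMOCLINIC",
                "SNIC": "SLE_CIRCLE",
                "HOPF": "SLE_HOPF",
            }[sle.offset]

    # terminal window: z relaxes on the 1/r timescale, so rest states are
    # judged from the end of the run while z may still be drifting
    span = tail.times[-1] - tail.times[0]
    w0 = int(np.searchsorted(tail.times, tail.times[-1] - min(800.0, span / 3)))
    x1_w = x1[w0:]
    if float(np.max(x1_w) - np.min(x1_w)) < 0.05:
        x1_star = float(np.mean(x1_w))
        if x1_star < cf.x1_fold:
            return "NORMAL_STATE"
        eqs = find_equilibria(SystemId.FULL, p)
        near = (
            min(eqs, key=lambda e: abs(float(e.state[0]) - x1_star))
            if eqs
            else None
        )
        if near is not None:
            # depolarization block: the discharge-generating x1-block is a
            # stable node (no subthreshold ringing); a focus means the
            # nonoscillatory ictal rest state
            from .systems import jacobian

            block = jacobian(SystemId.FULL, near.state, p)[:2, :2]
            eig = np.linalg.eigvals(block)
            if np.all(np.abs(eig.imag) < 1e-7) and np.all(eig.real < 0):
                return "DB"
        return "NONOSCILLATORY"

    # sustained spiking at quasi-stationary z: tonic small cycle or chaos
    try:
        series = isi(traj, "x1")
        if series.cv > cv_chaos:
            return "CHAOTIC"
        return "SLC_PERIODIC"
    except ValueError:
        return "NONOSCILLATORY"


def atlas_grid(
    m_values: Sequence[float],
    x0_values: Sequence[float],
    params: Optional[ParameterSet] = None,
    with_orbits: bool = False,
    with_behavior: bool = False,
) -> List[RegionDescriptor]:
    """Region descriptors over the cartesian (m, x0) grid.

    Orbit sets reuse one averaged curve per m value; behavior labels run
    a full simulation per point and are costly — enable selectively.
    """
    p = params or ParameterSet()
    out: List[RegionDescriptor] = []
    for m in m_values:
        curve = None
        if with_orbits:
            curve = AveragedCurve.compute(SystemId.FULL, p.with_(m=m))
        for x0 in x0_values:
            desc = equilibrium_region(m, x0, p)
            if with_orbits:
                desc.orbits = orbit_region(m, x0, p, curve)
            if with_behavior:
                desc.behavior = classify_behavior(p.with_(m=m, x0=x0))
            out.append(desc)
    return out


def atlas_to_csv(rows: List[RegionDescriptor], path) -> None:
    with open(path, "w") as fh:
        fh.write("m,x0,Iext2,n_equilibria,equilibria,orbits,behavior\n")
        for r in rows:
            eqs = ";".join(s.value for s in r.equilibria)
            orbs = ";".join(r.orbits)
            fh.write(
                f"{r.m},{r.x0},{r.Iext2},{r.n_equilibria},{eqs},{orbs},"
                f"{r.behavior or ''}\n"
            )
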