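"""(z, x1) bifurcation diagrams by grid continuation, limit-cycle
envelopes at frozen z, bifurcation detection, and seizure onset/offset
classification.

The procedure mirrors the diagram construction used for every published
figure: at each point of a z grid all equilibria of the frozen-z fast
equations are found (exactly, by per-branch polynomial roots), classified
through the fast Jacobian, and linked across neighboring grid points by
nearest-x1 matching into stability-homogeneous branches.  Bifurcations
are read off from count changes (folds), focus stability flips (Hopf),
and the termination of the limit-cycle envelope (Hopf, homoclinic, or
saddle-node-on-invariant-circle, disambiguated by whether an equilibrium
pair is born on the cycle).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .equilibria import (
    Equilibrium,
    StabilityClass,
    classify_stability,
    find_equilibria,
    full_frozen_equilibria,
    sub1_closed_form_points,
    sub1_equilibria_analytic,
)
from .params import FrozenInputs, ParameterSet
from .systems import SystemId, fast_dim, fast_rhs_batch

AMP_TOL = 1e-2  # below this peak-to-peak amplitude the attractor is a point
PERIOD_CAP = 2000.0  # periods beyond this mark homoclinic/SNIC terminations


# ---------------------------------------------------------------------------
# frozen-z equilibria and ensemble integration


def frozen_equilibria(
    system: SystemId, z: float, params: ParameterSet
) -> List[Equilibrium]:
    """Equilibria of the frozen-z fast equations (2-D or 4-D).

    For the full model the fast analysis carries the low-pass variable g
    at its stationary value x1/gamma (the diagram construction that
    reproduces the published branch structure at nonzero Iext2); the
    published 4x4 classification is applied at those points.
    """
    if system in (SystemId.SUB1, SystemId.FASTSLOW):
        return sub1_equilibria_analytic(z, params)
    if system is SystemId.FULL:
        return full_frozen_equilibria(z, params, g_drive="stationary")
    raise ValueError("frozen-z continuation applies to SUB1/FASTSLOW/FULL")


def _eq_x1(eq: Equilibrium) -> float:
    return float(eq.state[0])


def _upper_start(
    system: SystemId, z: float, params: ParameterSet, offset: float = 0.05
) -> Optional[np.ndarray]:
    """A state near the highest-x1 equilibrium, used to seed the upper
    attractor (the ictal branch) of the frozen-z fast system."""
    eqs = frozen_equilibria(system, z, params)
    if not eqs:
        return None
    eq = max(eqs, key=_eq_x1)
    if system is SystemId.FULL:
        g_star = eq.state[0] / params.gamma_filter
        y = np.array([eq.state[0], eq.state[1], eq.state[3], eq.state[4], g_star])
        y[2] += offset  # kick the spike-wave subsystem off its equilibrium too
    else:
        y = eq.state[:2].copy()
    y[0] += offset
    return y


@dataclass
class EnsembleResult:
    """Per-z attractor summary from batched frozen-z integration."""

    z: np.ndarray
    kind: np.ndarray  # "cycle" | "point" | "long" | "none"
    max_x1: np.ndarray
    min_x1: np.ndarray
    mean_x1: np.ndarray
    period: np.ndarray
    final: np.ndarray  # final fast states (n, dim)


def ensemble_attractors(
    system: SystemId,
    z_values: np.ndarray,
    params: ParameterSet,
    transient: float = 300.0,
    record: float = 300.0,
    dt: float = 0.02,
    inits: Optional[np.ndarray] = None,
    amp_tol: float = AMP_TOL,
) -> EnsembleResult:
    """Integrate the frozen-z fast equations for every z simultaneously
    and summarize the attractor reached from the upper-branch seed.

    Vectorized RK4 across the whole z batch; after discarding
    ``transient`` time units, the x1 series over ``record`` units gives
    peak/trough, the period (mean spacing of upward midline crossings),
    and the cycle-averaged x1 over an integer number of periods.
    """
    z = np.asarray(z_values, float)
    n = z.size
    dim = fast_dim(system)
    Y = np.empty((n, dim))
    valid = np.ones(n, bool)
    if inits is None:
        for i, zi in enumerate(z):
            st = _upper_start(system, zi, params)
            if st is None:
                valid[i] = False
                Y[i] = 0.0
            else:
                Y[i] = st
    else:
        Y[:] = inits

    def step_block(Y, n_steps):
        h = dt
        for i in range(n_steps):
            k1 = fast_rhs_batch(system, Y, z, params)
            k2 = fast_rhs_batch(system, Y + 0.5 * h * k1, z, params)
            k3 = fast_rhs_batch(system, Y + 0.5 * h * k2, z, params)
            k4 = fast_rhs_batch(system, Y + h * k3, z, params)
            Y = Y + (h / 6.0) * (k1 + 2.0 * (k2 + k3) + k4)
            if i % 256 == 0:
                # freeze rows that blew past the guard so inf/nan do not
                # churn through the remaining arithmetic
                bad = ~np.all(np.abs(Y) < OVERFLOW, axis=1)
                if bad.any():
                    Y[bad] = np.nan
        return Y

    OVERFLOW = 1e6
    n_tr = int(round(transient / dt))
    with np.errstate(over="ignore", invalid="ignore"):
        Y = step_block(Y, n_tr)
        bad = ~np.all(np.isfinite(Y), axis=1)
        valid &= ~bad
        Y[~valid] = 0.0

        n_rec = int(round(record / dt))
        x1_series = np.empty((n_rec, n))
        h = dt
        for istep in range(n_rec):
            k1 = fast_rhs_batch(system, Y, z, params)
            k2 = fast_rhs_batch(system, Y + 0.5 * h * k1, z, params)
            k3 = fast_rhs_batch(system, Y + 0.5 * h * k2, z, params)
            k4 = fast_rhs_batch(system, Y + h * k3, z, params)
            Y = Y + (h / 6.0) * (k1 + 2.0 * (k2 + k3) + k4)
            if istep % 256 == 0:
                bad = ~np.all(np.abs(Y) < OVERFLOW, axis=1)
                if bad.any():
                    Y[bad] = np.nan
            x1_series[istep] = Y[:, 0]
        bad = ~np.all(np.isfinite(Y), axis=1)
        valid &= ~bad

    kind = np.array(["none"] * n, dtype=object)
    max_x1 = np.full(n, np.nan)
    min_x1 = np.full(n, np.nan)
    mean_x1 = np.full(n, np.nan)
    period = np.full(n, np.nan)
    for i in range(n):
        if not valid[i]:
            continue
        s = x1_series[:, i]
        hi, lo = float(s.max()), float(s.min())
        max_x1[i], min_x1[i] = hi, lo
        if hi - lo < amp_tol:
            kind[i] = "point"
            mean_x1[i] = float(s[-1])
            continue
        mid = 0.5 * (hi + lo)
        above = s > mid
        ups = np.flatnonzero(~above[:-1] & above[1:])
        if ups.size < 2:
            kind[i] = "long"
            mean_x1[i] = float(s.mean())
            period[i] = np.inf
            continue
        kind[i] = "cycle"
        i0, i1 = ups[0], ups[-1]
        period[i] = (i1 - i0) * dt / (ups.size - 1)
        mean_x1[i] = float(np.mean(s[i0:i1])) if i1 > i0 else float(s.mean())
    return EnsembleResult(
        z=z, kind=kind, max_x1=max_x1, min_x1=min_x1,
        mean_x1=mean_x1, period=period, final=Y,
    )


# ---------------------------------------------------------------------------
# diagram data structures


@dataclass
class Branch:
    """A maximal run of equilibria with a single stability class."""

    z: np.ndarray
    x1: np.ndarray
    stability: StabilityClass
    states: np.ndarray  # full fast states (n, dim_state)

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class BifurcationPoint:
    kind: str  # "SN" | "HOPF" | "HOMOCLINIC" | "SNIC" | "SNPO"
    z: float
    x1: Optional[float] = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "z": self.z, "x1": self.x1}


@dataclass
class CycleEnvelope:
    """Limit-cycle envelope over a z grid with termination tags."""

    z: np.ndarray
    max_x1: np.ndarray
    min_x1: np.ndarray
    mean_x1: np.ndarray
    period: np.ndarray
    kind: np.ndarray
    term_low: str = "GRID_EDGE"
    term_high: str = "GRID_EDGE"
    z_term_low: Optional[float] = None
    z_term_high: Optional[float] = None

    @property
    def has_cycle(self) -> np.ndarray:
        return (self.kind == "cycle") | (self.kind == "long")


@dataclass
class BifurcationDiagram:
    """Stability-segmented equilibrium branches over a z grid."""

    system: SystemId
    params: ParameterSet
    z_grid: np.ndarray
    branches: List[Branch]
    points: List[BifurcationPoint] = field(default_factory=list)
    envelope: Optional[CycleEnvelope] = None

    def branches_of(self, cls: StabilityClass) -> List[Branch]:
        return [b for b in self.branches if b.stability is cls]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("branch,z,x1,stability\n")
            for i, b in enumerate(self.branches):
                for zz, xx in zip(b.z, b.x1):
                    fh.write(f"{i},{zz},{xx},{b.stability.value}\n")

    def points_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([pt.to_dict() for pt in self.points], fh, indent=2)


# ---------------------------------------------------------------------------
# branch sweep


def sweep_branches(
    system: SystemId,
    z_range: Tuple[float, float] = (-2.0, 6.0),
    n_grid: int = 801,
    params: Optional[ParameterSet] = None,
    link_tol: float = 0.5,
) -> BifurcationDiagram:
    """Grid continuation: solve the frozen-z fast equations at every grid
    point, link equilibria across neighboring z by nearest x1, and split
    the linked curves into stability-homogeneous branches."""
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")
    p = params or ParameterSet()
    z_grid = np.linspace(z_range[0], z_range[1], n_grid)

    per_z: List[List[Equilibrium]] = [frozen_equilibria(system, z, p) for z in z_grid]

    # link into curves
    curves: List[dict] = []  # each: {"z": [...], "x1": [...], "eqs": [...], "open": bool}
    active: List[dict] = []
    for zi, eqs in zip(z_grid, per_z):
        eqs = sorted(eqs, key=_eq_x1)
        used = [False] * len(eqs)
        new_active = []
        # match each active curve to the nearest unused equilibrium
        for cur in sorted(active, key=lambda c: c["x1"][-1]):
            best, best_d = None, link_tol
            for j, eq in enumerate(eqs):
                if used[j]:
                    continue
                d = abs(_eq_x1(eq) - cur["x1"][-1])
                if d < best_d:
                    best, best_d = j, d
            if best is None:
                curves.append(cur)
            else:
                used[best] = True
                cur["z"].append(zi)
                cur["x1"].append(_eq_x1(eqs[best]))
                cur["eqs"].append(eqs[best])
                new_active.append(cur)
        for j, eq in enumerate(eqs):
            if not used[j]:
                new_active.append(
                    {"z": [zi], "x1": [_eq_x1(eq)], "eqs": [eq]}
                )
        active = new_active
    curves.extend(active)

    # split curves at stability changes
    branches: List[Branch] = []
    for cur in curves:
        cls_seq = [eq.stability for eq in cur["eqs"]]
        start = 0
        for i in range(1, len(cls_seq) + 1):
            if i == len(cls_seq) or cls_seq[i] is not cls_seq[start]:
                seg = slice(start, i)
                branches.append(
                    Branch(
                        z=np.array(cur["z"][seg]),
                        x1=np.array(cur["x1"][seg]),
                        stability=cls_seq[start],
                        states=np.array([e.state for e in cur["eqs"][seg]]),
                    )
                )
                start = i
    branches.sort(key=lambda b: (b.z[0], b.x1[0]))
    return BifurcationDiagram(system=system, params=p, z_grid=z_grid, branches=branches)


# ---------------------------------------------------------------------------
# cycle envelope


def cycle_envelope(
    system: SystemId,
    z_grid: np.ndarray,
    params: Optional[ParameterSet] = None,
    transient: float = 300.0,
    record: float = 300.0,
    dt: float = 0.02,
    amp_tol: float = AMP_TOL,
    period_cap: float = PERIOD_CAP,
) -> CycleEnvelope:
    """Integrate the frozen-z fast equations over the grid and tag how the
    stable cycle terminates at each end of its existence range."""
    p = params or ParameterSet()
    z_grid = np.asarray(z_grid, float)
    res = ensemble_attractors(
        system, z_grid, p, transient=transient, record=record, dt=dt, amp_tol=amp_tol
    )
    env = CycleEnvelope(
        z=z_grid, max_x1=res.max_x1, min_x1=res.min_x1,
        mean_x1=res.mean_x1, period=res.period, kind=res.kind,
    )
    idx = np.flatnonzero(env.has_cycle)
    if idx.size == 0:
        return env
    lo_i, hi_i = idx[0], idx[-1]
    if lo_i > 0:
        env.z_term_low = 0.5 * (z_grid[lo_i - 1] + z_grid[lo_i])
        env.term_low = _termination_tag(system, p, env, lo_i, -1, period_cap)
    if hi_i < len(z_grid) - 1:
        env.z_term_high = 0.5 * (z_grid[hi_i] + z_grid[hi_i + 1])
        env.term_high = _termination_tag(system, p, env, hi_i, +1, period_cap)
    return env


def _unstable_pair_re(eq: Equilibrium, imag_tol: float = 1e-7) -> Optional[float]:
    """Max real part of the complex eigenvalue pair of ``eq`` (None if the
    spectrum is purely real)."""
    eig = eq.eigenvalues
    cplx = eig[np.abs(eig.imag) > imag_tol]
    if cplx.size == 0:
        return None
    return float(cplx.real.max())


def _termination_tag(
    system: SystemId,
    p: ParameterSet,
    env: CycleEnvelope,
    edge_i: int,
    direction: int,
    period_cap: float,
) -> str:
    """Classify how the cycle dies just past grid index ``edge_i``.

    Hopf: the focus the cycle surrounds flips stability across the edge
    (amplitude shrinks to zero).  SNIC: an equilibrium pair is born on
    the cycle itself, so cycle and pair never coexist.  Homoclinic: the
    cycle collides with a pre-existing saddle (it coexists with any
    nearby fold's pair on the cycle side) and the period diverges.
    """
    z_grid = env.z
    dz = abs(z_grid[1] - z_grid[0])
    z_in = z_grid[edge_i]
    z_out = z_in + direction * 2.0 * dz
    lo, hi = env.min_x1[edge_i], env.max_x1[edge_i]
    center = 0.5 * (lo + hi)

    eqs_in = frozen_equilibria(system, z_in, p)
    eqs_out = frozen_equilibria(system, z_out, p)

    # Hopf: track the focus the cycle surrounds (unstable complex pair,
    # nearest the cycle center) and test whether its pair stabilizes.
    # Only meaningful when no fold intervenes inside the cycle's band.
    def _in_band(eqs: List[Equilibrium]) -> List[Equilibrium]:
        return [e for e in eqs if lo - 0.1 <= _eq_x1(e) <= hi + 0.1]

    foci = [e for e in _in_band(eqs_in) if (_unstable_pair_re(e) or -1.0) > 0]
    if not foci and 0 <= edge_i - direction < len(z_grid):
        # ghost ringing past a Hopf can push the detected termination one
        # grid point beyond the flip; look back one cell for the focus
        z_back = z_grid[edge_i - direction]
        eqs_back = frozen_equilibria(system, z_back, p)
        foci = [
            e for e in eqs_back
            if (_unstable_pair_re(e) or -1.0) > 0
            and lo - 0.1 <= _eq_x1(e) <= hi + 0.1
        ]
    if len(_in_band(eqs_out)) != len(_in_band(eqs_in)):
        foci = []
    if foci:
        focus = min(foci, key=lambda e: abs(_eq_x1(e) - center))
        match = [e for e in eqs_out if abs(_eq_x1(e) - _eq_x1(focus)) < 0.3]
        if match:
            partner = min(match, key=lambda e: abs(_eq_x1(e) - _eq_x1(focus)))
            re_out = _unstable_pair_re(partner)
            if re_out is not None and re_out < 0:
                return "HOPF"
    # tiny terminal amplitude also indicates a Hopf end falling between
    # grid nodes
    if hi - lo < 3 * AMP_TOL:
        return "HOPF"

    # fold near the termination? bisect the equilibrium count change
    n_in = len(eqs_in)
    z_a, z_b = z_in, z_out
    n_b = len(eqs_out)
    if n_b == n_in:
        return "HOMOCLINIC"
    for _ in range(10):
        mid = 0.5 * (z_a + z_b)
        if len(frozen_equilibria(system, mid, p)) == n_in:
            z_a = mid
        else:
            z_b = mid
    z_fold = 0.5 * (z_a + z_b)
    # the new pair must be born inside the cycle's x1 band for a SNIC;
    # novelty is judged in the full fast state (a pair can be born close
    # to an existing equilibrium in x1 yet far in x2)
    in_states = np.array([e.state for e in eqs_in]) if eqs_in else np.empty((0, 1))
    born_in_band = False
    for eq in frozen_equilibria(system, z_fold + direction * 1e-3, p):
        if in_states.size and np.min(
            np.max(np.abs(in_states - eq.state), axis=1)
        ) < 0.05:
            continue
        if lo - 0.2 <= _eq_x1(eq) <= hi + 0.2:
            born_in_band = True
    if not born_in_band:
        return "HOMOCLINIC"
    # On a SNIC the cycle is destroyed exactly at the fold; a homoclinic
    # collision happens strictly beyond it, so cycle and newborn pair
    # coexist on a finite z interval.  Bisect the cycle's end point and
    # compare with the fold location.
    z_end = _bisect_cycle_end(system, p, z_in, z_in + direction * 2.5 * dz)
    if direction * (z_end - z_fold) > 0.006:
        return "HOMOCLINIC"
    return "SNIC"


def _bisect_cycle_end(
    system: SystemId,
    p: ParameterSet,
    z_cycle: float,
    z_none: float,
    resolution: float = 0.004,
) -> float:
    """z at which the stable fast cycle disappears, by bisection on
    direct integration (large-amplitude oscillation after a long
    transient counts as a cycle)."""

    def has_cycle(z: float) -> bool:
        # the transient must outlast the slow bottleneck passage near a
        # saddle-node ghost, else ringing is mistaken for a cycle
        res = ensemble_attractors(
            system, np.array([z]), p, transient=1500.0, record=300.0
        )
        return bool(
            res.kind[0] in ("cycle", "long")
            and (res.max_x1[0] - res.min_x1[0]) > 0.1
        )

    lo, hi = z_cycle, z_none
    for _ in range(8):
        if abs(hi - lo) < resolution:
            break
        mid = 0.5 * (lo + hi)
        if has_cycle(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# bifurcation detection


def detect_bifurcations(
    diagram: BifurcationDiagram, refine_bits: int = 8
) -> List[BifurcationPoint]:
    """Locate folds (equilibrium count changes) and Hopf points (focus
    stability flips) on the diagram grid, refined by bisection, and copy
    cycle-termination tags from the envelope if present."""
    system, p = diagram.system, diagram.params
    z_grid = diagram.z_grid
    pts: List[BifurcationPoint] = []

    counts = [len(frozen_equilibria(system, z, p)) for z in z_grid]
    for i in range(len(z_grid) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = z_grid[i], z_grid[i + 1]
            c_lo = counts[i]
            for _ in range(refine_bits):
                mid = 0.5 * (lo + hi)
                if len(frozen_equilibria(system, mid, p)) == c_lo:
                    lo = mid
                else:
                    hi = mid
            z_sn = 0.5 * (lo + hi)
            rich = frozen_equilibria(
                system, hi if counts[i + 1] > counts[i] else lo, p
            )
            poor = frozen_equilibria(
                system, lo if counts[i + 1] > counts[i] else hi, p
            )
            poor_x1 = np.array([_eq_x1(e) for e in poor])
            new = [
                _eq_x1(e)
                for e in rich
                if poor_x1.size == 0 or np.min(np.abs(poor_x1 - _eq_x1(e))) > 1e-3
            ]
            x1_sn = float(np.mean(new)) if new else None
            pts.append(BifurcationPoint("SN", z_sn, x1_sn))

    # Hopf: stability flip of a complex pair along the grid
    def _pair_re_near(eqs: List[Equilibrium], x1_ref: float) -> Optional[float]:
        near = [e for e in eqs if abs(_eq_x1(e) - x1_ref) < 0.3]
        if not near:
            return None
        return _unstable_pair_re(min(near, key=lambda e: abs(_eq_x1(e) - x1_ref)))

    for i in range(len(z_grid) - 1):
        eqs_a = frozen_equilibria(system, z_grid[i], p)
        eqs_b = frozen_equilibria(system, z_grid[i + 1], p)
        for eq in eqs_a:
            x1a = _eq_x1(eq)
            re_a = _unstable_pair_re(eq)
            re_b = _pair_re_near(eqs_b, x1a)
            if re_a is None or re_b is None:
                continue
            if re_a * re_b < 0:
                lo, hi = z_grid[i], z_grid[i + 1]
                for _ in range(refine_bits):
                    mid = 0.5 * (lo + hi)
                    re_m = _pair_re_near(frozen_equilibria(system, mid, p), x1a)
                    if re_m is None:
                        break
                    if re_m * re_a > 0:
                        lo = mid
                    else:
                        hi = mid
                z_h = 0.5 * (lo + hi)
                eq_h = min(
                    frozen_equilibria(system, z_h, p),
                    key=lambda e: abs(_eq_x1(e) - x1a),
                )
                pts.append(BifurcationPoint("HOPF", z_h, _eq_x1(eq_h)))
                break

    # deduplicate Hopf points found from both grid sides
    dedup: List[BifurcationPoint] = []
    for pt in sorted(pts, key=lambda q: (q.kind, q.z)):
        if any(
            q.kind == pt.kind and abs(q.z - pt.z) < 2 * (z_grid[1] - z_grid[0])
            for q in dedup
        ):
            continue
        dedup.append(pt)

    if diagram.envelope is not None:
        env = diagram.envelope
        if env.z_term_low is not None:
            dedup.append(BifurcationPoint(env.term_low, env.z_term_low))
        if env.z_term_high is not None:
            dedup.append(BifurcationPoint(env.term_high, env.z_term_high))
    diagram.points = dedup
    return dedup


# ---------------------------------------------------------------------------
# seizure onset/offset classification


@dataclass
class OnsetOffsetClass:
    """Burster class of the seizure-like-event attractor.

    Onset is always the fold (SN1) of the normal-state branch; the offset
    type names the bifurcation ending the ictal oscillation: HOMOCLINIC
    (fold/homoclinic), CIRCLE (fold/circle, i.e. SNIC), HOPF (fold/Hopf)
    or FOLD (fold/fold, no fast oscillation on the upper branch — a
    periodic switch between a nonoscillatory or depolarization-block
    state and the normal state).
    """

    has_sle: bool
    onset: Optional[str] = None
    offset: Optional[str] = None
    ictal_state: Optional[str] = None  # "oscillatory" | "nonoscillatory" | "db"
    bistability: Optional[Tuple[float, float]] = None
    reason: Optional[str] = None

    @property
    def label(self) -> Optional[str]:
        if not self.has_sle:
            return None
        return {
            "HOMOCLINIC": "fold/homoclinic",
            "SNIC": "fold/circle",
            "CIRCLE": "fold/circle",
            "HOPF": "fold/Hopf",
            "FOLD": "fold/fold",
        }[self.offset]

    def to_dict(self) -> dict:
        return {
            "has_sle": self.has_sle,
            "onset": self.onset,
            "offset": self.offset,
            "label": self.label,
            "ictal_state": self.ictal_state,
            "bistability": self.bistability,
            "reason": self.reason,
        }


def classify_sle(
    params: ParameterSet,
    system: SystemId = SystemId.FULL,
    n_grid: int = 121,
    transient: float = 400.0,
    record: float = 300.0,
    dt: float = 0.02,
) -> OnsetOffsetClass:
    """Determine the burster class of the SLE attractor at these parameters.

    Requires the slow nullcline to cut only the middle (saddle) branch —
    otherwise the trajectory parks on a stable equilibrium and no
    autonomous seizure-like alternation exists.  The offset type follows
    the fate of the upper attractor reached just below the onset fold
    SN1 as z increases: cycle ending in Hopf / SNIC / homoclinic, or a
    stable point (fold/fold; depolarization block if it is a node).
    """
    p = params
    eqs = find_equilibria(system, p)
    saddles = [e for e in eqs if e.stability is StabilityClass.SADDLE]
    stables = [e for e in eqs if e.stability.is_stable]
    if stables or not saddles:
        return OnsetOffsetClass(
            has_sle=False,
            reason="slow nullcline does not intersect only the saddle branch",
        )

    cf = sub1_closed_form_points(p)
    z_sn1 = cf.z_SN1
    z_lo = z_sn1 - 0.4
    z_hi = z_sn1 + 1.6
    z_grid = np.linspace(z_lo, z_hi, n_grid)
    env = cycle_envelope(
        system, z_grid, p, transient=transient, record=record, dt=dt
    )

    i_probe = int(np.searchsorted(z_grid, z_sn1 - 0.03)) - 1
    i_probe = max(i_probe, 0)
    kind = env.kind[i_probe]

    if kind == "point":
        # upper attractor is a stable equilibrium: fold/fold switch
        eqs_f = frozen_equilibria(system, z_grid[i_probe], p)
        upper = min(eqs_f, key=lambda e: abs(_eq_x1(e) - env.mean_x1[i_probe]))
        # node vs focus decided on the fast x1-block (discharge-generating part)
        from .systems import jacobian as _jac

        if system is SystemId.FULL:
            J5 = _jac(SystemId.FULL, upper.state, p)
            block = J5[np.ix_([0, 1], [0, 1])]
        else:
            from .params import FrozenInputs as _FI

            block = _jac(
                SystemId.SUB1, upper.state[:2], p, _FI(z_frozen=z_grid[i_probe])
            )
        eig = np.linalg.eigvals(block)
        is_node = bool(np.all(np.abs(eig.imag) < 1e-7))
        z_sn2 = _upper_stable_end(system, p, z_grid)
        return OnsetOffsetClass(
            has_sle=True,
            onset="SN",
            offset="FOLD",
            ictal_state="db" if is_node else "nonoscillatory",
            bistability=(z_sn1, z_sn2),
        )

    if kind not in ("cycle", "long"):
        return OnsetOffsetClass(
            has_sle=False, reason="no upper attractor found below SN1"
        )

    # follow the cycle upward to its termination
    idx = np.arange(i_probe, len(z_grid))
    cyc = np.array([env.kind[i] in ("cycle", "long") for i in idx])
    if cyc.all():
        return OnsetOffsetClass(
            has_sle=False, reason="cycle persists to the grid edge; widen grid"
        )
    i_last = idx[np.argmin(cyc)] - 1  # last cycle index before termination
    tag = _termination_tag(system, p, env, i_last, +1, PERIOD_CAP)
    z_term = 0.5 * (z_grid[i_last] + z_grid[i_last + 1])
    if tag == "HOMOCLINIC":
        bist = (z_sn1, z_term)
    else:
        bist = (z_sn1, _upper_stable_end(system, p, z_grid))
    return OnsetOffsetClass(
        has_sle=True,
        onset="SN",
        offset="SNIC" if tag == "SNIC" else tag,
        ictal_state="oscillatory",
        bistability=bist,
    )


def _upper_stable_end(
    system: SystemId, p: ParameterSet, z_grid: np.ndarray
) -> float:
    """Largest z (within the grid, bisection-refined) at which a stable
    equilibrium with x1 >= 0 exists — the upper fold SN2."""

    def has_stable_upper(z: float) -> bool:
        return any(
            e.stability.is_stable and _eq_x1(e) >= 0
            for e in frozen_equilibria(system, z, p)
        )

    flags = [has_stable_upper(z) for z in z_grid]
    if not any(flags):
        return float(z_grid[-1])
    i = max(np.flatnonzero(flags))
    if i == len(z_grid) - 1:
        return float(z_grid[-1])
    lo, hi = z_grid[i], z_grid[i + 1]
    for _ in range(10):
        mid = 0.5 * (lo + hi)
        if has_stable_upper(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
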