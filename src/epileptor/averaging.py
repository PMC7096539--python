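"""Averaging method for slow-fast periodic orbits.

The slow-fast structure of the model lets its periodic orbits be located
without integrating the slow dynamics at all: freeze z, find the fast
attractor (a limit cycle or an equilibrium), average x1 over it, and
substitute the average into the slow equation.  Zeros of the resulting
slow averaged nullcline

    <zdot>(z; x0) = r [ s(<x1>(z) - x0) - z - 0.1 z^7 (z<0) ]

are the periodic orbits of the coupled system; a zero is stable when
d<zdot>/dz < 0 there.  Because x0 enters linearly, one averaged curve
<x1>(z) serves every x0, which makes sweeps and the location of
saddle-node-of-periodic-orbit (SNPO) coalescences cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .continuation import ensemble_attractors
from .params import ParameterSet
from .systems import SystemId


@dataclass
class AveragedCurve:
    """<x1>(z) over a z grid: cycle average where the upper fast
    attractor is a limit cycle, equilibrium value where it is a point.

    ``valid`` masks grid points with a usable upper attractor (points
    resting on the lower x1 < 0 branch are excluded — the slow-fast
    periodic orbits live on the upper attractor)."""

    system: SystemId
    params: ParameterSet
    z: np.ndarray
    mean_x1: np.ndarray
    period: np.ndarray
    kind: np.ndarray
    valid: np.ndarray

    @classmethod
    def compute(
        cls,
        system: SystemId,
        params: ParameterSet,
        z_range: Tuple[float, float] = (-2.5, 4.25),
        n_grid: int = 400,
        transient: float = 300.0,
        record: float = 400.0,
        dt: float = 0.005,
    ) -> "AveragedCurve":
        # the large-amplitude relaxation cycles at negative z reach
        # x1 ~ -12 where the cubic branch is very stiff; the fixed RK4
        # step must resolve |lambda| ~ 5e2 there, hence dt = 0.005
        z = np.linspace(z_range[0], z_range[1], n_grid)
        res = ensemble_attractors(
            system, z, params, transient=transient, record=record, dt=dt
        )
        valid = np.array(
            [
                k in ("cycle", "long", "point") and np.isfinite(m)
                and not (k == "point" and m < 0.0)
                for k, m in zip(res.kind, res.mean_x1)
            ]
        )
        mean = res.mean_x1.copy()
        # quasi-periodic modulation (the spike-wave oscillator riding on
        # the fast cycle) leaves grid-point jitter in the estimated mean;
        # a width-3 median on the valid subsequence removes single-point
        # outliers without moving features wider than one grid cell
        idx = np.flatnonzero(valid)
        if idx.size >= 3:
            sub = mean[idx]
            sm = sub.copy()
            sm[1:-1] = np.median(
                np.column_stack([sub[:-2], sub[1:-1], sub[2:]]), axis=1
            )
            mean[idx] = sm
        return cls(
            system=system, params=params, z=z, mean_x1=mean,
            period=res.period, kind=res.kind, valid=valid,
        )

    def interp_mean(self, z: float) -> float:
        zz, mm = self.z[self.valid], self.mean_x1[self.valid]
        return float(np.interp(z, zz, mm))


def average_x1(
    z: float,
    system: SystemId,
    params: ParameterSet,
    transient: float = 300.0,
    record: float = 400.0,
    dt: float = 0.02,
) -> Tuple[float, float]:
    """(mean x1, period) of the upper fast attractor at constant z.

    The period is NaN for a point attractor and inf when fewer than two
    full oscillations fit the recording window (near homoclinic/SNIC
    terminations).  Raises if no attractor is found.
    """
    res = ensemble_attractors(
        system, np.asarray([z], float), params,
        transient=transient, record=record, dt=dt,
    )
    if res.kind[0] == "none":
        raise RuntimeError(f"no fast attractor found at z={z}")
    return float(res.mean_x1[0]), float(res.period[0])


def slow_rate(z: np.ndarray, mean_x1: np.ndarray, x0: float, p: ParameterSet) -> np.ndarray:
    """<zdot> on a grid, from precomputed <x1> values."""
    z = np.asarray(z, float)
    out = p.s * (np.asarray(mean_x1, float) - x0) - z
    if p.z_law == "modified":
        out = out - np.where(z < 0.0, 0.1 * z ** 7, 0.0)
    return p.r * out


def slow_nullcline(
    z_grid: np.ndarray,
    x0: float,
    system: SystemId,
    params: ParameterSet,
    curve: Optional[AveragedCurve] = None,
) -> np.ndarray:
    """<zdot> evaluated on ``z_grid`` (NaN where the averaged curve is
    invalid).  Sign changes bracket periodic orbits."""
    if curve is None:
        curve = AveragedCurve.compute(
            system, params, (float(np.min(z_grid)), float(np.max(z_grid))),
            n_grid=len(z_grid),
        )
    z_grid = np.asarray(z_grid, float)
    mean = np.array([curve.interp_mean(z) for z in z_grid])
    out = slow_rate(z_grid, mean, x0, params)
    inside = (z_grid >= curve.z[curve.valid].min()) & (
        z_grid <= curve.z[curve.valid].max()
    )
    out[~inside] = np.nan
    return out


@dataclass
class OrbitRoot:
    z: float
    stable: bool
    label: str  # "LC" | "S" | "SLC"
    slope: float  # d<zdot>/dz at the root


@dataclass
class PeriodicOrbitSet:
    """Zeros of the slow averaged nullcline at fixed (m, x0)."""

    x0: float
    params: ParameterSet
    roots: List[OrbitRoot] = field(default_factory=list)

    @property
    def labels(self) -> List[str]:
        return [r.label for r in self.roots]

    @property
    def stable_roots(self) -> List[OrbitRoot]:
        return [r for r in self.roots if r.stable]


def _label_roots(roots: List[Tuple[float, bool, float]]) -> List[OrbitRoot]:
    """Assign LC/S/SLC by z-order: lowest-z stable root is the large
    fast-slow cycle LC, further stable roots are small cycles (SLC),
    unstable roots are saddle orbits S."""
    out = []
    stable_seen = 0
    for z, stable, slope in sorted(roots):
        if stable:
            label = "LC" if stable_seen == 0 else "SLC"
            stable_seen += 1
        else:
            label = "S"
        out.append(OrbitRoot(z=z, stable=stable, label=label, slope=slope))
    return out


def find_periodic_orbits(
    x0: float,
    system: SystemId,
    params: ParameterSet,
    curve: Optional[AveragedCurve] = None,
    bisect_tol: float = 1e-4,
) -> PeriodicOrbitSet:
    """Periodic orbits of the slow-fast system at this x0: bracketed
    zeros of <zdot> on the averaged curve's grid, refined by bisection on
    the interpolant, with stability from the local slope sign."""
    p = params.with_(x0=x0)
    if curve is None:
        curve = AveragedCurve.compute(system, params)
    z = curve.z[curve.valid]
    mean = curve.mean_x1[curve.valid]
    G = slow_rate(z, mean, x0, p)

    def g_of(zq: float) -> float:
        return float(
            slow_rate(
                np.array([zq]), np.array([np.interp(zq, z, mean)]), x0, p
            )[0]
        )

    roots: List[Tuple[float, bool, float]] = []
    sign = np.sign(G)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        lo, hi = float(z[i]), float(z[i + 1])
        g_lo = G[i]
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            if g_of(mid) * g_lo > 0:
                lo = mid
            else:
                hi = mid
        z_star = 0.5 * (lo + hi)
        h = z[1] - z[0]
        slope = (g_of(z_star + h) - g_of(z_star - h)) / (2 * h)
        roots.append((z_star, slope < 0, slope))
    return PeriodicOrbitSet(x0=x0, params=p, roots=_label_roots(roots))


@dataclass
class OrbitSweep:
    """Per-x0 orbit sets along an x0 grid, with SNPO coalescence points."""

    x0_grid: np.ndarray
    sets: List[PeriodicOrbitSet]
    snpo: List[float] = field(default_factory=list)


def sweep_x0_orbits(
    x0_grid: Sequence[float],
    system: SystemId,
    params: ParameterSet,
    curve: Optional[AveragedCurve] = None,
    refine_tol: float = 1e-3,
) -> OrbitSweep:
    """Orbit diagram over x0.  Root-count changes along the sweep are
    refined by bisection in x0; a change by two marks an SNPO (a stable
    and a saddle orbit coalescing)."""
    if curve is None:
        curve = AveragedCurve.compute(system, params)
    x0_grid = np.asarray(x0_grid, float)
    sets = [find_periodic_orbits(x0, system, params, curve) for x0 in x0_grid]

    snpo: List[float] = []
    counts = [len(s.roots) for s in sets]
    for i in range(len(x0_grid) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = x0_grid[i], x0_grid[i + 1]
        n_lo = counts[i]
        while abs(hi - lo) > refine_tol:
            mid = 0.5 * (lo + hi)
            n_mid = len(find_periodic_orbits(mid, system, params, curve).roots)
            if n_mid == n_lo:
                lo = mid
            else:
                hi = mid
        if abs(counts[i + 1] - counts[i]) >= 2:
            snpo.append(0.5 * (lo + hi))
    return OrbitSweep(x0_grid=x0_grid, sets=sets, snpo=snpo)


def locate_snpo(
    system: SystemId,
    params: ParameterSet,
    x0_bracket: Tuple[float, float] = (-3.0, -1.0),
    curve: Optional[AveragedCurve] = None,
    tol: float = 1e-3,
) -> float:
    """x0 at which the stable (LC) and saddle (S) orbits coalesce,
    located by bisection on the root count over ``x0_bracket``."""
    if curve is None:
        curve = AveragedCurve.compute(system, params)

    def n_roots(x0: float) -> int:
        return len(find_periodic_orbits(x0, system, params, curve).roots)

    lo, hi = x0_bracket
    n_lo, n_hi = n_roots(lo), n_roots(hi)
    if n_lo == n_hi:
        raise ValueError(
            f"root count does not change over {x0_bracket} ({n_lo} roots)"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_roots(mid) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
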