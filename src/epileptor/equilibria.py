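"""Equilibrium points, stability classification, and closed-form bifurcation values.

The piecewise-polynomial structure of the model makes most equilibrium
problems exactly solvable: the uncoupled fast subsystem reduces to a cubic
(x1 < 0) plus a quadratic (x1 >= 0), the spike-wave subsystem to two
cubics, and the full model at frozen z factorizes because the x2 equation
decouples from x1 under the printed-Jacobian g convention.  Only the full
five-variable equilibrium problem (with the slow nullcline closing the
loop) needs a numeric solve, done by multi-start damped Newton with
starts seeded from the polynomial structure.

Several printed closed forms lost their square roots in rendering; they
are restored here from Tr(J) = 0 / Det(J) = 0 and verified against
numeric eigenvalue sweeps in the test suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .params import FrozenInputs, ParameterSet
from .systems import SystemId, f1, f2, jacobian, rhs

RESIDUAL_TOL = 1e-10
DEDUP_TOL = 1e-8


class StabilityClass(enum.Enum):
    STABLE_NODE = "stable node"
    STABLE_FOCUS = "stable focus"
    SADDLE = "saddle"
    UNSTABLE_NODE = "unstable node"
    UNSTABLE_FOCUS = "unstable focus"
    MARGINAL = "marginal"

    @property
    def is_stable(self) -> bool:
        return self in (StabilityClass.STABLE_NODE, StabilityClass.STABLE_FOCUS)


def classify_stability(
    eigenvalues: Sequence[complex],
    real_tol: float = 1e-7,
    imag_tol: float = 1e-7,
) -> StabilityClass:
    """Classify an equilibrium from its eigenvalues.

    Nodes and foci are split by ``imag_tol`` on the imaginary parts;
    saddles have real parts of mixed sign.  Any eigenvalue with
    |Re| < ``real_tol`` marks proximity to a bifurcation and yields
    MARGINAL rather than a definite class.
    """
    eig = np.asarray(eigenvalues, dtype=complex)
    if eig.size == 0:
        raise ValueError("empty eigenvalue list")
    re = eig.real
    if np.any(np.abs(re) < real_tol):
        return StabilityClass.MARGINAL
    focus = bool(np.any(np.abs(eig.imag) > imag_tol))
    if np.all(re < 0):
        return StabilityClass.STABLE_FOCUS if focus else StabilityClass.STABLE_NODE
    if np.all(re > 0):
        return StabilityClass.UNSTABLE_FOCUS if focus else StabilityClass.UNSTABLE_NODE
    # mixed signs: in dimension > 2, a real unstable eigenvalue gives a
    # one-dimensional escape direction and the point acts as a saddle
    # (e.g. the separatrix between normal and ictal states); if the only
    # unstable directions form complex pairs the point spirals out and is
    # labeled an unstable focus.
    pos = eig[re > 0]
    real_unstable = bool(np.any(np.abs(pos.imag) <= imag_tol))
    return StabilityClass.SADDLE if real_unstable else StabilityClass.UNSTABLE_FOCUS


@dataclass
class Equilibrium:
    """A state vector with residual, eigenvalues and stability label.

    For the full model the state is (x1, y1, z, x2, y2); when ``frozen``
    is set the eigenvalues come from the 4x4 fast Jacobian at that z.
    """

    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stability: StabilityClass
    system: SystemId
    frozen_z: Optional[float] = None

    @property
    def x1(self) -> float:
        if self.system is SystemId.SUB2:
            raise AttributeError("SUB2 equilibria have no x1")
        return float(self.state[0])

    @property
    def x2(self) -> float:
        if self.system is SystemId.SUB2:
            return float(self.state[0])
        if self.system is SystemId.FULL:
            return float(self.state[3])
        raise AttributeError(f"{self.system} equilibria have no x2")


# ---------------------------------------------------------------------------
# helpers


def slow_nullcline_z(x1: float, p: ParameterSet) -> float:
    """The unique z with zdot = 0 at this x1 (the z-nullcline).

    For z >= 0 it is the straight line z = s(x1 - x0); for z < 0 the
    stabilizing z^7 term makes the relation implicit but still monotone,
    so the root is unique and bracketed.
    """
    w = p.s * (x1 - p.x0)
    if w >= 0 or p.z_law == "original":
        return w
    # solve z + 0.1 z^7 = w for z < 0 (monotone increasing in z)
    lo = -((10.0 * abs(w)) ** (1.0 / 7.0)) - 1.0
    return optimize.brentq(lambda z: z + 0.1 * z ** 7 - w, lo, 0.0, xtol=1e-14)


def _real_roots(coeffs: Sequence[float], tol: float = 1e-9) -> np.ndarray:
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < tol].real
    return np.sort(real)


def sub1_x1_roots(z: float, p: ParameterSet, x2: Optional[float] = None) -> List[float]:
    """All equilibrium x1 of the fast subsystem at constant z.

    Cubic-branch roots are kept only if negative, quadratic-branch roots
    only if >= 0.  Passing ``x2`` uses the x2-coupled slope of the full
    model; None uses the uncoupled slope.
    """
    out: List[float] = []
    # cubic branch: c + (b-d) x1^2 - a x1^3 - z + Iext1 = 0, x1 < 0
    cube = _real_roots([-p.a, p.b - p.d, 0.0, p.c - z + p.Iext1])
    out.extend(r for r in cube if r < 0.0)
    # quadratic branch: c - d x1^2 + R x1 - z + Iext1 = 0, x1 >= 0
    R = p.m + 0.6 * (z - 4.0) ** 2
    if x2 is not None:
        R -= x2
    delta = R * R + 4.0 * p.d * (p.c - z + p.Iext1)
    if delta >= 0.0:
        sq = math.sqrt(delta)
        for r in ((R - sq) / (2 * p.d), (R + sq) / (2 * p.d)):
            if r >= 0.0:
                out.append(r)
    return out


def sub2_x2_roots(I: float, p: ParameterSet) -> List[float]:
    """All equilibrium x2 of the spike-wave subsystem at drive ``I``."""
    out: List[float] = []
    # x2 < -0.25: x2 - x2^3 + I = 0
    for r in _real_roots([-1.0, 0.0, 1.0, I]):
        if r < -0.25:
            out.append(r)
    # x2 >= -0.25: x2 - x2^3 - a2 (x2 + 0.25) + I = 0
    for r in _real_roots([-1.0, 0.0, 1.0 - p.a2, I - 0.25 * p.a2]):
        if r >= -0.25:
            out.append(r)
    return sorted(out)


def _make_equilibrium(
    system: SystemId,
    state: np.ndarray,
    p: ParameterSet,
    frozen: Optional[FrozenInputs] = None,
    real_tol: float = 1e-7,
    imag_tol: float = 1e-7,
) -> Equilibrium:
    fr = frozen or FrozenInputs()
    if system is SystemId.FULL and fr.z_frozen is not None:
        # fast 4x4 Jacobian: printed 5x5 without the z row/column
        J5 = jacobian(SystemId.FULL, state, p)
        idx = [0, 1, 3, 4]
        J = J5[np.ix_(idx, idx)]
        res = _full_frozen_residual(state, p)
        eig = np.linalg.eigvals(J)
        return Equilibrium(
            state=np.asarray(state, float),
            residual=res,
            eigenvalues=eig,
            stability=classify_stability(eig, real_tol, imag_tol),
            system=system,
            frozen_z=fr.z_frozen,
        )
    if system is SystemId.FULL:
        J = jacobian(system, state, p)
        res = float(np.max(np.abs(_full_reduced_rhs(np.asarray(state, float), p))))
    else:
        J = jacobian(system, state, p, fr)
        res = float(np.max(np.abs(rhs(system, state, p, fr))))
    eig = np.linalg.eigvals(J)
    return Equilibrium(
        state=np.asarray(state, float),
        residual=res,
        eigenvalues=eig,
        stability=classify_stability(eig, real_tol, imag_tol),
        system=system,
        frozen_z=fr.z_frozen,
    )


def sub1_equilibria_analytic(
    z: float, params: ParameterSet, **tol
) -> List[Equilibrium]:
    """Closed-form equilibria of the fast subsystem at constant z."""
    out = []
    for x1 in sub1_x1_roots(z, params):
        y1 = params.c - params.d * x1 ** 2
        out.append(
            _make_equilibrium(
                SystemId.SUB1,
                np.array([x1, y1]),
                params,
                FrozenInputs(z_frozen=z),
                **tol,
            )
        )
    return out


def sub2_equilibria_analytic(
    params: ParameterSet, external_input: Optional[float] = None, **tol
) -> List[Equilibrium]:
    """Closed-form equilibria of the spike-wave subsystem."""
    from .systems import f2

    I = params.Iext2 if external_input is None else external_input
    out = []
    for x2 in sub2_x2_roots(I, params):
        y2 = f2(x2, params)
        out.append(
            _make_equilibrium(
                SystemId.SUB2,
                np.array([x2, y2]),
                params,
                FrozenInputs(external_input=I),
                **tol,
            )
        )
    return out


# ---------------------------------------------------------------------------
# full model


def _g_drive(x1: float, p: ParameterSet) -> float:
    """Contribution of 0.002*g to the x2 equation under the active convention."""
    if p.g_convention == "stationary":
        return 0.002 * x1 / p.gamma_filter
    return 0.0


def _full_frozen_residual(state: Sequence[float], p: ParameterSet) -> float:
    x1, y1, z, x2, y2 = np.asarray(state, float)
    r1 = y1 - f1(x1, x2, z, p, True) - z + p.Iext1
    r2 = p.c - p.d * x1 ** 2 - y1
    r3 = -y2 + x2 - x2 ** 3 + p.Iext2 + _g_drive(x1, p) - 0.3 * (z - 3.5)
    r4 = (-y2 + f2(x2, p)) / p.tau2
    return float(max(abs(r1), abs(r2), abs(r3), abs(r4)))


def full_frozen_equilibria(
    z: float,
    params: ParameterSet,
    g_drive: Optional[str] = None,
    **tol,
) -> List[Equilibrium]:
    """All equilibria of the fast (x1, y1, x2, y2) equations at constant z.

    Under the "omit" convention the x2 cubic decouples from x1 and the
    solution set is the exact cross product of x2 roots with the x1 roots
    computed at each x2.  Under "stationary" the drive of the x2 equation
    carries the feedback 0.002*x1/gamma; the weakly coupled pair (x1, x2)
    is then solved by fixed-point seeding over both branch structures
    plus a final 2-D Newton polish.

    ``g_drive`` overrides ``params.g_convention`` for this call.
    """
    p = params if g_drive is None else params.with_(g_convention=g_drive)
    out: List[Equilibrium] = []

    def I2eff(x1: float) -> float:
        return p.Iext2 + _g_drive(x1, p) - 0.3 * (z - 3.5)

    pairs = set()
    # cubic-branch x1 roots are independent of x2
    cubic_x1 = [r for r in sub1_x1_roots(z, p) if r < 0.0]
    for x1 in cubic_x1:
        for x2 in sub2_x2_roots(I2eff(x1), p):
            pairs.add((round(x1, 9), round(x2, 9)))
    # quadratic branch: iterate the weak x1 <-> x2 coupling from spanning seeds
    x1_seeds = {0.0, 0.5, 1.0, 2.0, 3.0}
    for _ in range(3):
        new_seeds = set()
        for x1s in x1_seeds:
            for x2 in sub2_x2_roots(I2eff(x1s), p):
                for x1 in sub1_x1_roots(z, p, x2=x2):
                    if x1 >= 0.0:
                        new_seeds.add(round(x1, 6))
                        pairs.add((round(x1, 9), round(x2, 9)))
        if new_seeds <= x1_seeds:
            break
        x1_seeds |= new_seeds

    for x1, x2 in sorted(pairs):
        if p.g_convention == "stationary":

            def F(v):
                xx1, xx2 = v
                yy1 = p.c - p.d * xx1 ** 2
                r1 = yy1 - f1(xx1, xx2, z, p, True) - z + p.Iext1
                r3 = -f2(xx2, p) + xx2 - xx2 ** 3 + I2eff(xx1)
                return [r1, r3]

            sol = optimize.root(F, [x1, x2], tol=1e-13)
            # hybr can report failure when the seed is already converged;
            # judge by the residual instead
            if np.max(np.abs(F(sol.x))) > 1e-10:
                continue
            x1, x2 = sol.x
        state = np.array([x1, p.c - p.d * x1 ** 2, z, x2, f2(x2, p)])
        eq = _make_equilibrium(
            SystemId.FULL, state, p, FrozenInputs(z_frozen=z), **tol
        )
        if eq.residual < 1e-9:
            out.append(eq)
    return _dedup(out, tol=1e-6)


def _full_reduced_rhs(v: np.ndarray, p: ParameterSet) -> np.ndarray:
    """The 5-D equilibrium system (z row divided by r for conditioning)."""
    x1, y1, z, x2, y2 = v
    zrow = p.s * (x1 - p.x0) - z
    if p.z_law == "modified" and z < 0:
        zrow -= 0.1 * z ** 7
    return np.array(
        [
            y1 - f1(x1, x2, z, p, True) - z + p.Iext1,
            p.c - p.d * x1 ** 2 - y1,
            zrow,
            -y2 + x2 - x2 ** 3 + p.Iext2 + _g_drive(x1, p) - 0.3 * (z - 3.5),
            (-y2 + f2(x2, p)) / p.tau2,
        ]
    )


def _dedup(eqs: List[Equilibrium], tol: float = DEDUP_TOL) -> List[Equilibrium]:
    kept: List[Equilibrium] = []
    for eq in sorted(eqs, key=lambda e: tuple(e.state)):
        if all(np.max(np.abs(eq.state - k.state)) > tol for k in kept):
            kept.append(eq)
    return kept


def find_equilibria(
    system: SystemId,
    params: ParameterSet,
    frozen: Optional[FrozenInputs] = None,
    real_tol: float = 1e-7,
    imag_tol: float = 1e-7,
    z_window: Optional[Tuple[float, float]] = (-2.0, 6.0),
) -> List[Equilibrium]:
    """All real equilibria of the chosen system, deduplicated and classified.

    SUB1/SUB2 and the frozen-z full fast system are solved exactly by
    per-branch polynomial roots.  The free full model and fast-slow
    subsystem close the loop through the slow nullcline: the fast-slow
    case reduces to a scalar root problem in x1, the full model is solved
    by multi-start Newton seeded from the polynomial structure.

    ``z_window`` restricts full-model and fast-slow equilibria to the
    principal analysis window containing the Z-shaped diagram.  A second,
    outer family of equilibria exists at much larger z (beyond the outer
    fold of the x1 >= 0 branch); it plays no role in the model's
    repertoire and is reported only with ``z_window=None``.
    """
    tol = dict(real_tol=real_tol, imag_tol=imag_tol)
    fr = frozen or FrozenInputs()
    p = params

    if system is SystemId.SUB1:
        if fr.z_frozen is None:
            raise ValueError("SUB1 equilibria require frozen.z_frozen")
        return sub1_equilibria_analytic(fr.z_frozen, p, **tol)

    if system is SystemId.SUB2:
        return sub2_equilibria_analytic(p, fr.external_input, **tol)

    if system is SystemId.FASTSLOW:
        def F(x1: float) -> float:
            z = slow_nullcline_z(x1, p)
            return p.c - p.d * x1 ** 2 - f1(x1, 0.0, z, p, False) - z + p.Iext1

        grid = np.linspace(-4.0, 4.5, 1200)
        vals = np.array([F(x) for x in grid])
        out = []
        for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
            x1 = optimize.brentq(F, grid[i], grid[i + 1], xtol=1e-13)
            z = slow_nullcline_z(x1, p)
            state = np.array([x1, p.c - p.d * x1 ** 2, z])
            out.append(_make_equilibrium(system, state, p, **tol))
        for i in np.flatnonzero(vals == 0.0):
            x1 = grid[i]
            z = slow_nullcline_z(x1, p)
            state = np.array([x1, p.c - p.d * x1 ** 2, z])
            out.append(_make_equilibrium(system, state, p, **tol))
        out = _dedup(out)
        if z_window is not None:
            out = [e for e in out if z_window[0] <= e.state[2] <= z_window[1]]
        return out

    # FULL
    if fr.z_frozen is not None:
        return full_frozen_equilibria(fr.z_frozen, p, **tol)

    if z_window is not None:
        x1_lo = z_window[0] / p.s + p.x0 - 0.5
        x1_hi = z_window[1] / p.s + p.x0 + 0.5
    else:
        x1_lo, x1_hi = -3.0, 4.5
    starts = []
    for x1 in np.linspace(x1_lo, x1_hi, 121):
        z = slow_nullcline_z(x1, p)
        y1 = p.c - p.d * x1 ** 2
        I2eff = p.Iext2 + _g_drive(x1, p) - 0.3 * (z - 3.5)
        for x2 in sub2_x2_roots(I2eff, p):
            starts.append(np.array([x1, y1, z, x2, f2(x2, p)]))
    out = []
    failures = 0
    for v0 in starts:
        sol = optimize.root(_full_reduced_rhs, v0, args=(p,), method="hybr", tol=1e-12)
        if not sol.success:
            failures += 1
            continue
        v = sol.x
        if np.max(np.abs(_full_reduced_rhs(v, p))) > RESIDUAL_TOL:
            continue
        out.append(_make_equilibrium(SystemId.FULL, v, p, **tol))
    if not out and failures == len(starts):
        raise RuntimeError("equilibrium solver failed to converge from every start")
    out = _dedup(out)
    if z_window is not None:
        out = [e for e in out if z_window[0] <= e.state[2] <= z_window[1]]
    return out


# ---------------------------------------------------------------------------
# closed-form bifurcation values of the fast subsystem


@dataclass
class ClosedFormPoints:
    """Closed-form fold/Hopf locations of the uncoupled fast subsystem.

    z_SN1 : fold of the x1 < 0 branch (exactly Iext1 - 5/27 at defaults).
    z_SN2 : upper fold where the x1 >= 0 branch meets the middle branch
        (c + Iext1 for m <= 0, else min(X) + 4 from the quartic).
    z_H : supercritical Hopf on the x1 >= 0 branch, 4 - sqrt((5/3)(1-m));
        exists only for m <= 1.
    z_SN_outer : fold of the outer x1 >= 0 branch pair, max(X) + 4.
    p, q, w : coefficients of the quartic X^4 + pX^2 + qX + w in X = z-4
        whose roots bound the existence window of x1 >= 0 equilibria.
    alpha, beta, gamma_table : x1 breakpoints of the stability tables
        (the x1 >= 0 equilibrium evaluated at z_H, z(Det1), z(Det2)).
    """

    z_SN1: float
    z_SN2: float
    z_H: Optional[float]
    z_SN_outer: Optional[float]
    p: float
    q: float
    w: float
    alpha: Optional[float]
    beta: Optional[float]
    gamma_table: Optional[float]
    x1_fold: float

    def R(self, z: float, params: ParameterSet) -> float:
        return params.m + 0.6 * (z - 4.0) ** 2

    def delta_plus(self, z: float, params: ParameterSet) -> float:
        R = self.R(z, params)
        return R * R + 4.0 * params.d * (params.c - z + params.Iext1)

    def delta_minus(self, z: float, params: ParameterSet) -> float:
        """Discriminant of the depressed cubic branch at this z."""
        # a x^3 - (b-d) x^2 + (z - Iext1 - c) = 0
        a3, a2_, a0 = -params.a, params.b - params.d, params.c - z + params.Iext1
        # discriminant of a3 x^3 + a2 x^2 + a0
        return (
            18 * a3 * a2_ * 0.0 * a0
            - 4 * a2_ ** 3 * a0
            + 0.0
            - 27 * a3 ** 2 * a0 ** 2
        )


def _upper_x1(z: float, p: ParameterSet) -> Optional[float]:
    """The (R + sqrt(delta))/(2d) equilibrium branch at this z, if real."""
    R = p.m + 0.6 * (z - 4.0) ** 2
    delta = R * R + 4.0 * p.d * (p.c - z + p.Iext1)
    if delta < -1e-9:
        return None
    return (R + math.sqrt(max(delta, 0.0))) / (2.0 * p.d)


def sub1_closed_form_points(params: ParameterSet) -> ClosedFormPoints:
    p = params
    # fold of the cubic branch: extremum of z(x1) = c + (b-d)x1^2 - a x1^3 + I
    x1_fold = 2.0 * (p.b - p.d) / (3.0 * p.a)
    z_SN1 = p.c + (p.b - p.d) * x1_fold ** 2 - p.a * x1_fold ** 3 + p.Iext1
    # quartic in X = z - 4 bounding existence of x1 >= 0 equilibria
    qp = 10.0 * p.m / 3.0
    qq = -100.0 * p.d / 9.0
    qw = (25.0 / 9.0) * (p.m ** 2 + 4.0 * p.d * (p.c + p.Iext1 - 4.0))
    X = _real_roots([1.0, 0.0, qp, qq, qw])
    z_outer = float(X.max() + 4.0) if X.size else None
    if p.m <= 0:
        z_SN2 = p.c + p.Iext1
    else:
        if X.size == 0:
            raise RuntimeError("quartic has no real roots in the m > 0 regime")
        z_SN2 = float(X.min() + 4.0)
    z_H = None
    if p.m <= 1.0:
        z_H = 4.0 - math.sqrt((5.0 / 3.0) * (1.0 - p.m))
    z_det1 = p.c + p.Iext1 if p.m <= 0 else z_SN2
    alpha = _upper_x1(z_H, p) if z_H is not None else None
    beta = _upper_x1(z_det1, p)
    gamma_table = _upper_x1(z_outer, p) if z_outer is not None else None
    return ClosedFormPoints(
        z_SN1=z_SN1,
        z_SN2=z_SN2,
        z_H=z_H,
        z_SN_outer=z_outer,
        p=qp,
        q=qq,
        w=qw,
        alpha=alpha,
        beta=beta,
        gamma_table=gamma_table,
        x1_fold=x1_fold,
    )


def hopf_m_at_z(z: float, params: ParameterSet) -> float:
    """m at which the x1 >= 0 focus changes stability (Tr(J) = 0)."""
    return 1.0 - 0.6 * (z - 4.0) ** 2


def sub2_snic_point(params: ParameterSet) -> float:
    """Drive at which the node and saddle of the spike-wave subsystem
    coalesce on an invariant circle.

    Det(J2) = 0 on the x2 < -0.25 branch gives x2* = -1/sqrt(3); the
    equilibrium condition then yields I* = x2*^3 - x2* = 2/(3 sqrt 3).
    """
    x2 = -1.0 / math.sqrt(3.0)
    return x2 ** 3 - x2


# ---------------------------------------------------------------------------
# stability tables


def _z_for_upper_x1(x1: float, p: ParameterSet, regime: str) -> Optional[float]:
    """z of the x1 >= 0 equilibrium branch through this x1.

    ``regime`` selects the low-z ("inner", z <= z(Det1)) or high-z
    ("outer", z >= z(Det2)) root of the quadratic in z.
    """
    cf = sub1_closed_form_points(p)
    A = 0.6 * x1
    B = -(4.8 * x1 + 1.0)
    C = 9.6 * x1 + p.m * x1 + p.c - p.d * x1 ** 2 + p.Iext1
    if abs(A) < 1e-14:
        return -C / B
    disc = B * B - 4 * A * C
    if disc < 0:
        return None
    roots = sorted(((-B - math.sqrt(disc)) / (2 * A), (-B + math.sqrt(disc)) / (2 * A)))
    z_det1 = p.c + p.Iext1 if p.m <= 0 else cf.z_SN2
    if regime == "inner":
        cands = [z for z in roots if z <= z_det1 + 1e-9]
        return cands[-1] if cands else None
    cands = [z for z in roots if cf.z_SN_outer is not None and z >= cf.z_SN_outer - 1e-9]
    return cands[0] if cands else None


_TABLE_ROWS = {
    # table id -> (breakpoint names, expected classes per interval,
    #             expected (sign Det, sign Tr) per interval)
    "T2": (
        ["x1_fold", "0", "alpha"],
        ["stable", "saddle", "stable", "unstable"],
        [(1, -1), (-1, -1), (1, -1), (1, 1)],
    ),
    "T3": (
        ["x1_fold", "0", "beta", "alpha"],
        ["stable", "saddle", "saddle", "stable", "unstable"],
        [(1, -1), (-1, -1), (-1, -1), (1, -1), (1, 1)],
    ),
    "T4": (
        ["x1_fold", "0", "beta"],
        ["stable", "saddle", "saddle", "unstable"],
        [(1, -1), (-1, -1), (-1, 1), (1, 1)],
    ),
    "T5": (
        ["0", "gamma_table"],
        [None, "saddle", "unstable"],
        [None, (-1, 1), (1, 1)],
    ),
}


def _class_family(cls: StabilityClass) -> str:
    if cls is StabilityClass.SADDLE:
        return "saddle"
    if cls.is_stable:
        return "stable"
    return "unstable"


def stability_table_check(table_id: str, params: ParameterSet) -> dict:
    """Sample each interval of a printed stability table and verify the
    signs of Tr and Det and the resulting class.

    Tables T2-T5 cover the fast subsystem (the sampled x1 determines z
    through the equilibrium relation, restricted to the table's z-regime);
    T6 covers the spike-wave subsystem directly in x2.  Returns a report
    dict with one entry per sampled point and an overall ``ok`` flag.
    """
    p = params
    rows = []
    ok = True

    if table_id == "T6":
        t = p.tau2
        x2_det = -1.0 / math.sqrt(3.0)
        x2_tr = math.sqrt((1.0 - 1.0 / t) / 3.0)
        bps = [x2_det, -x2_tr, -0.25, x2_tr]
        expected = [
            ("stable", (1, -1)),
            ("saddle", (-1, -1)),
            ("saddle", (-1, 1)),
            ("unstable", (1, 1)),
            ("stable", (1, -1)),
        ]
        edges = [bps[0] - 0.5] + bps + [bps[-1] + 0.5]
        for i, (fam, signs) in enumerate(expected):
            lo, hi = edges[i], edges[i + 1]
            x2 = 0.5 * (lo + hi)
            G2 = 0.0 if x2 < -0.25 else p.a2 / t
            Det = G2 - (1.0 - 3.0 * x2 ** 2) / t
            Tr = 1.0 - 3.0 * x2 ** 2 - 1.0 / t
            J = np.array([[1.0 - 3.0 * x2 ** 2, -1.0], [G2, -1.0 / t]])
            fam_got = _class_family(classify_stability(np.linalg.eigvals(J)))
            good = fam_got == fam and np.sign(Det) == signs[0] and (
                signs[1] is None or np.sign(Tr) == signs[1]
            )
            ok &= good
            rows.append(
                dict(interval=(lo, hi), x=x2, Tr=Tr, Det=Det, expected=fam,
                     got=fam_got, ok=bool(good))
            )
        return dict(table=table_id, ok=bool(ok), rows=rows)

    if table_id not in _TABLE_ROWS:
        raise ValueError(f"unknown table id {table_id!r}")
    if table_id == "T2" and p.m > 0:
        raise ValueError("T2 applies for m <= 0")
    if table_id == "T3" and not (0 < p.m <= 1):
        raise ValueError("T3 applies for 0 < m <= 1")
    if table_id == "T4" and p.m <= 1:
        raise ValueError("T4 applies for m > 1")

    cf = sub1_closed_form_points(p)
    names, classes, signs = _TABLE_ROWS[table_id]
    bp_vals = {
        "x1_fold": cf.x1_fold,
        "0": 0.0,
        "alpha": cf.alpha,
        "beta": cf.beta,
        "gamma_table": cf.gamma_table,
    }
    bps = [bp_vals[n] for n in names]
    if any(v is None for v in bps):
        raise RuntimeError(f"breakpoints unavailable for {table_id}")
    edges = [bps[0] - 0.3] + list(bps) + [bps[-1] + 0.3]
    regime = "outer" if table_id == "T5" else "inner"
    for i, fam in enumerate(classes):
        if fam is None:  # T5 has no equilibria left of 0
            continue
        lo, hi = edges[i], edges[i + 1]
        x1 = 0.5 * (lo + hi)
        if x1 < 0:
            z = p.c + (p.b - p.d) * x1 ** 2 - p.a * x1 ** 3 + p.Iext1
            E = -3 * p.a * x1 ** 2 + 2 * p.b * x1
        else:
            z = _z_for_upper_x1(x1, p, regime)
            if z is None:
                # interval extends past where the branch is real; nudge inward
                x1 = lo + 0.25 * (hi - lo)
                z = _z_for_upper_x1(x1, p, regime)
                if z is None:
                    raise RuntimeError(
                        f"no {regime} z for sampled x1={x1:.3f} in {table_id}"
                    )
            E = p.m + 0.6 * (z - 4.0) ** 2
        Tr = E - 1.0
        Det = 2.0 * p.d * x1 - E
        J = np.array([[E, 1.0], [-2.0 * p.d * x1, -1.0]])
        fam_got = _class_family(classify_stability(np.linalg.eigvals(J)))
        sD, sT = signs[i]
        good = fam_got == fam and np.sign(Det) == sD and (
            sT is None or np.sign(Tr) == sT
        )
        ok &= good
        rows.append(
            dict(interval=(edges[i], edges[i + 1]), x=x1, z=z, Tr=Tr, Det=Det,
                 expected=fam, got=fam_got, ok=bool(good))
        )
    return dict(table=table_id, ok=bool(ok), rows=rows)
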