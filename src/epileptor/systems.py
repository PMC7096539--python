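"""Right-hand sides and analytic Jacobians of the four model systems.

Systems
-------
FULL
    The five-variable model (x1, y1, z, x2, y2) augmented with the
    low-pass filtered activity g as a sixth dynamic state
    (g' = x1 - gamma*g, the ODE form of the convolution kernel).
SUB1
    The fast discharge oscillator (x1, y1) at constant z, with the
    x2-free nullcline slope m + 0.6(z-4)^2.
SUB2
    The uncoupled spike-wave oscillator (x2, y2) with constant drive.
FASTSLOW
    (x1, y1, z): SUB1 coupled to the slow permittivity dynamics.

All pieces are continuous across their seams (x1 = 0, x2 = -0.25, z = 0):
both branches of each piecewise function agree at the seam, so the
printed tie-break (second branch at the seam) is observationally
irrelevant.  Jacobians follow the printed matrices: the full 5x5 carries
no g contribution in the x2 row (``g_convention="omit"``); with
``"stationary"`` the x2 row gains 0.002/gamma_filter in the x1 column.
"""

from __future__ import annotations

import enum
import math
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .params import FrozenInputs, ParameterSet


class SystemId(enum.Enum):
    FULL = "full"
    SUB1 = "sub1"
    SUB2 = "sub2"
    FASTSLOW = "fastslow"


#: state dimension per system
DIMS = {SystemId.FULL: 6, SystemId.SUB1: 2, SystemId.SUB2: 2, SystemId.FASTSLOW: 3}

#: column labels of trajectory states
STATE_NAMES = {
    SystemId.FULL: ("x1", "y1", "z", "x2", "y2", "g"),
    SystemId.SUB1: ("x1", "y1"),
    SystemId.SUB2: ("x2", "y2"),
    SystemId.FASTSLOW: ("x1", "y1", "z"),
}

#: default noise targets: the fast activity variables of each system
NOISE_TARGETS = {
    SystemId.FULL: (0, 3),
    SystemId.SUB1: (0,),
    SystemId.SUB2: (0,),
    SystemId.FASTSLOW: (0,),
}


def f1(x1: float, x2: float, z: float, p: ParameterSet, coupled: bool) -> float:
    """Fast-subsystem nonlinearity: cubic for x1 < 0, linear-slope branch above.

    ``coupled=True`` uses the x2-coupled slope (full model); ``False`` the
    x2-free slope (uncoupled fast subsystem)."""
    if x1 < 0.0:
        return p.a * x1 ** 3 - p.b * x1 ** 2
    slope = p.m + 0.6 * (z - 4.0) ** 2
    if coupled:
        slope -= x2
    return -slope * x1


def f2(x2: float, p: ParameterSet) -> float:
    if x2 < -0.25:
        return 0.0
    return p.a2 * (x2 + 0.25)


def zdot(x1: float, z: float, p: ParameterSet) -> float:
    """Slow permittivity dynamics; 'modified' adds -0.1 z^7 for z < 0."""
    out = p.s * (x1 - p.x0) - z
    if p.z_law == "modified" and z < 0.0:
        out -= 0.1 * z ** 7
    return p.r * out


def _check_state(system: SystemId, state: Sequence[float]) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (DIMS[system],):
        raise ValueError(
            f"{system.name} expects a state of dimension {DIMS[system]}, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite state")
    return arr


def rhs(
    system: SystemId,
    state: Sequence[float],
    params: ParameterSet,
    frozen: Optional[FrozenInputs] = None,
) -> np.ndarray:
    """Time derivative of ``state`` for the given system.

    When ``frozen.z_frozen`` is set, z is held at that value and (for
    systems carrying z) its derivative component is returned as zero.
    """
    p = params
    fr = frozen or FrozenInputs()
    arr = _check_state(system, state)

    if system is SystemId.SUB2:
        x2, y2 = arr
        I = p.Iext2 if fr.external_input is None else fr.external_input
        dx2 = -y2 + x2 - x2 ** 3 + I
        dy2 = (-y2 + f2(x2, p)) / p.tau2
        return np.array([dx2, dy2])

    if system is SystemId.SUB1:
        if fr.z_frozen is None:
            raise ValueError("SUB1 requires frozen.z_frozen")
        x1, y1 = arr
        z = fr.z_frozen
        dx1 = y1 - f1(x1, 0.0, z, p, coupled=False) - z + p.Iext1
        dy1 = p.c - p.d * x1 ** 2 - y1
        return np.array([dx1, dy1])

    if system is SystemId.FASTSLOW:
        x1, y1, z = arr
        if fr.z_frozen is not None:
            z = fr.z_frozen
        dx1 = y1 - f1(x1, 0.0, z, p, coupled=False) - z + p.Iext1
        dy1 = p.c - p.d * x1 ** 2 - y1
        dz = 0.0 if fr.z_frozen is not None else zdot(x1, z, p)
        return np.array([dx1, dy1, dz])

    # FULL
    x1, y1, z, x2, y2, g = arr
    if fr.z_frozen is not None:
        z = fr.z_frozen
    dx1 = y1 - f1(x1, x2, z, p, coupled=True) - z + p.Iext1
    dy1 = p.c - p.d * x1 ** 2 - y1
    dz = 0.0 if fr.z_frozen is not None else zdot(x1, z, p)
    dx2 = -y2 + x2 - x2 ** 3 + p.Iext2 + 0.002 * g - 0.3 * (z - 3.5)
    dy2 = (-y2 + f2(x2, p)) / p.tau2
    dg = x1 - p.gamma_filter * g
    return np.array([dx1, dy1, dz, dx2, dy2, dg])


# ---------------------------------------------------------------------------
# Jacobians


_SEAM_TOL = 0.0  # seams resolved by the printed >= / < conditions


def _E(x1: float, z: float, p: ParameterSet, x2: float, coupled: bool) -> float:
    """d(dx1)/dx1: -3a x1^2 + 2b x1 below the seam, nullcline slope above."""
    if x1 < 0.0:
        return -3.0 * p.a * x1 ** 2 + 2.0 * p.b * x1
    slope = p.m + 0.6 * (z - 4.0) ** 2
    if coupled:
        slope -= x2
    return slope


def _Z1(x1: float, z: float) -> float:
    """d(dx1)/dz."""
    if x1 < 0.0:
        return -1.0
    return 1.2 * (z - 4.0) * x1 - 1.0


def _Z2(z: float, p: ParameterSet) -> float:
    """d(dz)/dz."""
    if p.z_law == "modified" and z < 0.0:
        return p.r * (-1.0 - 0.7 * z ** 6)
    return -p.r


def jacobian(
    system: SystemId,
    state: Sequence[float],
    params: ParameterSet,
    frozen: Optional[FrozenInputs] = None,
) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs`.

    For FULL the Jacobian is the printed 5x5 on (x1, y1, z, x2, y2); a
    6-component state is accepted (g ignored under ``g_convention="omit"``;
    under ``"stationary"`` the x2 row gains 0.002/gamma in the x1 column).
    """
    p = params
    fr = frozen or FrozenInputs()

    if system is SystemId.SUB2:
        x2, _ = np.asarray(state, dtype=float)
        G2 = 0.0 if x2 < -0.25 else p.a2 / p.tau2
        return np.array([[1.0 - 3.0 * x2 ** 2, -1.0], [G2, -1.0 / p.tau2]])

    if system is SystemId.SUB1:
        x1 = float(np.asarray(state, dtype=float)[0])
        if fr.z_frozen is None:
            raise ValueError("SUB1 requires frozen.z_frozen")
        z = fr.z_frozen
        return np.array(
            [[_E(x1, z, p, 0.0, False), 1.0], [-2.0 * p.d * x1, -1.0]]
        )

    if system is SystemId.FASTSLOW:
        x1, _, z = np.asarray(state, dtype=float)
        return np.array(
            [
                [_E(x1, z, p, 0.0, False), 1.0, _Z1(x1, z)],
                [-2.0 * p.d * x1, -1.0, 0.0],
                [p.r * p.s, 0.0, _Z2(z, p)],
            ]
        )

    arr = np.asarray(state, dtype=float)
    if arr.shape == (6,):
        x1, y1, z, x2, y2, _ = arr
    else:
        x1, y1, z, x2, y2 = arr
    A = _E(x1, z, p, x2, True)
    B = 0.0 if x1 < 0.0 else -x1
    C = 0.0 if x2 < -0.25 else p.a2 / p.tau2
    J = np.array(
        [
            [A, 1.0, _Z1(x1, z), B, 0.0],
            [-2.0 * p.d * x1, -1.0, 0.0, 0.0, 0.0],
            [p.r * p.s, 0.0, _Z2(z, p), 0.0, 0.0],
            [0.0, 0.0, -0.3, 1.0 - 3.0 * x2 ** 2, -1.0],
            [0.0, 0.0, 0.0, C, -1.0 / p.tau2],
        ]
    )
    if p.g_convention == "stationary":
        # g* = x1/gamma feeds 0.002*g back into the x2 equation
        J[3, 0] = 0.002 / p.gamma_filter
    return J


# ---------------------------------------------------------------------------
# Fast scalar closures for the integrator (plain-float hot loop)


def make_scalar_rhs(
    system: SystemId, params: ParameterSet, frozen: Optional[FrozenInputs] = None
) -> Callable[[Tuple[float, ...]], Tuple[float, ...]]:
    """Return a tuple->tuple derivative function specialized to ``params``."""
    p = params
    fr = frozen or FrozenInputs()
    a, b, c, d = p.a, p.b, p.c, p.d
    I1, m, a2, tau2, I2 = p.Iext1, p.m, p.a2, p.tau2, p.Iext2
    gam, r, s, x0 = p.gamma_filter, p.r, p.s, p.x0
    modified = p.z_law == "modified"

    if system is SystemId.SUB2:
        Ieff = I2 if fr.external_input is None else fr.external_input

        def rhs_sub2(st):
            x2, y2 = st
            fx = 0.0 if x2 < -0.25 else a2 * (x2 + 0.25)
            return (-y2 + x2 - x2 * x2 * x2 + Ieff, (-y2 + fx) / tau2)

        return rhs_sub2

    if system is SystemId.SUB1:
        if fr.z_frozen is None:
            raise ValueError("SUB1 requires frozen.z_frozen")
        z = fr.z_frozen
        base = -z + I1

        def rhs_sub1(st):
            x1, y1 = st
            if x1 < 0.0:
                fx = a * x1 * x1 * x1 - b * x1 * x1
            else:
                fx = -(m + 0.6 * (z - 4.0) ** 2) * x1
            return (y1 - fx + base, c - d * x1 * x1 - y1)

        return rhs_sub1

    if system is SystemId.FASTSLOW:
        zf = fr.z_frozen

        def rhs_fs(st):
            x1, y1, z = st
            if zf is not None:
                z = zf
            if x1 < 0.0:
                fx = a * x1 * x1 * x1 - b * x1 * x1
            else:
                fx = -(m + 0.6 * (z - 4.0) ** 2) * x1
            if zf is not None:
                dz = 0.0
            else:
                dz = s * (x1 - x0) - z
                if modified and z < 0.0:
                    dz -= 0.1 * z ** 7
                dz *= r
            return (y1 - fx - z + I1, c - d * x1 * x1 - y1, dz)

        return rhs_fs

    zf = fr.z_frozen

    def rhs_full(st):
        x1, y1, z, x2, y2, g = st
        if zf is not None:
            z = zf
        if x1 < 0.0:
            fx = a * x1 * x1 * x1 - b * x1 * x1
        else:
            fx = -(m - x2 + 0.6 * (z - 4.0) ** 2) * x1
        if zf is not None:
            dz = 0.0
        else:
            dz = s * (x1 - x0) - z
            if modified and z < 0.0:
                dz -= 0.1 * z ** 7
            dz *= r
        fx2 = 0.0 if x2 < -0.25 else a2 * (x2 + 0.25)
        return (
            y1 - fx - z + I1,
            c - d * x1 * x1 - y1,
            dz,
            -y2 + x2 - x2 * x2 * x2 + I2 + 0.002 * g - 0.3 * (z - 3.5),
            (-y2 + fx2) / tau2,
            x1 - gam * g,
        )

    return rhs_full


# ---------------------------------------------------------------------------
# Batched frozen-z fast dynamics (used by continuation and averaging)


def fast_dim(system: SystemId) -> int:
    """Dimension of the frozen-z fast part: 2 for SUB1/FASTSLOW, 5 for
    FULL (x1, y1, x2, y2 plus the low-pass variable g)."""
    if system in (SystemId.SUB1, SystemId.FASTSLOW):
        return 2
    if system is SystemId.FULL:
        return 5
    raise ValueError("no frozen-z fast part for SUB2")


def fast_rhs_batch(
    system: SystemId, Y: np.ndarray, z: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """Vectorized derivative of the frozen-z fast equations.

    ``Y`` has shape (n, 2) for SUB1/FASTSLOW (columns x1, y1) or (n, 5)
    for FULL (columns x1, y1, x2, y2, g — everything except z evolves);
    ``z`` has shape (n,).
    """
    p = params
    x1 = Y[:, 0]
    y1 = Y[:, 1]
    neg = x1 < 0.0
    out = np.empty_like(Y)
    if system in (SystemId.SUB1, SystemId.FASTSLOW):
        slope = p.m + 0.6 * (z - 4.0) ** 2
        fx = np.where(neg, p.a * x1 ** 3 - p.b * x1 ** 2, -slope * x1)
        out[:, 0] = y1 - fx - z + p.Iext1
        out[:, 1] = p.c - p.d * x1 ** 2 - y1
        return out
    x2 = Y[:, 2]
    y2 = Y[:, 3]
    g = Y[:, 4]
    slope = p.m - x2 + 0.6 * (z - 4.0) ** 2
    fx = np.where(neg, p.a * x1 ** 3 - p.b * x1 ** 2, -slope * x1)
    fx2 = np.where(x2 < -0.25, 0.0, p.a2 * (x2 + 0.25))
    out[:, 0] = y1 - fx - z + p.Iext1
    out[:, 1] = p.c - p.d * x1 ** 2 - y1
    out[:, 2] = -y2 + x2 - x2 ** 3 + p.Iext2 + 0.002 * g - 0.3 * (z - 3.5)
    out[:, 3] = (-y2 + fx2) / p.tau2
    out[:, 4] = x1 - p.gamma_filter * g
    return out


# ---------------------------------------------------------------------------
# Observables


def observable(traj, which: str) -> np.ndarray:
    """Scalar readout of a trajectory.

    ``"psi"`` = -x1 + x2 (the field-potential-like signal of the full
    model); ``"psi1"`` = x1; ``"psi2"`` = x2.
    """
    names = list(traj.names)
    if which == "psi":
        if "x1" not in names or "x2" not in names:
            raise ValueError("psi requires x1 and x2 components")
        return -traj.states[:, names.index("x1")] + traj.states[:, names.index("x2")]
    if which == "psi1":
        if "x1" not in names:
            raise ValueError("psi1 requires an x1 component")
        return traj.states[:, names.index("x1")].copy()
    if which == "psi2":
        if "x2" not in names:
            raise ValueError("psi2 requires an x2 component")
        return traj.states[:, names.index("x2")].copy()
    raise ValueError(f"unknown observable {which!r}")
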