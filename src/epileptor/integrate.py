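"""Fixed-step time integration with reproducible seeding.

Deterministic runs use the classical 4th-order Runge-Kutta scheme with a
maximal time step of 0.01 (the scheme used for every deterministic figure
configuration); stochastic runs use Euler-Maruyama with additive Gaussian
white noise of variance 0.0025 by default.  Trajectories that leave the
overflow guard (|state| > 1e6) are truncated and flagged as divergent
rather than raising — the original (linear-for-all-z) slow law genuinely
diverges from initial conditions below the saddle orbit, and that
behavior is part of the model's repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .params import FrozenInputs, NoiseSpec, ParameterSet
from .systems import DIMS, NOISE_TARGETS, STATE_NAMES, SystemId, make_scalar_rhs

OVERFLOW_GUARD = 1e6


@dataclass
class Trajectory:
    """Time-stamped state samples from one integration run."""

    times: np.ndarray
    states: np.ndarray
    system: SystemId
    params: ParameterSet
    dt: float
    seed: Optional[int] = None
    diverged: bool = False
    truncated_at: Optional[int] = None

    @property
    def names(self) -> Tuple[str, ...]:
        return STATE_NAMES[self.system]

    def __len__(self) -> int:
        return len(self.times)

    def component(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_csv(self, path) -> None:
        header = "t," + ",".join(self.names)
        np.savetxt(
            path,
            np.column_stack([self.times, self.states]),
            delimiter=",",
            header=header,
            comments="",
        )


def _span(duration: Union[float, Tuple[float, float]]) -> Tuple[float, float]:
    if np.isscalar(duration):
        t0, t1 = 0.0, float(duration)
    else:
        t0, t1 = map(float, duration)
    if not (t1 > t0):
        raise ValueError("invalid time span")
    return t0, t1


def integrate_deterministic(
    system: SystemId,
    init: Sequence[float],
    duration: Union[float, Tuple[float, float]],
    params: ParameterSet,
    dt_max: float = 0.01,
    frozen: Optional[FrozenInputs] = None,
    sample_every: int = 1,
) -> Trajectory:
    """Classical RK4 at fixed step ``dt_max`` (default 0.01).

    ``sample_every`` thins the stored samples; the step itself is never
    coarsened.  Divergence truncates the trajectory and sets the flag.
    """
    t0, t1 = _span(duration)
    init = tuple(map(float, init))
    if len(init) != DIMS[system]:
        raise ValueError(f"init must have dimension {DIMS[system]}")
    f = make_scalar_rhs(system, params, frozen)
    d0 = f(init)
    if any(not np.isfinite(v) for v in d0):
        raise ValueError("NaN/inf in rhs at the initial state")

    n_steps = int(np.ceil((t1 - t0) / dt_max - 1e-12))
    dt = (t1 - t0) / n_steps
    half = dt / 2.0
    sixth = dt / 6.0
    dim = len(init)

    times = [t0]
    states = [init]
    y = init
    t = t0
    diverged = False
    for i in range(n_steps):
        k1 = f(y)
        y2 = tuple(y[j] + half * k1[j] for j in range(dim))
        k2 = f(y2)
        y3 = tuple(y[j] + half * k2[j] for j in range(dim))
        k3 = f(y3)
        y4 = tuple(y[j] + dt * k3[j] for j in range(dim))
        k4 = f(y4)
        y = tuple(
            y[j] + sixth * (k1[j] + 2.0 * (k2[j] + k3[j]) + k4[j])
            for j in range(dim)
        )
        t = t0 + (i + 1) * dt
        if any(abs(v) > OVERFLOW_GUARD or v != v for v in y):
            diverged = True
            break
        if (i + 1) % sample_every == 0:
            times.append(t)
            states.append(y)

    traj = Trajectory(
        times=np.array(times),
        states=np.array(states),
        system=system,
        params=params,
        dt=dt,
        diverged=diverged,
        truncated_at=len(times) - 1 if diverged else None,
    )
    return traj


def integrate_stochastic(
    system: SystemId,
    init: Sequence[float],
    duration: Union[float, Tuple[float, float]],
    params: ParameterSet,
    noise: NoiseSpec,
    dt: float = 0.01,
    frozen: Optional[FrozenInputs] = None,
    sample_every: int = 1,
) -> Trajectory:
    """Euler-Maruyama with additive white noise on the configured components.

    Identical seeds yield bitwise-identical trajectories; zero variance
    reduces exactly to the deterministic forward-Euler scheme.
    """
    t0, t1 = _span(duration)
    init = tuple(map(float, init))
    if len(init) != DIMS[system]:
        raise ValueError(f"init must have dimension {DIMS[system]}")
    f = make_scalar_rhs(system, params, frozen)

    n_steps = int(np.ceil((t1 - t0) / dt - 1e-12))
    h = (t1 - t0) / n_steps
    targets = noise.targets if noise.targets is not None else NOISE_TARGETS[system]
    seed = noise.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2 ** 31))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(noise.variance * h)
    if noise.variance > 0:
        incr = rng.normal(0.0, sigma, size=(n_steps, len(targets)))
    else:
        incr = np.zeros((n_steps, len(targets)))

    dim = len(init)
    times = [t0]
    states = [init]
    y = init
    diverged = False
    for i in range(n_steps):
        k = f(y)
        ylist = [y[j] + h * k[j] for j in range(dim)]
        for col, j in enumerate(targets):
            ylist[j] += incr[i, col]
        y = tuple(ylist)
        if any(abs(v) > OVERFLOW_GUARD or v != v for v in y):
            diverged = True
            break
        if (i + 1) % sample_every == 0:
            times.append(t0 + (i + 1) * h)
            states.append(y)

    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        system=system,
        params=params,
        dt=h,
        seed=seed,
        diverged=diverged,
        truncated_at=len(times) - 1 if diverged else None,
    )


def drop_transient(traj: Trajectory, cut: float, fraction: bool = False) -> Trajectory:
    """Return the suffix of ``traj`` after ``cut`` time units (or a fraction).

    Provenance (system, params, seed, dt, flags) is preserved.
    """
    t0, t1 = traj.times[0], traj.times[-1]
    span = t1 - t0
    cut_t = cut * span if fraction else cut
    if cut_t < 0 or cut_t >= span:
        if cut_t == 0:
            return replace(traj, times=traj.times.copy(), states=traj.states.copy())
        raise ValueError("cut must lie within the trajectory span")
    i0 = int(np.searchsorted(traj.times, t0 + cut_t))
    return replace(traj, times=traj.times[i0:].copy(), states=traj.states[i0:].copy())
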