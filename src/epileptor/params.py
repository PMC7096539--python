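"""Model parameters and auxiliary input records.

The Epileptor couples three timescales: a fast oscillator (x1, y1)
producing fast discharges, an intermediate spike-wave oscillator (x2, y2),
and a very slow permittivity variable z that mediates autonomous
transitions between normal and ictal states.  All constants of the three
subsystems live in :class:`ParameterSet`; the defaults are the standard
parameter block used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence, Tuple


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the model plus analysis conventions.

    Parameters
    ----------
    a, b, c, d : float
        Polynomial coefficients of the fast subsystem (dimensionless).
    Iext1 : float
        External drive of the fast subsystem.
    m : float
        Ictal control parameter; shifts the slope of the x1-nullcline for
        x1 >= 0 and thereby controls the frequency (and existence) of fast
        discharges during the ictal state.
    a2, tau2, Iext2, gamma_filter : float
        Slope, timescale, drive and low-pass rate of the spike-wave
        subsystem.  ``gamma_filter`` is the rate of the convolution kernel
        defining g(x1); it is distinct from the Table-5 breakpoint
        conventionally also called gamma.
    r, s, x0 : float
        Rate, gain and excitability offset of the slow z dynamics.
    z_law : {"modified", "original"}
        "modified" uses the stabilized z equation (extra -0.1 z^7 term for
        z < 0); "original" is linear in z for all z and admits divergent
        trajectories from initial conditions below the saddle orbit.
    g_convention : {"omit", "stationary"}
        How the 0.002*g coupling enters equilibrium and Jacobian analysis:
        "omit" drops it (matching the printed 5x5 Jacobian, the default for
        all reported values); "stationary" substitutes g* = x1/gamma_filter.
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    Iext1: float = 3.1
    m: float = 0.0
    a2: float = 6.0
    tau2: float = 10.0
    Iext2: float = 0.45
    gamma_filter: float = 0.01
    r: float = 0.00035
    s: float = 4.0
    x0: float = -1.6
    z_law: str = "modified"
    g_convention: str = "omit"

    def __post_init__(self) -> None:
        if self.tau2 < 1:
            raise ValueError("tau2 must be >= 1")
        if self.r <= 0 or self.s <= 0 or self.gamma_filter <= 0:
            raise ValueError("r, s and gamma_filter must be positive")
        if self.z_law not in ("modified", "original"):
            raise ValueError(f"unknown z_law {self.z_law!r}")
        if self.g_convention not in ("omit", "stationary"):
            raise ValueError(f"unknown g_convention {self.g_convention!r}")

    def with_(self, **kwargs) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)

    def to_text(self) -> str:
        """Serialize as plain ``key = value`` lines (TOML-compatible)."""
        lines = []
        for k, v in self.to_dict().items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            else:
                lines.append(f"{k} = {v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ParameterSet":
        import tomllib

        return cls.from_dict(tomllib.loads(text))


@dataclass(frozen=True)
class FrozenInputs:
    """Inputs held constant during fast-subsystem analysis.

    z_frozen : value of z when the fast equations are analyzed at constant
        z (the z-component of any returned derivative is then zero).
    external_input : effective drive of the uncoupled spike-wave subsystem;
        defaults to Iext2 of the parameter set when None.
    """

    z_frozen: Optional[float] = None
    external_input: Optional[float] = None


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian white-noise specification for Euler-Maruyama.

    ``variance`` is the variance of the white noise (default 0.0025);
    increments of sqrt(dt)*N(0, variance) are added to ``targets`` (state
    indices; None selects the fast activity variables x1 and x2 of the
    system being integrated).
    """

    variance: float = 0.0025
    targets: Optional[Tuple[int, ...]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")
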