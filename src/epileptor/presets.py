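"""Figure-preset registry and run configuration.

Each preset records, verbatim from the published figure caption, the
parameter overrides, initial condition, slow rate r and time span used
to produce that figure, together with the caption fragment it was read
from.  A :class:`RunConfig` is fully serializable, and a run is
reproducible from its config plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

from .params import NoiseSpec, ParameterSet
from .systems import SystemId


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    system: SystemId = SystemId.FULL
    params: ParameterSet = field(default_factory=ParameterSet)
    init: Tuple[float, ...] = (0.0, -5.0, 3.0, 0.0, 0.0, 0.01)
    t_span: Tuple[float, float] = (0.0, 4000.0)
    dt: float = 0.01
    noise: Optional[NoiseSpec] = None
    seed: Optional[int] = None
    source: str = ""  # caption fragment the values trace to

    def to_dict(self) -> dict:
        d = {
            "system": self.system.value,
            "params": self.params.to_dict(),
            "init": list(self.init),
            "t_span": list(self.t_span),
            "dt": self.dt,
            "seed": self.seed,
            "source": self.source,
        }
        if self.noise is not None:
            d["noise"] = {
                "variance": self.noise.variance,
                "targets": list(self.noise.targets) if self.noise.targets else None,
                "seed": self.noise.seed,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        noise = None
        if d.get("noise") is not None:
            nd = d["noise"]
            noise = NoiseSpec(
                variance=nd["variance"],
                targets=tuple(nd["targets"]) if nd.get("targets") else None,
                seed=nd.get("seed"),
            )
        return cls(
            system=SystemId(d.get("system", "full")),
            params=ParameterSet.from_dict(d["params"]),
            init=tuple(d["init"]),
            t_span=tuple(d.get("t_span", (0.0, 4000.0))),
            dt=d.get("dt", 0.01),
            noise=noise,
            seed=d.get("seed"),
            source=d.get("source", ""),
        )


def _cfg(**kw) -> RunConfig:
    params = ParameterSet(**kw.pop("p", {}))
    return RunConfig(params=params, **kw)


#: caption-faithful configurations of the figure simulations
PRESETS: Dict[str, RunConfig] = {
    # recurrent seizure-like events (stochastic)
    "fig1": _cfg(
        p=dict(m=0.0, x0=-1.6, r=0.00035),
        init=(0.0, -5.0, 3.0, 0.0, 0.0, 0.01),
        t_span=(0.0, 4000.0),
        noise=NoiseSpec(variance=0.0025),
        source="m = 0, x0 = -1.6, and r = 0.00035. "
               "Initial conditions are [0 -5 3 0 0 0.01].",
    ),
    "fig2c": _cfg(
        p=dict(m=0.0, x0=-2.5),
        noise=NoiseSpec(variance=0.0025),
        source="normal activity; m = 0 and x0 = -2.5",
    ),
    "fig2d": _cfg(
        p=dict(m=0.0, x0=-0.9),
        noise=NoiseSpec(variance=0.0025),
        source="nonoscillatory state; m = 0 and x0 = -0.9",
    ),
    "fig2e": _cfg(
        p=dict(m=0.5, x0=-0.9),
        noise=NoiseSpec(variance=0.0025),
        source="periodic solution; m = 0.5 and x0 = -0.9",
    ),
    # bifurcation-diagram trajectories
    "fig4_sle": _cfg(
        p=dict(m=0.5, x0=-1.6, r=0.0007),
        source="m = 0.5, Iext2 = 0.45; r = 0.003 for LC and r = 0.0007 for SLEs",
    ),
    "fig4_lc": _cfg(
        p=dict(m=0.5, x0=-1.6, r=0.003),
        init=(0.0, -5.0, 0.01, 0.0, 0.0, 0.01),
        source="m = 0.5, Iext2 = 0.45; r = 0.003 for LC and r = 0.0007 for SLEs",
    ),
    "fig5_right": _cfg(
        p=dict(m=0.0, x0=-1.6, r=0.0006),
        init=(0.0, -5.0, 2.5, 0.0, 0.0, 0.01),
        t_span=(0.0, 1337.0),
        source="For the right trajectory, r = 0.0006, I.C = [0 -5 2.5 0 0 0.01] "
               "and Ts = [0 1337].",
    ),
    "fig5_left": _cfg(
        p=dict(m=0.0, x0=-1.6, r=0.001),
        init=(0.0, -5.0, 1.0, 0.0, 0.0, 0.01),
        t_span=(0.0, 1000.0),
        source="For the left trajectory, r = 0.001, I.C = [0 -5 1 0 0 0.01], "
               "and Ts = [0 1000].",
    ),
    "fig6": _cfg(
        p=dict(m=0.0, x0=-1.6, Iext2=0.0, r=0.0005),
        init=(0.0, -5.0, 2.5, 0.0, 0.0, 0.01),
        t_span=(0.0, 1540.0),
        source="m = 0, Iext2 = 0; r = 0.0005, I.C = [0 -5 2.5 0 0 0.01] and "
               "Ts = [0:0.001: 1540].",
    ),
    "fig7": _cfg(
        p=dict(m=-0.5, x0=-1.6, Iext2=0.0, r=0.0007),
        init=(0.0, -5.0, 2.65, 0.0, 0.0, 0.01),
        t_span=(0.0, 1028.0),
        source="m = -0.5, Iext2 = 0; r = 0.0007, I.C = [0 -5 2.65 0 0 0.01] "
               "and Ts = [0:0.001: 1028].",
    ),
    "fig8": _cfg(
        p=dict(m=-1.0, x0=-1.6, Iext2=0.0, r=0.0008),
        init=(0.5, -5.0, 2.0, 0.0, 0.0, 0.01),
        t_span=(0.0, 1400.0),
        source="m = -1, Iext2 = 0; r = 0.0008, I.C = [0.5 -5 2 0 0 0.01] and "
               "Ts = [0:0.001: 1400].",
    ),
    # divergence (original z law) vs the fast-slow cycle LC
    "fig9c": _cfg(
        p=dict(m=0.5, x0=-1.6, r=0.009, z_law="original"),
        init=(0.0, -5.0, 0.01, 0.0, 0.0, 0.01),
        t_span=(0.0, 2000.0),
        source="the trajectory diverges with time; r = 0.009 for LC (i2) "
               "with initial z below the separatrix",
    ),
    "fig9d": _cfg(
        p=dict(m=0.5, x0=-1.6, r=0.009),
        init=(0.0, -5.0, 0.01, 0.0, 0.0, 0.01),
        t_span=(0.0, 2000.0),
        source="the fast-slow limit cycle LC; r = 0.009 for LC (i2)",
    ),
    "fig10": _cfg(
        p=dict(m=0.5, x0=-0.9, r=0.0035),
        init=(0.0, -5.0, 3.0, 0.0, 0.0, 0.01),
        t_span=(0.0, 1000.0),
        source="m = 0.5, Iext2 = 0.45, r = 0.0035, I.C = [0 -5 3 0 0 0.01] and "
               "Ts = [0 1000].",
    ),
    # coexisting small limit cycle
    "fig13a": _cfg(
        p=dict(m=1.0, x0=-1.8, Iext2=0.0, r=0.0007),
        source="The equilibrium point is a saddle (m = 1, x0 = -1.8) with "
               "Iext2 = 0, r = 0.0007.",
    ),
    "fig13b": _cfg(
        p=dict(m=-2.0, x0=0.0, Iext2=0.0, r=0.0007),
        source="an unstable focus (m = -2, x0 = 0) with Iext2 = 0, r = 0.0007.",
    ),
    # depolarization block
    "fig14": _cfg(
        p=dict(m=-8.0, x0=-1.6, Iext2=0.0, r=0.0005),
        source="Parameters are: m = -8, Iext2 = 0, r = 0.0005.",
    ),
    "fig15": _cfg(
        p=dict(m=-8.0, x0=-1.6, Iext2=0.45, r=0.0005),
        init=(0.0, -5.0, 2.7, 0.0, 0.0, 0.01),
        t_span=(0.0, 1600.0),
        source="m = -8, x0 = -1.6, Iext2 = 0.45, r = 0.0005, "
               "I.C = [0 -5 2.7 0 0 0.01], and Ts = [0:0.001: 1600].",
    ),
    "fig16d": _cfg(
        p=dict(m=-8.0, x0=-0.6, Iext2=0.0, r=0.00005),
        init=(-1.0, -5.0, 4.0, 0.0, 0.0, 0.01),
        t_span=(0.0, 3000.0),
        source="m = -8 and Iext2 = 0. Let x0 = -0.6 ... r = 0.00005 and "
               "Ts = [0:0.001:3000] for D.",
    ),
    # chaotic spiking
    "fig37a": _cfg(
        p=dict(m=1.0, x0=-1.6, Iext2=0.45),
        t_span=(0.0, 3000.0),
        source="a chaotic spiking for m = 1, x0 = -1.6",
    ),
    "fig37b": _cfg(
        p=dict(m=1.5, x0=-1.9, Iext2=0.45),
        t_span=(0.0, 3000.0),
        source="a chaotic transition between ictal and normal states for "
               "m = 1.5, x0 = -1.9",
    ),
}


def load_preset(figure_id: str) -> RunConfig:
    """Return the caption-faithful configuration for a figure id."""
    try:
        return PRESETS[figure_id.lower()]
    except KeyError:
        raise KeyError(
            f"unknown preset {figure_id!r}; known: {', '.join(sorted(PRESETS))}"
        ) from None


def run_preset(figure_id: str, seed: Optional[int] = None):
    """Integrate a preset and return the trajectory (stochastic presets
    use Euler-Maruyama with the given seed, deterministic ones RK4)."""
    from .integrate import integrate_deterministic, integrate_stochastic
    from .params import NoiseSpec as _NS

    cfg = load_preset(figure_id)
    if cfg.noise is not None:
        noise = _NS(
            variance=cfg.noise.variance,
            targets=cfg.noise.targets,
            seed=seed if seed is not None else cfg.noise.seed,
        )
        return integrate_stochastic(
            cfg.system, cfg.init, cfg.t_span, cfg.params, noise, dt=cfg.dt
        )
    return integrate_deterministic(
        cfg.system, cfg.init, cfg.t_span, cfg.params, dt_max=cfg.dt
    )
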