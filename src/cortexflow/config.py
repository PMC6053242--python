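"""Run configuration: every tunable of a simulation in one serializable object.

A :class:`RunConfig` round-trips losslessly through YAML, and remembers for
each parameter whether it came from the package's calibrated defaults or was
set by the user, so that any result artifact can be regenerated from its
logged configuration alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import (
    CytoplasmicPools,
    KineticParams,
    MechParams,
    PhaseFieldParams,
    ViscosityParams,
)

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # grid
    nx: int = 256
    ny: int = 256
    Lx: float = 90.0
    Ly: float = 90.0
    # geometry (um)
    rx: float = 15.0
    ry: float = 25.0
    e_d: float = 5.5
    # parameter blocks
    mech: MechParams = field(default_factory=MechParams)
    visc: ViscosityParams = field(default_factory=ViscosityParams)
    phase: PhaseFieldParams = field(default_factory=PhaseFieldParams)
    kin: KineticParams = field(default_factory=KineticParams)
    pools: CytoplasmicPools = field(default_factory=CytoplasmicPools)
    # initial species interface position and actomyosin level
    K0: float = -15.0
    m0: float = 0.7
    # time stepping / run control
    t_end: float = 8000.0
    cadence: float = 50.0  # observable sampling interval, s
    relax_time: float = 30.0  # force-free interface pre-relaxation before t=0
    exit_margin: float = 500.0  # stop this long after polarization completes
    cfl: float = 0.4
    solver_rtol: float = 1.0e-5
    solver_maxiter: int = 500
    # bookkeeping
    seed: int = 0  # used only by optional perturbation sweeps
    outdir: str | None = None
    #: parameter provenance: name -> "calibrated" | "user"
    provenance: dict = field(default_factory=dict, compare=False)

    _BLOCKS = ("mech", "visc", "phase", "kin", "pools")

    def __post_init__(self) -> None:
        if self.e_d < 0:
            raise ValueError("e_d must be nonnegative")
        if self.t_end <= 0 or self.cadence <= 0:
            raise ValueError("t_end and cadence must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("provenance", None)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        data.pop("provenance", None)
        kwargs = {}
        block_types = {
            "mech": MechParams,
            "visc": ViscosityParams,
            "phase": PhaseFieldParams,
            "kin": KineticParams,
            "pools": CytoplasmicPools,
        }
        provenance: dict[str, str] = {}
        for name, typ in block_types.items():
            block = data.pop(name, {}) or {}
            defaults = typ()
            for key, val in block.items():
                if getattr(defaults, key) != val:
                    provenance[f"{name}.{key}"] = "user"
            kwargs[name] = typ(**block)
        default_cfg_fields = {
            f.name: f.default for f in dataclasses.fields(cls)
            if f.default is not dataclasses.MISSING
        }
        for key, val in data.items():
            if key in default_cfg_fields and default_cfg_fields[key] != val:
                provenance[key] = "user"
            kwargs[key] = val
        cfg = cls(**kwargs)
        for name in cfg._all_param_names():
            provenance.setdefault(name, "calibrated")
        cfg.provenance = provenance
        return cfg

    def _all_param_names(self) -> list[str]:
        names = []
        for f in dataclasses.fields(self):
            if f.name in self._BLOCKS:
                names.extend(
                    f"{f.name}.{g.name}"
                    for g in dataclasses.fields(getattr(self, f.name))
                )
            elif f.name != "provenance":
                names.append(f.name)
        return names

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **updates) -> "RunConfig":
        """Copy with top-level or dotted block fields replaced
        (e.g. ``replace(e_d=3.5, **{"mech.c_g": 300})``)."""
        d = self.to_dict()
        for key, val in updates.items():
            if "." in key:
                block, sub = key.split(".", 1)
                d[block][sub] = val
            else:
                d[key] = val
        return RunConfig.from_dict(d)
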