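"""Structured simulation configuration (YAML) with validated defaults.

Internal units: length in l (the tether hard core), energy in k_BT,
temperature dimensionless.  Defaults are the vesicle-model conditions:
``D_v = 50 l``, ``D_p = 8 l``, 5882 vertices, ``kappa = 21 kBT``,
``K_A = 10^3 kBT/l^2``, ``K_V = 4x10^3 kBT/(D_p l^2)``, ``A_t = 1.05 A_0``,
``V_t = V_0``.  An empty config file yields exactly these defaults;
unknown keys are hard errors.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .energy import THETA_WR_90, EnergyParams
from .errors import ConfigError
from .mesh import DEFAULT_L_MAX, achievable_triangulation
from .montecarlo import AnnealSchedule


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    initial_temperature: float = 1.0
    final_temperature: float = 0.01
    n_stages: int = 40
    sweeps_per_stage: int = 60

    def build(self) -> AnnealSchedule:
        return AnnealSchedule(self.initial_temperature, self.final_temperature,
                              self.n_stages, self.sweeps_per_stage)


class SimConfig(BaseModel):
    """All parameters of a vesicle-particle simulation."""

    model_config = ConfigDict(extra="forbid")

    l: float = 1.0
    D_p: float = 8.0                      # particle diameter [l]
    D_v: float = 50.0                     # vesicle diameter [l]
    target_vertex_count: int | None = None  # None: scale 5882 by (D_v/50)^2
    kappa: float = 21.0                   # bending rigidity [kBT]
    kappa_disc: float | None = None       # None: 2 sqrt(3) kappa
    K_A: float = 1.0e3                    # [kBT / l^2]
    K_V_printed: float = 4.0e3            # [kBT / (D_p l^2)] as conventionally quoted
    area_factor: float = 1.05             # A_t = area_factor * A_0
    epsilon: float | None = None          # adhesion well depth [kBT]; None: auto
    adhesion_margin: float = 2.5          # auto-epsilon safety factor over threshold
    theta_wr: float = THETA_WR_90         # active-cone half angle [rad]
    cutoff_factor: float = 1.2            # adhesion cut-off, units of l_m
    well: str = "power6"
    l_max: float = DEFAULT_L_MAX
    seed: int = 0
    amp_vertex: float = 0.1
    amp_particle: float = 0.1
    flip_fraction: float = 0.1
    wrap_sweeps: int = 6000               # T=1 pre-relaxation budget for wrapping
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.D_p < self.D_v):
            raise ValueError("need 0 < D_p < D_v")
        if self.area_factor < 1.0:
            raise ValueError("area_factor must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        return self

    # -- derived quantities --------------------------------------------
    @property
    def R_v(self) -> float:
        return 0.5 * self.D_v

    @property
    def K_V(self) -> float:
        """Volume stiffness converted to kBT / l^3."""
        return self.K_V_printed / self.D_p

    def vertex_count(self) -> int:
        """Achievable vertex count at the reference vertex density.

        The reference resolution is 5882 vertices on a 50 l vesicle; other
        vesicle sizes keep the same areal vertex density.
        """
        target = self.target_vertex_count
        if target is None:
            target = int(round(5882 * (self.D_v / 50.0) ** 2))
        return achievable_triangulation(target)[0]

    def vertex_density(self) -> float:
        """Vertices per l^2 of target membrane area."""
        A0 = 4 * np.pi * self.R_v ** 2
        return self.vertex_count() / (self.area_factor * A0)

    def auto_epsilon(self) -> float:
        """Adhesion well depth: ``margin * 2 kappa / (R_p^2 rho_v)``.

        The wrapping threshold requires the areal adhesion energy
        ``epsilon * rho_v`` to exceed the bending cost ``2 kappa / R_p^2``;
        the margin keeps the wrapped state robust against the discrete,
        thermally fluctuating layer.
        """
        if self.epsilon is not None:
            return self.epsilon
        R_p = 0.5 * self.D_p
        return self.adhesion_margin * 2.0 * self.kappa / (R_p ** 2 * self.vertex_density())

    def energy_params(self, A_t: float, V_t: float) -> EnergyParams:
        return EnergyParams(
            kappa=self.kappa,
            kappa_disc=self.kappa_disc,
            K_A=self.K_A,
            K_V=self.K_V,
            A_t=A_t,
            V_t=V_t,
            epsilon=self.auto_epsilon(),
            l=self.l,
            D_p=self.D_p,
            theta_wr=self.theta_wr,
            cutoff_factor=self.cutoff_factor,
            l_max=self.l_max,
            well=self.well,
        )

    # -- I/O ------------------------------------------------------------
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def load_config(path) -> SimConfig:
    """Load and validate a YAML config; empty file -> full defaults.

    Unknown keys and invariant violations raise :class:`ConfigError` naming
    the offending field.
    """
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable YAML in {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return SimConfig(**data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
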