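"""Run configuration: a schema-validated YAML surface over the core types.

The defaults reproduce the reference study conditions (5x5x15 lattice of
10 um pores, maltodextrin/ice properties, shelf at -18 degC, chamber at
10 Pa / -42 degC).  Temperatures in the configuration file are given in
degrees Celsius, as process engineers write them; the core dataclasses
work in kelvin.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .conditions import BoundaryConditions, kelvin
from .engine import SolverOptions
from .network import LatticeSpec
from .properties import MaterialProps, p_sat_ice

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class LatticeConfig(_Strict):
    nx: int = 5
    ny: int = 5
    nz: int = 15
    L_cv_um: float = 10.0
    psd_mode: str = "monomodal"
    d_mean_large_um: float = 5.0
    d_mean_small_um: float = 1.0
    d_sd_um: float = 0.2
    center_extent: int = 3


class MaterialConfig(_Strict):
    rho_ice: float = 919.0
    rho_s: float = 1565.0
    lam_ice: float = 2.42
    lam_s: float = 0.5
    cp_ice: float = 1930.0
    cp_s: float = 1250.0
    cp_v: float = 1617.0
    M_v: float = 18.02e-3
    dh_sub: float = 2.838e6
    a_krischer: float = 0.5


class BoundaryConfig(_Strict):
    T_bot_C: float = -18.0
    T_inf_C: float = -42.0
    T_init_C: float = -28.0
    P_inf: float = 10.0
    P_init: float = 10.0
    g_inf: float = 1e-12

    @model_validator(mode="after")
    def _physical(self):
        for name in ("T_bot_C", "T_inf_C", "T_init_C"):
            if getattr(self, name) >= 0.01:
                raise ValueError(f"{name} must lie below the triple point (0.01 degC)")
        if self.P_inf > p_sat_ice(kelvin(self.T_bot_C)):
            raise ValueError(
                "P_inf exceeds the equilibrium pressure at the shelf temperature"
            )
        return self


class SolverConfig(_Strict):
    safety: float = 1.0
    dt_floor: float = 1e-12
    snapshot_ds: float = 0.05
    max_steps: int = 5_000_000


class RunConfig(_Strict):
    """Complete, validated description of one drying run."""

    lattice: LatticeConfig = LatticeConfig()
    material: MaterialConfig = MaterialConfig()
    boundary: BoundaryConfig = BoundaryConfig()
    solver: SolverConfig = SolverConfig()
    seed: int = 0

    # --- conversion to core objects ---------------------------------------
    def lattice_spec(self, psd_mode: str | None = None, seed: int | None = None) -> LatticeSpec:
        kw = self.lattice.model_dump()
        if psd_mode is not None:
            kw["psd_mode"] = psd_mode
        return LatticeSpec(seed=self.seed if seed is None else seed, **kw)

    def material_props(self) -> MaterialProps:
        return MaterialProps(**self.material.model_dump())

    def boundary_conditions(self) -> BoundaryConditions:
        b = self.boundary
        return BoundaryConditions(
            T_bot=kelvin(b.T_bot_C),
            T_inf=kelvin(b.T_inf_C),
            T_init=kelvin(b.T_init_C),
            P_inf=b.P_inf,
            P_init=b.P_init,
            g_inf=b.g_inf,
        )

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver.model_dump())


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration; an empty or missing body
    yields the full set of reference defaults.  Unknown keys are rejected
    with field-level messages."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
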