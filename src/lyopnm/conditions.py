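"""Boundary and initial conditions of the primary-drying problem."""

from __future__ import annotations

from dataclasses import dataclass

from .properties import T_TRIPLE, p_sat_ice

__all__ = ["BoundaryConditions", "celsius", "kelvin"]


def kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


def celsius(t_kelvin: float) -> float:
    return t_kelvin - 273.15


@dataclass(frozen=True)
class BoundaryConditions:
    """Process conditions (SI).

    The bottom node layer sits on a shelf at constant ``T_bot``; the top
    layer exchanges vapor with the chamber bulk (``P_inf``, ``T_inf``)
    through the constant surface coefficient ``g_inf``.  The network starts
    fully ice saturated at ``T_init`` with a uniform gas pressure
    ``P_init``.
    """

    T_bot: float = kelvin(-18.0)    # shelf temperature [K]
    T_inf: float = kelvin(-42.0)    # chamber temperature [K]
    P_inf: float = 10.0             # chamber pressure [Pa]
    g_inf: float = 1e-12            # top surface vapor coefficient [kg/(s Pa)]
    T_init: float = kelvin(-28.0)   # initial network temperature [K]
    P_init: float = 10.0            # initial network pressure [Pa]

    def __post_init__(self) -> None:
        for name in ("T_bot", "T_inf", "T_init"):
            if not 0 < getattr(self, name) < T_TRIPLE:
                raise ValueError(f"{name} must lie below the triple point")
        if self.P_inf <= 0 or self.P_init <= 0 or self.g_inf <= 0:
            raise ValueError("pressures and g_inf must be positive")
        if self.P_inf > p_sat_ice(self.T_bot):
            raise ValueError(
                "chamber pressure exceeds the equilibrium pressure at the shelf "
                "temperature: sublimation could not proceed"
            )
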