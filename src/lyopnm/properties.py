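"""Material properties, ice-vapor equilibrium and effective CV properties.

The solid skeleton is parameterised as maltodextrin; water ice fills the
pores.  Constants are mean values over the primary-drying temperature
window (roughly -40 to -15 degC) and are treated as temperature
independent, except for the vapor viscosity.

The ice-vapor equilibrium uses the Goff-Gratch correlation for the
saturation pressure over ice; its numerical inversion gives the saturation
temperature for a given chamber pressure.

Effective control-volume properties follow the Krischer mixing model: the
thermal conductivity is a weighted harmonic combination (weight ``a``) of
the series and parallel bounds of the ice/solid composite.  In a partially
dried CV the vacated pore fraction ``(1 - S) * eps`` contributes neither
conductance nor resistance, which leaves the dry cake with a reduced but
finite conductivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MaterialProps",
    "CvEffectiveProps",
    "vapor_viscosity",
    "p_sat_ice",
    "t_sat_ice",
    "effective_cv_properties",
    "cv_saturation",
]

T_TRIPLE = 273.16        #: triple-point temperature of water [K]
P_TRIPLE = 610.71        #: triple-point pressure of water [Pa] (6.1071 hPa)
T_MIN_VALID = 150.0      #: lower validity bound of the ice correlation [K]


@dataclass(frozen=True)
class MaterialProps:
    """Physical constants of the ice / maltodextrin / vapor system (SI)."""

    rho_ice: float = 919.0       # [kg/m^3]
    rho_s: float = 1565.0        # [kg/m^3]
    lam_ice: float = 2.42        # [W/m/K]
    lam_s: float = 0.5           # [W/m/K]
    cp_ice: float = 1930.0       # [J/kg/K]
    cp_s: float = 1250.0         # [J/kg/K]
    cp_v: float = 1617.0         # [J/kg/K]
    M_v: float = 18.02e-3        # [kg/mol]
    dh_sub: float = 2.838e6      # [J/kg]
    a_krischer: float = 0.5      # series/parallel weighting [-]
    R: float = 8.3145            # [J/mol/K]

    def __post_init__(self) -> None:
        for name in (
            "rho_ice", "rho_s", "lam_ice", "lam_s", "cp_ice", "cp_s",
            "cp_v", "M_v", "dh_sub", "R",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.a_krischer <= 1.0:
            raise ValueError("a_krischer must lie in [0, 1]")


@dataclass(frozen=True)
class CvEffectiveProps:
    """Saturation- and porosity-dependent effective CV properties (per node)."""

    rho: np.ndarray        # [kg/m^3]
    cp: np.ndarray         # [J/kg/K]
    lam: np.ndarray        # Krischer effective conductivity [W/m/K]
    lam_ser: np.ndarray    # series bound [W/m/K]
    lam_par: np.ndarray    # parallel bound [W/m/K]

    @property
    def rho_cp(self) -> np.ndarray:
        """Volumetric heat capacity [J/m^3/K]."""
        return self.rho * self.cp


def vapor_viscosity(T):
    """Dynamic viscosity of water vapor [Pa s].

    ``eta = 18.4558e-7 * T**1.5 / (T + 650)`` with T in kelvin.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    out = 18.4558e-7 * T**1.5 / (T + 650.0)
    return out if out.ndim else float(out)


def p_sat_ice(T):
    """Equilibrium (saturation) vapor pressure over ice [Pa], Goff-Gratch.

    log10(P) = -9.09718 (T*/T - 1) - 3.56654 log10(T*/T)
               + 0.876793 (1 - T/T*) + log10(P*)

    with T* = 273.16 K and P* = 610.71 Pa.  Valid for
    ``150 K < T <= T*``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= T_MIN_VALID) or np.any(T > T_TRIPLE + 1e-9):
        raise ValueError(
            f"temperature outside ice-equilibrium validity window "
            f"({T_MIN_VALID} K, {T_TRIPLE} K]"
        )
    x = T_TRIPLE / T
    log10p = (
        -9.09718 * (x - 1.0)
        - 3.56654 * np.log10(x)
        + 0.876793 * (1.0 - 1.0 / x)
        + np.log10(P_TRIPLE)
    )
    out = 10.0**log10p
    return out if out.ndim else float(out)


def t_sat_ice(P: float) -> float:
    """Saturation temperature over ice for pressure ``P`` [Pa] -> [K].

    Inverts the Goff-Gratch relation by bracketed root finding; the
    correlation is strictly monotone so the bracket is safe.
    """
    if not 0.0 < P <= P_TRIPLE:
        raise ValueError(f"pressure must lie in (0, {P_TRIPLE}] Pa")
    lo = T_MIN_VALID + 1e-6
    if P <= p_sat_ice(lo):
        raise ValueError("pressure below validity window of the correlation")
    return float(brentq(lambda T: p_sat_ice(T) - P, lo, T_TRIPLE, xtol=1e-9))


def effective_cv_properties(eps, S, mat: MaterialProps) -> CvEffectiveProps:
    """Krischer effective density, heat capacity and conductivity per CV.

    rho   = S eps rho_ice + (1 - eps) rho_s
    cp    = S eps cp_ice + (1 - eps) cp_s
    l_ser = [S eps / l_ice + (1 - eps) / l_s]^-1
    l_par = S eps l_ice + (1 - eps) l_s
    l     = [a / l_ser + (1 - a) / l_par]^-1
    """
    eps = np.asarray(eps, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(eps < 0) or np.any(eps >= 1):
        raise ValueError("CV porosity must lie in [0, 1)")
    if np.any(S < -1e-12) or np.any(S > 1 + 1e-12):
        raise ValueError("CV saturation must lie in [0, 1]")
    S = np.clip(S, 0.0, 1.0)
    ice = S * eps
    solid = 1.0 - eps
    rho = ice * mat.rho_ice + solid * mat.rho_s
    cp = ice * mat.cp_ice + solid * mat.cp_s
    lam_ser = 1.0 / (ice / mat.lam_ice + solid / mat.lam_s)
    lam_par = ice * mat.lam_ice + solid * mat.lam_s
    a = mat.a_krischer
    lam = 1.0 / (a / lam_ser + (1.0 - a) / lam_par)
    return CvEffectiveProps(rho=rho, cp=cp, lam=lam, lam_ser=lam_ser, lam_par=lam_par)


def cv_saturation(ice_volumes, void_volumes):
    """Per-node CV saturation: half-pore ice volume over half-pore void volume.

    Nodes with zero void volume are defined to have zero saturation.
    """
    ice = np.asarray(ice_volumes, dtype=float)
    void = np.asarray(void_volumes, dtype=float)
    if np.any(ice > void * (1.0 + 1e-9) + 1e-30):
        raise ValueError("CV ice volume exceeds CV void volume")
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(void > 0, ice / np.maximum(void, 1e-300), 0.0)
    return np.clip(S, 0.0, 1.0)
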