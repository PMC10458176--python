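"""Closed-form reference drying-rate models.

Classical continuum descriptions of primary freeze drying bound the
area-specific sublimation rate by a mass-transfer-limited (MTL) branch
through the growing dry cake, a heat-transfer-limited (HTL) branch through
the shrinking frozen layer, their harmonic combination (the transition
regime), and a Darcy vapor-flow expression driven by the front equilibrium
pressure:

    m_MTL   = K_eff M (P_eq(T_bot) - P_inf) / (R T_bot L_PN) * 1/(1 - S)
    m_HTL   = lam_eff (T_bot - T_inf) / (dh_sub L_PN) * 1/S
    m_trans = (1/m_MTL + 1/m_HTL)^-1
    m_Da    = K_eff M (P_eq(T_front) - P) / (R T_front (L_PN - z_front))

All rates are in kg/(s m^2).  ``K_eff`` and ``lam_eff`` are
caller-supplied effective coefficients (typically fitted to, or computed
from, pore-network simulations); a least-squares helper for ``K_eff`` is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .properties import MaterialProps, p_sat_ice

__all__ = ["RegimeParams", "RegimeRates", "regime_rates", "darcy_rate", "fit_keff"]


@dataclass(frozen=True)
class RegimeParams:
    """Effective parameters of the continuum regime models (SI)."""

    K_eff: float                    # effective mass transfer coefficient [m^2/s]
    lam_eff: float                  # effective thermal conductivity [W/m/K]
    L_pn: float = 150e-6            # network height [m]
    T_bot: float = 255.15           # shelf temperature [K]
    T_inf: float = 231.15           # chamber temperature [K]
    P_inf: float = 10.0             # chamber pressure [Pa]

    def __post_init__(self) -> None:
        if self.K_eff <= 0 or self.lam_eff <= 0 or self.L_pn <= 0:
            raise ValueError("K_eff, lam_eff and L_pn must be positive")


class RegimeRates(NamedTuple):
    mtl: np.ndarray
    htl: np.ndarray
    trans: np.ndarray


def regime_rates(S, params: RegimeParams, mat: MaterialProps | None = None) -> RegimeRates:
    """MTL, HTL and transition rates at overall saturation ``S``.

    The MTL branch is singular at S = 1 (no dry cake yet) and the HTL
    branch at S = 0 (no frozen layer); those endpoints return ``inf``.
    """
    mat = mat or MaterialProps()
    S = np.asarray(S, dtype=float)
    if np.any(S < 0) or np.any(S > 1):
        raise ValueError("saturation must lie in [0, 1]")
    dP = p_sat_ice(params.T_bot) - params.P_inf
    with np.errstate(divide="ignore"):
        mtl = (
            params.K_eff * mat.M_v * dP
            / (mat.R * params.T_bot * params.L_pn)
            / (1.0 - S)
        )
        htl = (
            params.lam_eff * (params.T_bot - params.T_inf)
            / (mat.dh_sub * params.L_pn)
            / S
        )
        trans = 1.0 / (1.0 / mtl + 1.0 / htl)
    if mtl.ndim == 0:
        return RegimeRates(float(mtl), float(htl), float(trans))
    return RegimeRates(mtl, htl, trans)


def darcy_rate(
    z_front,
    T_front,
    params: RegimeParams,
    P: float | None = None,
    mat: MaterialProps | None = None,
):
    """Darcy vapor-flow rate for a front at height-from-top ``z_front`` [m].

    ``z_front`` runs from 0 (front at the bottom, full cake thickness
    ``L_pn``) to ``L_pn`` (front at the surface, where the rate diverges).
    """
    mat = mat or MaterialProps()
    P = params.P_inf if P is None else P
    z = np.asarray(z_front, dtype=float)
    T = np.asarray(T_front, dtype=float)
    with np.errstate(divide="ignore"):
        out = (
            params.K_eff * mat.M_v * (p_sat_ice(T) - P)
            / (mat.R * T * (params.L_pn - z))
        )
    return out if out.ndim else float(out)


def fit_keff(S, flux, params: RegimeParams, mat: MaterialProps | None = None) -> float:
    """Least-squares ``K_eff`` so the MTL curve matches a simulated
    rate-vs-saturation series ``flux`` [kg/(s m^2)].

    The MTL rate is linear in ``K_eff``, so the fit is closed form.
    """
    mat = mat or MaterialProps()
    S = np.asarray(S, dtype=float)
    flux = np.asarray(flux, dtype=float)
    ok = (S < 1.0) & np.isfinite(flux)
    base = regime_rates(S[ok], RegimeParams(
        K_eff=1.0, lam_eff=params.lam_eff, L_pn=params.L_pn,
        T_bot=params.T_bot, T_inf=params.T_inf, P_inf=params.P_inf,
    ), mat).mtl
    return float(np.dot(base, flux[ok]) / np.dot(base, base))
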