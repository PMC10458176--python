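"""Post-processing: slice profiles and sublimation-front geometry.

A *slice* is one horizontal layer of the lattice: the CVs of one node
layer, the lateral pores lying in it and the vertical pores assigned to it
(a vertical pore belongs to the slice of its upper node, so a flat
receding front occupies exactly one slice).

The *front* is the set of ice-containing pores in contact with the
vapor-active region.  Its position is characterised by the ice-volume
weighted mean front position (MFP) and the two extremes: the most
advanced point (MAP, lowest slice reached, drying proceeds downward) and
the least advanced point (LAP).  The front width counts occupied slices
inclusively, ``width = (LAP - MAP) + L_cv``, so a flat front is one pore
layer wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import PoreNetwork
from .vapor import active_nodes

__all__ = ["FrontMetrics", "slice_profiles", "front_metrics"]


class NetworkDryError(ValueError):
    """Front metrics requested on a completely dry network."""


@dataclass(frozen=True)
class FrontMetrics:
    """Sublimation-front geometry in micrometres (heights above the shelf)."""

    mfp_um: float    # ice-volume-weighted mean front position
    map_um: float    # most advanced (lowest) front position
    lap_um: float    # least advanced (highest) front position
    width_um: float  # (LAP - MAP) + L_cv
    n_layers: int    # width expressed in pore layers

    def __post_init__(self) -> None:
        if not (self.map_um <= self.mfp_um + 1e-9 and self.mfp_um <= self.lap_um + 1e-9):
            raise ValueError("front metrics must satisfy MAP <= MFP <= LAP")


def front_metrics(
    net: PoreNetwork,
    pore_ice: np.ndarray,
    active: np.ndarray | None = None,
) -> FrontMetrics:
    """Front geometry for the current ice distribution.

    ``active`` is the vapor-active node mask; it is recomputed from the
    ice distribution when omitted.  Raises :class:`NetworkDryError` when
    no ice remains.
    """
    icy = np.asarray(pore_ice) > 0
    if not icy.any():
        raise NetworkDryError("no ice-containing pores remain")
    if active is None:
        active = active_nodes(net, ~icy)
    front_pores = icy & (active[net.pore_i] | active[net.pore_j])
    if not front_pores.any():
        raise NetworkDryError("no ice pore is in contact with the vapor phase")
    L_um = net.spec.L_cv_um
    z = net.pore_layer[front_pores] * L_um
    w = np.asarray(pore_ice, dtype=float)[front_pores]
    map_, lap = float(z.min()), float(z.max())
    mfp = min(max(float(np.average(z, weights=w)), map_), lap)
    width = lap - map_ + L_um
    return FrontMetrics(
        mfp_um=mfp, map_um=map_, lap_um=lap, width_um=width,
        n_layers=int(round(width / L_um)),
    )


def slice_profiles(
    net: PoreNetwork,
    pore_ice: np.ndarray,
    T: np.ndarray | None = None,
    P: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-slice saturation and temperature/pressure statistics.

    Slice saturation is the slice's total ice volume over its total void
    volume; temperature and pressure statistics aggregate the nodes of the
    slice.  Returns one row per node layer, bottom first.
    """
    nz = net.spec.nz
    layer = net.pore_layer
    void = np.bincount(layer, weights=net.V, minlength=nz)
    ice = np.bincount(layer, weights=np.asarray(pore_ice, dtype=float), minlength=nz)
    with np.errstate(invalid="ignore"):
        sat = np.where(void > 0, ice / np.maximum(void, 1e-300), 0.0)
    out = {
        "z_um": np.arange(nz) * net.spec.L_cv_um,
        "saturation": sat,
    }
    node_layer = net.coords[:, 2]
    for name, vals in (("T", T), ("P", P)):
        if vals is None:
            continue
        vals = np.asarray(vals, dtype=float)
        df = pd.DataFrame({"layer": node_layer, "v": vals})
        g = df.groupby("layer")["v"]
        out[f"{name}_mean"] = g.mean().reindex(range(nz)).to_numpy()
        out[f"{name}_min"] = g.min().reindex(range(nz)).to_numpy()
        out[f"{name}_max"] = g.max().reindex(range(nz)).to_numpy()
    return pd.DataFrame(out)
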