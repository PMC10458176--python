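"""Regular 3D bond lattices for pore-network freeze-drying simulations.

The void space of the frozen product is discretised into cylindrical pores
(bonds) that meet at volumeless computational nodes on a regular cubic grid.
Laterally the lattice is periodic (one wrap pore per row/column); the top
node layer is open to the drying chamber and the bottom layer sits on the
heating shelf.  Each node carries a cubic control volume (CV) of edge
``L_cv`` whose porosity collects half the volume of every incident pore.

All quantities are stored in SI units (m, m**2, m**3); the public
constructors accept the micrometre values that are natural for this
pore-scale geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

UM = 1e-6  #: metres per micrometre

__all__ = [
    "LatticeSpec",
    "PoreNetwork",
    "CvGeometry",
    "build_lattice",
    "assign_diameters",
    "compute_cv_geometry",
]


class GeometryError(ValueError):
    """Raised for invalid or degenerate network geometry."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometric recipe for a regular lattice.

    Parameters
    ----------
    nx, ny, nz
        Node counts per axis.  The drying direction is z; the top node
        layer (``iz = nz - 1``) faces the chamber.
    L_cv_um
        Node spacing = pore length = CV edge length, in micrometres.
    psd_mode
        ``"monomodal"``: every pore diameter ~ Normal(d_mean_large, d_sd).
        ``"bimodal"``: pores whose two end nodes both lie in the central
        ``center_extent`` x ``center_extent`` block of lateral node columns
        are "large" (Normal(d_mean_large, d_sd)); all others are "small"
        (Normal(d_mean_small, d_sd)).
    d_mean_large, d_mean_small, d_sd
        Pore-diameter distribution parameters in micrometres.
    center_extent
        Lateral node span of the large-pore core (bimodal only).
    seed
        Seed for the diameter sampling RNG.
    """

    nx: int = 5
    ny: int = 5
    nz: int = 15
    L_cv_um: float = 10.0
    psd_mode: str = "monomodal"
    d_mean_large_um: float = 5.0
    d_mean_small_um: float = 1.0
    d_sd_um: float = 0.2
    center_extent: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise GeometryError("node counts must be >= 1")
        if self.L_cv_um <= 0:
            raise GeometryError("L_cv must be positive")
        if self.psd_mode not in ("monomodal", "bimodal"):
            raise GeometryError(f"unknown psd_mode {self.psd_mode!r}")
        for mean in (self.d_mean_large_um,) + (
            (self.d_mean_small_um,) if self.psd_mode == "bimodal" else ()
        ):
            if mean - 3.0 * self.d_sd_um <= 0:
                raise GeometryError(
                    "diameter distribution too wide: mean - 3*sd must stay positive"
                )
        if self.psd_mode == "bimodal":
            if self.center_extent < 1 or self.center_extent > min(self.nx, self.ny):
                raise GeometryError("center_extent must fit inside the lateral grid")


@dataclass(frozen=True)
class PoreNetwork:
    """Immutable lattice topology plus per-pore geometry.

    Pores are directed ``i -> j`` only for bookkeeping; the physics is
    symmetric.  ``pore_layer`` assigns every pore to a horizontal slice:
    lateral pores belong to the node layer they lie in, vertical pores to
    the layer of their *upper* node (their midpoint sits on the slab
    boundary and is rounded up, which makes a flat receding front occupy
    exactly one slice).
    """

    spec: LatticeSpec
    coords: np.ndarray        # (N, 3) integer grid indices
    pore_i: np.ndarray        # (P,) node index
    pore_j: np.ndarray        # (P,)
    pore_axis: np.ndarray     # (P,) 0=x, 1=y, 2=z
    d: np.ndarray             # (P,) diameter [m]
    large: np.ndarray | None = None   # (P,) bool, bimodal label
    # derived, filled in __post_init__
    L: float = field(init=False)
    n_nodes: int = field(init=False)
    n_pores: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "L", self.spec.L_cv_um * UM)
        object.__setattr__(self, "n_nodes", self.coords.shape[0])
        object.__setattr__(self, "n_pores", self.pore_i.shape[0])

    # --- per-pore geometry -------------------------------------------------
    @cached_property
    def r(self) -> np.ndarray:
        """Pore radii [m]."""
        return 0.5 * self.d

    @cached_property
    def A(self) -> np.ndarray:
        """Cross-sectional areas pi*r**2 [m**2]."""
        return np.pi * self.r**2

    @cached_property
    def V(self) -> np.ndarray:
        """Pore volumes A*L [m**3]."""
        return self.A * self.L

    # --- node tags ---------------------------------------------------------
    @cached_property
    def top(self) -> np.ndarray:
        """Boolean mask of top-layer nodes (open to the chamber)."""
        return self.coords[:, 2] == self.spec.nz - 1

    @cached_property
    def bottom(self) -> np.ndarray:
        """Boolean mask of bottom-layer nodes (on the heating shelf)."""
        return self.coords[:, 2] == 0

    @cached_property
    def pore_layer(self) -> np.ndarray:
        """Slice index of every pore (vertical pores -> upper node layer)."""
        iz_i = self.coords[self.pore_i, 2]
        iz_j = self.coords[self.pore_j, 2]
        return np.where(self.pore_axis == 2, np.maximum(iz_i, iz_j), iz_i)

    @cached_property
    def node_pos_um(self) -> np.ndarray:
        """Physical node positions [um]."""
        return self.coords * self.spec.L_cv_um

    @cached_property
    def bandwidth(self) -> int:
        """Maximum node-index distance across a pore.

        With the x-fastest node numbering the lattice couplings stay within
        ``nx * ny`` indices of the diagonal, so the linear systems of the
        pressure and heat solves are banded.
        """
        if self.n_pores == 0:
            return 0
        return int(np.max(np.abs(self.pore_i - self.pore_j)))

    @cached_property
    def band_scatter(self) -> np.ndarray:
        """Flattened banded-storage indices for edge-Laplacian assembly.

        For banded storage ``ab`` of shape ``(2B+1, N)`` (diagonal in row
        B), scattering the weight pattern ``[w, w, -w, -w]`` per edge onto
        these flat indices assembles the graph Laplacian of the pore
        lattice in one ``bincount``.
        """
        B, N = self.bandwidth, self.n_nodes
        i, j = self.pore_i, self.pore_j
        return np.concatenate(
            [
                B * N + i,                  # diagonal, node i
                B * N + j,                  # diagonal, node j
                (B + i - j) * N + j,        # off-diagonal (i, j)
                (B + j - i) * N + i,        # off-diagonal (j, i)
            ]
        )

    # --- incidence ---------------------------------------------------------
    @cached_property
    def incidence(self) -> tuple[np.ndarray, np.ndarray]:
        """COO incidence: (node index, pore index), two entries per pore."""
        inc_node = np.concatenate([self.pore_i, self.pore_j])
        inc_pore = np.concatenate([np.arange(self.n_pores)] * 2)
        return inc_node, inc_pore

    def node_sum(self, pore_values: np.ndarray) -> np.ndarray:
        """Sum a per-pore quantity onto the incident nodes."""
        inc_node, inc_pore = self.incidence
        return np.bincount(
            inc_node, weights=np.asarray(pore_values, dtype=float)[inc_pore],
            minlength=self.n_nodes,
        )

    def with_diameters(self, d: np.ndarray, large: np.ndarray | None) -> "PoreNetwork":
        return replace(self, d=np.asarray(d, dtype=float), large=large)


@dataclass(frozen=True)
class CvGeometry:
    """Per-node control-volume geometry derived from the pore lattice."""

    V_cv: float               # L**3 [m**3]
    A_cv: float               # L**2 [m**2]
    eps: np.ndarray           # (N,) CV porosity, eps = (sum V_ij / 2) / L**3
    void_cv: np.ndarray       # (N,) CV void volume = sum V_ij / 2 [m**3]

    @property
    def total_void(self) -> float:
        return float(self.void_cv.sum())

    def overall_porosity(self, n_nodes: int) -> float:
        """Network porosity: total pore volume over total domain volume."""
        return self.total_void / (n_nodes * self.V_cv)


def _lateral_pairs(n: int) -> np.ndarray:
    """Index pairs along one periodic lateral axis.

    ``n >= 3``: nearest-neighbour pairs plus one wrap pair -> n pores.
    ``n == 2``: the wrap pair duplicates (0, 1) and is silently dropped.
    ``n == 1``: no pores (a wrap edge would be a self-loop).
    """
    if n == 1:
        return np.empty((0, 2), dtype=int)
    if n == 2:
        return np.array([[0, 1]], dtype=int)
    k = np.arange(n)
    return np.stack([k, (k + 1) % n], axis=1)


def build_lattice(spec: LatticeSpec) -> PoreNetwork:
    """Construct the regular bond lattice (topology only, diameters zero).

    Vertical pores join z-adjacent nodes; lateral pores join x/y-adjacent
    nodes including one periodic wrap pore per row/column.  For the 5x5x15
    reference lattice this yields 375 nodes and 1100 pores
    (350 vertical + 375 x-periodic + 375 y-periodic).
    """
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    coords = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    coords = coords[order]

    def node_id(ax, ay, az):
        return ax + nx * (ay + ny * az)

    pi, pj, paxis = [], [], []

    # x pores: one per lateral pair, for every (iy, iz)
    pairs = _lateral_pairs(nx)
    if len(pairs):
        ay, az = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
        for a, b in pairs:
            pi.append(node_id(a, ay.ravel(), az.ravel()))
            pj.append(node_id(b, ay.ravel(), az.ravel()))
            paxis.append(np.zeros(ay.size, dtype=int))
    # y pores
    pairs = _lateral_pairs(ny)
    if len(pairs):
        ax, az = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
        for a, b in pairs:
            pi.append(node_id(ax.ravel(), a, az.ravel()))
            pj.append(node_id(ax.ravel(), b, az.ravel()))
            paxis.append(np.full(ax.size, 1, dtype=int))
    # z pores
    if nz >= 2:
        ax, ay, az = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz - 1), indexing="ij"
        )
        pi.append(node_id(ax.ravel(), ay.ravel(), az.ravel()))
        pj.append(node_id(ax.ravel(), ay.ravel(), az.ravel() + 1))
        paxis.append(np.full(ax.size, 2, dtype=int))

    if pi:
        pore_i = np.concatenate(pi)
        pore_j = np.concatenate(pj)
        pore_axis = np.concatenate(paxis)
    else:
        pore_i = pore_j = np.empty(0, dtype=int)
        pore_axis = np.empty(0, dtype=int)

    if np.any(pore_i == pore_j):  # pragma: no cover - guarded by _lateral_pairs
        raise GeometryError("self-loop pore generated")
    key = np.minimum(pore_i, pore_j) * coords.shape[0] + np.maximum(pore_i, pore_j)
    if len(np.unique(key)) != len(key):  # pragma: no cover
        raise GeometryError("duplicate pore generated")

    return PoreNetwork(
        spec=spec,
        coords=coords,
        pore_i=pore_i,
        pore_j=pore_j,
        pore_axis=pore_axis,
        d=np.zeros(len(pore_i)),
    )


def _core_mask(spec: LatticeSpec, coords: np.ndarray) -> np.ndarray:
    """Nodes inside the central ``center_extent``-square block of columns."""
    x0 = (spec.nx - spec.center_extent) // 2
    y0 = (spec.ny - spec.center_extent) // 2
    return (
        (coords[:, 0] >= x0)
        & (coords[:, 0] < x0 + spec.center_extent)
        & (coords[:, 1] >= y0)
        & (coords[:, 1] < y0 + spec.center_extent)
    )


def _sample_truncated(rng, mean_um, sd_um, size, d_min_um=0.1, max_tries=100):
    """Normal diameters, resampling any draw at or below ``d_min_um``."""
    d = rng.normal(mean_um, sd_um, size)
    for _ in range(max_tries):
        bad = d <= d_min_um
        if not bad.any():
            return d
        d[bad] = rng.normal(mean_um, sd_um, int(bad.sum()))
    raise GeometryError(
        f"could not sample positive diameters from N({mean_um}, {sd_um}) "
        f"after {max_tries} retries"
    )


def assign_diameters(
    net: PoreNetwork, spec: LatticeSpec | None = None, rng=None
) -> PoreNetwork:
    """Sample pore diameters according to the spec's pore-size distribution.

    The bimodal large/small labelling is purely geometric (a pore is large
    iff both of its end nodes lie in the central block), so it is invariant
    to the RNG seed.
    """
    spec = spec or net.spec
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.psd_mode == "monomodal":
        d_um = _sample_truncated(rng, spec.d_mean_large_um, spec.d_sd_um, net.n_pores)
        large = np.ones(net.n_pores, dtype=bool)
    else:
        core = _core_mask(spec, net.coords)
        large = core[net.pore_i] & core[net.pore_j]
        d_um = np.empty(net.n_pores)
        d_um[large] = _sample_truncated(
            rng, spec.d_mean_large_um, spec.d_sd_um, int(large.sum())
        )
        d_um[~large] = _sample_truncated(
            rng, spec.d_mean_small_um, spec.d_sd_um, int((~large).sum())
        )
    return net.with_diameters(d_um * UM, large)


def compute_cv_geometry(net: PoreNetwork) -> CvGeometry:
    """Control-volume porosities: half of every incident pore volume per CV.

    Splitting each pore half/half between its two end CVs makes the sum of
    CV void volumes equal the total pore volume exactly.
    """
    V_cv = net.L**3
    void_cv = 0.5 * net.node_sum(net.V)
    eps = void_cv / V_cv
    if np.any(eps >= 1.0):
        raise GeometryError(
            f"CV porosity >= 1 (max {eps.max():.3f}); pores overfill the control volume"
        )
    return CvGeometry(V_cv=V_cv, A_cv=net.L**2, eps=eps, void_cv=void_cv)
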