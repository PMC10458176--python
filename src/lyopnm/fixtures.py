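"""Deterministic reference networks for tests, examples and benchmarks."""

from __future__ import annotations

from .config import RunConfig
from .network import LatticeSpec, PoreNetwork, assign_diameters, build_lattice

__all__ = ["make_fixture", "FIXTURES"]

#: name -> LatticeSpec factory
FIXTURES = {
    # two nodes joined by one vertical pore, no spread
    "chain2": lambda: LatticeSpec(nx=1, ny=1, nz=2, d_sd_um=0.0, seed=7),
    # a ten-pore vertical chain for solver cross-checks
    "chain10": lambda: LatticeSpec(nx=1, ny=1, nz=11, d_sd_um=0.0, seed=7),
    # a 15-CV dry column for heat-stepper cross-checks
    "column15": lambda: LatticeSpec(nx=1, ny=1, nz=15, d_sd_um=0.0, seed=7),
    # small fast-drying lattices
    "mono_small": lambda: LatticeSpec(nx=3, ny=3, nz=5, seed=11),
    "bi_small": lambda: LatticeSpec(nx=5, ny=5, nz=5, psd_mode="bimodal", seed=11),
    # the reference study geometries (375 nodes / 1100 pores)
    "mono_ref": lambda: LatticeSpec(seed=2131),
    "bi_ref": lambda: LatticeSpec(psd_mode="bimodal", seed=2131),
}


def make_fixture(name: str) -> tuple[PoreNetwork, RunConfig]:
    """Build a named deterministic network plus a matching run config."""
    try:
        spec = FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    net = assign_diameters(build_lattice(spec))
    cfg = RunConfig.model_validate(
        {
            "lattice": {
                k: getattr(spec, k)
                for k in (
                    "nx", "ny", "nz", "L_cv_um", "psd_mode",
                    "d_mean_large_um", "d_mean_small_um", "d_sd_um",
                    "center_extent",
                )
            },
            "seed": spec.seed,
        }
    )
    return net, cfg
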