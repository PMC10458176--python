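"""Serialization: run outputs, network snapshots, legacy-VTK export.

Everything is plain text (CSV / JSON / ASCII VTK) with deterministic
ordering, so re-running with the same configuration and seed reproduces
the files byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import celsius
from .engine import DryingRecord
from .metrics import slice_profiles
from .network import UM, LatticeSpec, PoreNetwork

__all__ = [
    "write_outputs",
    "network_to_json",
    "network_from_json",
    "write_network_vtk",
]

#: fixed column contract of drying_curve.csv
DRYING_CURVE_COLUMNS = [
    "t_s", "S", "rate_kg_s", "MFP_um", "MAP_um", "LAP_um", "width_um", "T_front_C",
]


def write_outputs(
    record: DryingRecord,
    outdir: str | Path,
    config=None,
    vtk: bool = False,
    net: PoreNetwork | None = None,
) -> Path:
    """Write a completed run to ``outdir``.

    Produces ``drying_curve.csv``, per-snapshot ``slices_S*.csv`` (when the
    network is supplied), ``snapshots.json``, ``audit.json`` and the
    resolved provenance (``config.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    df = pd.DataFrame(
        {
            "t_s": record["t"],
            "S": record["S"],
            "rate_kg_s": record["rate"],
            "MFP_um": record["mfp_um"],
            "MAP_um": record["map_um"],
            "LAP_um": record["lap_um"],
            "width_um": record["width_um"],
            "T_front_C": record["T_front"] - 273.15,
        }
    )
    df.to_csv(outdir / "drying_curve.csv", index=False, float_format="%.10g")

    snaps = []
    for snap in record.snapshots:
        snaps.append(
            {
                "t": snap["t"],
                "S": snap["S"],
                "T": np.round(snap["T"], 9).tolist(),
                "P": np.round(snap["P"], 9).tolist(),
                "pore_saturation": np.round(snap["pore_saturation"], 12).tolist(),
            }
        )
        if net is not None:
            prof = slice_profiles(
                net,
                snap["pore_saturation"] * net.V,
                T=snap["T"],
                P=snap["P"],
            )
            prof.to_csv(
                outdir / f"slices_S{snap['S']:.3f}.csv",
                index=False,
                float_format="%.10g",
            )
    (outdir / "snapshots.json").write_text(json.dumps(snaps))
    (outdir / "audit.json").write_text(json.dumps(record.audit, indent=2, sort_keys=True))
    (outdir / "run_summary.json").write_text(
        json.dumps(record_summary(record), indent=2, sort_keys=True)
    )
    provenance = {"meta": _jsonable(record.meta)}
    if config is not None:
        provenance["config"] = config.model_dump()
    (outdir / "config.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# --- network snapshots ------------------------------------------------------

def network_to_json(net: PoreNetwork, path: str | Path) -> None:
    """Write nodes, pores, diameters and labels as JSON (lengths in um)."""
    payload = {
        "spec": net.spec.__dict__ | {},
        "coords": net.coords.tolist(),
        "pore_i": net.pore_i.tolist(),
        "pore_j": net.pore_j.tolist(),
        "pore_axis": net.pore_axis.tolist(),
        "d_um": (net.d / UM).tolist(),
        "large": None if net.large is None else net.large.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def network_from_json(path: str | Path) -> PoreNetwork:
    data = json.loads(Path(path).read_text())
    spec = LatticeSpec(**data["spec"])
    net = PoreNetwork(
        spec=spec,
        coords=np.asarray(data["coords"], dtype=int),
        pore_i=np.asarray(data["pore_i"], dtype=int),
        pore_j=np.asarray(data["pore_j"], dtype=int),
        pore_axis=np.asarray(data["pore_axis"], dtype=int),
        d=np.asarray(data["d_um"], dtype=float) * UM,
        large=None if data["large"] is None else np.asarray(data["large"], dtype=bool),
    )
    return net


def write_network_vtk(
    net: PoreNetwork,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Minimal legacy-VTK (ASCII) unstructured grid of the pore lattice.

    Pores are written as line cells with their diameter (and any extra
    per-pore arrays) as cell data, for inspection in ParaView.
    """
    pos = net.node_pos_um
    lines = [
        "# vtk DataFile Version 3.0",
        "lyopnm pore network",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {net.n_nodes} float",
    ]
    lines += [f"{x:.6g} {y:.6g} {z:.6g}" for x, y, z in pos]
    lines.append(f"CELLS {net.n_pores} {3 * net.n_pores}")
    lines += [f"2 {i} {j}" for i, j in zip(net.pore_i, net.pore_j)]
    lines.append(f"CELL_TYPES {net.n_pores}")
    lines += ["3"] * net.n_pores
    data = {"diameter_um": net.d / UM}
    if net.large is not None:
        data["large"] = net.large.astype(float)
    data.update(cell_data or {})
    lines.append(f"CELL_DATA {net.n_pores}")
    for name, arr in data.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in np.asarray(arr, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def record_summary(record: DryingRecord) -> dict:
    """Headline numbers of a run (times in s, widths in um)."""
    return {
        "drying_time_s": record.drying_time,
        "n_steps": int(record.audit["n_steps"]),
        "max_front_width_um": record.max_front_width(),
        "final_T_front_C": celsius(float(record["T_front"][-1])),
        "mass_closure": record.audit["mass_closure"],
        "energy_closure": record.audit["energy_closure"],
    }
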