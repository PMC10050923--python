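"""File export: VTK legacy unstructured grids and PLY surface pairs."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import BillSpec, TetMesh, bill_surfaces

__all__ = ["write_vtk", "export_surface_pair"]


def write_vtk(
    mesh: TetMesh,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a Tet4 mesh as a VTK legacy ASCII unstructured grid.

    The material id is always emitted as cell data; extra nodal scalars
    (e.g. von Mises stress for heat maps) go in ``point_data``.
    """
    path = Path(path)
    cell_data = {"material_id": mesh.material_id, **(cell_data or {})}
    lines = [
        "# vtk DataFile Version 3.0",
        f"billmech mesh ({mesh.provenance})",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in row) for row in mesh.nodes]
    lines.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    lines += ["4 " + " ".join(str(i) for i in tet) for tet in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines += ["10"] * mesh.n_tets  # VTK_TETRA

    lines.append(f"CELL_DATA {mesh.n_tets}")
    for name, values in cell_data.items():
        values = np.asarray(values)
        kind = "int" if np.issubdtype(values.dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        fmt = (lambda v: str(int(v))) if kind == "int" else (lambda v: f"{v:.9g}")
        lines += [fmt(v) for v in values]

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in np.asarray(values, dtype=float)]

    path.write_text("\n".join(lines) + "\n")


def export_surface_pair(spec: BillSpec, rham_path, bone_path,
                        n_axial: int = 32, n_circumferential: int = 32) -> None:
    """Export the rhamphotheca and bone-core surfaces of a parametric bill as ASCII PLY."""
    rham, bone = bill_surfaces(spec, n_axial, n_circumferential)
    for m, p in ((rham, rham_path), (bone, bone_path)):
        Path(p).write_bytes(m.export(file_type="ply", encoding="ascii"))
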