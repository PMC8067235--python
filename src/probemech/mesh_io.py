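"""Mesh and field export: ASCII VTU (VTK unstructured grid) and Gmsh MSH 2.2.

Minimal writers sufficient for visualizing the two-body hexahedral meshes
and nodal/element fields produced by the solver.
"""

from __future__ import annotations

import numpy as np

from .geometry import Mesh

__all__ = ["write_vtu", "write_msh"]

_VTK_HEX = 12


def _fmt(arr):
    return " ".join(repr(float(x)) for x in np.asarray(arr).ravel())


def write_vtu(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh with optional nodal / element scalar or vector fields."""
    n, e = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{e}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(map(str, mesh.hexes.ravel())),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(8 * (i + 1)) for i in range(e)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join([str(_VTK_HEX)] * e),
        "</DataArray>",
        "</Cells>",
    ]
    lines.append("<PointData>")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        comp = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{comp}" format="ascii">',
            _fmt(np.nan_to_num(arr)),
            "</DataArray>",
        ]
    lines.append("</PointData>")
    lines.append("<CellData>")
    cd = dict(cell_data or {})
    cd.setdefault("region", mesh.region.astype(float))
    for name, arr in cd.items():
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            'NumberOfComponents="1" format="ascii">',
            _fmt(arr),
            "</DataArray>",
        ]
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_msh(path, mesh: Mesh) -> None:
    """Write Gmsh MSH 2.2 ASCII with region ids as physical tags."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x!r} {y!r} {z!r}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for i, (conn, reg) in enumerate(zip(mesh.hexes, mesh.region), start=1):
            nodes = " ".join(str(c + 1) for c in conn)
            fh.write(f"{i} 5 2 {int(reg)} {int(reg)} {nodes}\n")
        fh.write("$EndElements\n")
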