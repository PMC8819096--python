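"""Mesh and result file I/O.

Volume meshes and fields are written as ASCII VTU (XML unstructured grid)
and legacy ASCII VTK, both readable by ParaView; surfaces go through
trimesh (STL/PLY).  Floats are printed with 17 significant digits so a
write/read round trip reproduces arrays bit-exactly.  A solver-deck export
mirroring the layout of biomechanics FE input files (geometry, materials,
springs, boundary sections in one XML document) is provided for
interoperability.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .mesh import VolumeMesh

_F = "%.17g"


def _fmt_floats(arr: np.ndarray, per_line: int) -> str:
    flat = np.asarray(arr, dtype=float).reshape(-1)
    lines = []
    for i in range(0, len(flat), per_line):
        lines.append(" ".join(_F % v for v in flat[i:i + per_line]))
    return "\n".join(lines)


def _fmt_ints(arr: np.ndarray, per_line: int) -> str:
    flat = np.asarray(arr).reshape(-1)
    lines = []
    for i in range(0, len(flat), per_line):
        lines.append(" ".join(str(int(v)) for v in flat[i:i + per_line]))
    return "\n".join(lines)


# --------------------------------------------------------------------------
# VTU (XML)
# --------------------------------------------------------------------------

def write_vtu(path, mesh: VolumeMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """ASCII .vtu with part/region ids always included as cell data."""
    n, m = len(mesh.nodes), len(mesh.tets)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("part_id", mesh.part_ids)
    cell_data.setdefault("region_id", mesh.region_ids)

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n),
                          NumberOfCells=str(m))

    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = _fmt_floats(mesh.nodes, 3)

    cells = ET.SubElement(piece, "Cells")
    con = ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity",
                        format="ascii")
    con.text = _fmt_ints(mesh.tets, 4)
    off = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                        format="ascii")
    off.text = _fmt_ints(4 * np.arange(1, m + 1), 8)
    typ = ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                        format="ascii")
    typ.text = _fmt_ints(np.full(m, 10), 16)   # VTK_TETRA

    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            comp = 1 if arr.ndim == 1 else arr.shape[1]
            e = ET.SubElement(pd, "DataArray", type="Float64", Name=name,
                              NumberOfComponents=str(comp), format="ascii")
            e.text = _fmt_floats(arr, comp)
    cd = ET.SubElement(piece, "CellData")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        comp = 1 if arr.ndim == 1 else arr.shape[1]
        kind = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        e = ET.SubElement(cd, "DataArray", type=kind, Name=name,
                          NumberOfComponents=str(comp), format="ascii")
        e.text = (_fmt_ints(arr, comp) if kind == "Int64"
                  else _fmt_floats(arr, comp))

    # part/region names are not representable as VTK arrays; keep them in a
    # leading comment so a read round trip can restore the labels
    names = ("carpalfem:parts=" + ",".join(mesh.part_names)
             + ";regions=" + ",".join(mesh.region_names))
    text = ET.tostring(root, encoding="unicode")
    with open(path, "w") as fh:
        fh.write(f"<?xml version=\"1.0\"?>\n<!--{names}-->\n{text}\n")


def read_vtu(path):
    """Read an ASCII .vtu written by :func:`write_vtu`.

    Returns (VolumeMesh, point_data, cell_data).
    """
    with open(path) as fh:
        content = fh.read()
    part_names, region_names = ["part"], ["part"]
    if "carpalfem:parts=" in content:
        tag = content.split("carpalfem:parts=")[1].split("-->")[0]
        part_names = tag.split(";regions=")[0].split(",")
        region_names = tag.split(";regions=")[1].split(",")
    root = ET.fromstring(content[content.index("<VTKFile"):])
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    nodes = np.fromstring(pts.text, sep=" ").reshape(-1, 3)

    def _cell_array(name):
        for da in piece.find("Cells"):
            if da.get("Name") == name:
                return np.fromstring(da.text, sep=" ").astype(int)
        raise KeyError(name)

    tets = _cell_array("connectivity").reshape(-1, 4)
    point_data, cell_data = {}, {}
    pd = piece.find("PointData")
    if pd is not None:
        for da in pd:
            comp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            point_data[da.get("Name")] = (arr if comp == 1
                                          else arr.reshape(-1, comp))
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd:
            comp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            if da.get("type") == "Int64":
                arr = arr.astype(int)
            cell_data[da.get("Name")] = (arr if comp == 1
                                         else arr.reshape(-1, comp))
    part_ids = cell_data.pop("part_id", np.zeros(len(tets), dtype=int))
    region_ids = cell_data.pop("region_id", np.zeros(len(tets), dtype=int))
    mesh = VolumeMesh(nodes, tets, part_names, part_ids,
                      region_names, region_ids)
    return mesh, point_data, cell_data


# --------------------------------------------------------------------------
# legacy VTK
# --------------------------------------------------------------------------

def write_vtk_legacy(path, mesh: VolumeMesh,
                     cell_data: dict[str, np.ndarray] | None = None) -> None:
    n, m = len(mesh.nodes), len(mesh.tets)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("carpalfem parts=" + ",".join(mesh.part_names)
                 + " regions=" + ",".join(mesh.region_names) + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        fh.write(_fmt_floats(mesh.nodes, 3) + "\n")
        fh.write(f"CELLS {m} {5 * m}\n")
        cells = np.column_stack([np.full(m, 4), mesh.tets])
        fh.write(_fmt_ints(cells, 5) + "\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write(_fmt_ints(np.full(m, 10), 16) + "\n")
        fh.write(f"CELL_DATA {m}\n")
        data = {"part_id": mesh.part_ids, "region_id": mesh.region_ids}
        data.update(cell_data or {})
        for name, arr in data.items():
            arr = np.asarray(arr)
            if np.issubdtype(arr.dtype, np.integer):
                fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                fh.write(_fmt_ints(arr, 16) + "\n")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write(_fmt_floats(arr, 8) + "\n")


def read_vtk_legacy(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = lines[1]
    part_names = region_names = ["part"]
    if "parts=" in header:
        part_names = header.split("parts=")[1].split(" ")[0].split(",")
        region_names = header.split("regions=")[1].split(",")
    i = lines.index(next(ln for ln in lines if ln.startswith("POINTS")))
    n = int(lines[i].split()[1])
    vals, j = [], i + 1
    while len(vals) < 3 * n:
        vals += lines[j].split()
        j += 1
    nodes = np.array(vals, dtype=float).reshape(-1, 3)
    while not lines[j].startswith("CELLS"):
        j += 1
    m = int(lines[j].split()[1])
    vals, j = [], j + 1
    while len(vals) < 5 * m:
        vals += lines[j].split()
        j += 1
    tets = np.array(vals, dtype=int).reshape(-1, 5)[:, 1:]
    cell_data = {}
    while j < len(lines):
        if lines[j].startswith("SCALARS"):
            name, kind = lines[j].split()[1:3]
            vals, j2 = [], j + 2
            while j2 < len(lines) and len(vals) < m:
                vals += lines[j2].split()
                j2 += 1
            arr = np.array(vals[:m],
                           dtype=int if kind == "int" else float)
            cell_data[name] = arr
            j = j2
        else:
            j += 1
    part_ids = cell_data.pop("part_id", np.zeros(m, dtype=int))
    region_ids = cell_data.pop("region_id", np.zeros(m, dtype=int))
    mesh = VolumeMesh(nodes, tets, part_names, part_ids,
                      region_names, region_ids)
    return mesh, cell_data


# --------------------------------------------------------------------------
# result series + solver deck
# --------------------------------------------------------------------------

def write_result_series(out_dir, result, basename: str = "step") -> list[str]:
    """One .vtu per converged step (displacement, stress, pressure) plus a
    .pvd collection file; returns the paths written."""
    import os

    from .postprocess import MPA_TO_PA, element_pressure
    os.makedirs(out_dir, exist_ok=True)
    written = []
    entries = []
    for k in range(result.n_steps):
        sig = result.stresses[k]
        voigt = np.column_stack([sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2],
                                 sig[:, 0, 1], sig[:, 1, 2], sig[:, 0, 2]])
        path = os.path.join(out_dir, f"{basename}_{k:03d}.vtu")
        write_vtu(path, result.mesh,
                  point_data={"displacement_mm": result.displacements[k]},
                  cell_data={"stress_voigt_MPa": voigt,
                             "pressure_Pa":
                             element_pressure(sig) * MPA_TO_PA})
        written.append(path)
        entries.append((float(result.ramp[k]), os.path.basename(path)))
    pvd = os.path.join(out_dir, f"{basename}.pvd")
    with open(pvd, "w") as fh:
        fh.write('<?xml version="1.0"?>\n<VTKFile type="Collection" '
                 'version="0.1">\n<Collection>\n')
        for t, name in entries:
            fh.write(f'<DataSet timestep="{t:g}" file="{name}"/>\n')
        fh.write("</Collection>\n</VTKFile>\n")
    written.append(pvd)
    return written


def write_solver_deck(path, case) -> None:
    """Solver-ready XML deck: nodes, elements, materials, springs, BCs."""
    from .materials import LinearElasticParams

    mesh = case.mesh
    root = ET.Element("fem_model", units="mm-N-MPa")
    mats = ET.SubElement(root, "Materials")
    for rname in mesh.region_names:
        p = case.materials[rname]
        if isinstance(p, LinearElasticParams):
            ET.SubElement(mats, "material", name=rname,
                          type="isotropic elastic", E=_F % p.E, v=_F % p.nu)
        else:
            ET.SubElement(mats, "material", name=rname,
                          type="Mooney-Rivlin", c1=_F % p.C1, c2=_F % p.C2,
                          k=_F % p.K)
    geo = ET.SubElement(root, "Geometry")
    nodes_el = ET.SubElement(geo, "Nodes")
    for i, xyz in enumerate(mesh.nodes, start=1):
        ET.SubElement(nodes_el, "node", id=str(i)).text = \
            ",".join(_F % v for v in xyz)
    for rid, rname in enumerate(mesh.region_names):
        idx = np.flatnonzero(mesh.region_ids == rid)
        if not len(idx):
            continue
        el = ET.SubElement(geo, "Elements", type="tet4", mat=rname)
        for e in idx:
            ET.SubElement(el, "elem", id=str(int(e) + 1)).text = \
                ",".join(str(int(v) + 1) for v in mesh.tets[e])
    if case.springs is not None:
        spr = ET.SubElement(root, "Springs")
        for s in case.springs.elements:
            ET.SubElement(spr, "spring", name=s.name, E=_F % s.k,
                          L0=_F % s.rest_length).text = \
                f"{s.node_a + 1},{s.node_b + 1}"
    bnd = ET.SubElement(root, "Boundary")
    fix = ET.SubElement(bnd, "fix", bc="xyz")
    fix.text = ",".join(str(int(i) + 1) for i in case.bcs.fixed_nodes)
    pres = ET.SubElement(bnd, "prescribe",
                         displacement=",".join(
                             _F % v for v in case.bcs.target_displacement))
    pres.text = ",".join(str(int(i) + 1) for i in case.bcs.prescribed_nodes)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
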