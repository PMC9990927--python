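"""Mesh and field I/O in standard ASCII formats.

Readers and writers for tetrahedral volume meshes in Gmsh ``.msh`` (ASCII
2.2 and 4.1), VTK XML unstructured grids ``.vtu`` (ASCII), and XDMF
``.xdmf`` (inline XML data or HDF5 heavy data via h5py).  Field output for
time series uses ``.vtu`` snapshots with point data plus a ``.pvd``
collection file, readable by ParaView.

Coordinates are assumed to be millimetres.  Only tetrahedral volume cells
are retained; lower-dimensional elements (boundary triangles, lines) in the
input are skipped because the boundary is recovered from the cell
connectivity.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import Mesh

__all__ = ["read_mesh", "write_mesh", "write_vtu", "PvdWriter"]

_FORMATS = ("gmsh", "vtu", "xdmf")
_SUFFIX_FORMAT = {".msh": "gmsh", ".vtu": "vtu", ".xdmf": "xdmf",
                  ".xmf": "xdmf"}


class MeshIOError(IOError):
    """The mesh file cannot be parsed."""


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise MeshIOError(f"unknown mesh format {fmt!r}; expected one of "
                              f"{_FORMATS} or 'auto'")
        return fmt
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise MeshIOError(f"cannot infer mesh format from suffix "
                          f"{path.suffix!r}; pass format= explicitly") from None


def read_mesh(path, format: str = "auto") -> Mesh:
    """Read and validate a tetrahedral mesh (Gmsh, VTU or XDMF)."""
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"mesh file {path} does not exist")
    fmt = _detect_format(path, format)
    reader = {"gmsh": _read_gmsh, "vtu": _read_vtu, "xdmf": _read_xdmf}[fmt]
    vertices, cells = reader(path)
    if len(cells) == 0:
        raise MeshIOError(f"{path}: no tetrahedral cells found")
    mesh = Mesh(np.asarray(vertices, dtype=float),
                np.asarray(cells, dtype=np.int64))
    return mesh.validate()


def write_mesh(mesh: Mesh, path, format: str = "auto") -> Path:
    """Write a mesh in the format implied by the suffix (or ``format``)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    writer = {"gmsh": _write_gmsh, "vtu": _write_vtu_mesh,
              "xdmf": _write_xdmf}[fmt]
    writer(mesh, path)
    return path


# ---------------------------------------------------------------------------
# Gmsh ASCII
# ---------------------------------------------------------------------------

def _gmsh_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("$End"):
            current = None
        elif line.startswith("$"):
            current = line[1:]
            sections[current] = []
        elif current is not None and line:
            sections[current].append(line)
    return sections


def _read_gmsh(path: Path):
    sections = _gmsh_sections(path.read_text())
    if "MeshFormat" not in sections:
        raise MeshIOError(f"{path}: missing $MeshFormat section")
    header = sections["MeshFormat"][0].split()
    version = float(header[0])
    if int(header[1]) != 0:
        raise MeshIOError(f"{path}: binary Gmsh files are not supported")
    if version >= 4.0:
        return _read_gmsh41(path, sections)
    return _read_gmsh22(path, sections)


def _read_gmsh22(path: Path, sections):
    try:
        node_lines = sections["Nodes"]
        elem_lines = sections["Elements"]
    except KeyError as err:
        raise MeshIOError(f"{path}: missing ${err.args[0]} section") from None
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 3))
    for k, line in enumerate(node_lines[1:1 + n_nodes]):
        parts = line.split()
        ids[k] = int(parts[0])
        coords[k] = [float(v) for v in parts[1:4]]
    renumber = {int(i): k for k, i in enumerate(ids)}

    cells = []
    for line in elem_lines[1:]:
        parts = line.split()
        etype = int(parts[1])
        if etype != 4:          # keep linear tetrahedra only
            continue
        ntags = int(parts[2])
        conn = [renumber[int(v)] for v in parts[3 + ntags:7 + ntags]]
        cells.append(conn)
    return coords, cells


def _read_gmsh41(path: Path, sections):
    try:
        node_lines = sections["Nodes"]
        elem_lines = sections["Elements"]
    except KeyError as err:
        raise MeshIOError(f"{path}: missing ${err.args[0]} section") from None

    n_blocks, n_nodes = (int(v) for v in node_lines[0].split()[:2])
    ids: list[int] = []
    coords: list[list[float]] = []
    pos = 1
    for _ in range(n_blocks):
        block_n = int(node_lines[pos].split()[3])
        pos += 1
        ids += [int(node_lines[pos + k]) for k in range(block_n)]
        pos += block_n
        coords += [[float(v) for v in node_lines[pos + k].split()[:3]]
                   for k in range(block_n)]
        pos += block_n
    if len(ids) != n_nodes:
        raise MeshIOError(f"{path}: $Nodes section is inconsistent")
    renumber = {i: k for k, i in enumerate(ids)}

    cells = []
    n_blocks = int(elem_lines[0].split()[0])
    pos = 1
    for _ in range(n_blocks):
        _, _, etype, block_n = (int(v) for v in elem_lines[pos].split())
        pos += 1
        if etype == 4:
            for k in range(block_n):
                conn = [renumber[int(v)]
                        for v in elem_lines[pos + k].split()[1:5]]
                cells.append(conn)
        pos += block_n
    return np.asarray(coords), cells


def _write_gmsh(mesh: Mesh, path: Path) -> None:
    buf = io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    buf.write(f"$Nodes\n{mesh.n_vertices}\n")
    for k, (x, y, z) in enumerate(mesh.vertices, start=1):
        buf.write(f"{k} {x:.17g} {y:.17g} {z:.17g}\n")
    buf.write("$EndNodes\n")
    buf.write(f"$Elements\n{mesh.n_cells}\n")
    for k, cell in enumerate(mesh.cells, start=1):
        a, b, c, d = (int(v) + 1 for v in cell)
        buf.write(f"{k} 4 2 0 1 {a} {b} {c} {d}\n")
    buf.write("$EndElements\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# VTK XML (.vtu), ASCII
# ---------------------------------------------------------------------------

def _da_text(values, per_line: int = 6) -> str:
    flat = np.asarray(values).ravel()
    lines = []
    for k in range(0, flat.size, per_line):
        lines.append(" ".join(f"{v:.17g}" for v in flat[k:k + per_line]))
    return "\n".join(lines)


def _read_vtu(path: Path):
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshIOError(f"{path}: no <Piece> element")

    def data_array(parent, name):
        for da in parent.findall("DataArray"):
            if da.get("Name") == name:
                if da.get("format", "ascii") != "ascii":
                    raise MeshIOError(f"{path}: only ascii .vtu is supported")
                return np.array(da.text.split(), dtype=float)
        raise MeshIOError(f"{path}: missing DataArray {name!r}")

    points = data_array(piece.find("Points"), "Points").reshape(-1, 3)
    cells_el = piece.find("Cells")
    conn = data_array(cells_el, "connectivity").astype(np.int64)
    offsets = data_array(cells_el, "offsets").astype(np.int64)
    types = data_array(cells_el, "types").astype(np.int64)

    cells = []
    start = 0
    for off, ctype in zip(offsets, types):
        if ctype == 10:          # VTK_TETRA
            cells.append(conn[start:off])
        start = off
    return points, cells


def _vtu_document(mesh: Mesh, point_data: dict[str, np.ndarray] | None = None
                  ) -> ET.ElementTree:
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece",
                          NumberOfPoints=str(mesh.n_vertices),
                          NumberOfCells=str(mesh.n_cells))
    points = ET.SubElement(piece, "Points")
    ET.SubElement(points, "DataArray", type="Float64", Name="Points",
                  NumberOfComponents="3", format="ascii"
                  ).text = _da_text(mesh.vertices)
    cells = ET.SubElement(piece, "Cells")
    ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity",
                  format="ascii").text = _da_text(mesh.cells)
    ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                  format="ascii").text = _da_text(
                      4 * np.arange(1, mesh.n_cells + 1))
    ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                  format="ascii").text = _da_text(
                      np.full(mesh.n_cells, 10))
    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, values in point_data.items():
            values = np.asarray(values)
            ncomp = 1 if values.ndim == 1 else values.shape[1]
            ET.SubElement(pd, "DataArray", type="Float64", Name=name,
                          NumberOfComponents=str(ncomp), format="ascii"
                          ).text = _da_text(values)
    return ET.ElementTree(root)


def _write_vtu_mesh(mesh: Mesh, path: Path) -> None:
    _vtu_document(mesh).write(path, xml_declaration=True)


def write_vtu(mesh: Mesh, path, point_data: dict[str, np.ndarray]) -> Path:
    """Write one .vtu snapshot with named nodal fields."""
    path = Path(path)
    for name, values in point_data.items():
        if np.asarray(values).shape[0] != mesh.n_vertices:
            raise MeshIOError(f"point data {name!r} has wrong length")
    _vtu_document(mesh, point_data).write(path, xml_declaration=True)
    return path


class PvdWriter:
    """ParaView .pvd collection of time-stamped .vtu snapshots."""

    def __init__(self, directory, basename: str = "fields"):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.basename = basename
        self.entries: list[tuple[float, str]] = []

    def add(self, mesh: Mesh, time: float,
            point_data: dict[str, np.ndarray]) -> Path:
        fname = f"{self.basename}_{len(self.entries):04d}.vtu"
        write_vtu(mesh, self.directory / fname, point_data)
        self.entries.append((time, fname))
        return self.directory / fname

    def close(self) -> Path:
        root = ET.Element("VTKFile", type="Collection", version="0.1")
        coll = ET.SubElement(root, "Collection")
        for time, fname in self.entries:
            ET.SubElement(coll, "DataSet", timestep=f"{time:g}", part="0",
                          file=fname)
        out = self.directory / f"{self.basename}.pvd"
        ET.ElementTree(root).write(out, xml_declaration=True)
        return out


# ---------------------------------------------------------------------------
# XDMF
# ---------------------------------------------------------------------------

def _read_xdmf(path: Path):
    root = ET.parse(path).getroot()
    grid = root.find(".//Grid")
    if grid is None:
        raise MeshIOError(f"{path}: no <Grid> element")
    topo = grid.find("Topology")
    geom = grid.find("Geometry")
    if topo is None or geom is None:
        raise MeshIOError(f"{path}: missing Topology/Geometry")
    ttype = (topo.get("TopologyType") or topo.get("Type") or "").lower()
    if ttype != "tetrahedron":
        raise MeshIOError(f"{path}: unsupported topology {ttype!r} "
                          "(expected Tetrahedron)")

    def load(item: ET.Element) -> np.ndarray:
        fmt = (item.get("Format") or "XML").upper()
        if fmt == "XML":
            return np.array(item.text.split(), dtype=float)
        if fmt == "HDF":
            import h5py
            ref = item.text.strip()
            fname, _, dset = ref.partition(":")
            with h5py.File(path.parent / fname, "r") as h5:
                return np.asarray(h5[dset]).ravel()
        raise MeshIOError(f"{path}: unsupported XDMF data format {fmt!r}")

    cells = load(topo.find("DataItem")).astype(np.int64).reshape(-1, 4)
    points = load(geom.find("DataItem")).reshape(-1, 3)
    return points, list(cells)


def _write_xdmf(mesh: Mesh, path: Path) -> None:
    root = ET.Element("Xdmf", Version="3.0")
    domain = ET.SubElement(root, "Domain")
    grid = ET.SubElement(domain, "Grid", Name="mesh", GridType="Uniform")
    topo = ET.SubElement(grid, "Topology", TopologyType="Tetrahedron",
                         NumberOfElements=str(mesh.n_cells))
    ET.SubElement(topo, "DataItem",
                  Dimensions=f"{mesh.n_cells} 4", NumberType="Int",
                  Format="XML").text = _da_text(mesh.cells)
    geom = ET.SubElement(grid, "Geometry", GeometryType="XYZ")
    ET.SubElement(geom, "DataItem",
                  Dimensions=f"{mesh.n_vertices} 3", NumberType="Float",
                  Format="XML").text = _da_text(mesh.vertices)
    ET.ElementTree(root).write(path, xml_declaration=True)
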