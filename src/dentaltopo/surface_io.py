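"""Surface ingestion and tooth-row height-map construction.

Tooth-row scans arrive as triangle meshes (PLY), raw point clouds (XYZ
text) or already-gridded elevation fields (Surfer DSAA ASCII grids).
Everything downstream of this module works on a :class:`HeightMap` -- a
regular elevation raster whose row axis runs mesiodistally (the axis
along which the teeth succeed one another) and whose column axis runs
buccolingually.  All distances are millimetres and the occlusal plane is
assumed pre-aligned with the xy plane, z pointing occlusally.

The one scientifically load-bearing operation here is
:func:`standardize_tooth_row`: every tooth row is resampled to a fixed
number of data rows per tooth (default 50) so that rows of different
tooth counts are compared at equal per-tooth sampling density.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import binned_statistic_2d
from skimage.measure import label as _cc_label

__all__ = [
    "SurfaceFormatError",
    "GeometryError",
    "SurfaceMesh",
    "PointCloud",
    "HeightMap",
    "ToothRowGrid",
    "read_ply",
    "write_ply",
    "read_xyz",
    "write_xyz",
    "read_surfer_grid",
    "write_surfer_grid",
    "grid_point_cloud",
    "standardize_tooth_row",
    "SURFER_BLANK",
]

#: Surfer's conventional blank (no data) sentinel.
SURFER_BLANK = 1.70141e38


class SurfaceFormatError(ValueError):
    """A surface file violates its format contract."""


class GeometryError(ValueError):
    """Input geometry is degenerate for the requested operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm.  ``faces`` indexes ``vertices``."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3 or len(self.vertices) < 3:
            raise SurfaceFormatError("mesh needs >= 3 vertices with xyz coordinates")
        if not np.isfinite(self.vertices).all():
            raise SurfaceFormatError("mesh has non-finite vertex coordinates")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            bad = int(self.faces.max())
            raise SurfaceFormatError(
                f"face vertex index {bad} out of range for {len(self.vertices)} vertices"
            )


@dataclass
class PointCloud:
    """Unordered 3D points in mm."""

    points: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise SurfaceFormatError("point cloud is empty")
        if not np.isfinite(self.points).all():
            raise SurfaceFormatError("point cloud has non-finite coordinates")


@dataclass
class HeightMap:
    """Regular elevation grid.

    Row axis = mesiodistal, column axis = buccolingual.  ``mask`` is True
    where the cell holds a valid elevation; masked cells carry no
    elevation semantics.
    """

    values: np.ndarray  # (rows, cols) float, mm
    spacing_row: float
    spacing_col: float
    mask: np.ndarray | None = None  # True = valid
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("height map must be a 2D grid")
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise GeometryError("grid spacing must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise GeometryError("mask shape must match values shape")
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class ToothRowGrid:
    """A height map standardized to a fixed number of rows per tooth."""

    heightmap: HeightMap
    n_teeth: int
    rows_per_tooth: int = 50

    def __post_init__(self) -> None:
        if self.n_teeth < 1:
            raise ValueError("n_teeth must be >= 1")
        expected = self.n_teeth * self.rows_per_tooth
        if self.heightmap.shape[0] != expected:
            raise ValueError(
                f"height map has {self.heightmap.shape[0]} rows, expected "
                f"{expected} (= {self.n_teeth} teeth x {self.rows_per_tooth} rows)"
            )


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_ply_header(lines: list[bytes]):
    """Parse header lines (without terminators); raise naming the bad line."""
    if not lines or lines[0].strip() != b"ply":
        raise SurfaceFormatError("not a PLY file: missing 'ply' magic on line 1")
    fmt = None
    elements = []  # (name, count, [(prop_name, dtype, is_list, count_dtype)])
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        tok = line.split()
        if tok[0] == "format":
            if len(tok) != 3 or tok[1] not in ("ascii", "binary_little_endian") or tok[2] != "1.0":
                raise SurfaceFormatError(f"unsupported PLY format on line {lineno}: '{line}'")
            fmt = tok[1]
        elif tok[0] == "element":
            if len(tok) != 3 or not tok[2].isdigit():
                raise SurfaceFormatError(f"malformed element declaration on line {lineno}: '{line}'")
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise SurfaceFormatError(f"property before any element on line {lineno}: '{line}'")
            if tok[1] == "list":
                if len(tok) != 5 or tok[2] not in _PLY_DTYPES or tok[3] not in _PLY_DTYPES:
                    raise SurfaceFormatError(f"malformed list property on line {lineno}: '{line}'")
                elements[-1][2].append((tok[4], _PLY_DTYPES[tok[3]], True, _PLY_DTYPES[tok[2]]))
            else:
                if len(tok) != 3 or tok[1] not in _PLY_DTYPES:
                    raise SurfaceFormatError(f"malformed property on line {lineno}: '{line}'")
                elements[-1][2].append((tok[2], _PLY_DTYPES[tok[1]], False, None))
        elif tok[0] == "end_header":
            break
        else:
            raise SurfaceFormatError(f"unrecognized PLY header keyword on line {lineno}: '{line}'")
    else:
        raise SurfaceFormatError("PLY header has no 'end_header' line")
    if fmt is None:
        raise SurfaceFormatError("PLY header has no 'format' line")
    return fmt, elements


def _triangulate(polys: list[list[int]]) -> np.ndarray:
    tris = []
    warned = False
    for poly in polys:
        if len(poly) < 3:
            raise SurfaceFormatError(f"face with {len(poly)} vertices cannot be triangulated")
        if len(poly) > 3 and not warned:
            warnings.warn("non-triangular PLY faces triangulated as fans", stacklevel=3)
            warned = True
        for k in range(1, len(poly) - 1):
            tris.append((poly[0], poly[k], poly[k + 1]))
    return np.asarray(tris, dtype=np.int64).reshape(-1, 3)


def read_ply(path) -> SurfaceMesh:
    """Read an ascii or binary_little_endian 1.0 PLY triangle mesh.

    Non-triangular faces are fan-triangulated with a warning; face
    indices are validated against the vertex count.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    # split the header off: find end_header terminator
    end = blob.find(b"end_header")
    if end < 0:
        raise SurfaceFormatError("PLY header has no 'end_header' line")
    nl = blob.find(b"\n", end)
    header_bytes, body = blob[: nl + 1], blob[nl + 1:]
    fmt, elements = _parse_ply_header(header_bytes.splitlines())

    verts = None
    polys: list[list[int]] = []
    if fmt == "ascii":
        tokens = body.decode("ascii", errors="replace").split("\n")
        tokens = [t.split() for t in tokens if t.strip()]
        pos = 0
        for name, count, props in elements:
            rows = tokens[pos: pos + count]
            if len(rows) < count:
                raise SurfaceFormatError(f"element '{name}' declares {count} rows, found {len(rows)}")
            pos += count
            if name == "vertex":
                cols = {p[0]: i for i, p in enumerate(props)}
                for ax in ("x", "y", "z"):
                    if ax not in cols:
                        raise SurfaceFormatError(f"vertex element lacks property '{ax}'")
                try:
                    arr = np.array([[float(v) for v in r] for r in rows])
                except ValueError as e:
                    raise SurfaceFormatError(f"non-numeric vertex data: {e}") from None
                verts = arr[:, [cols["x"], cols["y"], cols["z"]]]
            elif name == "face":
                for r in rows:
                    n = int(r[0])
                    if len(r) != n + 1:
                        raise SurfaceFormatError(f"face row '{' '.join(r)}' length mismatch")
                    polys.append([int(v) for v in r[1: n + 1]])
    else:  # binary_little_endian
        off = 0
        for name, count, props in elements:
            if any(p[2] for p in props):  # has a list property -> per-row parse
                for _ in range(count):
                    row_lists = []
                    for pname, pdt, is_list, cdt in props:
                        if is_list:
                            (n,) = struct.unpack_from("<" + np.dtype(cdt).char, body, off)
                            off += np.dtype(cdt).itemsize
                            vals = np.frombuffer(body, dtype="<" + pdt, count=int(n), offset=off)
                            off += int(n) * np.dtype(pdt).itemsize
                            row_lists.append(vals)
                        else:
                            off += np.dtype(pdt).itemsize
                    if name == "face" and row_lists:
                        polys.append([int(v) for v in row_lists[0]])
            else:
                dt = np.dtype([(p[0], "<" + p[1]) for p in props])
                arr = np.frombuffer(body, dtype=dt, count=count, offset=off)
                off += count * dt.itemsize
                if name == "vertex":
                    for ax in ("x", "y", "z"):
                        if ax not in dt.names:
                            raise SurfaceFormatError(f"vertex element lacks property '{ax}'")
                    verts = np.column_stack([arr["x"], arr["y"], arr["z"]]).astype(float)
    if verts is None:
        raise SurfaceFormatError("PLY file has no vertex element")
    faces = _triangulate(polys) if polys else np.empty((0, 3), dtype=np.int64)
    return SurfaceMesh(vertices=verts, faces=faces, provenance=f"{path}:ply/{fmt}")


def write_ply(mesh: SurfaceMesh, path, binary: bool = False) -> None:
    """Write a triangle mesh as PLY 1.0 (ascii by default)."""
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {len(mesh.vertices)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(mesh.faces)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            for f in mesh.faces:
                fh.write(struct.pack("<B3i", 3, *map(int, f)))
        else:
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n".encode("ascii"))
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


# ---------------------------------------------------------------------------
# XYZ point clouds
# ---------------------------------------------------------------------------


def read_xyz(path) -> PointCloud:
    """Read whitespace- or comma-delimited xyz triples; '#' comments allowed."""
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            fields = body.replace(",", " ").split()
            if len(fields) != 3:
                raise SurfaceFormatError(
                    f"line {lineno}: expected 3 numeric fields, got {len(fields)}"
                )
            try:
                pts.append([float(v) for v in fields])
            except ValueError:
                raise SurfaceFormatError(f"line {lineno}: non-numeric field") from None
    if not pts:
        raise SurfaceFormatError("no points found in XYZ file")
    return PointCloud(points=np.asarray(pts))


def write_xyz(cloud: PointCloud, path) -> None:
    np.savetxt(path, cloud.points, fmt="%.17g")


# ---------------------------------------------------------------------------
# Surfer DSAA ASCII grids
# ---------------------------------------------------------------------------


def read_surfer_grid(path) -> HeightMap:
    """Read a Surfer ASCII grid (DSAA dialect).

    Cells >= the Surfer blank sentinel (1.70141e38) are masked.  Row 0 of
    the returned map is the ymin row, matching the file order.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens or tokens[0] != "DSAA":
        raise SurfaceFormatError("missing DSAA magic: not a Surfer ASCII grid")
    try:
        ncol, nrow = int(tokens[1]), int(tokens[2])
        xmin, xmax, ymin, ymax, _zmin, _zmax = (float(t) for t in tokens[3:9])
        data = np.array([float(t) for t in tokens[9:]])
    except (ValueError, IndexError):
        raise SurfaceFormatError("malformed DSAA header or non-numeric grid data") from None
    if data.size != nrow * ncol:
        raise SurfaceFormatError(
            f"grid size mismatch: header declares {nrow}x{ncol}={nrow * ncol} cells, "
            f"file holds {data.size}"
        )
    values = data.reshape(nrow, ncol)
    mask = values < SURFER_BLANK * (1 - 1e-6)
    values = np.where(mask, values, np.nan)
    spacing_col = (xmax - xmin) / (ncol - 1) if ncol > 1 else 1.0
    spacing_row = (ymax - ymin) / (nrow - 1) if nrow > 1 else 1.0
    return HeightMap(values=values, spacing_row=spacing_row, spacing_col=spacing_col,
                     mask=mask, origin=np.array([ymin, xmin]))


def write_surfer_grid(hm: HeightMap, path) -> None:
    """Write a HeightMap as a Surfer DSAA ASCII grid (masked -> blank sentinel)."""
    nrow, ncol = hm.shape
    ymin, xmin = hm.origin
    xmax = xmin + hm.spacing_col * (ncol - 1)
    ymax = ymin + hm.spacing_row * (nrow - 1)
    valid = hm.values[hm.mask]
    zmin = float(valid.min()) if valid.size else 0.0
    zmax = float(valid.max()) if valid.size else 0.0
    out = np.where(hm.mask, hm.values, SURFER_BLANK)
    with open(path, "w") as fh:
        fh.write("DSAA\n")
        fh.write(f"{ncol} {nrow}\n")
        fh.write(f"{xmin:.17g} {xmax:.17g}\n")
        fh.write(f"{ymin:.17g} {ymax:.17g}\n")
        fh.write(f"{zmin:.17g} {zmax:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# rasterization and standardization
# ---------------------------------------------------------------------------


def _fill_small_holes(values: np.ndarray, mask: np.ndarray, max_hole: int = 2):
    """Fill masked components of <= max_hole cells with their valid-neighbour mean."""
    holes = _cc_label(~mask, connectivity=1)
    out_v, out_m = values.copy(), mask.copy()
    for lab in range(1, holes.max() + 1):
        cells = np.argwhere(holes == lab)
        if len(cells) > max_hole:
            continue
        for r, c in cells:
            nb = []
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc]:
                    nb.append(values[rr, cc])
            if nb:
                out_v[r, c] = float(np.mean(nb))
                out_m[r, c] = True
    return out_v, out_m


def grid_point_cloud(cloud: PointCloud, target_rows: int,
                     occlusal_axis_convention: str = "yx",
                     fill_holes: int = 2) -> HeightMap:
    """Rasterize an occlusal point cloud onto a regular grid.

    Each cell takes the *maximum* z of the points that fall in it (the
    occlusal, i.e. exposed, envelope); empty cells are masked, then
    masked holes of at most ``fill_holes`` cells are filled from their
    valid neighbours.  ``occlusal_axis_convention`` names which point
    axes map to (row, column): "yx" (default, mesiodistal = y) or "xy".
    """
    if target_rows < 3:
        raise ValueError("target_rows must be >= 3")
    pts = cloud.points
    if occlusal_axis_convention == "yx":
        rowc, colc = pts[:, 1], pts[:, 0]
    elif occlusal_axis_convention == "xy":
        rowc, colc = pts[:, 0], pts[:, 1]
    else:
        raise ValueError("occlusal_axis_convention must be 'yx' or 'xy'")
    z = pts[:, 2]
    row_extent = rowc.max() - rowc.min()
    col_extent = colc.max() - colc.min()
    if row_extent <= 0 or col_extent <= 0:
        raise GeometryError("point cloud is degenerate along a grid axis")
    cell = row_extent / target_rows
    n_cols = max(3, int(round(col_extent / cell)))
    stat, row_edges, col_edges, _ = binned_statistic_2d(
        rowc, colc, z, statistic="max", bins=[target_rows, n_cols])
    mask = np.isfinite(stat)
    values, mask = _fill_small_holes(stat, mask, max_hole=fill_holes)
    spacing_row = row_edges[1] - row_edges[0]
    spacing_col = col_edges[1] - col_edges[0]
    return HeightMap(values=np.where(mask, values, np.nan),
                     spacing_row=spacing_row, spacing_col=spacing_col,
                     mask=mask, origin=np.array([row_edges[0], col_edges[0]]))


def standardize_tooth_row(hm: HeightMap, n_teeth: int,
                          rows_per_tooth: int = 50) -> ToothRowGrid:
    """Resample a tooth-row height map to ``n_teeth * rows_per_tooth`` rows.

    Bilinear resampling of valid cells; the column count is rescaled by
    the same factor so the aspect ratio is preserved.  The mask is
    resampled conservatively: an output cell is masked if any input cell
    contributing to its interpolation is masked.
    """
    if n_teeth < 1:
        raise ValueError("n_teeth must be >= 1")
    n_in_r, n_in_c = hm.shape
    if int(hm.mask.any(axis=1).sum()) < 3:
        raise GeometryError("height map needs at least 3 valid rows")
    n_out_r = n_teeth * rows_per_tooth
    factor = n_out_r / n_in_r
    n_out_c = max(3, int(round(n_in_c * factor)))

    filled = np.where(hm.mask, hm.values, 0.0)
    bad = (~hm.mask).astype(float)
    interp_v = RegularGridInterpolator(
        (np.arange(n_in_r), np.arange(n_in_c)), filled, method="linear",
        bounds_error=False, fill_value=None)
    interp_b = RegularGridInterpolator(
        (np.arange(n_in_r), np.arange(n_in_c)), bad, method="linear",
        bounds_error=False, fill_value=None)

    # map output cell centres into input index space (standard resize map)
    rr = np.clip((np.arange(n_out_r) + 0.5) * (n_in_r / n_out_r) - 0.5, 0, n_in_r - 1)
    cc = np.clip((np.arange(n_out_c) + 0.5) * (n_in_c / n_out_c) - 0.5, 0, n_in_c - 1)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    pts = np.column_stack([grid_r.ravel(), grid_c.ravel()])
    values = interp_v(pts).reshape(n_out_r, n_out_c)
    badness = interp_b(pts).reshape(n_out_r, n_out_c)
    mask = badness < 1e-12  # any masked contributor poisons the output cell
    out = HeightMap(values=np.where(mask, values, np.nan),
                    spacing_row=hm.spacing_row * n_in_r / n_out_r,
                    spacing_col=hm.spacing_col * n_in_c / n_out_c,
                    mask=mask, origin=hm.origin.copy())
    return ToothRowGrid(heightmap=out, n_teeth=n_teeth, rows_per_tooth=rows_per_tooth)
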