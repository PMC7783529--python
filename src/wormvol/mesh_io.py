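"""Triangle-mesh I/O (OBJ / PLY / STL) and transform baking.

Meshes are stored with float64 vertices and 0-based int64 face indices;
conversion from the 1-based OBJ convention happens only at the I/O
boundary.  Coordinates are kept in the file's native units ("model
units"); unit calibration is an explicit downstream step in
:mod:`wormvol.volumetrics`.

Supported dialects:

* OBJ — ASCII, ``v``/``f`` records only; ``vn``/``vt``/``usemtl`` and
  friends are ignored; negative indices resolve relative to the vertices
  defined so far, per the OBJ standard.
* PLY — ASCII and binary little-endian.
* STL — ASCII and binary.  STL stores unshared triangle soup, so exactly
  coincident vertices are merged on read to recover connectivity.

Polygonal faces with more than three vertices are fan-triangulated from
the first vertex.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TriangleMesh",
    "AffineTransform",
    "MeshFormatError",
    "EmptyMeshError",
    "read_mesh",
    "write_mesh",
    "read_collection",
    "bake_transform",
]

_FORMATS = ("obj", "ply", "stl")


class MeshFormatError(ValueError):
    """Raised when a mesh file does not parse under its named standard."""


class EmptyMeshError(ValueError):
    """Raised when a parsed mesh contains no faces."""


@dataclass(frozen=True)
class TriangleMesh:
    """A named, indexed triangle surface of one cell, in model units.

    Faces are counter-clockwise when viewed from outside for an
    outward-oriented mesh.

    Invariants (checked on construction): every face index addresses a
    valid vertex, no face repeats a vertex, and all coordinates are
    finite.
    """

    name: str
    vertices: np.ndarray
    faces: np.ndarray
    collection: str | None = None

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"mesh {self.name!r}: non-finite vertex coordinates")
        if f.size:
            if f.min() < 0 or f.max() >= len(v):
                raise ValueError(
                    f"mesh {self.name!r}: face index out of range "
                    f"[0, {len(v) - 1}]"
                )
            degenerate = (
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            )
            if degenerate.any():
                bad = int(np.nonzero(degenerate)[0][0])
                raise ValueError(
                    f"mesh {self.name!r}: face {bad} references a vertex twice"
                )
        v.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_collection(self, collection: str) -> "TriangleMesh":
        return replace(self, collection=collection)

    def translated(self, offset: Sequence[float]) -> "TriangleMesh":
        off = np.asarray(offset, dtype=np.float64)
        return replace(self, vertices=self.vertices + off)


@dataclass(frozen=True)
class AffineTransform:
    """3x3 linear part plus translation, in model units.

    The linear part must be invertible so the transform can be baked
    without collapsing the mesh.
    """

    linear: np.ndarray
    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3, dtype=np.float64)
    )

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=np.float64).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.linalg.det(lin) == 0.0:
            raise ValueError("affine transform has a singular linear part")
        lin.setflags(write=False)
        tr.setflags(write=False)
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    @classmethod
    def scaling(cls, s: float | Sequence[float]) -> "AffineTransform":
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        if s.size == 1:
            s = np.repeat(s, 3)
        return cls(np.diag(s))

    @classmethod
    def translating(cls, offset: Sequence[float]) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(offset, dtype=np.float64))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return AffineTransform(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.linear))


# ---------------------------------------------------------------------------
# Fan triangulation


def _fan_triangulate(
    polygon: Sequence[int],
    vertices: np.ndarray | None = None,
    where: str = "",
) -> list[tuple[int, int, int]]:
    """Triangulate an n-gon from its first vertex, preserving winding.

    If ``vertices`` is given, warns when the polygon is non-planar beyond
    1e-6 times the bounding-box diagonal of its vertices.
    """
    if len(polygon) < 3:
        raise MeshFormatError(f"face with fewer than 3 vertices {where}")
    if vertices is not None and len(polygon) > 3:
        pts = vertices[list(polygon)]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        # smallest singular value ~ out-of-plane extent
        sv = np.linalg.svd(centered, compute_uv=False)
        diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        if diag > 0 and sv[-1] > 1e-6 * diag:
            warnings.warn(
                f"non-planar {len(polygon)}-gon fan-triangulated {where}",
                stacklevel=3,
            )
    return [(polygon[0], polygon[i], polygon[i + 1]) for i in range(1, len(polygon) - 1)]


# ---------------------------------------------------------------------------
# OBJ


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    vertices: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            tag = tokens[0]
            if tag == "v":
                if len(tokens) < 4:
                    raise MeshFormatError(
                        f"{path}:{lineno}: vertex record needs 3 coordinates"
                    )
                try:
                    vertices.append(
                        (float(tokens[1]), float(tokens[2]), float(tokens[3]))
                    )
                except ValueError as exc:
                    raise MeshFormatError(
                        f"{path}:{lineno}: bad vertex coordinate: {exc}"
                    ) from None
            elif tag == "f":
                idx: list[int] = []
                for tok in tokens[1:]:
                    head = tok.split("/", 1)[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise MeshFormatError(
                            f"{path}:{lineno}: bad face index {tok!r}"
                        ) from None
                    if i == 0:
                        raise MeshFormatError(
                            f"{path}:{lineno}: OBJ indices are 1-based, got 0"
                        )
                    # negative indices count back from the vertices seen so far
                    j = len(vertices) + i if i < 0 else i - 1
                    if not 0 <= j < len(vertices):
                        raise MeshFormatError(
                            f"{path}:{lineno}: face index {i} out of range"
                        )
                    idx.append(j)
                varr = np.asarray(vertices, dtype=np.float64)
                faces.extend(_fan_triangulate(idx, varr, f"at {path}:{lineno}"))
            # vn / vt / usemtl / o / g / s / mtllib: ignored by design
    return (
        np.asarray(vertices, dtype=np.float64).reshape(-1, 3),
        np.asarray(faces, dtype=np.int64).reshape(-1, 3),
    )


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"o {mesh.name}\n")
        for x, y, z in mesh.vertices.tolist():
            fh.write(f"v {x!r} {y!r} {z!r}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


# ---------------------------------------------------------------------------
# PLY


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str, str | None]]]] = []
        current_props: list[tuple[str, str, str | None]] = []
        while True:
            raw = fh.readline()
            if not raw:
                raise MeshFormatError(f"{path}: unexpected EOF in PLY header")
            line = raw.decode("ascii", errors="replace").strip()
            if not line or line.startswith("comment") or line.startswith("obj_info"):
                continue
            parts = line.split()
            if parts[0] == "format":
                fmt = parts[1]
                if fmt not in ("ascii", "binary_little_endian"):
                    raise MeshFormatError(
                        f"{path}: unsupported PLY format {fmt!r} "
                        "(ascii and binary_little_endian supported)"
                    )
            elif parts[0] == "element":
                current_props = []
                elements.append((parts[1], int(parts[2]), current_props))
            elif parts[0] == "property":
                if parts[1] == "list":
                    # (name, value-type, count-type)
                    current_props.append((parts[4], parts[3], parts[2]))
                else:
                    current_props.append((parts[2], parts[1], None))
            elif parts[0] == "end_header":
                break
            else:
                raise MeshFormatError(f"{path}: bad PLY header line {line!r}")
        if fmt is None:
            raise MeshFormatError(f"{path}: PLY header missing 'format' line")
        if fmt == "ascii":
            return _read_ply_ascii(fh, elements, path)
        return _read_ply_binary_le(fh, elements, path)


_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _read_ply_ascii(fh, elements, path) -> tuple[np.ndarray, np.ndarray]:
    vertices: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    text = fh.read().decode("ascii", errors="replace").split()
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        if pos + n > len(text):
            raise MeshFormatError(f"{path}: truncated PLY body")
        out = text[pos : pos + n]
        pos += n
        return out

    for ename, count, props in elements:
        for _ in range(count):
            if ename == "vertex":
                row: dict[str, float] = {}
                for pname, _ptype, ltype in props:
                    if ltype is not None:
                        n = int(take(1)[0])
                        take(n)
                    else:
                        row[pname] = float(take(1)[0])
                vertices.append([row["x"], row["y"], row["z"]])
            elif ename == "face":
                for pname, _ptype, ltype in props:
                    if ltype is not None:
                        n = int(take(1)[0])
                        poly = [int(t) for t in take(n)]
                        if pname in ("vertex_indices", "vertex_index"):
                            faces.extend(_fan_triangulate(poly, where=f"in {path}"))
                    else:
                        take(1)
            else:  # unknown element: consume
                for _pname, _ptype, ltype in props:
                    if ltype is not None:
                        n = int(take(1)[0])
                        take(n)
                    else:
                        take(1)
    return (
        np.asarray(vertices, dtype=np.float64).reshape(-1, 3),
        np.asarray(faces, dtype=np.int64).reshape(-1, 3),
    )


def _read_ply_binary_le(fh, elements, path) -> tuple[np.ndarray, np.ndarray]:
    vertices = np.empty((0, 3))
    faces: list[tuple[int, int, int]] = []
    for ename, count, props in elements:
        if ename == "vertex" and all(lt is None for _, _, lt in props):
            dtype = np.dtype([(p, "<" + _PLY_TYPES[t]) for p, t, _ in props])
            buf = fh.read(dtype.itemsize * count)
            if len(buf) != dtype.itemsize * count:
                raise MeshFormatError(f"{path}: truncated PLY vertex block")
            rec = np.frombuffer(buf, dtype=dtype)
            vertices = np.stack(
                [rec["x"], rec["y"], rec["z"]], axis=1
            ).astype(np.float64)
        else:
            for _ in range(count):
                for pname, ptype, ltype in props:
                    if ltype is not None:
                        csize = np.dtype(_PLY_TYPES[ltype]).itemsize
                        cbuf = fh.read(csize)
                        if len(cbuf) != csize:
                            raise MeshFormatError(f"{path}: truncated PLY body")
                        n = int(
                            np.frombuffer(cbuf, dtype="<" + _PLY_TYPES[ltype])[0]
                        )
                        vsize = np.dtype(_PLY_TYPES[ptype]).itemsize
                        vbuf = fh.read(vsize * n)
                        if len(vbuf) != vsize * n:
                            raise MeshFormatError(f"{path}: truncated PLY body")
                        vals = np.frombuffer(vbuf, dtype="<" + _PLY_TYPES[ptype])
                        if ename == "face" and pname in (
                            "vertex_indices",
                            "vertex_index",
                        ):
                            faces.extend(
                                _fan_triangulate(
                                    [int(v) for v in vals], where=f"in {path}"
                                )
                            )
                    else:
                        fh.read(np.dtype(_PLY_TYPES[ptype]).itemsize)
    return vertices, np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _write_ply(mesh: TriangleMesh, path: Path, binary: bool = False) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"comment {mesh.name}\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            for a, b, c in mesh.faces:
                fh.write(struct.pack("<Biii", 3, a, b, c))
        else:
            lines = []
            for x, y, z in mesh.vertices.tolist():
                lines.append(f"{x!r} {y!r} {z!r}\n")
            for a, b, c in mesh.faces:
                lines.append(f"3 {a} {b} {c}\n")
            fh.write("".join(lines).encode("ascii"))


# ---------------------------------------------------------------------------
# STL


def _soup_to_indexed(
    tris: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge exactly-coincident vertices of an (n, 3, 3) triangle soup."""
    flat = tris.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3).astype(np.int64)
    return uniq.astype(np.float64), faces


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        head = fh.read(5)
        fh.seek(0)
        if head == b"solid":
            # may still be binary: check for 'facet' in the first chunk
            chunk = fh.read(1024)
            fh.seek(0)
            if b"facet" in chunk:
                return _read_stl_ascii(fh, path)
        return _read_stl_binary(fh, path)


def _read_stl_ascii(fh, path) -> tuple[np.ndarray, np.ndarray]:
    tris: list[list[list[float]]] = []
    current: list[list[float]] = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.decode("ascii", errors="replace").strip()
        if line.startswith("vertex"):
            parts = line.split()
            if len(parts) != 4:
                raise MeshFormatError(f"{path}:{lineno}: bad STL vertex record")
            try:
                current.append([float(p) for p in parts[1:]])
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: {exc}") from None
        elif line.startswith("endfacet"):
            if len(current) != 3:
                raise MeshFormatError(
                    f"{path}:{lineno}: facet with {len(current)} vertices"
                )
            tris.append(current)
            current = []
    if not tris:
        raise EmptyMeshError(f"{path}: STL file contains no facets")
    return _soup_to_indexed(np.asarray(tris, dtype=np.float64))


def _read_stl_binary(fh, path) -> tuple[np.ndarray, np.ndarray]:
    fh.read(80)  # header, ignored
    count_buf = fh.read(4)
    if len(count_buf) != 4:
        raise MeshFormatError(f"{path}: truncated binary STL header")
    (n,) = struct.unpack("<I", count_buf)
    body = fh.read(50 * n)
    if len(body) != 50 * n:
        raise MeshFormatError(
            f"{path}: binary STL declares {n} facets but body is short"
        )
    rec = np.frombuffer(
        body,
        dtype=np.dtype(
            [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
        ),
    )
    return _soup_to_indexed(rec["verts"].astype(np.float64))


def _write_stl(mesh: TriangleMesh, path: Path, binary: bool = False) -> None:
    tris = mesh.vertices[mesh.faces]  # (m, 3, 3)
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
    if binary:
        with open(path, "wb") as fh:
            fh.write(mesh.name.encode("ascii", "replace")[:80].ljust(80, b"\0"))
            fh.write(struct.pack("<I", mesh.n_faces))
            for nrm, tri in zip(normals, tris):
                fh.write(
                    struct.pack(
                        "<12fH",
                        *nrm.astype(np.float32),
                        *tri.astype(np.float32).ravel(),
                        0,
                    )
                )
    else:
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write(f"solid {mesh.name}\n")
            for nrm, tri in zip(normals.tolist(), tris.tolist()):
                fh.write(f"  facet normal {nrm[0]!r} {nrm[1]!r} {nrm[2]!r}\n")
                fh.write("    outer loop\n")
                for v in tri:
                    fh.write(f"      vertex {v[0]!r} {v[1]!r} {v[2]!r}\n")
                fh.write("    endloop\n")
                fh.write("  endfacet\n")
            fh.write(f"endsolid {mesh.name}\n")


# ---------------------------------------------------------------------------
# Public API


def _detect_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in _FORMATS:
            raise ValueError(f"unknown mesh format {format!r}; expected {_FORMATS}")
        return fmt
    ext = path.suffix.lower().lstrip(".")
    if ext not in _FORMATS:
        raise ValueError(
            f"cannot auto-detect format of {path} (extension {ext!r}); "
            "pass format explicitly"
        )
    return ext


def read_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from an OBJ, PLY, or STL file.

    The format is auto-detected from the file extension unless given.
    Polygonal faces are fan-triangulated; the mesh name defaults to the
    file stem.

    Raises
    ------
    MeshFormatError
        If the file does not parse, naming the offending line/record.
    EmptyMeshError
        If the file parses but contains no faces.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    reader = {"obj": _read_obj, "ply": _read_ply, "stl": _read_stl}[fmt]
    vertices, faces = reader(path)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: mesh has no faces")
    return TriangleMesh(name=path.stem, vertices=vertices, faces=faces)


def write_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    format: str | None = None,
    binary: bool = False,
) -> Path:
    """Write a mesh as OBJ (ASCII), PLY, or STL.

    ``binary`` selects binary little-endian PLY or binary STL; it is
    ignored for OBJ.  Vertex coordinates are written with full float64
    round-trip precision in the ASCII formats.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path, binary=binary)
    else:
        _write_stl(mesh, path, binary=binary)
    return path


def iter_collection_files(root: Path) -> Iterator[tuple[str, Path]]:
    subdirs = sorted(p for p in root.iterdir() if p.is_dir())
    for sub in subdirs:
        files = sorted(
            p for p in sub.iterdir() if p.suffix.lower().lstrip(".") in _FORMATS
        )
        for f in files:
            yield sub.name, f


def read_collection(root: str | Path) -> list[TriangleMesh]:
    """Read all meshes under ``root/<tissue>/<cell>.<ext>``.

    Each mesh's ``collection`` label is its subdirectory name.  Ordering
    is deterministic (lexicographic by directory, then file).  Duplicate
    cell names across collections are an error because the anatomy join
    is keyed by cell name.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(root)
    meshes: list[TriangleMesh] = []
    seen: dict[str, str] = {}
    dupes: list[str] = []
    for collection, path in iter_collection_files(root):
        mesh = read_mesh(path).with_collection(collection)
        if mesh.name in seen:
            dupes.append(f"{mesh.name} ({seen[mesh.name]}, {collection})")
        else:
            seen[mesh.name] = collection
        meshes.append(mesh)
    if dupes:
        raise ValueError(
            "duplicate cell names across collections: " + "; ".join(dupes)
        )
    if not meshes:
        raise ValueError(f"no mesh files found under {root}")
    return meshes


def bake_transform(mesh: TriangleMesh, t: AffineTransform) -> TriangleMesh:
    """Apply ``t`` to every vertex, returning a new mesh.

    If the determinant of the linear part is negative (a reflection),
    face winding is flipped so that outward orientation is preserved.
    """
    vertices = t.apply(mesh.vertices)
    faces = mesh.faces
    if t.determinant < 0:
        faces = faces[:, ::-1]
    return replace(mesh, vertices=vertices, faces=faces)
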