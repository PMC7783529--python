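"""Synthetic "virtual worms": meshes with analytically known volumes.

Generates complete pipeline inputs — a tissue-collection directory of
closed meshes, a calibration cube, an anatomy CSV, and a ground-truth
manifest — so every stage is testable without external downloads.

Boxes carry exact analytic volumes (edge products).  Curved convex
shapes (icospheres, capped tubes, random hulls) carry mesh-exact oracle
volumes computed with :class:`scipy.spatial.ConvexHull`, which is
independent of the divergence-theorem implementation under test; the
smooth closed forms are kept separately for convergence checks only.

A single seed governs all randomness and outputs are byte-identical for
a given seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull

from wormvol.mesh_io import TriangleMesh, write_mesh

__all__ = [
    "SyntheticCellSpec",
    "WormManifest",
    "make_box",
    "make_box_shell",
    "make_icosphere",
    "make_tube",
    "make_random_hull",
    "hull_volume",
    "perturb",
    "generate_worm",
    "DEFAULT_CELLS_PER_TISSUE",
]

# unit-icosahedron vertices and outward-wound faces
_PHI = (1.0 + math.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=np.float64,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)

_BOX_FACES = np.array(
    [
        (0, 3, 1), (0, 2, 3),  # -z
        (4, 7, 6), (4, 5, 7),  # +z
        (0, 5, 4), (0, 1, 5),  # -y
        (2, 7, 3), (2, 6, 7),  # +y
        (0, 6, 2), (0, 4, 6),  # -x
        (1, 7, 5), (1, 3, 7),  # +x
    ],
    dtype=np.int64,
)


def _box_vertices(edges: Sequence[float]) -> np.ndarray:
    ex, ey, ez = (float(e) for e in edges)
    if ex <= 0 or ey <= 0 or ez <= 0:
        raise ValueError(f"box edges must be positive, got {edges}")
    # corner at the origin keeps tetrahedron determinants exact for
    # integer-like edges
    return np.array(
        [
            (0, 0, 0), (ex, 0, 0), (0, ey, 0), (ex, ey, 0),
            (0, 0, ez), (ex, 0, ez), (0, ey, ez), (ex, ey, ez),
        ],
        dtype=np.float64,
    )


def make_box(edges: Sequence[float], name: str = "box") -> TriangleMesh:
    """Axis-aligned closed box: 8 vertices, 12 outward triangles.

    The signed volume equals the edge product (exactly, in float, for
    representable products).
    """
    return TriangleMesh(name=name, vertices=_box_vertices(edges), faces=_BOX_FACES)


def make_box_shell(
    outer: Sequence[float],
    thickness: float,
    name: str = "shell",
) -> TriangleMesh:
    """Hollow box: outer shell plus an inward-oriented inner shell.

    Its divergence-theorem volume is the wall volume
    (outer product minus inner product); both shells are watertight and
    the combined mesh is orientation-consistent per component.
    """
    outer = [float(e) for e in outer]
    inner = [e - 2.0 * thickness for e in outer]
    if min(inner) <= 0:
        raise ValueError("shell thickness leaves no interior")
    vo = _box_vertices(outer)
    vi = _box_vertices(inner) + thickness
    faces_inner = _BOX_FACES[:, ::-1] + 8  # inverted: encloses the cavity
    return TriangleMesh(
        name=name,
        vertices=np.vstack([vo, vi]),
        faces=np.vstack([_BOX_FACES, faces_inner]),
    )


def box_shell_volume(outer: Sequence[float], thickness: float) -> float:
    ox, oy, oz = (float(e) for e in outer)
    ix, iy, iz = (e - 2.0 * thickness for e in (ox, oy, oz))
    return ox * oy * oz - ix * iy * iz


def make_icosphere(
    radius: float, subdivisions: int, name: str = "icosphere"
) -> TriangleMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected onto the
    sphere of the given radius.

    The mesh is inscribed, so its volume is strictly below 4*pi*r^3/3
    and increases with subdivision level.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in 0..6")
    verts = [v / np.linalg.norm(v) for v in _ICO_VERTS]
    faces = [tuple(f) for f in _ICO_FACES]
    for _ in range(subdivisions):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                p = verts[a] + verts[b]
                verts.append(p / np.linalg.norm(p))
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return TriangleMesh(
        name=name,
        vertices=np.asarray(verts) * radius,
        faces=np.asarray(faces, dtype=np.int64),
    )


def make_tube(
    radius: float, length: float, segments: int = 24, name: str = "tube"
) -> TriangleMesh:
    """Closed circular cylinder along z (a convex capped tube)."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if segments < 3:
        raise ValueError("need at least 3 segments")
    ang = 2.0 * np.pi * np.arange(segments) / segments
    ring = np.stack([radius * np.cos(ang), radius * np.sin(ang)], axis=1)
    bottom = np.column_stack([ring, np.zeros(segments)])
    top = np.column_stack([ring, np.full(segments, float(length))])
    verts = np.vstack([bottom, top, [[0, 0, 0]], [[0, 0, float(length)]]])
    cb, ct = 2 * segments, 2 * segments + 1
    faces = []
    for i in range(segments):
        j = (i + 1) % segments
        faces += [
            (i, j, segments + j),
            (i, segments + j, segments + i),
            (cb, j, i),                      # bottom cap (normal -z)
            (ct, segments + i, segments + j),  # top cap (normal +z)
        ]
    return TriangleMesh(
        name=name, vertices=verts, faces=np.asarray(faces, dtype=np.int64)
    )


def make_random_hull(
    n_points: int,
    rng: np.random.Generator,
    scale: float | Sequence[float] = 1.0,
    name: str = "hull",
) -> TriangleMesh:
    """Convex hull of random points in a ball, outward-oriented."""
    if n_points < 4:
        raise ValueError("need at least 4 points for a hull")
    pts = rng.standard_normal((n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= rng.uniform(0.3, 1.0, (n_points, 1)) ** (1.0 / 3.0)
    pts = pts * np.atleast_1d(np.asarray(scale, dtype=np.float64))
    hull = ConvexHull(pts)
    used = np.unique(hull.simplices)
    remap = {int(v): i for i, v in enumerate(used)}
    verts = pts[used]
    faces = np.array(
        [[remap[int(v)] for v in simplex] for simplex in hull.simplices],
        dtype=np.int64,
    )
    # orient each face outward relative to the interior centroid
    centroid = verts.mean(axis=0)
    tris = verts[faces] - centroid
    dets = np.einsum(
        "ij,ij->i", tris[:, 0], np.cross(tris[:, 1], tris[:, 2])
    )
    flip = dets < 0
    faces[flip] = faces[flip][:, ::-1]
    return TriangleMesh(name=name, vertices=verts, faces=faces)


def hull_volume(mesh: TriangleMesh) -> float:
    """Independent convex-hull volume oracle (valid for convex meshes)."""
    return float(ConvexHull(mesh.vertices).volume)


def perturb(
    mesh: TriangleMesh,
    kind: str,
    seed: int = 0,
    sigma: float = 0.0,
    n_faces: int = 1,
) -> TriangleMesh:
    """Damage a mesh to exercise validation paths.

    kinds: ``jitter`` (Gaussian vertex noise of scale ``sigma``),
    ``puncture`` (remove ``n_faces`` faces, creating boundary edges),
    ``flip_all`` (negate orientation), ``flip_one`` (flip one face).
    """
    rng = np.random.default_rng(seed)
    if kind == "jitter":
        noise = sigma * rng.standard_normal(mesh.vertices.shape) if sigma else 0.0
        return replace(mesh, vertices=mesh.vertices + noise)
    if kind == "puncture":
        if n_faces >= mesh.n_faces:
            raise ValueError(
                f"cannot puncture {n_faces} of {mesh.n_faces} faces"
            )
        drop = rng.choice(mesh.n_faces, size=n_faces, replace=False)
        keep = np.setdiff1d(np.arange(mesh.n_faces), drop)
        return replace(mesh, faces=mesh.faces[keep])
    if kind == "flip_all":
        return replace(mesh, faces=mesh.faces[:, ::-1])
    if kind == "flip_one":
        idx = int(rng.integers(mesh.n_faces))
        faces = mesh.faces.copy()
        faces[idx] = faces[idx][::-1]
        return replace(mesh, faces=faces)
    raise ValueError(f"unknown perturbation kind {kind!r}")


# ---------------------------------------------------------------------------
# Whole-worm generation


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Ground truth for one generated cell."""

    name: str
    tissue: str
    shape: str
    volume_um3: float  # exact (boxes) or ConvexHull-oracle (curved)
    closed_form_um3: float | None
    nuclei: int
    ploidy_c: float
    somatic: bool
    offset: tuple[float, float, float]


@dataclass(frozen=True)
class WormManifest:
    """Everything needed to verify pipeline output on a synthetic worm."""

    seed: int
    model_units_per_um: float
    calibration_name: str
    calibration_edge_model_units: float
    calibration_known_volume_um3: float
    cells: tuple[SyntheticCellSpec, ...]
    expected: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = asdict(self)
        doc["cells"] = [asdict(c) for c in self.cells]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "WormManifest":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        doc["cells"] = tuple(
            SyntheticCellSpec(**{**c, "offset": tuple(c["offset"])})
            for c in doc["cells"]
        )
        return cls(**doc)


DEFAULT_CELLS_PER_TISSUE: Mapping[str, int] = {
    "intestine": 10,
    "hypodermis": 8,
    "body wall muscle": 12,
    "pharynx": 8,
    "neurons": 15,
    "somatic gonad": 6,
}

# log-normal medians (um^3) per tissue, long-tailed like real cell sizes;
# chosen so tissue totals tend to follow the target ordering
_DEFAULT_SIZE_PARAMS: Mapping[str, tuple[float, float]] = {
    "intestine": (math.log(2400.0), 0.35),
    "hypodermis": (math.log(900.0), 0.5),
    "body wall muscle": (math.log(850.0), 0.3),
    "pharynx": (math.log(650.0), 0.4),
    "neurons": (math.log(25.0), 0.6),
    "somatic gonad": (math.log(1100.0), 0.4),
}

_SHAPES = ("box", "icosphere", "hull", "tube")


def _shape_for_volume(
    shape: str,
    volume_um3: float,
    scale: float,
    rng: np.random.Generator,
    name: str,
) -> tuple[TriangleMesh, float, float | None]:
    """Build a mesh with target volume, returning (mesh, oracle volume in
    um^3, smooth closed form if any).  ``scale`` is model units per um."""
    v_model = volume_um3 * scale**3
    if shape == "box":
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(0.5, 2.0)
        base = (v_model / (a * b)) ** (1.0 / 3.0)
        edges = (base * a, base * b, base)
        mesh = make_box(edges, name=name)
        exact = edges[0] * edges[1] * edges[2]
        return mesh, exact / scale**3, None
    if shape == "icosphere":
        r = (3.0 * v_model / (4.0 * math.pi)) ** (1.0 / 3.0)
        mesh = make_icosphere(r, subdivisions=2, name=name)
        closed = 4.0 * math.pi * r**3 / 3.0 / scale**3
        return mesh, hull_volume(mesh) / scale**3, closed
    if shape == "tube":
        aspect = rng.uniform(2.0, 6.0)
        r = (v_model / (math.pi * aspect)) ** (1.0 / 3.0)
        mesh = make_tube(r, aspect * r, segments=24, name=name)
        closed = math.pi * r**2 * (aspect * r) / scale**3
        return mesh, hull_volume(mesh) / scale**3, closed
    if shape == "hull":
        n = int(rng.integers(10, 31))
        mesh = make_random_hull(n, rng, scale=1.0, name=name)
        raw = hull_volume(mesh)
        s = (v_model / raw) ** (1.0 / 3.0)
        mesh = replace(mesh, vertices=mesh.vertices * s)
        return mesh, hull_volume(mesh) / scale**3, None
    raise ValueError(f"unknown shape {shape!r}")


def _expected_summaries(
    cells: Sequence[SyntheticCellSpec], include_germline: bool
) -> dict:
    pool = [c for c in cells if include_germline or c.somatic]
    tissues = sorted({c.tissue for c in pool})
    total_v = math.fsum(c.volume_um3 for c in pool)
    total_n = sum(c.nuclei for c in pool)
    total_g = math.fsum(c.nuclei * c.ploidy_c / 2.0 for c in pool)
    out = {}
    for t in tissues:
        sub = [c for c in pool if c.tissue == t]
        tv = math.fsum(c.volume_um3 for c in sub)
        tn = sum(c.nuclei for c in sub)
        tg = math.fsum(c.nuclei * c.ploidy_c / 2.0 for c in sub)
        out[t] = {
            "total_volume_um3": tv,
            "volume_fraction": tv / total_v,
            "nuclei_total": tn,
            "nuclei_fraction": tn / total_n if total_n else 0.0,
            "genome_fraction": tg / total_g if total_g else 0.0,
        }
    return out


def generate_worm(
    out_dir: str | Path,
    seed: int = 0,
    cells_per_tissue: Mapping[str, int] | None = None,
    size_params: Mapping[str, tuple[float, float]] | None = None,
    model_units_per_um: float = 2.0,
) -> WormManifest:
    """Write a complete synthetic worm and return its manifest.

    Produces ``<out_dir>/meshes/<tissue>/<cell>.obj`` (plus the
    calibration cube under ``meshes/reference/``), ``anatomy.csv`` and
    ``manifest.json``.  Deterministic and byte-identical for a given
    seed.

    Always includes, by construction: a 139-nucleus diploid syncytium
    (``hyp7s``), a mononucleate 32C polyploid cell per intestinal slot,
    a zero-nuclei hollow cuticle shell, and a non-somatic germline
    pseudo-record.
    """
    out_dir = Path(out_dir)
    cells_per_tissue = dict(
        DEFAULT_CELLS_PER_TISSUE if cells_per_tissue is None else cells_per_tissue
    )
    if not cells_per_tissue or all(n <= 0 for n in cells_per_tissue.values()):
        raise ValueError("need at least one tissue with at least one cell")
    size_params = dict(_DEFAULT_SIZE_PARAMS if size_params is None else size_params)
    for t, n in cells_per_tissue.items():
        mu, sg = size_params.get(t, (math.log(100.0), 0.5))
        if sg < 0 or not math.isfinite(mu):
            raise ValueError(f"invalid size distribution for {t!r}: {(mu, sg)}")

    scale = float(model_units_per_um)
    rng = np.random.default_rng(seed)
    mesh_root = out_dir / "meshes"
    specs: list[SyntheticCellSpec] = []
    grid = 0

    def place(mesh: TriangleMesh) -> tuple[TriangleMesh, tuple[float, float, float]]:
        nonlocal grid
        off = (1000.0 * (grid % 16), 1000.0 * (grid // 16), 0.0)
        grid += 1
        return mesh.translated(off), off

    def emit(
        mesh: TriangleMesh,
        tissue: str,
        volume_um3: float,
        closed_form: float | None,
        nuclei: int,
        ploidy_c: float,
        somatic: bool,
        shape: str,
    ) -> None:
        mesh, off = place(mesh)
        d = mesh_root / tissue.replace(" ", "_")
        d.mkdir(parents=True, exist_ok=True)
        write_mesh(mesh.with_collection(tissue), d / f"{mesh.name}.obj")
        specs.append(
            SyntheticCellSpec(
                name=mesh.name,
                tissue=tissue,
                shape=shape,
                volume_um3=volume_um3,
                closed_form_um3=closed_form,
                nuclei=nuclei,
                ploidy_c=ploidy_c,
                somatic=somatic,
                offset=off,
            )
        )

    for tissue in sorted(cells_per_tissue):
        n = cells_per_tissue[tissue]
        mu, sg = size_params.get(tissue, (math.log(100.0), 0.5))
        short = tissue.replace(" ", "_")
        for i in range(n):
            name = f"{short}_{i:02d}"
            nuclei, ploidy = 1, 2.0
            if tissue == "hypodermis" and i == 0:
                name, nuclei = "hyp7s", 139  # giant syncytium
                v = 40.0 * math.exp(mu)
            elif tissue == "intestine":
                ploidy = 32.0  # young-adult endoreduplicated
                v = float(rng.lognormal(mu, sg))
            elif tissue == "pharynx" and i == 0:
                name, nuclei = "pm1s", 6
                v = float(rng.lognormal(mu, sg))
            else:
                v = float(rng.lognormal(mu, sg))
            shape = _SHAPES[(i + len(tissue)) % len(_SHAPES)]
            mesh, vol, closed = _shape_for_volume(shape, v, scale, rng, name)
            emit(mesh, tissue, vol, closed, nuclei, ploidy, True, shape)

    # hollow cuticle shell (extracellular, zero nuclei)
    shell_outer = (400.0, 80.0, 80.0)
    shell = make_box_shell(shell_outer, thickness=2.0, name="cuticle_shell")
    emit(
        shell,
        "cuticle",
        box_shell_volume(shell_outer, 2.0) / scale**3,
        None,
        0,
        2.0,
        True,
        "box_shell",
    )

    # germline/rachis pseudo-cell: one long tube, many packed nuclei
    rachis = make_tube(8.0 * scale, 300.0 * scale, segments=32, name="rachis")
    emit(
        rachis,
        "germline",
        hull_volume(rachis) / scale**3,
        math.pi * (8.0 * scale) ** 2 * 300.0 * scale / scale**3,
        1000,
        2.0,
        False,
        "tube",
    )

    # calibration cube: edge 100 um in model units
    edge = 100.0 * scale
    cube = make_box((edge, edge, edge), name="100um_cube")
    ref_dir = mesh_root / "reference"
    ref_dir.mkdir(parents=True, exist_ok=True)
    write_mesh(cube, ref_dir / "100um_cube.obj")

    with open(out_dir / "anatomy.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# synthetic anatomy table, seed %d\n" % seed)
        fh.write("cell,tissue,somatic,nuclei,ploidy_c\n")
        for c in specs:
            fh.write(
                f"{c.name},{c.tissue},{str(c.somatic).lower()},"
                f"{c.nuclei},{c.ploidy_c:g}\n"
            )

    cells = tuple(specs)
    with_g = _expected_summaries(cells, include_germline=True)
    somatic_only = _expected_summaries(cells, include_germline=False)
    ordering = sorted(
        with_g, key=lambda t: (-with_g[t]["total_volume_um3"], t)
    )
    manifest = WormManifest(
        seed=seed,
        model_units_per_um=scale,
        calibration_name="100um_cube",
        calibration_edge_model_units=edge,
        calibration_known_volume_um3=1_000_000.0,
        cells=cells,
        expected={
            "total_volume_um3": math.fsum(c.volume_um3 for c in cells),
            "with_germline": with_g,
            "somatic_only": somatic_only,
            "ordering_with_germline": ordering,
            "volume_per_genome": {
                c.name: c.volume_um3 / (c.nuclei * c.ploidy_c / 2.0)
                for c in cells
                if c.nuclei > 0
            },
        },
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
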