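import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormvol.mesh_io import (
    AffineTransform,
    EmptyMeshError,
    MeshFormatError,
    TriangleMesh,
    bake_transform,
    read_collection,
    read_mesh,
    write_mesh,
)
from wormvol.synthetic import make_box, make_random_hull
from wormvol.volumetrics import signed_volume

CUBE_OBJ = """\
# unit cube
v 0 0 0
v 1 0 0
v 0 1 0
v 1 1 0
v 0 0 1
v 1 0 1
v 0 1 1
v 1 1 1
f 1 4 2
f 1 3 4
f 5 8 7
f 5 6 8
f 1 6 5
f 1 2 6
f 3 8 4
f 3 7 8
f 1 7 3
f 1 5 7
f 2 8 6
f 2 4 8
"""


class TestReadObj:
    def test_cube_counts(self, tmp_path):
        p = tmp_path / "cube.obj"
        p.write_text(CUBE_OBJ)
        mesh = read_mesh(p)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12
        assert mesh.name == "cube"

    def test_quad_fan_triangulated(self, tmp_path):
        p = tmp_path / "quad.obj"
        p.write_text(
            "v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n"
        )
        mesh = read_mesh(p)
        assert mesh.n_faces == 2
        np.testing.assert_array_equal(mesh.faces, [[0, 1, 2], [0, 2, 3]])

    def test_negative_indices(self, tmp_path):
        p = tmp_path / "neg.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf -3 -2 -1\n")
        mesh = read_mesh(p)
        np.testing.assert_array_equal(mesh.faces, [[0, 1, 2]])

    def test_vn_vt_usemtl_ignored(self, tmp_path):
        p = tmp_path / "mat.obj"
        p.write_text(
            "usemtl skin\nvn 0 0 1\nvt 0 0\n"
            "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1/1/1 2/1/1 3/1/1\n"
        )
        mesh = read_mesh(p)
        assert mesh.n_faces == 1

    def test_bad_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 oops 0\n")
        with pytest.raises(MeshFormatError, match=r":2"):
            read_mesh(p)

    def test_out_of_range_index_names_line(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 9\n")
        with pytest.raises(MeshFormatError, match=r":4"):
            read_mesh(p)

    def test_zero_faces_is_empty_mesh(self, tmp_path):
        p = tmp_path / "empty.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\n")
        with pytest.raises(EmptyMeshError):
            read_mesh(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh(tmp_path / "nope.obj")


class TestPly:
    def test_handwritten_binary_ply_matches_obj(self, tmp_path):
        """PLY binary assembled record-by-record with struct, compared
        against the same cube parsed from OBJ text."""
        obj = tmp_path / "cube.obj"
        obj.write_text(CUBE_OBJ)
        ref = read_mesh(obj)

        header = (
            b"ply\nformat binary_little_endian 1.0\n"
            b"element vertex 8\n"
            b"property float x\nproperty float y\nproperty float z\n"
            b"element face 12\n"
            b"property list uchar int vertex_indices\n"
            b"end_header\n"
        )
        body = b""
        for v in ref.vertices:
            body += struct.pack("<3f", *v)
        for f in ref.faces:
            body += struct.pack("<Biii", 3, *f)
        p = tmp_path / "cube.ply"
        p.write_bytes(header + body)

        mesh = read_mesh(p)
        np.testing.assert_array_equal(mesh.vertices, ref.vertices)
        np.testing.assert_array_equal(mesh.faces, ref.faces)

    def test_ascii_ply_with_extra_vertex_props(self, tmp_path):
        p = tmp_path / "tri.ply"
        p.write_text(
            "ply\nformat ascii 1.0\n"
            "element vertex 3\n"
            "property double x\nproperty double y\nproperty double z\n"
            "property uchar red\n"
            "element face 1\n"
            "property list uchar int vertex_indices\n"
            "end_header\n"
            "0 0 0 255\n1 0 0 255\n0 1 0 255\n"
            "3 0 1 2\n"
        )
        mesh = read_mesh(p)
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1

    def test_bad_magic(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_bytes(b"plyx\n")
        with pytest.raises(MeshFormatError, match="magic"):
            read_mesh(p)

    def test_truncated_binary_body(self, tmp_path):
        p = tmp_path / "trunc.ply"
        p.write_bytes(
            b"ply\nformat binary_little_endian 1.0\n"
            b"element vertex 8\n"
            b"property double x\nproperty double y\nproperty double z\n"
            b"element face 0\n"
            b"property list uchar int vertex_indices\n"
            b"end_header\n" + b"\x00" * 10
        )
        with pytest.raises(MeshFormatError, match="truncated"):
            read_mesh(p)


class TestStl:
    def test_ascii_and_binary_recover_cube_volume(self, tmp_path, cube100):
        for binary in (False, True):
            p = tmp_path / f"c_{binary}.stl"
            write_mesh(cube100, p, binary=binary)
            back = read_mesh(p)
            # vertex soup is re-indexed, so compare geometry not arrays
            assert back.n_faces == 12
            assert back.n_vertices == 8
            assert signed_volume(back) == signed_volume(cube100)

    def test_binary_declared_count_checked(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_bytes(b"\0" * 80 + struct.pack("<I", 5) + b"\0" * 10)
        with pytest.raises(MeshFormatError, match="facets"):
            read_mesh(p)


@pytest.mark.parametrize("fmt,binary", [("obj", False), ("ply", False), ("ply", True)])
def test_round_trip_exact(tmp_path, rng, fmt, binary):
    mesh = make_random_hull(25, rng, scale=3.0, name="cell")
    p = tmp_path / f"cell.{fmt}"
    write_mesh(mesh, p, binary=binary)
    back = read_mesh(p)
    np.testing.assert_array_equal(back.vertices, mesh.vertices)
    np.testing.assert_array_equal(back.faces, mesh.faces)


def test_round_trip_stl_geometry(tmp_path, rng):
    # STL stores an unshared triangle soup; identity holds at the level
    # of triangle sets, and exactly so for ASCII (full repr precision)
    mesh = make_random_hull(15, rng, name="cell")
    p = tmp_path / "cell.stl"
    write_mesh(mesh, p, binary=False)
    back = read_mesh(p)
    original = {tuple(sorted(map(tuple, tri))) for tri in mesh.vertices[mesh.faces]}
    returned = {tuple(sorted(map(tuple, tri))) for tri in back.vertices[back.faces]}
    assert original == returned


class TestCollections:
    def _write(self, root, tissue, name):
        d = root / tissue
        d.mkdir(exist_ok=True)
        write_mesh(make_box((1, 1, 1), name=name), d / f"{name}.obj")

    def test_labels_and_order(self, tmp_path):
        self._write(tmp_path, "intestine", "int2")
        self._write(tmp_path, "intestine", "int1")
        self._write(tmp_path, "hypodermis", "hyp7")
        meshes = read_collection(tmp_path)
        assert [(m.collection, m.name) for m in meshes] == [
            ("hypodermis", "hyp7"),
            ("intestine", "int1"),
            ("intestine", "int2"),
        ]

    def test_duplicate_names_rejected(self, tmp_path):
        self._write(tmp_path, "hypodermis", "hyp7")
        self._write(tmp_path, "cuticle", "hyp7")
        with pytest.raises(ValueError, match="hyp7"):
            read_collection(tmp_path)

    def test_empty_root(self, tmp_path):
        with pytest.raises(ValueError, match="no mesh files"):
            read_collection(tmp_path)


class TestBakeTransform:
    def test_identity(self, cube100):
        baked = bake_transform(cube100, AffineTransform.identity())
        np.testing.assert_array_equal(baked.vertices, cube100.vertices)
        np.testing.assert_array_equal(baked.faces, cube100.faces)

    def test_uniform_scale_cubes_volume(self, unit_cube):
        baked = bake_transform(unit_cube, AffineTransform.scaling(2.0))
        assert signed_volume(baked) == pytest.approx(8.0, rel=1e-12)

    def test_mirror_preserves_sign(self, unit_cube):
        mirror = AffineTransform(np.diag([-1.0, 1.0, 1.0]))
        baked = bake_transform(unit_cube, mirror)
        assert signed_volume(baked) == pytest.approx(
            signed_volume(unit_cube), rel=1e-12
        )

    def test_singular_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.zeros((3, 3)))

    @given(
        a=st.lists(st.floats(-2, 2), min_size=9, max_size=9),
        b=st.lists(st.floats(-2, 2), min_size=9, max_size=9),
        t1=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        t2=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_bake_composes(self, a, b, t1, t2, ):
        la = np.asarray(a).reshape(3, 3) + np.eye(3) * 3  # keep invertible
        lb = np.asarray(b).reshape(3, 3) + np.eye(3) * 3
        if abs(np.linalg.det(la)) < 1e-6 or abs(np.linalg.det(lb)) < 1e-6:
            return
        mesh = make_box((1, 2, 3))
        ta = AffineTransform(la, t1)
        tb = AffineTransform(lb, t2)
        two_step = bake_transform(bake_transform(mesh, ta), tb)
        one_step = bake_transform(mesh, tb.compose(ta))
        np.testing.assert_allclose(
            two_step.vertices, one_step.vertices, rtol=1e-12, atol=1e-12
        )
        np.testing.assert_array_equal(two_step.faces, one_step.faces)


class TestMeshInvariants:
    def test_face_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            TriangleMesh("m", [(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1, 3)])

    def test_repeated_vertex_in_face(self):
        with pytest.raises(ValueError, match="twice"):
            TriangleMesh("m", [(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1, 1)])

    def test_nonfinite_vertex(self):
        with pytest.raises(ValueError, match="finite"):
            TriangleMesh(
                "m", [(0, 0, 0), (np.nan, 0, 0), (0, 1, 0)], [(0, 1, 2)]
            )
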