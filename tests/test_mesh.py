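"""Mesh container, I/O round trips, and the preprocessing operators."""

import numpy as np
import pytest
import trimesh

from ssmrec.geometry import SurfaceQuery
from ssmrec.mesh import (
    EmptyMeshError,
    MeshFormatError,
    TriangleMesh,
    make_watertight,
    merge_fragments,
    mirror_sagittal,
    quality_report,
    read_mesh,
    remesh_isotropic,
    wrap_fragment,
    write_mesh,
)

TETRA = TriangleMesh(
    vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
    faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
    name="tetra",
)


def sphere_mesh(subdivisions=3, radius=1.0):
    s = trimesh.creation.icosphere(subdivisions=subdivisions)
    return TriangleMesh(np.asarray(s.vertices) * radius, np.asarray(s.faces), "sphere")


# -- container invariants ----------------------------------------------


def test_invalid_meshes_rejected():
    with pytest.raises(ValueError):
        TriangleMesh([[0, 0, 0]], [[0, 0, 1]])  # face index out of range + degenerate
    with pytest.raises(ValueError):
        TriangleMesh([[0, 0, np.nan]], np.zeros((0, 3)))
    with pytest.raises(ValueError):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]])


# -- I/O ----------------------------------------------------------------


@pytest.mark.parametrize("ext", ["stl", "ply", "obj"])
def test_roundtrip_tetrahedron(tmp_path, ext):
    path = tmp_path / f"tetra.{ext}"
    write_mesh(TETRA, path)
    back = read_mesh(path)
    # vertex sets equal (order may change with deduplication)
    a = np.asarray(sorted(map(tuple, np.round(TETRA.vertices, 9))))
    b = np.asarray(sorted(map(tuple, np.round(back.vertices, 9))))
    np.testing.assert_allclose(a, b, atol=1e-6)
    assert back.n_faces == 4
    assert back.is_watertight


def test_stl_duplicate_vertices_merged(tmp_path):
    box = trimesh.creation.box(extents=(1, 1, 1))
    path = tmp_path / "cube.stl"
    box.export(str(path))  # STL stores 3 loose vertices per facet
    cube = read_mesh(path)
    assert cube.n_vertices == 8
    assert cube.n_faces == 12


def test_read_empty_and_corrupt_files(tmp_path):
    empty = tmp_path / "empty.stl"
    empty.touch()
    with pytest.raises(EmptyMeshError):
        read_mesh(empty)
    bad = tmp_path / "bad.ply"
    bad.write_bytes(b"ply\nformat binary_little_endian 1.0\nelement vertex 10\n")
    with pytest.raises((MeshFormatError, EmptyMeshError)):
        read_mesh(bad)
    with pytest.raises(MeshFormatError):
        read_mesh(tmp_path / "x.xyz")


def test_write_pointcloud_requires_flag(tmp_path):
    cloud = TriangleMesh(np.random.default_rng(0).normal(size=(5, 3)), np.zeros((0, 3)))
    with pytest.raises(EmptyMeshError):
        write_mesh(cloud, tmp_path / "pc.ply")


def test_units_scale_applied_on_read(tmp_path):
    path = tmp_path / "t.ply"
    write_mesh(TETRA, path)
    scaled = read_mesh(path, units_scale=10.0)
    assert scaled.bbox_diagonal() == pytest.approx(10.0 * TETRA.bbox_diagonal(), rel=1e-6)


def test_large_mesh_roundtrip_binary_exact(tmp_path, template_small):
    path = tmp_path / "tpl.ply"
    write_mesh(template_small.mesh, path)
    back = read_mesh(path)
    assert back.n_vertices == template_small.mesh.n_vertices
    d = np.linalg.norm(
        np.asarray(sorted(map(tuple, back.vertices)))
        - np.asarray(sorted(map(tuple, template_small.mesh.vertices))),
        axis=1,
    )
    assert d.max() < 1e-6


# -- remeshing ----------------------------------------------------------


def test_remesh_sphere_reaches_target_statistics():
    m = sphere_mesh()
    out = remesh_isotropic(m, target_edge=0.3)
    q = quality_report(out)
    assert 0.225 <= q.mean_edge_length <= 0.375
    assert q.edge_length_cv <= 0.35
    assert q.is_watertight
    # surface deviation bounded by the target edge
    _, d, _ = SurfaceQuery(m.vertices, m.faces).closest(out.vertices)
    assert d.max() <= 0.3
    # smooth shape: area preserved within 5%
    assert abs(out.area - m.area) / m.area <= 0.05


def test_remesh_identity_scale_preserves_area():
    m = sphere_mesh()
    target = float(m.edge_lengths().mean())
    out = remesh_isotropic(m, target_edge=target)
    assert abs(out.area - m.area) / m.area <= 0.05
    _, d, _ = SurfaceQuery(m.vertices, m.faces).closest(out.vertices)
    assert d.max() <= target


def test_remesh_vertex_count_tracks_area(template_small):
    mesh = template_small.mesh
    target = 3.0
    out = remesh_isotropic(mesh, target)
    # equilateral-triangle estimate of the face count
    expected_faces = mesh.area / (np.sqrt(3) / 4 * target**2)
    assert expected_faces / 2 <= out.n_faces <= expected_faces * 2


def test_remesh_parameter_errors():
    m = sphere_mesh(2)
    with pytest.raises(ValueError):
        remesh_isotropic(m, target_edge=1e4)
    with pytest.raises(ValueError):
        remesh_isotropic(m, target_edge=-1.0)
    with pytest.raises(EmptyMeshError):
        remesh_isotropic(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3))), 1.0)


# -- watertight closing -------------------------------------------------


def test_fill_single_triangle_hole():
    m = sphere_mesh(2)
    holed = TriangleMesh(m.vertices, m.faces[1:], "holed")
    assert not holed.is_watertight
    fixed = make_watertight(holed)
    assert fixed.is_watertight
    assert fixed.n_faces - holed.n_faces in (1, 2)


def test_watertight_input_unchanged():
    m = sphere_mesh(2)
    out = make_watertight(m)
    assert out.n_faces == m.n_faces
    np.testing.assert_array_equal(out.vertices, m.vertices)


def test_large_hole_respects_perimeter_threshold():
    m = sphere_mesh(3)
    hemi_faces = m.faces[m.vertices[m.faces].mean(axis=1)[:, 2] <= 0]
    hemi = TriangleMesh(m.vertices, hemi_faces)
    # equator perimeter ~ 2*pi > 1 -> left open
    still_open = make_watertight(hemi, hole_fill_max_perimeter=1.0)
    assert not still_open.is_watertight
    closed = make_watertight(hemi, hole_fill_max_perimeter=100.0)
    assert closed.is_watertight


def test_wrap_fragment_closes_and_keeps_largest_component():
    m = sphere_mesh(2)
    far = TriangleMesh(TETRA.vertices + 50.0, TETRA.faces)
    both = merge_fragments([TriangleMesh(m.vertices, m.faces[1:]), far])
    wrapped = wrap_fragment(both)
    assert wrapped.is_watertight
    assert wrapped.n_connected_components() == 1
    assert wrapped.n_vertices > 4  # the sphere survived, not the tetra


# -- merging ------------------------------------------------------------


def test_merge_two_tetrahedra_additive():
    other = TriangleMesh(TETRA.vertices + 10.0, TETRA.faces)
    merged = merge_fragments([TETRA, other])
    assert merged.n_vertices == 8
    assert merged.n_faces == 8
    assert merged.n_connected_components() == 2


def test_merge_identity_and_errors():
    single = merge_fragments([TETRA])
    np.testing.assert_array_equal(single.vertices, TETRA.vertices)
    np.testing.assert_array_equal(single.faces, TETRA.faces)
    with pytest.raises(EmptyMeshError):
        merge_fragments([])


def test_merge_associative_in_vertex_count():
    parts = [TriangleMesh(TETRA.vertices + 10.0 * i, TETRA.faces) for i in range(3)]
    left = merge_fragments([merge_fragments(parts[:2]), parts[2]])
    right = merge_fragments([parts[0], merge_fragments(parts[1:])])
    np.testing.assert_allclose(
        np.sort(left.vertices, axis=0), np.sort(right.vertices, axis=0)
    )
    assert left.n_faces == right.n_faces == 12
    assert left.n_connected_components() == 3


# -- mirroring ----------------------------------------------------------


def test_mirror_reflects_and_inverts():
    m = TriangleMesh([[1, 2, 3], [0, 1, 0], [0, 0, 1]], [[0, 1, 2]])
    out = mirror_sagittal(m)
    np.testing.assert_allclose(out.vertices[0], [-1, 2, 3])
    twice = mirror_sagittal(out)
    np.testing.assert_allclose(twice.vertices, m.vertices, atol=1e-9)


def test_mirror_preserves_volume_and_distances():
    m = sphere_mesh(2, radius=3.0)
    out = mirror_sagittal(m, plane_normal=(1, 1, 0), plane_point=(1, 0, 0))
    assert out.signed_volume() == pytest.approx(m.signed_volume(), rel=1e-9)
    rng = np.random.default_rng(3)
    i, j = rng.integers(0, m.n_vertices, size=(2, 20))
    before = np.linalg.norm(m.vertices[i] - m.vertices[j], axis=1)
    after = np.linalg.norm(out.vertices[i] - out.vertices[j], axis=1)
    np.testing.assert_allclose(before, after, atol=1e-9)


def test_mirror_zero_normal_rejected():
    with pytest.raises(ValueError):
        mirror_sagittal(TETRA, plane_normal=(0, 0, 0))


def test_quality_report_counts(template_small):
    q = quality_report(template_small.mesh)
    assert q.n_vertices == template_small.mesh.n_vertices
    assert q.n_faces == template_small.mesh.n_faces
    assert q.is_watertight
    assert q.n_connected_components == 1
    assert q.mean_edge_length > 0
    assert "n_vertices" in q.to_json()
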