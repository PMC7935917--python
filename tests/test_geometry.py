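"""Geometry synthesis: rectangle meshes, folded outlines, polygon meshing, I/O."""

import numpy as np
import pytest

from corollafold import (
    FormatError,
    GeometryError,
    Polygon2D,
    TriMesh,
    polygon_mesh,
    read_outline,
    rectangle_mesh,
    synthetic_folded_outline,
    write_outline,
)
from conftest import mirror_node_map


def brute_force_simple(vertices):
    """O(n^2) segment-intersection check that a closed polygon is simple."""
    n = len(vertices)
    segs = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]

    def cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    def intersects(p1, p2, p3, p4):
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            if intersects(*segs[i], *segs[j]):
                return False
    return True


class TestRectangleMesh:
    def test_node_and_triangle_counts(self):
        m = rectangle_mesh(0.1, 0.8, 2, 16)
        assert len(m.nodes) == 51
        assert len(m.triangles) == 64
        base = m.nodes[m.boundary_nodes("base")]
        assert np.allclose(base[:, 1], 0.0)
        assert np.isclose(base[:, 0].min(), 0.0)
        assert np.isclose(base[:, 0].max(), 0.1)

    @pytest.mark.parametrize("nx,ny", [(1, 1), (4, 32), (3, 7)])
    def test_positive_areas_partition_rectangle(self, nx, ny):
        m = rectangle_mesh(0.1, 0.8, nx, ny)
        areas = m.signed_areas()
        assert np.all(areas > 0)
        assert np.isclose(areas.sum(), 0.1 * 0.8, rtol=1e-12)

    def test_mirror_symmetric_triangulation(self):
        m = rectangle_mesh(0.1, 0.8, 4, 32)
        mapping = mirror_node_map(m, 0.1)
        tris = {frozenset(t) for t in m.triangles.tolist()}
        mirrored = {frozenset(mapping[t].tolist()) for t in m.triangles}
        assert tris == mirrored

    def test_boundary_tags_cover_perimeter(self):
        m = rectangle_mesh(1.0, 2.0, 3, 4)
        assert set(m.boundary_edges) == {"base", "top", "left", "right"}
        n_edges = sum(len(e) for e in m.boundary_edges.values())
        assert n_edges == 2 * (3 + 4)

    @pytest.mark.parametrize("bad", [dict(width=0), dict(height=-1),
                                     dict(nx=0), dict(ny=0)])
    def test_invalid_dimensions_raise(self, bad):
        kwargs = dict(width=0.1, height=0.8, nx=2, ny=2)
        kwargs.update(bad)
        with pytest.raises(GeometryError):
            rectangle_mesh(**kwargs)


class TestTriMeshInvariants:
    def test_index_out_of_range_rejected(self):
        with pytest.raises(GeometryError, match="out of range"):
            TriMesh(nodes=np.zeros((3, 2)), triangles=np.array([[0, 1, 3]]))

    def test_repeated_index_rejected(self):
        nodes = np.array([[0, 0], [1, 0], [0, 1]], float)
        with pytest.raises(GeometryError, match="repeated"):
            TriMesh(nodes=nodes, triangles=np.array([[0, 1, 1]]))

    def test_negative_area_rejected(self):
        nodes = np.array([[0, 0], [1, 0], [0, 1]], float)
        with pytest.raises(GeometryError, match="area"):
            TriMesh(nodes=nodes, triangles=np.array([[0, 2, 1]]))

    def test_open_boundary_loop_rejected(self):
        nodes = np.array([[0, 0], [1, 0], [0, 1]], float)
        with pytest.raises(GeometryError, match="closed"):
            TriMesh(
                nodes=nodes,
                triangles=np.array([[0, 1, 2]]),
                boundary_edges={"partial": np.array([[0, 1]])},
            )


class TestSyntheticFoldedOutline:
    def test_zero_folds_degenerates_to_rectangle(self):
        poly = synthetic_folded_outline(0.8, 0.1, 0, 0.0, n_points=40)
        v = poly.vertices
        assert np.isclose(v[:, 0].min(), 0.0, atol=1e-12)
        assert np.isclose(v[:, 0].max(), 0.1, atol=1e-12)
        on_sides = np.isclose(v[:, 0], 0, atol=1e-12) | np.isclose(
            v[:, 0], 0.1, atol=1e-12
        )
        assert on_sides.all()
        assert np.isclose(poly.area, 0.08, rtol=1e-9)

    def test_deterministic_given_seed(self):
        a = synthetic_folded_outline(3.0, 0.4, 2, 0.08, 120, seed=1, jitter=0.01)
        b = synthetic_folded_outline(3.0, 0.4, 2, 0.08, 120, seed=1, jitter=0.01)
        assert np.array_equal(a.vertices, b.vertices)
        c = synthetic_folded_outline(3.0, 0.4, 2, 0.08, 120, seed=2, jitter=0.01)
        assert not np.array_equal(a.vertices, c.vertices)

    @pytest.mark.parametrize(
        "n_folds,depth", [(0, 0.0), (1, 0.2), (2, 0.08), (3, 0.03)]
    )
    def test_simple_by_brute_force(self, n_folds, depth):
        poly = synthetic_folded_outline(3.0, 0.3, n_folds, depth, 100)
        assert brute_force_simple(poly.vertices)

    def test_too_tight_fold_reports_index(self):
        with pytest.raises(GeometryError, match="fold"):
            synthetic_folded_outline(1.0, 0.5, 4, 0.4, 100)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_folds=-1), dict(fold_depth=0.5), dict(n_points=10)],
    )
    def test_parameter_validation(self, kwargs):
        base = dict(height=1.0, width=0.2, n_folds=1, fold_depth=0.1,
                    n_points=50)
        base.update(kwargs)
        with pytest.raises(GeometryError):
            synthetic_folded_outline(**base)


class TestPolygonMesh:
    def test_unit_square_area_conserved(self):
        sq = Polygon2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        m = polygon_mesh(sq, 0.5)
        assert np.isclose(m.area, 1.0, atol=1e-10)

    def test_folded_outline_area_matches_shoelace(self):
        poly = synthetic_folded_outline(3.0, 0.4, 2, 0.08, 160)
        m = polygon_mesh(poly, 0.05)
        assert abs(m.area - poly.area) < 0.005 * poly.area

    def test_refinement_increases_triangle_count_and_quality(self):
        poly = synthetic_folded_outline(3.0, 0.4, 2, 0.08, 160)
        coarse = polygon_mesh(poly, 0.05)
        fine = polygon_mesh(poly, 0.025)
        assert len(fine.triangles) > len(coarse.triangles)
        assert coarse.min_angle_deg() >= 15.0
        assert fine.min_angle_deg() >= 15.0

    def test_max_edge_bounded(self):
        poly = synthetic_folded_outline(3.0, 0.4, 2, 0.08, 160)
        h = 0.05
        m = polygon_mesh(poly, h)
        p = m.nodes[m.triangles]
        for k in range(3):
            assert np.all(
                np.linalg.norm(p[:, (k + 1) % 3] - p[:, k], axis=1) <= 2 * h
            )

    def test_boundary_tagged_outline(self):
        sq = Polygon2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        m = polygon_mesh(sq, 0.5)
        assert set(m.boundary_edges) == {"outline"}

    def test_invalid_target_edge(self):
        sq = Polygon2D(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        with pytest.raises(GeometryError):
            polygon_mesh(sq, 0.0)


class TestOutlineIO:
    def test_round_trip_identity(self, tmp_path):
        poly = Polygon2D(np.array([[0, 0], [2, 0], [2, 1], [0, 1]], float))
        path = tmp_path / "square.csv"
        write_outline(poly, path)
        back = read_outline(path)
        assert np.allclose(back.vertices, poly.vertices, atol=1e-9)

    def test_round_trip_folded(self, tmp_path):
        poly = synthetic_folded_outline(3.0, 0.4, 2, 0.08, 100)
        path = tmp_path / "folded.csv"
        write_outline(poly, path)
        back = read_outline(path)
        assert np.allclose(back.vertices, poly.vertices, atol=1e-9)

    def test_too_few_vertices(self, tmp_path):
        path = tmp_path / "two.csv"
        path.write_text("x_mm,y_mm\n0,0\n1,0\n")
        with pytest.raises(FormatError, match="3 vertices"):
            read_outline(path)

    def test_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("x_mm,y_mm\n")
        with pytest.raises(FormatError):
            read_outline(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x_mm,y_mm\n0,0\n1,zero\n1,1\n")
        with pytest.raises(FormatError, match="line 3"):
            read_outline(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "nohdr.csv"
        path.write_text("0,0\n1,0\n1,1\n")
        with pytest.raises(FormatError, match="header"):
            read_outline(path)


class TestPolygon2D:
    def test_orientation_normalized_ccw(self):
        cw = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], float)
        poly = Polygon2D(cw)
        assert poly.area > 0

    def test_self_intersecting_rejected(self):
        bow = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        with pytest.raises(GeometryError):
            Polygon2D(bow)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError, match="3"):
            Polygon2D(np.array([[0, 0], [1, 0]], float))
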