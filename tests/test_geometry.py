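import numpy as np
import pytest

from embryovar import geometry, synthetic
from embryovar.geometry import (
    NeighbourGraph,
    assign_spots_to_cells,
    build_cell_polygons,
    convex_polygon,
    detect_contact_neighbours,
    detect_radius_neighbours,
    neighbour_count_histogram,
    polygon_pair_distance,
)
from embryovar.tables_io import SpotRecord

from oracles import random_hull_pair, sampled_surface_distance


def _cube(offset=(0.0, 0.0, 0.0), cell_id="cube"):
    pts = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    ) + np.asarray(offset)
    return convex_polygon(cell_id, pts)


def _spots(points, cell_id, kind="membrane"):
    return [
        SpotRecord(f"{cell_id}-{i}", kind, float(p[0]), float(p[1]), float(p[2]),
                   cell_id=cell_id)
        for i, p in enumerate(points)
    ]


class TestHulls:
    def test_unit_cube_volume_and_vertices(self):
        cube = _cube()
        assert cube.volume_um3 == pytest.approx(1.0)
        assert len(cube.vertices) == 8
        assert cube.centroid == pytest.approx([0.5, 0.5, 0.5])

    def test_coplanar_cell_reported_degenerate(self):
        spots = _spots([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)], "flat")
        polygons, degenerate = build_cell_polygons(spots)
        assert degenerate == ["flat"] and polygons == {}

    def test_identical_points_degenerate(self):
        polygons, degenerate = build_cell_polygons(_spots([(1, 1, 1)] * 6, "point"))
        assert degenerate == ["point"]

    def test_zero_spots_is_empty_not_error(self):
        assert build_cell_polygons([]) == ({}, [])

    def test_every_source_spot_satisfies_hull_halfspaces(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(200, 3))
        pts /= np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1.0)
        poly = convex_polygon("ball", pts)
        assert poly.contains(pts, tol=1e-9).all()
        assert poly.contains(poly.centroid).all()


class TestPairDistance:
    def test_parallel_faces_gap(self):
        assert polygon_pair_distance(_cube(), _cube((2, 0, 0))) == pytest.approx(1.0)

    def test_overlap_is_zero(self):
        assert polygon_pair_distance(_cube(), _cube((0.5, 0.2, 0.0))) == 0.0

    def test_crossing_without_vertex_containment_is_zero(self):
        # long thin box through the middle of the cube: hulls intersect but
        # neither contains a vertex of the other
        bar = convex_polygon(
            "bar",
            np.array([[x, y, z] for x in (-2, 3) for y in (0.4, 0.6) for z in (0.4, 0.6)],
                     dtype=float),
        )
        assert polygon_pair_distance(_cube(), bar) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_boundary_sampling_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_hull_pair(rng)
        d_impl = polygon_pair_distance(a, b)
        d_oracle = sampled_surface_distance(a, b, seed=seed)
        assert d_impl == pytest.approx(d_oracle, abs=1e-3)


class TestContactNeighbours:
    def test_expansion_threshold_is_twice_r(self):
        a = _cube((0, 0, 0), "a")
        near = _cube((2.0, 0, 0), "b")  # 1.0 gap < 1.2
        far = _cube((2.5, 0, 0), "b")  # 1.5 gap > 1.2
        assert detect_contact_neighbours({"a": a, "b": near}, 0.6).edges == {("a", "b")}
        assert detect_contact_neighbours({"a": a, "b": far}, 0.6).edges == set()

    def test_tie_at_exactly_two_r_is_not_adjacent(self):
        g = detect_contact_neighbours({"a": _cube((0, 0, 0), "a"),
                                       "b": _cube((2.2, 0, 0), "b")}, 0.6)
        assert g.edges == set()

    def test_single_polygon_graph_has_node_no_edges(self):
        g = detect_contact_neighbours({"a": _cube()}, 0.6)
        assert g.cells == {"a"} and g.edges == set()

    def test_hex_monolayer_centre_cell_has_six_neighbours(self):
        params = synthetic.SimParams(
            n_cells_target=19, membrane_jitter_um=0.0, seed=5, aspect=2.0
        )
        embryo = synthetic.generate_embryo(params)
        polygons, _ = build_cell_polygons(embryo.membrane_spots)
        g = detect_contact_neighbours(polygons, 0.6)
        g.validate()
        centres = np.array([c.centroid[:2] for c in embryo.cells])
        mid = np.argmin(np.linalg.norm(centres - centres.mean(axis=0), axis=1))
        assert g.degree(embryo.cells[mid].cell_id) == 6

    def test_edge_set_monotone_in_expansion(self, small_embryo):
        polygons, _ = build_cell_polygons(small_embryo.membrane_spots)
        prev = set()
        for r in (0.2, 0.6, 1.0):
            edges = detect_contact_neighbours(polygons, r).edges
            assert prev <= edges
            prev = edges


class TestRadiusNeighbours:
    def test_chain_interior_cells_have_two_neighbours(self):
        cents = {f"c{i}": (float(i), 0.0, 0.0) for i in range(10)}
        g = detect_radius_neighbours(cents, 1.1)
        g.validate()
        for i in range(1, 9):
            assert g.degree(f"c{i}") == 2
        assert g.degree("c0") == g.degree("c9") == 1

    def test_zero_radius_gives_no_edges(self):
        g = detect_radius_neighbours({"a": (0, 0, 0), "b": (0, 0, 0)}, 0.0)
        assert g.edges == set()

    def test_edge_set_monotone_in_radius(self):
        rng = np.random.default_rng(8)
        cents = {f"c{i}": tuple(rng.uniform(0, 20, 3)) for i in range(60)}
        prev = set()
        for radius in (2.0, 4.0, 8.0):
            edges = detect_radius_neighbours(cents, radius).edges
            assert prev <= edges
            prev = edges


class TestSpotAssignment:
    def test_spot_in_lone_cell_takes_its_id(self):
        spot = SpotRecord("r1", "mrna", 0.5, 0.5, 0.5, gene="eve")
        out = assign_spots_to_cells([spot], {"cube": _cube()})
        assert out[0].cell_id == "cube"
        assert out[0].extra["assignment"] == "unique"

    def test_spot_outside_all_hulls_unassigned(self):
        spot = SpotRecord("r1", "mrna", 11.0, 0.5, 0.5, gene="eve")
        out = assign_spots_to_cells([spot], {"cube": _cube()})
        assert out[0].cell_id == "" and out[0].extra["assignment"] == "unassigned"

    def test_overlapping_hulls_resolve_to_nearest_centroid(self):
        a = _cube((0, 0, 0), "a")
        b = _cube((0.5, 0, 0), "b")  # overlap region x in [0.5, 1.0]
        spot = SpotRecord("r1", "mrna", 0.6, 0.5, 0.5, gene="eve")
        out = assign_spots_to_cells([spot], {"a": a, "b": b})
        assert out[0].cell_id == "a"  # centroid at 0.5 vs 1.0
        assert out[0].extra["assignment"] == "ambiguous"

    def test_inset_synthetic_spots_recover_generating_cells(self):
        params = synthetic.SimParams(n_cells_target=40, seed=9, membrane_jitter_um=0.0)
        embryo = synthetic.generate_embryo(params)
        polygons, _ = build_cell_polygons(embryo.membrane_spots)
        out = assign_spots_to_cells(embryo.mrna_spots, polygons)
        assert all(r.cell_id == r.extra["true_cell_id"] for r in out)


class TestDegreeHistogram:
    def test_triangle_graph(self):
        g = NeighbourGraph.from_edges(
            "abc", [("a", "b"), ("b", "c"), ("a", "c")], "contact")
        assert neighbour_count_histogram(g) == {2: 3}

    def test_isolated_cell(self):
        g = NeighbourGraph.from_edges(["a"], [], "contact")
        assert neighbour_count_histogram(g) == {0: 1}

    def test_counts_sum_to_cells(self, small_embryo):
        g = small_embryo.true_adjacency
        hist = neighbour_count_histogram(g)
        assert sum(hist.values()) == g.n_cells()


class TestGraphInvariants:
    def test_self_edges_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            NeighbourGraph.from_edges(["a"], [("a", "a")], "contact")

    def test_edges_outside_cell_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            NeighbourGraph.from_edges(["a"], [("a", "b")], "contact")

    def test_generated_graphs_symmetric_irreflexive(self, small_embryo):
        polygons, _ = build_cell_polygons(small_embryo.membrane_spots)
        for g in (
            detect_contact_neighbours(polygons, 0.6),
            detect_radius_neighbours({c: p.centroid for c, p in polygons.items()}, 7.0),
        ):
            g.validate()
            for a, b in g.edges:
                assert a in g.neighbours(b) and b in g.neighbours(a)
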