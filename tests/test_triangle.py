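"""Tests for the 2-D (MISC+REJ) partition of the clinical triangle.

The face enumeration is cross-checked against shapely's polygonizer, an
independent geometric engine, and against Monte-Carlo winner counting.
"""

from fractions import Fraction

import pytest
from shapely.geometry import MultiLineString
from shapely.ops import polygonize, unary_union

from costspace import (
    BoundaryLine,
    PredictorProfile,
    ValidationError,
    boundary_line,
    build_arrangement,
    enumerate_faces,
    generate_profiles,
    interval_fractions,
    merge_regions,
    oracle_fractions,
    partition_grouped,
    partition_interval,
    partition_triangle,
)
from costspace.triangle import TRIANGLE_AREA, assign_best_predictor

F = Fraction


def line(a, b, c):
    return BoundaryLine(F(a), F(b), F(c))


class TestBuildArrangement:
    def test_empty_arrangement_is_the_triangle(self):
        g = build_arrangement([])
        assert len(g.vertices) == 3 and len(g.edges) == 3

    def test_single_interior_line_counts(self):
        # a line through (1/5, 0) and (0, 3/10): two sides crossed interiorly
        g = build_arrangement([line(3, 2, F(-3, 5))])
        assert len(g.vertices) == 5 and len(g.edges) == 6

    def test_concurrent_lines_share_one_vertex(self):
        # three lines through (1/4, 1/4)
        lines = [line(1, -1, 0), line(1, 1, F(-1, 2)), line(1, 0, F(-1, 4))]
        g = build_arrangement(lines)
        assert g.vertices.count((F(1, 4), F(1, 4))) == 1

    def test_coincident_and_outside_lines_dropped(self):
        g = build_arrangement(
            [
                line(1, -1, 0),
                line(-2, 2, 0),        # same locus, rescaled
                line(1, 1, -5),        # far outside T
                line(1, 1, -1),        # the hypotenuse itself
                BoundaryLine(F(0), F(0), F(0)),   # coincident pair
                BoundaryLine(F(0), F(0), F(1)),   # empty locus
            ]
        )
        faces = enumerate_faces(g)
        assert len(faces) == 2  # only the diagonal survives


class TestEnumerateFaces:
    def test_no_lines_single_face(self):
        faces = enumerate_faces(build_arrangement([]))
        assert len(faces) == 1 and faces[0].area == TRIANGLE_AREA

    def test_one_crossing_line_two_faces(self):
        faces = enumerate_faces(build_arrangement([line(1, -1, 0)]))
        assert len(faces) == 2
        assert sum(f.area for f in faces) == TRIANGLE_AREA

    def test_two_generic_lines_four_faces(self):
        faces = enumerate_faces(
            build_arrangement([line(1, -1, F(1, 10)), line(1, 1, F(-1, 2))])
        )
        assert len(faces) == 4
        assert sum(f.area for f in faces) == TRIANGLE_AREA

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_faces_match_shapely_polygonize(self, seed):
        """Face count and areas agree with an independent polygonizer."""
        profs = generate_profiles(6, seed=seed)
        lines = [
            boundary_line(profs[i], profs[j], 0.3)
            for i in range(5)
            for j in range(i + 1, 6)
        ]
        faces = enumerate_faces(build_arrangement(lines))

        tri = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (0.0, 0.0)]
        segs = [tri]
        for ln in lines:
            if ln.coincident or ln.is_empty:
                continue
            a, b, c = float(ln.a), float(ln.b), float(ln.c)
            # extended chord; polygonize needs noded input -> node via union
            if b != 0:
                segs.append([(-2.0, (-c + 2 * a) / b), (3.0, (-c - 3 * a) / b)])
            else:
                segs.append((( -c / a, -2.0), (-c / a, 3.0)))
        noded = unary_union(MultiLineString(segs))
        # float noding splits each concurrency point (l_ij, l_jk, l_ik always
        # meet at one point) into sliver polygons; drop those before comparing
        polys = [
            p
            for p in polygonize(noded)
            if p.area > 1e-10
            and p.representative_point().x + p.representative_point().y < 1
            and p.representative_point().x > 0
            and p.representative_point().y > 0
        ]
        assert len(polys) == len(faces)
        ours = sorted(float(f.area) for f in faces)
        theirs = sorted(p.area for p in polys)
        assert ours == pytest.approx(theirs, abs=1e-8)
        assert sum(theirs) == pytest.approx(0.5, abs=1e-8)

    @pytest.mark.parametrize("seed,rho", [(1, 0.5), (5, 0.001)])
    def test_faces_are_convex_and_disjoint(self, seed, rho):
        profs = generate_profiles(7, seed=seed)
        lines = [
            boundary_line(profs[i], profs[j], rho)
            for i in range(len(profs) - 1)
            for j in range(i + 1, len(profs))
        ]
        faces = enumerate_faces(build_arrangement(lines))
        assert all(f.is_convex() for f in faces)
        assert sum(f.area for f in faces) == TRIANGLE_AREA
        # interiors are pairwise disjoint: representative points are unique
        # and each lies in exactly one face
        for f in faces:
            rp = f.representative_point
            assert sum(1 for g in faces if g.contains(rp)) == 1


class TestAssignAndMerge:
    def test_single_profile_wins_any_polygon(self):
        faces = enumerate_faces(build_arrangement([]))
        p = PredictorProfile("solo", 0.6, 0.6, 0.8)
        winner, tied = assign_best_predictor(faces[0], [p], 0.5)
        assert winner == "solo" and tied == ("solo",)

    def test_two_predictor_sides_of_diagonal(self, crossing_pair):
        """Winners on each side of the rc0 = rc1 boundary match direct costs."""
        a, b = crossing_pair
        part = partition_triangle([a, b], 0.5)
        assert part.fractions == {"A": 0.5, "B": 0.5}
        from costspace import miscrej_normalized_cost

        for region in part.regions:
            for poly in region.polygons:
                rx, ry = poly.representative_point
                costs = {
                    p.name: miscrej_normalized_cost(p, 0.5, (rx, ry)) for p in (a, b)
                }
                assert min(costs, key=costs.get) == region.predictor

    def test_perfect_predictor_beats_all_reject(self):
        perfect = PredictorProfile("perfect", 1, 1, 1)
        rejector = PredictorProfile("rejector", 0.99, 0.99, 0)
        part = partition_triangle([rejector, perfect], 0.5)
        assert part.fractions == {"perfect": 1.0}

    def test_all_faces_same_winner_single_region(self):
        dominated = PredictorProfile("worse", 0.6, 0.6, 0.9)
        dominator = PredictorProfile("better", 0.95, 0.95, 1)
        part = partition_triangle([dominated, dominator], 0.25)
        assert part.winners() == ["better"]
        assert float(part.regions[0].area_fraction) == 1.0

    def test_identical_predictors_tie_recorded(self):
        p = PredictorProfile("first", 0.8, 0.7, 0.9)
        q = PredictorProfile("second", 0.8, 0.7, 0.9)
        part = partition_triangle([p, q], 0.5)
        assert part.winners() == ["first"]
        assert set(part.regions[0].ties) == {"first", "second"}

    def test_merge_requires_tiling(self):
        faces = enumerate_faces(build_arrangement([line(1, -1, 0)]))
        with pytest.raises(RuntimeError):
            merge_regions([(faces[0], "x")])  # one face missing


class TestPartitionTriangle:
    @pytest.mark.parametrize("rho", [0.001, 0.5])
    def test_fractions_sum_to_one(self, rho):
        profs = generate_profiles(9, seed=2)
        part = partition_triangle(profs, rho)
        assert part.total_area == TRIANGLE_AREA
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_agreement(self):
        profs = generate_profiles(8, seed=4)
        part = partition_triangle(profs, 0.1)
        est = oracle_fractions(profs, 0.1, "miscrej", 200_000, seed=8)
        assert est.max_abs_difference(part.fractions) < 0.01

    def test_hypotenuse_consistency_with_interval_partition(self):
        """With every alpha = 1, the hypotenuse inherits the MISC partition."""
        profs = [
            PredictorProfile("P1", 0.9, 0.7),
            PredictorProfile("P2", 0.7, 0.9),
            PredictorProfile("P3", 0.85, 0.85),
        ]
        rho = 0.4
        part = partition_triangle(profs, rho)
        # collect hypotenuse edges of faces, labelled by their region's winner
        spans = []
        for region in part.regions:
            for poly in region.polygons:
                vs = poly.vertices
                for p, q in zip(vs, vs[1:] + vs[:1]):
                    if p[0] + p[1] == 1 and q[0] + q[1] == 1:
                        lo, hi = sorted((p[1], q[1]))
                        spans.append((lo, hi, region.predictor))
        spans.sort()
        assert spans, "no region touches the hypotenuse"
        merged = [spans[0]]
        for lo, hi, name in spans[1:]:
            if name == merged[-1][2] and lo == merged[-1][1]:
                merged[-1] = (merged[-1][0], hi, name)
            else:
                merged.append((lo, hi, name))
        expected = [
            (iv.lo, iv.hi, iv.predictor) for iv in partition_interval(profs, rho)
        ]
        assert merged == expected

    def test_all_zero_coverage_full_tie(self):
        profs = [
            PredictorProfile("a", 0.9, 0.9, 0),
            PredictorProfile("b", 0.5, 0.5, 0),
        ]
        part = partition_triangle(profs, 0.5)
        assert part.winners() == ["a"]
        assert set(part.regions[0].ties) == {"a", "b"}

    def test_duplicate_names_rejected(self):
        p = PredictorProfile("x", 0.9, 0.9)
        with pytest.raises(ValidationError):
            partition_triangle([p, p], 0.5)


class TestPartitionGrouped:
    def test_small_set_identical_to_direct(self):
        profs = generate_profiles(5, seed=1)
        direct = partition_triangle(profs, 0.3)
        grouped = partition_grouped(profs, 0.3, group_size=8)
        assert grouped.fractions == direct.fractions

    @pytest.mark.parametrize("seed", [0, 7])
    def test_large_set_matches_direct_run(self, seed):
        profs = generate_profiles(17, seed=seed)
        direct = partition_triangle(profs, 0.5)
        grouped = partition_grouped(profs, 0.5, group_size=6)
        names = set(direct.fractions) | set(grouped.fractions)
        for nm in names:
            assert grouped.fractions.get(nm, 0.0) == pytest.approx(
                direct.fractions.get(nm, 0.0), abs=1e-3
            )

    def test_group_size_validated(self):
        with pytest.raises(ValidationError):
            partition_grouped(generate_profiles(3, seed=0), 0.5, group_size=1)

    def test_dominated_in_group_never_reappears(self):
        strong = PredictorProfile("strong", 0.99, 0.99, 1)
        weak = [
            PredictorProfile(f"w{i}", 0.5 + 0.01 * i, 0.5, 0.9) for i in range(5)
        ]
        part = partition_grouped([strong] + weak, 0.5, group_size=3)
        assert part.winners() == ["strong"]
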