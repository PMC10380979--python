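"""Partition of the triangular clinical space under the MISC+REJ cost model.

Every pair of predictors defines an equal-cost line in the (rc0, rc1) plane.
The lines that cross the triangle T with vertices (0,0), (1,0), (0,1) carve
it into convex faces; within a face no cost plane crossing occurs, so a
single predictor is cheapest on the whole face.  The pipeline is

    boundary_line -> build_arrangement -> enumerate_faces
                  -> assign_best_predictor -> merge_regions

All geometry runs on exact rational coordinates: intersection points,
shoelace areas and cost comparisons are computed with Fractions, so faces
tile T exactly (areas sum to 1/2) and coincident lines or concurrent
intersection points are recognised by equality, not by tolerance.

Face extraction walks half-edges of the planar arrangement graph: at each
vertex the outgoing edges are sorted by exact angle, and following, from an
incoming edge, the next outgoing edge in clockwise order traces every
bounded face counter-clockwise (the single clockwise cycle is the outer
face and is discarded).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .cost_models import (
    BoundaryLine,
    Number,
    Prevalence,
    PredictorProfile,
    ValidationError,
    boundary_line,
    miscrej_plane_coefficients,
)

__all__ = [
    "TRIANGLE_AREA",
    "TRIANGLE_CORNERS",
    "ArrangementGraph",
    "ConvexPolygon",
    "Region",
    "RegionPartition",
    "build_arrangement",
    "enumerate_faces",
    "assign_best_predictor",
    "merge_regions",
    "partition_triangle",
    "partition_grouped",
]

Point = Tuple[Fraction, Fraction]

F0, F1 = Fraction(0), Fraction(1)
TRIANGLE_CORNERS: Tuple[Point, ...] = ((F0, F0), (F1, F0), (F0, F1))
TRIANGLE_AREA = Fraction(1, 2)

# The three sides of T as lines a*x + b*y + c = 0.
_SIDE_LINES = (
    (F1, F0, F0),    # rc0 = 0
    (F0, F1, F0),    # rc1 = 0
    (F1, F1, -F1),   # rc0 + rc1 = 1
)


def _in_triangle(p: Point) -> bool:
    x, y = p
    return x >= 0 and y >= 0 and x + y <= 1


def _intersect(l1: Tuple[Fraction, Fraction, Fraction],
               l2: Tuple[Fraction, Fraction, Fraction]) -> Optional[Point]:
    a1, b1, c1 = l1
    a2, b2, c2 = l2
    det = a1 * b2 - a2 * b1
    if det == 0:
        return None
    x = (b1 * c2 - b2 * c1) / det
    y = (a2 * c1 - a1 * c2) / det
    return (x, y)


def _canonical(line: Tuple[Fraction, Fraction, Fraction]) -> Tuple[Fraction, ...]:
    for lead in line:
        if lead != 0:
            return tuple(v / abs(lead) for v in line)
    return (F0, F0, F0)


@dataclass
class ArrangementGraph:
    """Planar graph of the boundary-line arrangement clipped to T.

    ``vertices`` are exact points (triangle corners, line-side and line-line
    intersections inside the closed triangle); ``adjacency`` maps each
    vertex index to the sorted set of neighbouring vertex indices.
    """

    vertices: List[Point]
    adjacency: Dict[int, List[int]]

    @property
    def edges(self) -> List[Tuple[int, int]]:
        return [(u, v) for u, nbrs in self.adjacency.items() for v in nbrs if u < v]


@dataclass(frozen=True)
class ConvexPolygon:
    """A convex face of the arrangement, vertices in counter-clockwise order."""

    vertices: Tuple[Point, ...]

    @property
    def area(self) -> Fraction:
        return abs(self.signed_area)

    @property
    def signed_area(self) -> Fraction:
        s = Fraction(0)
        vs = self.vertices
        for (x1, y1), (x2, y2) in zip(vs, vs[1:] + vs[:1]):
            s += x1 * y2 - x2 * y1
        return s / 2

    @property
    def representative_point(self) -> Point:
        """Arithmetic mean of the vertices; interior for a convex polygon."""
        n = len(self.vertices)
        sx = sum(v[0] for v in self.vertices)
        sy = sum(v[1] for v in self.vertices)
        return (sx / n, sy / n)

    def is_convex(self) -> bool:
        """True for a positively oriented convex boundary.

        Collinear vertices are allowed: a face picks one up wherever another
        arrangement line terminates on its edge.
        """
        vs = self.vertices
        n = len(vs)
        if n < 3 or self.signed_area <= 0:
            return False
        for i in range(n):
            ox, oy = vs[i]
            ax, ay = vs[(i + 1) % n]
            bx, by = vs[(i + 2) % n]
            if (ax - ox) * (by - oy) - (ay - oy) * (bx - ox) < 0:
                return False
        return True

    def contains(self, p: Point) -> bool:
        """Closed containment test (exact)."""
        vs = self.vertices
        n = len(vs)
        for i in range(n):
            ax, ay = vs[i]
            bx, by = vs[(i + 1) % n]
            if (bx - ax) * (p[1] - ay) - (by - ay) * (p[0] - ax) < 0:
                return False
        return True

    def as_float_vertices(self) -> List[Tuple[float, float]]:
        return [(float(x), float(y)) for x, y in self.vertices]


@dataclass
class Region:
    """Union of faces sharing one cost-optimal predictor."""

    predictor: str
    polygons: List[ConvexPolygon]
    ties: tuple = field(default=())

    @property
    def area(self) -> Fraction:
        return sum((p.area for p in self.polygons), Fraction(0))

    @property
    def area_fraction(self) -> Fraction:
        return self.area / TRIANGLE_AREA

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "area": float(self.area),
            "fraction": float(self.area_fraction),
            "ties": list(self.ties),
            "polygons": [p.as_float_vertices() for p in self.polygons],
        }


@dataclass
class RegionPartition:
    """The MISC+REJ solution: regions of T and their area fractions."""

    regions: List[Region]

    @property
    def fractions(self) -> Dict[str, float]:
        return {r.predictor: float(r.area_fraction) for r in self.regions}

    @property
    def total_area(self) -> Fraction:
        return sum((r.area for r in self.regions), Fraction(0))

    def winners(self) -> List[str]:
        return [r.predictor for r in self.regions]

    def as_dict(self) -> dict:
        return {"regions": [r.as_dict() for r in self.regions],
                "fractions": self.fractions}


# ---------------------------------------------------------------------------
# arrangement construction


def build_arrangement(lines: Sequence[BoundaryLine]) -> ArrangementGraph:
    """Build the planar graph of boundary lines clipped to the triangle.

    Coincident and empty lines, duplicates of one another or of a triangle
    side, and lines meeting the closed triangle in at most a point are all
    dropped.  Edges are maximal segments between consecutive vertices along
    each surviving line and each triangle side.
    """
    side_canon = {_canonical(s) for s in _SIDE_LINES}
    kept: List[Tuple[Fraction, Fraction, Fraction]] = []
    seen = set(side_canon)
    for ln in lines:
        if ln.coincident or ln.is_empty:
            continue
        canon = _canonical((ln.a, ln.b, ln.c))
        if canon in seen:
            continue
        seen.add(canon)
        kept.append(canon)

    # Keep only lines whose intersection with closed T is a real segment.
    crossing: List[Tuple[Fraction, Fraction, Fraction]] = []
    for ln in kept:
        pts = set()
        for side in _SIDE_LINES:
            p = _intersect(ln, side)
            if p is not None and _in_triangle(p):
                pts.add(p)
        if len(pts) >= 2:
            crossing.append(ln)

    all_lines = list(_SIDE_LINES) + crossing

    # Vertex set: all pairwise intersections inside closed T.  Line
    # membership is recorded as intersections are found, so no separate
    # point-on-line pass is needed (concurrent lines share one vertex via
    # the exact-coordinate index).
    vertex_ix: Dict[Point, int] = {}
    vertices: List[Point] = []
    on_line: List[set] = [set() for _ in all_lines]

    def add_vertex(p: Point) -> int:
        if p not in vertex_ix:
            vertex_ix[p] = len(vertices)
            vertices.append(p)
        return vertex_ix[p]

    for i in range(len(all_lines) - 1):
        for j in range(i + 1, len(all_lines)):
            p = _intersect(all_lines[i], all_lines[j])
            if p is not None and _in_triangle(p):
                ix = add_vertex(p)
                on_line[i].add(ix)
                on_line[j].add(ix)

    # Edges: sort the vertices on each line along its direction.
    adjacency: Dict[int, set] = {i: set() for i in range(len(vertices))}
    for (a, b, _c), members in zip(all_lines, on_line):
        ordered = sorted(
            ((-b) * vertices[ix][0] + a * vertices[ix][1], ix) for ix in members
        )
        for (_, u), (_, v) in zip(ordered[:-1], ordered[1:]):
            adjacency[u].add(v)
            adjacency[v].add(u)

    return ArrangementGraph(vertices, {u: sorted(n) for u, n in adjacency.items()})


def _angle_cmp(d1: Point, d2: Point) -> int:
    """Exact counter-clockwise comparison of two direction vectors."""
    def half(d: Point) -> int:
        x, y = d
        return 0 if (y > 0 or (y == 0 and x > 0)) else 1

    h1, h2 = half(d1), half(d2)
    if h1 != h2:
        return -1 if h1 < h2 else 1
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if cross > 0:
        return -1
    if cross < 0:
        return 1
    return 0


def enumerate_faces(graph: ArrangementGraph) -> List[ConvexPolygon]:
    """Extract the bounded faces of the arrangement as convex polygons."""
    verts = graph.vertices
    order: Dict[int, List[int]] = {}
    pos: Dict[Tuple[int, int], int] = {}
    for u, nbrs in graph.adjacency.items():
        if len(nbrs) == 1:
            raise RuntimeError(f"dangling edge at vertex {verts[u]}")

        def key(v: int, _u: int = u):
            ux, uy = verts[_u]
            vx, vy = verts[v]
            return (vx - ux, vy - uy)

        ccw = sorted(nbrs, key=functools.cmp_to_key(
            lambda p, q: _angle_cmp(key(p), key(q))))
        order[u] = ccw
        for i, v in enumerate(ccw):
            pos[(u, v)] = i

    faces: List[ConvexPolygon] = []
    visited = set()
    for start_u, nbrs in order.items():
        for start_v in nbrs:
            if (start_u, start_v) in visited:
                continue
            cycle = []
            u, v = start_u, start_v
            while (u, v) not in visited:
                visited.add((u, v))
                cycle.append(v)
                # next half-edge: clockwise successor of the reverse edge at v
                i = pos[(v, u)]
                w = order[v][(i - 1) % len(order[v])]
                u, v = v, w
            poly = ConvexPolygon(tuple(verts[i] for i in cycle))
            if poly.signed_area > 0:
                faces.append(poly)

    total = sum((f.area for f in faces), Fraction(0))
    if total != TRIANGLE_AREA:
        raise RuntimeError(
            f"faces do not tile the triangle: total area {total} != 1/2"
        )
    return faces


# ---------------------------------------------------------------------------
# predictor assignment and region merging


def assign_best_predictor(
    polygon: ConvexPolygon,
    profiles: Sequence[PredictorProfile],
    rho: Union[Prevalence, Number],
) -> Tuple[str, tuple]:
    """Cheapest predictor on a face, decided at the vertex-average point.

    No boundary line crosses a face, so the winner at the representative
    point wins the whole face.  Exact ties are broken by input order; the
    tie set is returned alongside.
    """
    if not profiles:
        raise ValidationError("at least one predictor profile is required")
    planes = [miscrej_plane_coefficients(p, rho) for p in profiles]
    return _assign(polygon, planes, [p.name for p in profiles])


def _assign(polygon: ConvexPolygon, planes: list, names: list) -> Tuple[str, tuple]:
    rx, ry = polygon.representative_point
    costs = [A * rx + B * ry + C for A, B, C in planes]
    best = min(costs)
    tied = tuple(nm for nm, c in zip(names, costs) if c == best)
    return tied[0], tied


def merge_regions(
    faces: Sequence[Tuple[ConvexPolygon, str]],
    ties: Optional[Dict[str, tuple]] = None,
) -> RegionPartition:
    """Merge faces with the same winning predictor into regions."""
    total = sum((poly.area for poly, _ in faces), Fraction(0))
    if total != TRIANGLE_AREA:
        raise RuntimeError(
            f"assigned faces do not tile the triangle: total area {total} != 1/2"
        )
    grouped: Dict[str, List[ConvexPolygon]] = {}
    for poly, name in faces:
        grouped.setdefault(name, []).append(poly)
    regions = [
        Region(name, polys, ties=(ties or {}).get(name, ()))
        for name, polys in grouped.items()
    ]
    regions.sort(key=lambda r: r.area, reverse=True)
    return RegionPartition(regions)


def partition_triangle(
    profiles: Sequence[PredictorProfile], rho: Union[Prevalence, Number]
) -> RegionPartition:
    """Full MISC+REJ pipeline: lines, arrangement, faces, winners, regions."""
    if not profiles:
        raise ValidationError("at least one predictor profile is required")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate predictor names in profile list")

    lines = []
    for i in range(len(profiles) - 1):
        for j in range(i + 1, len(profiles)):
            ln = boundary_line(profiles[i], profiles[j], rho)
            if not ln.coincident and not ln.is_empty:
                lines.append(ln)

    # Exact arithmetic yields no zero-area slivers: every traced face with
    # positive area is a genuine arrangement face and participates in the
    # exact tiling of T.
    graph = build_arrangement(lines)
    faces = enumerate_faces(graph)

    planes = [miscrej_plane_coefficients(p, rho) for p in profiles]
    assigned = []
    tie_sets: Dict[str, tuple] = {}
    for face in faces:
        winner, tied = _assign(face, planes, names)
        assigned.append((face, winner))
        if len(tied) > 1:
            prev = tie_sets.get(winner, tied)
            tie_sets[winner] = prev if set(prev) == set(tied) else tuple(
                sorted(set(prev) | set(tied), key=names.index))
    return merge_regions(assigned, ties=tie_sets)


def partition_grouped(
    profiles: Sequence[PredictorProfile],
    rho: Union[Prevalence, Number],
    group_size: int = 8,
) -> RegionPartition:
    """Divide-and-conquer driver for large predictor sets.

    Partitions groups of at most ``group_size`` predictors separately,
    keeps the survivors (nonzero area) of each group, and repeats until one
    direct run suffices.  A predictor dominated within its group never
    reappears.
    """
    if not 2 <= group_size <= 10:
        raise ValidationError("group_size must be in [2, 10]")
    current = list(profiles)
    while len(current) > group_size:
        survivors: List[str] = []
        for k in range(0, len(current), group_size):
            chunk = current[k:k + group_size]
            if len(chunk) == 1:
                survivors.extend(p.name for p in chunk)
                continue
            part = partition_triangle(chunk, rho)
            survivors.extend(r.predictor for r in part.regions if r.area > 0)
        nxt = [p for p in current if p.name in set(survivors)]
        if len(nxt) == len(current):
            break  # no elimination possible; fall through to a direct run
        current = nxt
    return partition_triangle(current, rho)
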