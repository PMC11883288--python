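"""Triangle lineage across remesh boundaries, as a weighted DAG.

Every hour the deformed domain is re-triangulated, so a triangle of hour ``t``
has no identity at hour ``t + 1``.  Lineage is recovered geometrically: the
end-of-hour configuration of mesh ``t`` (its last substep frame, which tiles
the same domain instant as the fresh mesh of hour ``t + 1``) is intersected
with mesh ``t + 1``, and every strictly positive overlap area becomes a
directed edge ``(t, i) -> (t + 1, j)``.  The resulting graph is the substrate
from which tissue tracks are extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import shapely
from shapely.strtree import STRtree

from .errors import ValidationError
from .morphomovie import Morphomovie, TriangleRef, triangle_signed_areas

#: overlaps below MIN_OVERLAP_FRAC x (mean triangle area) are clipping slivers
MIN_OVERLAP_FRAC = 1e-12

#: relative outline-area disagreement above which a warning is emitted
OUTLINE_MISMATCH_RTOL = 0.02


# ---------------------------------------------------------------------------
# Triangle-triangle overlap by Sutherland-Hodgman clipping
# ---------------------------------------------------------------------------

def _shoelace(poly: List[np.ndarray]) -> float:
    area = 0.0
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return 0.5 * area


def _ccw(tri: np.ndarray) -> np.ndarray:
    a, b, c = tri
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
    return tri if cross >= 0 else tri[::-1]


def triangle_overlap_area(a, b) -> float:
    """Area of the intersection of two triangles (0 when disjoint).

    Clips triangle ``a`` against the three half-planes of triangle ``b``
    (Sutherland-Hodgman); the intersection of two convex polygons is convex,
    so its shoelace area is exact up to floating-point rounding.
    """
    a = np.asarray(a, dtype=float).reshape(3, 2)
    b = np.asarray(b, dtype=float).reshape(3, 2)
    for name, tri in (("a", a), ("b", b)):
        p, q, r = tri
        if abs((q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1])) < 1e-300:
            raise ValidationError(f"degenerate input triangle {name}")
    a = _ccw(a)
    b = _ccw(b)

    poly = [a[0], a[1], a[2]]
    for i in range(3):
        cp1, cp2 = b[i], b[(i + 1) % 3]
        ex, ey = cp2[0] - cp1[0], cp2[1] - cp1[1]
        nxt: List[np.ndarray] = []
        if not poly:
            break
        s = poly[-1]
        # ccw clip polygon: a point is inside when cross(edge, point - cp1) >= 0
        s_in = ex * (s[1] - cp1[1]) - ey * (s[0] - cp1[0]) >= 0
        for e in poly:
            e_in = ex * (e[1] - cp1[1]) - ey * (e[0] - cp1[0]) >= 0
            if e_in:
                if not s_in:
                    nxt.append(_intersect(s, e, cp1, cp2))
                nxt.append(e)
            elif s_in:
                nxt.append(_intersect(s, e, cp1, cp2))
            s, s_in = e, e_in
        poly = nxt
    if len(poly) < 3:
        return 0.0
    return abs(_shoelace(poly))


def _intersect(s, e, cp1, cp2) -> np.ndarray:
    dcx, dcy = cp1[0] - cp2[0], cp1[1] - cp2[1]
    dpx, dpy = s[0] - e[0], s[1] - e[1]
    n1 = cp1[0] * cp2[1] - cp1[1] * cp2[0]
    n2 = s[0] * e[1] - s[1] * e[0]
    den = dcx * dpy - dcy * dpx
    return np.array([(n1 * dpx - n2 * dcx) / den, (n1 * dpy - n2 * dcy) / den])


# ---------------------------------------------------------------------------
# Lineage graph
# ---------------------------------------------------------------------------

@dataclass
class LineageGraph:
    """Weighted edges between triangles of consecutive hourly meshes.

    ``edges[t]`` holds three parallel arrays ``(tri_from, tri_to, area)`` for
    the hour boundary ``t -> t + 1``.
    """

    n_hours: int
    n_triangles: List[int]
    edges: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def predecessors(self, t_to: int, j: int) -> Tuple[np.ndarray, np.ndarray]:
        """Triangle indices at hour ``t_to - 1`` overlapping triangle ``j``, with weights."""
        tf, tt, w = self.edges[t_to - 1]
        sel = tt == j
        return tf[sel], w[sel]

    def successors(self, t_from: int, i: int) -> Tuple[np.ndarray, np.ndarray]:
        tf, tt, w = self.edges[t_from]
        sel = tf == i
        return tt[sel], w[sel]

    def best_predecessor(self, t_to: int, j: int) -> int:
        """Max-overlap predecessor of triangle ``j`` at hour ``t_to``; ties -> lowest index."""
        cand, w = self.predecessors(t_to, j)
        if cand.size == 0:
            from .errors import StructuralError
            raise StructuralError(
                f"triangle {TriangleRef(t_to, j)} has no predecessor edge")
        return _argmax_lowest(cand, w)

    def best_successor(self, t_from: int, i: int) -> int:
        cand, w = self.successors(t_from, i)
        if cand.size == 0:
            from .errors import StructuralError
            raise StructuralError(
                f"triangle {TriangleRef(t_from, i)} has no successor edge")
        return _argmax_lowest(cand, w)

    def to_table(self) -> np.ndarray:
        """Columnar (t, tri_from, tri_to, overlap_area) over all hour boundaries."""
        rows = []
        for t in sorted(self.edges):
            tf, tt, w = self.edges[t]
            rows.append(np.column_stack([np.full(len(tf), t, dtype=float), tf, tt, w]))
        return np.vstack(rows) if rows else np.empty((0, 4))

    def save(self, path: str) -> None:
        np.savetxt(path, self.to_table(), fmt=["%d", "%d", "%d", "%.17g"],
                   header="t\ttri_from\ttri_to\toverlap_area", delimiter="\t")

    @classmethod
    def load(cls, path: str, n_hours: int, n_triangles: List[int]) -> "LineageGraph":
        tab = np.loadtxt(path, ndmin=2)
        graph = cls(n_hours=n_hours, n_triangles=n_triangles)
        if tab.size:
            for t in range(n_hours - 1):
                sel = tab[:, 0].astype(int) == t
                graph.edges[t] = (tab[sel, 1].astype(np.int64),
                                  tab[sel, 2].astype(np.int64),
                                  tab[sel, 3])
        return graph


def _argmax_lowest(indices: np.ndarray, weights: np.ndarray) -> int:
    """Index with maximal weight; exact ties resolved to the lowest index."""
    best = weights == weights.max()
    return int(indices[best].min())


def build_lineage_graph(movie: Morphomovie) -> LineageGraph:
    """Overlap all consecutive hour pairs in their common domain instant.

    For each boundary ``t -> t + 1`` the triangles of the end-of-hour
    configuration of mesh ``t`` are intersected with the triangles of mesh
    ``t + 1`` using an STR packed R-tree bounding-box index, so the cost is
    near-linear in triangle count.  All overlaps above the sliver threshold
    become edges.
    """
    if movie.n_hours < 2:
        raise ValidationError("lineage requires a movie with at least 2 hours")
    graph = LineageGraph(
        n_hours=movie.n_hours,
        n_triangles=[m.n_triangles for m in movie.hourly_meshes],
    )
    for t in range(movie.n_hours - 1):
        verts_a = movie.end_of_hour_vertices(t)
        mesh_a = movie.hourly_meshes[t]
        mesh_b = movie.hourly_meshes[t + 1]

        area_a = float(np.abs(triangle_signed_areas(verts_a, mesh_a.triangles)).sum())
        area_b = float(np.abs(triangle_signed_areas(mesh_b.vertices, mesh_b.triangles)).sum())
        if abs(area_a - area_b) / area_b > OUTLINE_MISMATCH_RTOL:
            warnings.warn(
                f"hour boundary {t}->{t + 1}: outline areas disagree by "
                f"{abs(area_a - area_b) / area_b:.1%}; overlaps clipped as computed",
                stacklevel=2)

        polys_a = shapely.polygons(verts_a[mesh_a.triangles])
        polys_b = shapely.polygons(mesh_b.vertices[mesh_b.triangles])
        tree = STRtree(polys_b)
        ia, ib = tree.query(polys_a)  # bbox candidate pairs
        if ia.size:
            inter = shapely.intersection(polys_a[ia], polys_b[ib])
            w = shapely.area(inter)
        else:
            w = np.empty(0)
        mean_tri = 0.5 * (area_a / max(mesh_a.n_triangles, 1)
                          + area_b / max(mesh_b.n_triangles, 1))
        keep = w > MIN_OVERLAP_FRAC * mean_tri
        tf, tt, w = ia[keep].astype(np.int64), ib[keep].astype(np.int64), w[keep]
        order = np.lexsort((tt, tf))
        graph.edges[t] = (tf[order], tt[order], w[order])
    return graph
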