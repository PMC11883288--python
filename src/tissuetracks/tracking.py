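"""Tissue-track extraction from the lineage graph.

A tissue track is a chronological sequence of triangles, exactly one per
hourly mesh, approximating how one small piece of tissue moves through the
growing domain.  Tracks are built in two phases:

Phase 1
    For every triangle of the final mesh, walk backwards hour by hour, at each
    remesh boundary choosing the predecessor with the largest area overlap
    (exact ties broken to the lowest triangle index).  Because the tissue
    grows, many final triangles funnel back to the same early triangles.

Phase 2
    Some intermediate triangles are never visited by phase 1.  Scanning hours
    ascending and triangle indices ascending, each still-uncovered triangle
    seeds a new track completed both backwards and forwards by the same
    max-overlap rule, until every triangle of every hour belongs to at least
    one track and every track spans the whole movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np

from .errors import StructuralError, ValidationError
from .lineage import LineageGraph
from .morphomovie import Morphomovie, TriangleRef

ORIGIN_FINAL_BACKWARD = "final_backward"
ORIGIN_FILL = "fill_bidirectional"


@dataclass
class TissueTrack:
    """One triangle index per hour, chronologically ordered."""

    refs: np.ndarray          # (T,) triangle index at each hour
    origin: str               # ORIGIN_FINAL_BACKWARD or ORIGIN_FILL

    def __len__(self) -> int:
        return len(self.refs)

    def ref(self, hour: int) -> TriangleRef:
        return TriangleRef(hour, int(self.refs[hour]))


@dataclass
class TrackSet:
    """All tracks plus the reverse map triangle -> containing tracks."""

    n_hours: int
    tracks: List[TissueTrack] = field(default_factory=list)
    membership: Dict[Tuple[int, int], Set[int]] = field(default_factory=dict)

    def add(self, track: TissueTrack) -> int:
        tid = len(self.tracks)
        self.tracks.append(track)
        for h, i in enumerate(track.refs):
            self.membership.setdefault((h, int(i)), set()).add(tid)
        return tid

    def tracks_through(self, hour: int, index: int) -> Set[int]:
        return self.membership.get((hour, index), set())

    def refs_matrix(self) -> np.ndarray:
        """(n_tracks, T) triangle-index matrix."""
        return np.array([t.refs for t in self.tracks], dtype=np.int64)

    def to_table(self) -> List[Tuple[int, int, int, str]]:
        rows = []
        for tid, tr in enumerate(self.tracks):
            for h, i in enumerate(tr.refs):
                rows.append((tid, h, int(i), tr.origin))
        return rows

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# track_id\thour\ttriangle_index\torigin\n")
            for tid, h, i, origin in self.to_table():
                fh.write(f"{tid}\t{h}\t{i}\t{origin}\n")

    @classmethod
    def load(cls, path: str) -> "TrackSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                tid, h, i, origin = line.split()
                rows.append((int(tid), int(h), int(i), origin))
        n_hours = max(r[1] for r in rows) + 1
        ts = cls(n_hours=n_hours)
        n_tracks = max(r[0] for r in rows) + 1
        for tid in range(n_tracks):
            mine = sorted((h, i, o) for t, h, i, o in rows if t == tid)
            refs = np.array([i for _, i, _ in mine], dtype=np.int64)
            ts.add(TissueTrack(refs=refs, origin=mine[0][2]))
        return ts


def _argmax_tables(graph: LineageGraph):
    """Vectorised per-triangle best predecessor / successor lookup tables.

    best_pred[t][j] = max-overlap predecessor at hour t-1 of triangle j at
    hour t; best_succ[t][i] likewise forwards.  Ties go to the lowest index.
    Missing edges are marked -1.
    """
    T = graph.n_hours
    best_pred = [None] * T
    best_succ = [None] * T
    for t in range(T - 1):
        tf, tt, w = graph.edges[t]
        # successors of hour-t triangles: sort by (tf, -w, tt); first row per tf wins
        succ = np.full(graph.n_triangles[t], -1, dtype=np.int64)
        if len(tf):
            order = np.lexsort((tt, -w, tf))
            first = np.ones(len(tf), dtype=bool)
            first[1:] = tf[order][1:] != tf[order][:-1]
            succ[tf[order][first]] = tt[order][first]
        best_succ[t] = succ
        pred = np.full(graph.n_triangles[t + 1], -1, dtype=np.int64)
        if len(tt):
            order = np.lexsort((tf, -w, tt))
            first = np.ones(len(tt), dtype=bool)
            first[1:] = tt[order][1:] != tt[order][:-1]
            pred[tt[order][first]] = tf[order][first]
        best_pred[t + 1] = pred
    return best_pred, best_succ


def extract_tracks(graph: LineageGraph) -> TrackSet:
    """Build the full-span track set (phase 1 + phase 2, see module docs)."""
    T = graph.n_hours
    if T < 2:
        raise ValidationError("track extraction requires at least 2 hours")
    best_pred, best_succ = _argmax_tables(graph)
    for t in range(1, T):
        missing = np.flatnonzero(best_pred[t] == -1)
        if missing.size:
            raise StructuralError(
                f"triangle {TriangleRef(t, int(missing[0]))} has no predecessor edge")
    for t in range(T - 1):
        missing = np.flatnonzero(best_succ[t] == -1)
        if missing.size:
            raise StructuralError(
                f"triangle {TriangleRef(t, int(missing[0]))} has no successor edge")

    tracks = TrackSet(n_hours=T)

    # phase 1: backwards from every final-mesh triangle
    for j in range(graph.n_triangles[T - 1]):
        refs = np.empty(T, dtype=np.int64)
        refs[T - 1] = j
        for t in range(T - 1, 0, -1):
            refs[t - 1] = best_pred[t][refs[t]]
        tracks.add(TissueTrack(refs=refs, origin=ORIGIN_FINAL_BACKWARD))

    # phase 2: fill uncovered triangles, ascending hour then ascending index
    for t in range(T):
        for i in range(graph.n_triangles[t]):
            if tracks.tracks_through(t, i):
                continue
            refs = np.empty(T, dtype=np.int64)
            refs[t] = i
            for u in range(t, 0, -1):
                refs[u - 1] = best_pred[u][refs[u]]
            for u in range(t, T - 1):
                refs[u + 1] = best_succ[u][refs[u]]
            tracks.add(TissueTrack(refs=refs, origin=ORIGIN_FILL))
    return tracks


def coverage_report(tracks: TrackSet, movie: Morphomovie) -> dict:
    """Per-hour coverage counts plus track totals."""
    per_hour = []
    for t, mesh in enumerate(movie.hourly_meshes):
        counts = np.zeros(mesh.n_triangles, dtype=int)
        for (h, i), tids in tracks.membership.items():
            if h == t:
                counts[i] += len(tids)
        per_hour.append({
            "hour": t,
            "triangles": mesh.n_triangles,
            "covered": int((counts > 0).sum()),
            "multiply_covered": int((counts > 1).sum()),
        })
    n_fill = sum(1 for tr in tracks.tracks if tr.origin == ORIGIN_FILL)
    return {
        "per_hour": per_hour,
        "total_tracks": len(tracks.tracks),
        "final_backward_tracks": len(tracks.tracks) - n_fill,
        "fill_tracks": n_fill,
        "fully_covered": all(h["covered"] == h["triangles"] for h in per_hour),
    }
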