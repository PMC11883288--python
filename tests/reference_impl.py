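"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's spatial index, vectorised grouping and
clipping code: overlaps come from shapely polygon intersection over all
triangle pairs, and track extraction is a plain dictionary walk.
"""

import numpy as np
from shapely.geometry import Polygon


def brute_force_lineage(movie, min_overlap_frac=1e-12):
    """All-pairs overlap scan between consecutive hour configurations."""
    edges = {}
    for t in range(movie.n_hours - 1):
        verts_a = movie.end_of_hour_vertices(t)
        mesh_a = movie.hourly_meshes[t]
        mesh_b = movie.hourly_meshes[t + 1]
        polys_a = [Polygon(verts_a[tri]) for tri in mesh_a.triangles]
        polys_b = [Polygon(mesh_b.vertices[tri]) for tri in mesh_b.triangles]
        area_a = sum(p.area for p in polys_a)
        area_b = sum(p.area for p in polys_b)
        mean_tri = 0.5 * (area_a / len(polys_a) + area_b / len(polys_b))
        rows = []
        for i, pa in enumerate(polys_a):
            for j, pb in enumerate(polys_b):
                if pa.bounds[2] < pb.bounds[0] or pb.bounds[2] < pa.bounds[0]:
                    continue
                if pa.bounds[3] < pb.bounds[1] or pb.bounds[3] < pa.bounds[1]:
                    continue
                w = pa.intersection(pb).area
                if w > min_overlap_frac * mean_tri:
                    rows.append((i, j, w))
        edges[t] = rows
    return edges


def brute_force_tracks(edges, n_hours, n_final):
    """Reference two-phase track extraction by explicit argmax walks."""

    def best_pred(t_to, j):
        cand = [(w, i) for i, jj, w in edges[t_to - 1] if jj == j]
        wmax = max(w for w, _ in cand)
        return min(i for w, i in cand if w == wmax)

    def best_succ(t_from, i):
        cand = [(w, j) for ii, j, w in edges[t_from] if ii == i]
        wmax = max(w for w, _ in cand)
        return min(j for w, j in cand if w == wmax)

    tracks = []
    for j in range(n_final):
        refs = [0] * n_hours
        refs[n_hours - 1] = j
        for t in range(n_hours - 1, 0, -1):
            refs[t - 1] = best_pred(t, refs[t])
        tracks.append((tuple(refs), "final_backward"))

    covered = {(h, r) for refs, _ in tracks for h, r in enumerate(refs)}
    # per-hour triangle counts recovered from the edge lists
    counts = []
    for t in range(n_hours):
        if t < n_hours - 1:
            n = 1 + max(i for i, _, _ in edges[t])
        else:
            n = n_final
        counts.append(n)
    for t in range(n_hours):
        for i in range(counts[t]):
            if (t, i) in covered:
                continue
            refs = [0] * n_hours
            refs[t] = i
            for u in range(t, 0, -1):
                refs[u - 1] = best_pred(u, refs[u])
            for u in range(t, n_hours - 1):
                refs[u + 1] = best_succ(u, refs[u])
            tracks.append((tuple(refs), "fill_bidirectional"))
            covered.update((h, r) for h, r in enumerate(refs))
    return tracks


def shoelace_boundary_area(mesh):
    """Polygon area of the mesh's outer boundary, via edge chaining + shoelace."""
    from collections import Counter

    edge_count = Counter()
    for a, b, c in mesh.triangles:
        for u, v in ((a, b), (b, c), (c, a)):
            edge_count[frozenset((int(u), int(v)))] += 1
    boundary = [e for e, n in edge_count.items() if n == 1]
    adj = {}
    for e in boundary:
        u, v = tuple(e)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    start = next(iter(adj))
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = [v for v in adj[cur] if v != prev]
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        loop.append(cur)
    pts = mesh.vertices[loop]
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def mc_overlap_estimate(tri_a, tri_b, n=10**6, seed=0):
    """Monte-Carlo estimate of triangle intersection area, with standard error."""
    tri_a = np.asarray(tri_a, float)
    tri_b = np.asarray(tri_b, float)
    lo = np.minimum(tri_a.min(axis=0), tri_b.min(axis=0))
    hi = np.maximum(tri_a.max(axis=0), tri_b.max(axis=0))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n, 2))
    box = np.prod(hi - lo)

    def inside(tri, p):
        sign = None
        ok = np.ones(len(p), dtype=bool)
        for k in range(3):
            a, b = tri[k], tri[(k + 1) % 3]
            cross = (b[0] - a[0]) * (p[:, 1] - a[1]) - (b[1] - a[1]) * (p[:, 0] - a[0])
            area2 = ((tri[1][0] - tri[0][0]) * (tri[2][1] - tri[0][1])
                     - (tri[2][0] - tri[0][0]) * (tri[1][1] - tri[0][1]))
            ok &= (cross * np.sign(area2)) >= 0
        return ok

    hit = inside(tri_a, pts) & inside(tri_b, pts)
    p_hat = hit.mean()
    est = p_hat * box
    se = np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n) * box
    return est, se
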