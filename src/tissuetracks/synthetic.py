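"""Synthetic growing-domain movies, ground-truth patterns and staged images.

Every pipeline stage is testable without laboratory data: this module
generates (i) a limb-bud-like growing outline meshed at constant element size
with hourly remeshing and 10-minute vertex-displacement substeps, (ii) smooth
time-dependent ground-truth expression patterns, and (iii) staged grayscale
images rendered from those patterns with per-image gain/offset/noise
corruption emulating experimental intensity variation.

The outline is a half-ellipse (flat proximal base on the x-axis) with a
distally elongating bulge, expressed in polar form ``r(theta, t)`` about the
origin — star-shaped, so a purely radial map carries any domain point exactly
onto the outline of another hour.  That map drives the substep displacement
frames; the scale factor is chosen each hour so the outline area compounds at
a fixed growth rate.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .errors import TissueTracksError, ValidationError
from .intensity import POLARITY_BRIGHT, StagedImage, TriangleField, digitize_image
from .lineage import build_lineage_graph
from .morphomovie import Mesh, Morphomovie, triangle_signed_areas
from .tracking import TrackSet, extract_tracks


# ---------------------------------------------------------------------------
# Growth specification and outline geometry
# ---------------------------------------------------------------------------

@dataclass
class GrowthSpec:
    """Parameters of the synthetic growing outline.

    The outline area grows by ``area_growth_per_hour`` (compounded) each hour;
    the distal bulge amplitude ramps linearly over the movie, emulating the
    elongating limb bud.  ``target_edge_length`` sets the (constant) element
    size restored by the hourly remeshing.
    """

    T: int = 12
    substeps_per_hour: int = 6
    semi_axis_x: float = 1.2
    semi_axis_y: float = 0.9
    bulge_amplitude: tuple = (0.15, 0.6)
    bulge_width: float = 0.5          # radians
    area_growth_per_hour: float = 0.06
    target_edge_length: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_edge_length <= 0:
            raise ValidationError("target edge length must be positive")
        if self.area_growth_per_hour < 0:
            raise ValidationError("outline area must be strictly non-shrinking")
        if self.T < 1:
            raise ValidationError("movie length must be at least 1 hour")

    # -- outline in polar form about the origin, theta in [0, pi] ----------

    def _shape_radius(self, theta: np.ndarray, t: float) -> np.ndarray:
        """Unscaled outline radius: half-ellipse times the distal bulge."""
        a, b = self.semi_axis_x, self.semi_axis_y
        ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        tau = t / max(self.T - 1, 1)
        amp = self.bulge_amplitude[0] + (self.bulge_amplitude[1]
                                         - self.bulge_amplitude[0]) * tau
        return ell * (1.0 + amp * np.exp(-((theta - np.pi / 2) ** 2)
                                         / (2 * self.bulge_width ** 2)))

    def _scale(self, t: float) -> float:
        """Scale factor making the outline area exactly area0 * (1+g)^t."""
        theta = np.linspace(0.0, np.pi, 2049)
        K = np.trapezoid(0.5 * self._shape_radius(theta, t) ** 2, theta)
        theta0 = theta
        K0 = np.trapezoid(0.5 * self._shape_radius(theta0, 0.0) ** 2, theta0)
        target = K0 * (1.0 + self.area_growth_per_hour) ** t
        return float(np.sqrt(target / K))

    def outline_radius(self, theta: np.ndarray, t: float) -> np.ndarray:
        return self._scale(t) * self._shape_radius(np.asarray(theta, float), t)

    def outline_polygon(self, t: float, n: int = 512) -> Polygon:
        theta = np.linspace(0.0, np.pi, n)
        r = self.outline_radius(theta, t)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        return Polygon(pts)   # closes along the base segment

    def radial_map(self, points: np.ndarray, t_from: float, t_to: float) -> np.ndarray:
        """Carry points of the hour-``t_from`` domain onto hour ``t_to``.

        Exact on the outline; smooth inside; the base segment stays on y = 0.
        """
        p = np.asarray(points, dtype=float)
        x, y = p[:, 0], np.maximum(p[:, 1], 0.0)
        theta = np.arctan2(y, x)
        rho = np.hypot(x, y)
        r_from = self.outline_radius(theta, t_from)
        r_to = self.outline_radius(theta, t_to)
        scale = np.where(rho > 0, r_to / np.maximum(r_from, 1e-300), 1.0)
        return np.column_stack([x * scale, p[:, 1] * scale])


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

def _mesh_outline(spec: GrowthSpec, t: int) -> Mesh:
    """Triangulate the hour-t outline at the target edge length.

    Boundary points are placed by arc length (slightly denser than the target
    edge so the polygonal outline hugs the curve); interior points sit on a
    jittered hexagonal lattice; the Delaunay triangulation is clipped to the
    outline by centroid membership.
    """
    h = spec.target_edge_length
    rng = np.random.default_rng([spec.seed, 7919, t])

    # boundary: arc-length sampling of the polar curve
    theta_f = np.linspace(0.0, np.pi, 4096)
    r_f = spec.outline_radius(theta_f, t)
    bx, by = r_f * np.cos(theta_f), r_f * np.sin(theta_f)
    seg = np.hypot(np.diff(bx), np.diff(by))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_arc = max(int(np.ceil(arc[-1] / (0.75 * h))), 8)
    s_pos = np.linspace(0.0, arc[-1], n_arc + 1)
    theta_b = np.interp(s_pos, arc, theta_f)
    r_b = spec.outline_radius(theta_b, t)
    curve = np.column_stack([r_b * np.cos(theta_b), r_b * np.sin(theta_b)])
    curve[0, 1] = 0.0
    curve[-1, 1] = 0.0
    # base segment from (-r(pi), 0) to (r(0), 0), endpoints already present
    x_left, x_right = curve[-1, 0], curve[0, 0]
    n_base = max(int(np.ceil((x_right - x_left) / (0.75 * h))), 2)
    base_x = np.linspace(x_left, x_right, n_base + 1)[1:-1]
    base = np.column_stack([base_x, np.zeros_like(base_x)])
    boundary = np.vstack([curve, base])

    poly = Polygon(np.vstack([curve]))
    # interior: jittered hexagonal lattice, kept clear of the boundary
    xmin, ymin, xmax, ymax = poly.bounds
    dy = h * np.sqrt(3) / 2
    rows = np.arange(ymin + 0.6 * h, ymax, dy)
    pts = []
    for i, yy in enumerate(rows):
        xs = np.arange(xmin, xmax + h, h) + (0.5 * h if i % 2 else 0.0)
        pts.append(np.column_stack([xs, np.full_like(xs, yy)]))
    interior = np.vstack(pts) if pts else np.empty((0, 2))
    if len(interior):
        interior = interior + rng.uniform(-0.12 * h, 0.12 * h, size=interior.shape)
        eroded = poly.buffer(-0.55 * h)
        keep = shapely.contains(eroded, shapely.points(interior))
        interior = interior[keep]

    points = np.vstack([boundary, interior])
    try:
        tri = Delaunay(points)
    except Exception as exc:  # pragma: no cover - qhull failure surfaces rarely
        raise TissueTracksError(f"meshing failed at hour {t}: {exc}") from exc

    simplices = tri.simplices
    cent = points[simplices].mean(axis=1)
    inside = shapely.contains(poly, shapely.points(cent))
    areas = np.abs(triangle_signed_areas(points, simplices))
    keep = inside & (areas > 1e-9 * h * h)
    simplices = simplices[keep]

    used = np.unique(simplices)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return Mesh(vertices=points[used], triangles=remap[simplices], timepoint=t)


def generate_morphomovie(spec: GrowthSpec) -> Morphomovie:
    """Hourly meshes plus substep frames morphing each hour onto the next."""
    meshes = [_mesh_outline(spec, t) for t in range(spec.T)]
    substeps: List[List[np.ndarray]] = []
    for t in range(spec.T):
        frames: List[np.ndarray] = []
        if t < spec.T - 1:
            start = meshes[t].vertices
            for k in range(1, spec.substeps_per_hour + 1):
                frac = k / spec.substeps_per_hour
                target = spec.radial_map(start, t, t + frac)
                frames.append(target)
        substeps.append(frames)
    stages = {t: f"synthetic:{t:02d}" for t in range(spec.T)}
    return Morphomovie(hourly_meshes=meshes, substeps=substeps,
                       minutes_per_substep=60 // spec.substeps_per_hour,
                       stage_labels=stages)


# ---------------------------------------------------------------------------
# Ground-truth patterns
# ---------------------------------------------------------------------------

PATTERN_SIMPLE = "simple_front"
PATTERN_COMPLEX = "complex_stripes"


@dataclass
class PatternSpec:
    """A smooth dynamic expression pattern in outline-normalised coordinates.

    ``simple_front`` is a sigmoid expression front sweeping across the domain
    (a Dusp6-like single-boundary pattern); ``complex_stripes`` is a single
    central domain that splits into several stripes after an onset time (a
    Sox9-like condensation pattern).  ``p(x_rel, y_rel, t)`` is bounded in
    [0, 1] and continuous in all arguments; coordinates are normalised to the
    mesh bounding box at each hour.
    """

    kind: str = PATTERN_SIMPLE
    duration_hours: int = 12
    # simple_front parameters
    front_start: float = -0.25
    front_end: float = 1.25
    front_steepness: float = 0.08
    # complex_stripes parameters
    n_stripes: int = 3
    onset_fraction: float = 0.25
    stripe_width: float = 0.09
    stripe_spacing: float = 0.28

    def __post_init__(self) -> None:
        if self.kind not in (PATTERN_SIMPLE, PATTERN_COMPLEX):
            raise ValidationError(f"unknown pattern kind {self.kind!r}")

    def stripe_centers(self, t: float) -> np.ndarray:
        tau = t / max(self.duration_hours - 1, 1)
        ramp = np.clip((tau - self.onset_fraction) / (1.0 - self.onset_fraction), 0.0, 1.0)
        ramp = ramp * ramp * (3.0 - 2.0 * ramp)   # smoothstep: C1 in time
        offsets = (np.arange(self.n_stripes) - (self.n_stripes - 1) / 2.0)
        return 0.5 + offsets * self.stripe_spacing * ramp

    def evaluate(self, x_rel: np.ndarray, y_rel: np.ndarray, t: float) -> np.ndarray:
        x_rel = np.asarray(x_rel, dtype=float)
        if self.kind == PATTERN_SIMPLE:
            tau = t / max(self.duration_hours - 1, 1)
            front = self.front_start + (self.front_end - self.front_start) * tau
            return 1.0 / (1.0 + np.exp(-(front - x_rel) / self.front_steepness))
        centers = self.stripe_centers(t)
        d2 = (x_rel[..., None] - centers[None, :]) ** 2
        return np.exp(-d2 / (2.0 * self.stripe_width ** 2)).max(axis=-1)


def _normalized_coords(mesh: Mesh, points: np.ndarray) -> tuple:
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    span = np.maximum(hi - lo, 1e-300)
    rel = (points - lo) / span
    return rel[:, 0], rel[:, 1]


# degree-4 symmetric triangle quadrature (6 points): barycentric coords, weights
_TRI_QUAD_BARY = np.array([
    [0.108103018168070, 0.445948490915965, 0.445948490915965],
    [0.445948490915965, 0.108103018168070, 0.445948490915965],
    [0.445948490915965, 0.445948490915965, 0.108103018168070],
    [0.816847572980459, 0.091576213509771, 0.091576213509771],
    [0.091576213509771, 0.816847572980459, 0.091576213509771],
    [0.091576213509771, 0.091576213509771, 0.816847572980459],
])
_TRI_QUAD_W = np.array([0.223381589678011] * 3 + [0.109951743655322] * 3)


def ground_truth_field(pattern: PatternSpec, mesh: Mesh, hour: int) -> TriangleField:
    """The pattern averaged over each triangle: the oracle for accuracy tests.

    Uses a 6-point degree-4 quadrature rule, matching the semantics of
    digitization (which averages pixel intensities over each triangle).
    """
    corners = mesh.triangle_points()                       # (m, 3, 2)
    vals = np.zeros(mesh.n_triangles)
    for bary, w in zip(_TRI_QUAD_BARY, _TRI_QUAD_W):
        pts = np.einsum("k,mkd->md", bary, corners)
        xr, yr = _normalized_coords(mesh, pts)
        vals += w * pattern.evaluate(xr, yr, hour)
    return TriangleField(hour=hour, values=np.clip(vals, 0.0, 1.0),
                         provenance="ground_truth")


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass
class CorruptionSpec:
    """Per-image intensity corruption emulating experimental variation."""

    gain_range: tuple = (0.6, 1.0)
    offset_range: tuple = (0.0, 0.2)
    noise_sd: float = 0.02
    seed: int = 0


def render_staged_image(movie: Morphomovie, pattern: PatternSpec, hour: int,
                        resolution: int = 300,
                        corruption: Optional[CorruptionSpec] = None,
                        image_id: str = "") -> StagedImage:
    """Rasterise the ground-truth pattern over the hour's mesh.

    Pixels outside the domain are 0; corruption applies gain, offset and
    additive Gaussian noise, then clips to [0, 1].  The returned image carries
    the exact affine registration into mesh coordinates.
    """
    from matplotlib.tri import TrapezoidMapTriFinder, Triangulation

    if not 0 <= hour < movie.n_hours:
        raise ValidationError(f"hour {hour} outside movie range")
    mesh = movie.hourly_meshes[hour]
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    margin = 2.0
    scale = (resolution - 2 * margin) / max(hi[0] - lo[0], 1e-300)
    W = resolution
    H = int(np.ceil((hi[1] - lo[1]) * scale + 2 * margin))
    # mesh (x, y) -> pixel (px, py), y flipped because rows grow downwards
    # px = (x - lo_x) * scale + margin;  py = (hi_y - y) * scale + margin
    a, b, c = 1.0 / scale, 0.0, lo[0] - margin / scale
    d, e, f = 0.0, -1.0 / scale, hi[1] + margin / scale
    image_to_mesh = (a, b, c, d, e, f)

    cols, rows_ = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    mx = a * cols + b * rows_ + c
    my = d * cols + e * rows_ + f
    tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
    finder = TrapezoidMapTriFinder(tri)
    inside = finder(mx.ravel(), my.ravel()).reshape(H, W) >= 0

    xr, yr = _normalized_coords(mesh, np.column_stack([mx.ravel(), my.ravel()]))
    vals = np.clip(pattern.evaluate(xr, yr, hour), 0.0, 1.0).reshape(H, W)
    pixels = np.where(inside, vals, 0.0)

    if corruption is not None:
        rng = np.random.default_rng([corruption.seed, 104729, hour])
        gain = rng.uniform(*corruption.gain_range)
        offset = rng.uniform(*corruption.offset_range)
        noise = (rng.normal(0.0, corruption.noise_sd, size=pixels.shape)
                 if corruption.noise_sd > 0 else 0.0)
        pixels = np.where(inside, np.clip(gain * pixels + offset + noise, 0.0, 1.0), 0.0)

    return StagedImage(pixels=pixels, hour=hour, polarity=POLARITY_BRIGHT,
                       image_to_mesh=image_to_mesh,
                       image_id=image_id or f"synthetic_h{hour:03d}")


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, generated from two specs and a seed."""

    movie: Morphomovie
    tracks: TrackSet
    images: List[StagedImage]
    fields: List[TriangleField]          # digitized raw fields
    truth: List[TriangleField]           # ground truth per hour
    pattern: PatternSpec
    growth: GrowthSpec


def synthesize_dataset(growth: GrowthSpec, pattern: PatternSpec,
                       image_hours: Optional[Sequence[int]] = None,
                       images_per_hour: int = 1, resolution: int = 300,
                       corruption: Optional[CorruptionSpec] = None) -> SyntheticDataset:
    """Generate movie, tracks, staged images and their digitized fields."""
    pattern.duration_hours = growth.T
    movie = generate_morphomovie(growth)
    graph = build_lineage_graph(movie)
    tracks = extract_tracks(graph)
    hours = list(image_hours) if image_hours is not None else list(range(growth.T))
    images: List[StagedImage] = []
    fields: List[TriangleField] = []
    for h in hours:
        for rep in range(images_per_hour):
            corr = None
            if corruption is not None:
                corr = CorruptionSpec(gain_range=corruption.gain_range,
                                      offset_range=corruption.offset_range,
                                      noise_sd=corruption.noise_sd,
                                      seed=corruption.seed + 1000 * rep + h)
            img = render_staged_image(movie, pattern, h, resolution=resolution,
                                      corruption=corr,
                                      image_id=f"img_h{h:03d}_r{rep}")
            images.append(img)
            fields.append(digitize_image(img, movie.hourly_meshes[h]))
    truth = [ground_truth_field(pattern, m, m.timepoint) for m in movie.hourly_meshes]
    return SyntheticDataset(movie=movie, tracks=tracks, images=images,
                            fields=fields, truth=truth, pattern=pattern, growth=growth)
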