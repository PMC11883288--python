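"""Temporal B-spline interpolation along tissue tracks and reassembly.

Expression along one tissue track is a scatter of (hour, intensity) samples,
one per image staged to each hour the track crosses.  Per-hour means of these
samples become the control points of a uniform cubic B-spline curve in the
(hour, intensity) plane: every curve section is shaped by its four
neighbouring control points, so control is local and the curve is C2 — the
rate of expression change never jumps, which is the biological motivation for
splines over piecewise-linear interpolation.  Reflected phantom control points
make the curve pass exactly through the first and last means while preserving
the spline's exact reproduction of constant and collinear data.  Interior
means act as control points in the classical B-spline sense: the curve is
attracted to, but not forced through, them, which gives a mild temporal
smoothing of per-hour intensity fluctuations.

Evaluating the curve at an arbitrary hour inverts the (monotone) hour
component of the parametric curve by Newton iteration.  Outside the sampled
span the value is held at the nearest endpoint mean; all outputs are clamped
to [0, 1].

Reassembly maps every track's spline value back onto the mesh sequence;
triangles shared by several tracks are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .intensity import TriangleField
from .morphomovie import Morphomovie
from .tracking import TrackSet

MIN_DISTINCT_HOURS = 4


# ---------------------------------------------------------------------------
# Uniform cubic B-spline machinery
# ---------------------------------------------------------------------------

def _extension_matrix(n: int) -> np.ndarray:
    """(n + 2, n) operator adding reflected phantom endpoints to n control points."""
    E = np.zeros((n + 2, n))
    E[0, 0], E[0, 1] = 2.0, -1.0
    E[np.arange(1, n + 1), np.arange(n)] = 1.0
    E[n + 1, n - 1], E[n + 1, n - 2] = 2.0, -1.0
    return E


def _basis_matrix(n: int, u: np.ndarray, derivative: bool = False) -> np.ndarray:
    """(len(u), n + 2) cubic B-spline weights over the extended control points.

    The curve parameter u runs over [0, n - 1]; section k (u in [k, k+1])
    blends extended controls k..k+3 with the standard uniform cubic basis.
    """
    u = np.clip(np.asarray(u, dtype=float), 0.0, n - 1.0)
    k = np.clip(np.floor(u).astype(int), 0, n - 2)
    s = u - k
    if not derivative:
        w = np.stack([(1 - s) ** 3,
                      3 * s ** 3 - 6 * s ** 2 + 4,
                      -3 * s ** 3 + 3 * s ** 2 + 3 * s + 1,
                      s ** 3], axis=-1) / 6.0
    else:
        w = np.stack([-3 * (1 - s) ** 2,
                      9 * s ** 2 - 12 * s,
                      -9 * s ** 2 + 6 * s + 3,
                      3 * s ** 2], axis=-1) / 6.0
    M = np.zeros((len(u), n + 2))
    rows = np.arange(len(u))
    for j in range(4):
        M[rows, k + j] += w[:, j]
    return M


def _invert_time(hours_ctrl: np.ndarray, u_query_of: np.ndarray) -> np.ndarray:
    """Solve x(u) = h for the monotone hour component of the curve."""
    n = len(hours_ctrl)
    hx = _extension_matrix(n) @ hours_ctrl
    h = np.clip(u_query_of, hours_ctrl[0], hours_ctrl[-1])
    # dense piecewise-linear first guess, then Newton
    u_dense = np.linspace(0.0, n - 1.0, 8 * (n - 1) + 1)
    x_dense = _basis_matrix(n, u_dense) @ hx
    u = np.interp(h, x_dense, u_dense)
    for _ in range(6):
        x = _basis_matrix(n, u) @ hx
        dx = _basis_matrix(n, u, derivative=True) @ hx
        u = np.clip(u - (x - h) / np.maximum(dx, 1e-12), 0.0, n - 1.0)
    return u


@dataclass
class SplineModel:
    """Parametric uniform cubic B-spline through one track's per-hour means."""

    hours: np.ndarray     # (n,) sampled hours, strictly increasing
    means: np.ndarray     # (n,) per-hour mean intensities (the control points)

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if len(self.hours) < MIN_DISTINCT_HOURS:
            raise ValidationError(
                "B-spline interpolation requires at least 4 unique time points; "
                f"got {len(self.hours)}")
        if np.any(np.diff(self.hours) <= 0):
            raise ValidationError("sampled hours must be strictly increasing")

    @property
    def degree(self) -> int:
        return 3

    def __call__(self, t) -> np.ndarray:
        """Intensity at hour(s) t, clamped to [0, 1]; constant outside the span."""
        scalar = np.isscalar(t)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        n = len(self.hours)
        u = _invert_time(self.hours, t)
        y = _basis_matrix(n, u) @ (_extension_matrix(n) @ self.means)
        y = np.clip(y, 0.0, 1.0)
        return float(y[0]) if scalar else y


# ---------------------------------------------------------------------------
# Track series
# ---------------------------------------------------------------------------

@dataclass
class TrackSeries:
    """Raw (hour, value, source) samples of one track, plus per-hour means."""

    track_id: int
    samples: list = field(default_factory=list)   # (hour, value, source_id) tuples

    @property
    def hour_means(self) -> Dict[int, float]:
        acc: Dict[int, List[float]] = {}
        for h, v, _ in self.samples:
            acc.setdefault(int(h), []).append(float(v))
        return {h: float(np.mean(vs)) for h, vs in sorted(acc.items())}

    @property
    def distinct_hours(self) -> List[int]:
        return sorted({int(h) for h, _, _ in self.samples})


def collect_track_series(tracks: TrackSet, fields: Sequence[TriangleField]) -> List[TrackSeries]:
    """One sample per (track, staged field): the field value at the track's triangle."""
    hours = sorted({f.hour for f in fields})
    if len(hours) < MIN_DISTINCT_HOURS:
        raise ValidationError(
            "B-spline interpolation requires at least 4 unique time points; "
            f"the dataset covers only {len(hours)}")
    series = [TrackSeries(track_id=tid) for tid in range(len(tracks.tracks))]
    for f in sorted(fields, key=lambda f: (f.hour, f.provenance)):
        for tid, tr in enumerate(tracks.tracks):
            series[tid].samples.append((f.hour, float(f.values[tr.refs[f.hour]]),
                                        f.provenance))
    return series


def fit_track_spline(series: TrackSeries) -> SplineModel:
    """Fit the temporal B-spline through one track's per-hour means."""
    means = series.hour_means
    if len(means) < MIN_DISTINCT_HOURS:
        raise ValidationError(
            "B-spline interpolation requires at least 4 unique time points; "
            f"track {series.track_id} has {len(means)}")
    hours = np.array(sorted(means), dtype=float)
    vals = np.array([means[int(h)] for h in hours])
    return SplineModel(hours=hours, means=vals)


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

@dataclass
class Reconstruction:
    """One TriangleField per hour: the continuous output of the pipeline."""

    fields: List[TriangleField]
    metadata: dict = field(default_factory=dict)

    @property
    def n_hours(self) -> int:
        return len(self.fields)

    def save(self, out_dir: str) -> None:
        import json
        import os
        os.makedirs(out_dir, exist_ok=True)
        for f in self.fields:
            f.save(os.path.join(out_dir, f"field_{f.hour:03d}.tsv"))
        with open(os.path.join(out_dir, "reconstruction.json"), "w") as fh:
            json.dump({"n_hours": self.n_hours, "metadata": self.metadata}, fh, indent=1)

    @classmethod
    def load(cls, out_dir: str) -> "Reconstruction":
        import json
        import os
        with open(os.path.join(out_dir, "reconstruction.json")) as fh:
            meta = json.load(fh)
        fields = [TriangleField.load(os.path.join(out_dir, f"field_{t:03d}.tsv"))
                  for t in range(meta["n_hours"])]
        return cls(fields=fields, metadata=meta.get("metadata", {}))


def assemble_reconstruction(tracks: TrackSet, splines: Dict[int, SplineModel],
                            movie: Morphomovie) -> Reconstruction:
    """Average every track's spline back onto the hourly meshes."""
    T = movie.n_hours
    missing = [tid for tid in range(len(tracks.tracks)) if tid not in splines]
    if missing:
        raise ValidationError(f"missing spline for track {missing[0]}")
    sums = [np.zeros(m.n_triangles) for m in movie.hourly_meshes]
    counts = [np.zeros(m.n_triangles) for m in movie.hourly_meshes]
    query = np.arange(T, dtype=float)
    for tid, tr in enumerate(tracks.tracks):
        vals = splines[tid](query)
        for h in range(T):
            sums[h][tr.refs[h]] += vals[h]
            counts[h][tr.refs[h]] += 1.0
    fields = []
    for h in range(T):
        if np.any(counts[h] == 0):
            raise ValidationError(f"hour {h}: triangle not covered by any track")
        fields.append(TriangleField(hour=h, values=np.clip(sums[h] / counts[h], 0, 1),
                                    provenance="reconstruction"))
    return Reconstruction(fields=fields)


def reconstruct(movie: Morphomovie, tracks: TrackSet,
                fields: Sequence[TriangleField], metadata: Optional[dict] = None,
                ) -> Reconstruction:
    """Full interpolation stage: collect series, fit splines, reassemble.

    Vectorised across tracks: all tracks share the dataset's sampled hours, so
    the curve-parameter inversion and basis weights are computed once and the
    per-track spline evaluation collapses to a matrix product.
    """
    hours = sorted({f.hour for f in fields})
    if len(hours) < MIN_DISTINCT_HOURS:
        raise ValidationError(
            "B-spline interpolation requires at least 4 unique time points; "
            f"the dataset covers only {len(hours)}")
    T = movie.n_hours
    refs = tracks.refs_matrix()                       # (n_tracks, T)
    n_tracks = refs.shape[0]

    # per-hour mean sample of each track
    means = np.zeros((n_tracks, len(hours)))
    for k, h in enumerate(hours):
        per_hour = [f.values[refs[:, h]] for f in fields if f.hour == h]
        means[:, k] = np.mean(per_hour, axis=0)

    hours_arr = np.array(hours, dtype=float)
    n = len(hours_arr)
    query = np.arange(T, dtype=float)
    u = _invert_time(hours_arr, query)
    A = _basis_matrix(n, u) @ _extension_matrix(n)    # (T, n)
    vals = np.clip(means @ A.T, 0.0, 1.0)             # (n_tracks, T)

    sums = [np.zeros(m.n_triangles) for m in movie.hourly_meshes]
    counts = [np.zeros(m.n_triangles) for m in movie.hourly_meshes]
    for h in range(T):
        np.add.at(sums[h], refs[:, h], vals[:, h])
        np.add.at(counts[h], refs[:, h], 1.0)
    out = []
    for h in range(T):
        if np.any(counts[h] == 0):
            raise ValidationError(f"hour {h}: triangle not covered by any track")
        out.append(TriangleField(hour=h, values=np.clip(sums[h] / counts[h], 0, 1),
                                 provenance="reconstruction"))
    meta = {"imaged_hours": hours, "n_tracks": n_tracks}
    if metadata:
        meta.update(metadata)
    return Reconstruction(fields=out, metadata=meta)
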