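"""Reconstruction-accuracy metrics and the image-count subset experiment.

A reconstruction ``R`` is compared to reference fields ``D`` through the sum
of squared differences ``f(x, y) = sum_i (R_i - g(D_i, x, y, D_min, D_max))^2``
where ``g`` is a piecewise-linear intensity transform anchored at the observed
reference range: it maps ``D_min -> x`` and ``D_max -> y`` linearly and clips
outside the range.  Optimising ``(x, y)`` over [0, 1]^2 absorbs the arbitrary
intensity scaling of the reference before residuals are measured, so the
comparison reflects pattern shape rather than stain strength.

The subset experiment measures how reconstruction error depends on the number
of input images: a subset of ``k`` images (always including the youngest and
oldest, plus two random intermediates so at least four distinct hours are
present, as the B-spline requires) is reconstructed and scored against control
images excluded from the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .errors import ValidationError
from .intensity import TriangleField
from .interpolation import Reconstruction, reconstruct
from .morphomovie import Morphomovie
from .tracking import TrackSet


# ---------------------------------------------------------------------------
# The intensity transform g and its fit
# ---------------------------------------------------------------------------

@dataclass
class TransformParams:
    """Endpoints (x, y) of the linear ramp over the reference range."""

    x: float
    y: float
    d_min: float
    d_max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValidationError(f"x, y must lie in [0, 1]; got ({self.x}, {self.y})")
        if self.d_min >= self.d_max:
            raise ValidationError(f"D_min must be < D_max; got [{self.d_min}, {self.d_max}]")


def transform_g(D, params: TransformParams):
    """Piecewise-linear transform: D_min -> x, D_max -> y, clipped outside."""
    D = np.asarray(D, dtype=float)
    u = np.clip((D - params.d_min) / (params.d_max - params.d_min), 0.0, 1.0)
    out = params.x + (params.y - params.x) * u
    return float(out) if out.ndim == 0 else out


def fit_transform(R: TriangleField, D: TriangleField) -> Tuple[TransformParams, float]:
    """Least-squares fit of (x, y) in [0, 1]^2 minimising the SSD of R vs g(D).

    Seeded at the closed-form unconstrained solution (the objective is linear
    in x and y) projected into the box, then polished with L-BFGS-B.
    """
    if R.hour != D.hour:
        raise ValidationError(f"hour mismatch: {R.hour} vs {D.hour}")
    if len(R.values) != len(D.values):
        raise ValidationError("field lengths differ: fields are not on the same mesh")
    r = R.values
    d = D.values
    d_min, d_max = float(d.min()), float(d.max())
    if d_min == d_max:
        import warnings
        warnings.warn("constant reference field: degenerate range, fitting only "
                      "the intercept (x = y)", stacklevel=2)
        x = float(np.clip(r.mean(), 0.0, 1.0))
        ssd = float(np.sum((r - x) ** 2))
        return TransformParams(x=x, y=x, d_min=0.0, d_max=1.0), ssd

    u = (d - d_min) / (d_max - d_min)
    A = np.column_stack([1.0 - u, u])
    sol, *_ = np.linalg.lstsq(A, r, rcond=None)
    x0 = np.clip(sol, 0.0, 1.0)

    def objective(p):
        resid = r - (A @ p)
        return float(resid @ resid), -2.0 * (A.T @ resid)

    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, 1.0), (0.0, 1.0)])
    p = res.x
    params = TransformParams(x=float(p[0]), y=float(p[1]), d_min=d_min, d_max=d_max)
    ssd = float(np.sum((r - transform_g(d, params)) ** 2))
    return params, ssd


# ---------------------------------------------------------------------------
# Residual curves
# ---------------------------------------------------------------------------

@dataclass
class ResidualCurve:
    hours: List[int]
    residuals: List[float]

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# hour\tresidual\n")
            for h, r in zip(self.hours, self.residuals):
                fh.write(f"{h}\t{r:.17g}\n")


def residual_curve(rec: Reconstruction, references: Sequence[TriangleField],
                   normalize: bool = True) -> ResidualCurve:
    """Per-hour SSD of the reconstruction against reference fields.

    With ``normalize`` the intensity transform g is fitted first; without it
    residuals are plain SSDs.  Multiple references at one hour are averaged.
    """
    by_hour: Dict[int, List[float]] = {}
    for ref in references:
        if ref.hour >= rec.n_hours:
            raise ValidationError(f"reference hour {ref.hour} outside the reconstruction")
        R = rec.fields[ref.hour]
        if normalize:
            _, ssd = fit_transform(R, ref)
        else:
            ssd = float(np.sum((R.values - ref.values) ** 2))
        by_hour.setdefault(ref.hour, []).append(ssd)
    hours = sorted(by_hour)
    return ResidualCurve(hours=hours,
                         residuals=[float(np.mean(by_hour[h])) for h in hours])


# ---------------------------------------------------------------------------
# Subset experiment
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A movie, its track set, and digitized fields keyed by image id."""

    movie: Morphomovie
    tracks: TrackSet
    fields: List[TriangleField]

    def field_ids(self) -> List[str]:
        return [f.provenance for f in self.fields]


@dataclass
class SubsetResult:
    k: int
    seed: int
    subset_ids: List[str]
    control_ids: List[str]
    residuals: List[float]

    @property
    def total(self) -> float:
        return float(np.sum(self.residuals))


def _contains(pool, item) -> bool:
    return any(f is item for f in pool)


def run_subset_experiment(dataset: ExpressionDataset, k: int, seed: int,
                          n_controls: int = 5) -> SubsetResult:
    """Reconstruct from k images and score against excluded controls.

    The subset always contains the youngest and the oldest image; two random
    intermediate frames at distinct hours guarantee at least four unique time
    points; random extras top the subset up to k.  Controls are drawn from the
    images excluded from the subset.  Fully reproducible from ``seed``.
    """
    fields = sorted(dataset.fields, key=lambda f: (f.hour, f.provenance))
    n = len(fields)
    if k < 4:
        raise ValidationError(f"subset size k must be at least 4, got {k}")
    if n < k + n_controls:
        raise ValidationError(
            f"dataset has {n} images; needs at least k + n_controls = {k + n_controls}")
    rng = np.random.default_rng(seed)

    youngest, oldest = fields[0], fields[-1]
    chosen = [youngest, oldest]
    chosen_hours = {youngest.hour, oldest.hour}

    middle = [f for f in fields if f is not youngest and f is not oldest]
    # two intermediate frames at two further distinct hours
    for _ in range(2):
        pool_hours = sorted({f.hour for f in middle if f.hour not in chosen_hours})
        if not pool_hours:
            raise ValidationError("cannot reach 4 distinct hours with this dataset")
        h = pool_hours[rng.integers(len(pool_hours))]
        at_h = [f for f in middle if f.hour == h and not _contains(chosen, f)]
        chosen.append(at_h[rng.integers(len(at_h))])
        chosen_hours.add(h)
    remaining = [f for f in middle if not _contains(chosen, f)]
    extra = k - len(chosen)
    if extra > 0:
        idx = rng.choice(len(remaining), size=extra, replace=False)
        chosen.extend(remaining[i] for i in sorted(idx))

    excluded = [f for f in fields if not _contains(chosen, f)]
    cidx = rng.choice(len(excluded), size=n_controls, replace=False)
    controls = [excluded[i] for i in sorted(cidx)]

    rec = reconstruct(dataset.movie, dataset.tracks, chosen,
                      metadata={"subset_k": k, "seed": int(seed)})
    residuals = []
    for ctrl in controls:
        _, ssd = fit_transform(rec.fields[ctrl.hour], ctrl)
        residuals.append(ssd)
    return SubsetResult(k=k, seed=int(seed),
                        subset_ids=[f.provenance for f in chosen],
                        control_ids=[f.provenance for f in controls],
                        residuals=residuals)


def subset_sweep(dataset: ExpressionDataset, ks: Sequence[int],
                 seeds: Sequence[int], n_controls: int = 5) -> Dict[int, List[float]]:
    """Total subset-experiment residual for every (k, seed) combination."""
    out: Dict[int, List[float]] = {}
    for k in ks:
        out[k] = [run_subset_experiment(dataset, k, seed, n_controls).total
                  for seed in seeds]
    return out
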