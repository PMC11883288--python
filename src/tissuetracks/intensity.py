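"""Digitization of staged expression images and histogram matching.

Digitization projects a grayscale expression image (pre-registered to the mesh
frame by an affine transform) onto one mesh, yielding one intensity per
triangle.  Internally 1 always means high expression: chromogenic stains such
as BCIP/NBT, where dark signal marks expression, are handled by the
``high_is_dark`` polarity flag which inverts values on digitization.

Histogram matching follows the textbook CDF rule: a source value ``z`` maps to
the smallest reference bin ``z'`` whose cumulative mass reaches the source's
cumulative mass at ``z``.  The bootstrap refinement uses it to normalise raw
digitized fields against a first-pass reconstruction.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
from PIL import Image
from scipy.ndimage import map_coordinates

from .errors import ValidationError
from .morphomovie import Mesh

POLARITY_BRIGHT = "high_is_bright"
POLARITY_DARK = "high_is_dark"

DEFAULT_BINS = 256


# ---------------------------------------------------------------------------
# Staged images
# ---------------------------------------------------------------------------

@dataclass
class StagedImage:
    """A grayscale snapshot staged to one mesh timepoint.

    ``image_to_mesh`` is a 6-float affine ``(a, b, c, d, e, f)`` mapping pixel
    centers (column px, row py; rows increase downwards) to mesh coordinates:
    ``x = a*px + b*py + c``, ``y = d*px + e*py + f``.
    """

    pixels: np.ndarray            # (H, W) float in [0, 1]
    hour: int
    polarity: str = POLARITY_BRIGHT
    image_to_mesh: tuple = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError(f"image {self.image_id}: pixels must be 2D")
        if self.polarity not in (POLARITY_BRIGHT, POLARITY_DARK):
            raise ValidationError(f"image {self.image_id}: unknown polarity {self.polarity}")
        a, b, c, d, e, f = self.image_to_mesh
        if abs(a * e - b * d) < 1e-300:
            raise ValidationError(f"image {self.image_id}: non-invertible affine transform")

    @property
    def mesh_to_image(self) -> tuple:
        a, b, c, d, e, f = self.image_to_mesh
        det = a * e - b * d
        ia, ib, id_, ie = e / det, -b / det, -d / det, a / det
        return (ia, ib, -(ia * c + ib * f), id_, ie, -(id_ * c + ie * f))

    def save(self, png_path: str) -> None:
        """Write the raster as 16-bit PNG plus a JSON metadata sidecar."""
        arr = np.clip(np.round(self.pixels * 65535), 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(png_path)
        with open(png_path + ".json", "w") as fh:
            json.dump({
                "hour": self.hour,
                "polarity": self.polarity,
                "image_to_mesh": list(self.image_to_mesh),
                "image_id": self.image_id or os.path.basename(png_path),
            }, fh, indent=1)

    @classmethod
    def load(cls, png_path: str) -> "StagedImage":
        img = Image.open(png_path)
        arr = np.asarray(img, dtype=float)
        if img.mode in ("I;16", "I"):
            arr = arr / 65535.0
        elif arr.dtype.kind in "ui" or arr.max() > 1.0:
            arr = arr / 255.0
        with open(png_path + ".json") as fh:
            meta = json.load(fh)
        return cls(pixels=arr, hour=int(meta["hour"]),
                   polarity=meta.get("polarity", POLARITY_BRIGHT),
                   image_to_mesh=tuple(meta["image_to_mesh"]),
                   image_id=meta.get("image_id", os.path.basename(png_path)))


# ---------------------------------------------------------------------------
# Triangle fields
# ---------------------------------------------------------------------------

@dataclass
class TriangleField:
    """One expression intensity in [0, 1] per triangle of one hourly mesh."""

    hour: int
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("field values must be 1D")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValidationError(
                f"field values outside [0, 1]: range "
                f"[{self.values.min():.4g}, {self.values.max():.4g}]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# hour={self.hour}\tprovenance={self.provenance}\n")
            fh.write("# triangle_index\tvalue\n")
            for i, v in enumerate(self.values):
                fh.write(f"{i}\t{v:.17g}\n")

    @classmethod
    def load(cls, path: str) -> "TriangleField":
        hour, provenance = 0, ""
        values = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "hour=" in line:
                        for part in line[1:].split():
                            if part.startswith("hour="):
                                hour = int(part[5:])
                            elif part.startswith("provenance="):
                                provenance = part[11:]
                    continue
                if line.strip():
                    values.append(float(line.split()[1]))
        return cls(hour=hour, values=np.array(values), provenance=provenance)


def digitize_image(img: StagedImage, mesh: Mesh) -> TriangleField:
    """Project a staged image onto mesh triangles.

    Each triangle gets the mean intensity of the pixels whose centers fall
    inside it; triangles containing no pixel center fall back to a bilinear
    sample at their centroid.  Triangles entirely outside the raster get 0
    with a warning.
    """
    if img.hour != mesh.timepoint:
        raise ValidationError(
            f"image hour {img.hour} does not match mesh timepoint {mesh.timepoint}")
    vals = img.pixels if img.polarity == POLARITY_BRIGHT else 1.0 - img.pixels

    h, w = vals.shape
    a, b, c, d, e, f = img.image_to_mesh
    # pixel centers of the raster region covering the mesh bounding box
    ia, ib, ic, id_, ie, if_ = img.mesh_to_image
    corners = np.array([[mesh.vertices[:, 0].min(), mesh.vertices[:, 1].min()],
                        [mesh.vertices[:, 0].min(), mesh.vertices[:, 1].max()],
                        [mesh.vertices[:, 0].max(), mesh.vertices[:, 1].min()],
                        [mesh.vertices[:, 0].max(), mesh.vertices[:, 1].max()]])
    px_c = ia * corners[:, 0] + ib * corners[:, 1] + ic
    py_c = id_ * corners[:, 0] + ie * corners[:, 1] + if_
    c0 = max(int(np.floor(px_c.min())) - 1, 0)
    c1 = min(int(np.ceil(px_c.max())) + 2, w)
    r0 = max(int(np.floor(py_c.min())) - 1, 0)
    r1 = min(int(np.ceil(py_c.max())) + 2, h)

    sums = np.zeros(mesh.n_triangles)
    counts = np.zeros(mesh.n_triangles, dtype=np.int64)
    if c1 > c0 and r1 > r0:
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        px, py = cols.ravel().astype(float), rows.ravel().astype(float)
        mx = a * px + b * py + c
        my = d * px + e * py + f
        tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
        finder = TrapezoidMapTriFinder(tri)
        idx = finder(mx, my)
        inside = idx >= 0
        np.add.at(sums, idx[inside], vals[rows.ravel()[inside], cols.ravel()[inside]])
        np.add.at(counts, idx[inside], 1)

    out = np.zeros(mesh.n_triangles)
    have = counts > 0
    out[have] = sums[have] / counts[have]

    empty = np.flatnonzero(~have)
    if empty.size:
        cent = mesh.centroids()[empty]
        cpx = ia * cent[:, 0] + ib * cent[:, 1] + ic
        cpy = id_ * cent[:, 0] + ie * cent[:, 1] + if_
        off = (cpx < -0.5) | (cpx > w - 0.5) | (cpy < -0.5) | (cpy > h - 0.5)
        if off.any():
            warnings.warn(
                f"image {img.image_id}: {int(off.sum())} triangle(s) entirely outside "
                "the raster; assigned 0", stacklevel=2)
        ok = empty[~off]
        if ok.size:
            out[ok] = map_coordinates(vals, [cpy[~off], cpx[~off]], order=1, mode="nearest")

    return TriangleField(hour=mesh.timepoint, values=np.clip(out, 0.0, 1.0),
                         provenance=img.image_id or "image")


def rasterize_field(mesh: Mesh, field_: TriangleField, resolution: int = 300,
                    invert: bool = False) -> np.ndarray:
    """Flat-fill rendering of a triangle field as a grayscale raster.

    The inverse of :func:`digitize_image` for display: each pixel inside the
    domain takes its triangle's value (pixels outside are 0).  ``invert``
    flips the display convention (dark = high expression).
    """
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    margin = 2.0
    scale = (resolution - 2 * margin) / max(hi[0] - lo[0], 1e-300)
    W = resolution
    H = int(np.ceil((hi[1] - lo[1]) * scale + 2 * margin))
    cols, rows = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    mx = cols / scale + lo[0] - margin / scale
    my = hi[1] + margin / scale - rows / scale
    tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
    idx = TrapezoidMapTriFinder(tri)(mx.ravel(), my.ravel()).reshape(H, W)
    img = np.zeros((H, W))
    inside = idx >= 0
    img[inside] = field_.values[idx[inside]]
    if invert:
        img[inside] = 1.0 - img[inside]
    return img


# ---------------------------------------------------------------------------
# Histograms and matching
# ---------------------------------------------------------------------------

@dataclass
class Histogram:
    """Counts over B equal-width bins on [0, 1]."""

    counts: np.ndarray
    bins: int = DEFAULT_BINS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) != self.bins:
            raise ValidationError(
                f"histogram must have exactly {self.bins} bins, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("histogram counts must be non-negative")

    @classmethod
    def from_values(cls, values: np.ndarray, bins: int = DEFAULT_BINS) -> "Histogram":
        counts, _ = np.histogram(np.asarray(values, float), bins=bins, range=(0.0, 1.0))
        return cls(counts=counts.astype(float), bins=bins)

    @classmethod
    def from_field(cls, field_: TriangleField, bins: int = DEFAULT_BINS) -> "Histogram":
        return cls.from_values(field_.values, bins=bins)

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.bins) + 0.5) / self.bins


def cdf(h: Histogram) -> np.ndarray:
    """Normalised cumulative distribution over bins (non-decreasing, ends at 1)."""
    total = h.counts.sum()
    if total <= 0:
        raise ValidationError("cannot compute the CDF of an empty histogram")
    return np.cumsum(h.counts) / total


@dataclass
class IntensityMapping:
    """Monotone bin-value -> bin-value lookup produced by histogram matching."""

    table: np.ndarray    # (B,) mapped value for each source bin
    bins: int = DEFAULT_BINS

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if np.any(np.diff(self.table) < 0):
            raise ValidationError("intensity mapping must be monotone non-decreasing")
        if self.table.min() < 0 or self.table.max() > 1:
            raise ValidationError("intensity mapping range must lie in [0, 1]")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        idx = np.clip((np.asarray(values, float) * self.bins).astype(int), 0, self.bins - 1)
        return self.table[idx]


def match_histogram(source: Histogram, reference: Histogram) -> IntensityMapping:
    """CDF-based histogram matching.

    ``M(z)`` is the center of the smallest reference bin ``z'`` with
    ``CDF_r(z') >= CDF_s(z)``; monotone non-decreasing by construction.
    """
    if source.bins != reference.bins:
        raise ValidationError(
            f"bin-count mismatch: source {source.bins} vs reference {reference.bins}")
    cs = cdf(source)
    cr = cdf(reference)
    # first reference bin whose CDF reaches the source CDF (tiny slack for fp)
    idx = np.searchsorted(cr, cs - 1e-12, side="left")
    idx = np.clip(idx, 0, reference.bins - 1)
    return IntensityMapping(table=reference.bin_centers()[idx], bins=source.bins)


def apply_mapping(field_: TriangleField, mapping: IntensityMapping) -> TriangleField:
    """Bin each triangle value and push it through the mapping."""
    return TriangleField(
        hour=field_.hour,
        values=np.clip(mapping(field_.values), 0.0, 1.0),
        provenance=f"{field_.provenance}|matched",
    )
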