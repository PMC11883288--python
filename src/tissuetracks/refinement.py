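"""Bootstrap intensity normalisation of raw digitized fields.

Raw expression images carry inconsistent intensity scales (stain strength,
exposure, specimen variation), and no absolute reference exists to normalise
them against.  The bootstrap uses the pipeline's own first-pass reconstruction
as that reference: each raw digitized field is histogram-matched to the
reconstruction field of its hour, and the reconstruction is then rebuilt from
the matched fields.  Because the temporal B-spline blends neighbouring hours,
the first-pass reconstruction carries a temporally smoothed intensity scale;
matching transfers that consistency back onto the raw data.  One cycle is the
default; more can be requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .intensity import (DEFAULT_BINS, Histogram, TriangleField, apply_mapping,
                        match_histogram)
from .interpolation import Reconstruction, reconstruct
from .morphomovie import Morphomovie
from .tracking import TrackSet


@dataclass
class BootstrapResult:
    refined_fields: List[TriangleField]
    refined: Reconstruction
    initial: Reconstruction
    cycles: int


def bootstrap_cycle(raw_fields: Sequence[TriangleField], movie: Morphomovie,
                    tracks: TrackSet, cycles: int = 1,
                    bins: int = DEFAULT_BINS) -> BootstrapResult:
    """Run ``cycles`` rounds of reconstruction-referenced histogram matching.

    Returns the matched fields and the rebuilt reconstruction, along with the
    initial (cycle-0) reconstruction for comparison.
    """
    fields = list(raw_fields)
    initial = reconstruct(movie, tracks, fields, metadata={"bootstrap_cycles": 0})
    current = initial
    for cycle in range(cycles):
        refined = []
        for f in fields:
            ref_field = current.fields[f.hour]
            if np.ptp(ref_field.values) == 0:
                warnings.warn(
                    f"hour {f.hour}: reconstruction field is uniform; histogram "
                    "matching degenerates to a constant mapping", stacklevel=2)
            mapping = match_histogram(Histogram.from_field(f, bins=bins),
                                      Histogram.from_field(ref_field, bins=bins))
            refined.append(apply_mapping(f, mapping))
        fields = refined
        current = reconstruct(movie, tracks, fields,
                              metadata={"bootstrap_cycles": cycle + 1})
    return BootstrapResult(refined_fields=fields, refined=current,
                           initial=initial, cycles=cycles)
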