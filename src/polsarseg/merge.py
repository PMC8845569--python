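"""Multi-temporal over-segmentation by label-map intersection.

Per-date over-segmentations are combined so that two pixels share a region
in the merged map only if they share a region on every date; spatially
disjoint pieces of the same label tuple become distinct regions
(4-connected relabelling).  The merged map is therefore a common refinement
of all input maps.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .core import LabelMap

__all__ = ["merge_labelmaps"]


def merge_labelmaps(maps: list[LabelMap]) -> LabelMap:
    """Intersect per-date label maps into the multi-temporal over-segmentation.

    Two pixels share an output label iff they share a label in every input
    map and are 4-connected through pixels satisfying the same condition.
    Ids are contiguous 1..N.
    """
    if not maps:
        raise ValueError("need at least one label map")
    shape = maps[0].shape
    for t, m in enumerate(maps):
        if m.shape != shape:
            raise ValueError(
                f"label map at date index {t} has shape {m.shape}, expected {shape}"
            )
    combined = np.zeros(shape, dtype=np.int64)
    for m in maps:
        combined = combined * (int(m.labels.max(initial=0)) + 1) + m.labels
    # collapse the tuple codes to small ints before connected components
    _, inv = np.unique(combined, return_inverse=True)
    labels = measure.label(inv.reshape(shape) + 1, connectivity=1)
    return LabelMap(labels.astype(np.int32))
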