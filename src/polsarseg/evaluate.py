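"""Segmentation accuracy against a reference map, limited by under-segmentation.

For a reference region SS, the candidate region A with the largest overlap
A_SS = |A ∩ SS| represents it.  The under-segmentation ratio

    USR = 1 - A_SS / |A|

measures how much of A spills outside SS.  If USR exceeds the chosen
threshold the reference region scores 0 (its best candidate is a wrong,
under-segmented object); otherwise it scores A_SS / |SS|, the fraction of
the reference region recovered.  The image-wide accuracy is the unweighted
mean over reference regions, so the metric punishes both under-segmentation
(USR rejection) and over-segmentation (small best overlaps).

Reference id 0 marks pixels excluded from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelMap

__all__ = [
    "EvaluationReport",
    "under_segmentation_ratio",
    "region_accuracy",
    "image_accuracy",
    "classification_map",
]


@dataclass
class EvaluationReport:
    """Per-reference-region and overall USR-limited accuracies."""

    usr_threshold: float
    per_region: dict  # reference region id -> accuracy in [0, 1]
    overall: float
    n_excluded_pixels: int

    def validate(self) -> None:
        vals = np.array(list(self.per_region.values()), dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")
        if abs(self.overall - vals.mean()) > 1e-12:
            raise ValueError("overall must be the unweighted mean of per-region values")

    def __str__(self) -> str:  # printed accuracies rounded to 2 decimals
        lines = [f"USR threshold: {self.usr_threshold:.2f}"]
        for rid in sorted(self.per_region):
            lines.append(f"  region {rid}: {self.per_region[rid]:.2f}")
        lines.append(f"overall: {self.overall:.2f}")
        return "\n".join(lines)


def under_segmentation_ratio(candidate_size: int, overlap_size: int) -> float:
    """USR = 1 - overlap/candidate for a candidate region and its best overlap."""
    if candidate_size < 1:
        raise ValueError("candidate region must have at least one pixel")
    if not 0 <= overlap_size <= candidate_size:
        raise ValueError("overlap must lie between 0 and the candidate size")
    return 1.0 - overlap_size / candidate_size


def region_accuracy(reference_mask: np.ndarray, candidate: LabelMap,
                    usr: float, candidate_sizes: np.ndarray | None = None) -> float:
    """Accuracy of one reference region under the max-overlap / USR rule.

    ``candidate_sizes`` optionally supplies the per-id candidate sizes |A|
    (e.g. restricted to the evaluated area); by default full region sizes
    are used.  Ties for the largest overlap go to the lower candidate id.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    ss = int(reference_mask.sum())
    if ss == 0:
        raise ValueError("reference region is empty")
    ids = candidate.labels[reference_mask]
    overlaps = np.bincount(ids, minlength=candidate.n_regions + 1)
    best = int(np.argmax(overlaps[1:])) + 1  # argmax -> lowest id on ties
    a_ss = int(overlaps[best])
    if candidate_sizes is None:
        candidate_sizes = np.bincount(candidate.labels.ravel(),
                                      minlength=candidate.n_regions + 1)
    a = int(candidate_sizes[best])
    if under_segmentation_ratio(a, min(a_ss, a)) > usr:
        return 0.0
    return a_ss / ss


def image_accuracy(reference: LabelMap, candidate: LabelMap, usr: float,
                   full_candidate_size: bool = False) -> EvaluationReport:
    """Evaluate a candidate segmentation against a reference map.

    Reference pixels labelled 0 do not participate.  By default the
    candidate size |A| also counts only pixels inside the evaluated area,
    keeping USR well defined when the reference covers the scene partially;
    ``full_candidate_size=True`` uses full candidate region sizes instead.
    """
    if reference.shape != candidate.shape:
        raise ValueError("reference and candidate grids differ")
    ref = reference.labels
    ref_ids = np.unique(ref[ref > 0])
    if ref_ids.size == 0:
        raise ValueError("reference map has no regions to evaluate")
    if full_candidate_size:
        sizes = np.bincount(candidate.labels.ravel(),
                            minlength=candidate.n_regions + 1)
    else:
        sizes = np.bincount(candidate.labels[ref > 0].ravel(),
                            minlength=candidate.n_regions + 1)
    per_region = {}
    for rid in ref_ids:
        per_region[int(rid)] = region_accuracy(
            ref == rid, candidate, usr, candidate_sizes=sizes
        )
    overall = float(np.mean(list(per_region.values())))
    report = EvaluationReport(
        usr_threshold=usr,
        per_region=per_region,
        overall=overall,
        n_excluded_pixels=int((ref == 0).sum()),
    )
    report.validate()
    return report


def classification_map(reference: LabelMap, candidate: LabelMap, usr: float,
                       full_candidate_size: bool = False) -> np.ndarray:
    """Correct / wrong / excluded pixel map with codes 1 / 0 / 255.

    A reference region's pixels are "correct" where they lie in its
    max-overlap candidate region and that region passed the USR test.
    """
    if reference.shape != candidate.shape:
        raise ValueError("reference and candidate grids differ")
    ref = reference.labels
    out = np.zeros(ref.shape, dtype=np.uint8)
    out[ref == 0] = 255
    if full_candidate_size:
        sizes = np.bincount(candidate.labels.ravel(),
                            minlength=candidate.n_regions + 1)
    else:
        sizes = np.bincount(candidate.labels[ref > 0].ravel(),
                            minlength=candidate.n_regions + 1)
    for rid in np.unique(ref[ref > 0]):
        mask = ref == rid
        ids = candidate.labels[mask]
        overlaps = np.bincount(ids, minlength=candidate.n_regions + 1)
        best = int(np.argmax(overlaps[1:])) + 1
        a = int(sizes[best])
        a_ss = int(overlaps[best])
        if a >= 1 and under_segmentation_ratio(a, min(a_ss, a)) <= usr:
            out[mask & (candidate.labels == best)] = 1
    return out
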