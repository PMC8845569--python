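"""End-to-end orchestration of the multi-temporal segmentation pipeline.

Stage order: Pauli features -> per-date mean-shift over-segmentation ->
cross-date label-map merge -> per-date Wishart edges + oriented NMS ->
cross-date edge fusion -> region graph (centers + affinity) ->
normalized-cuts partition -> projection to a pixel label map.

With a single date the merge and fusion steps are identities, so the same
code path is the single-date baseline.  All in-memory stages live here so
tests and the CLI share one implementation; file I/O is done only by
:func:`run_pipeline`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import CovarianceImage, LabelMap, PauliImage, multilook, pauli_features
from .edges import EdgeMap, detect_edges, fuse_edges, oriented_nms
from .graph import RegionGraph, build_affinity
from .meanshift import MeanShiftConfig, enforce_min_region, label_modes, meanshift_filter
from .merge import merge_labelmaps
from .ncut import partition_graph, regions_to_pixels

logger = logging.getLogger("polsarseg")

__all__ = [
    "PipelineParams",
    "PipelineResult",
    "per_date_stages",
    "combine_and_cut",
    "segment_timeseries",
    "run_pipeline",
    "pipeline_stats",
]


@dataclass
class PipelineParams:
    """Every tunable of the pipeline, with the published defaults.

    hs, hr : mean-shift spatial / range bandwidths (pixels, linear Pauli
        amplitude units).
    min_region : minimum over-segmentation region size M in pixels.
    window : Wishart edge-detector window side (odd).
    alpha_deg : azimuth step of the extensibility ray cast.
    sigma_c : affinity kernel scale; None selects 0.1 x max dissimilarity.
    k : number of final segments.
    multilook_window : optional (rows, cols) block-average applied before
        everything else; None skips it.
    prefilter : optionally smooth the Pauli features with an extra 5x5
        mean-shift filtering pass before over-segmentation.
    method : k-way strategy, "kmeans" or "recursive".
    """

    hs: float = 7.0
    hr: float = 6.5
    min_region: int = 1
    max_iter: int = 100
    tol: float = 1e-3
    window: int = 7
    alpha_deg: float = 10.0
    sigma_c: float | None = None
    k: int = 47
    multilook_window: tuple[int, int] | None = None
    prefilter: bool = False
    method: str = "kmeans"
    seed: int = 0

    def meanshift_config(self) -> MeanShiftConfig:
        return MeanShiftConfig(
            hs=self.hs, hr=self.hr, min_region=self.min_region,
            max_iter=self.max_iter, tol=self.tol,
        )


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one run."""

    per_date_labels: list
    per_date_edges: list      # thinned (NMS) per-date edge maps
    merged: LabelMap
    fused: EdgeMap
    graph: RegionGraph
    assignment: np.ndarray
    segmentation: LabelMap
    counts: dict = field(default_factory=dict)


def per_date_stages(cov: CovarianceImage, params: PipelineParams
                    ) -> tuple[LabelMap, EdgeMap]:
    """Single-date work: over-segmentation labels and thinned edge map."""
    if params.multilook_window is not None:
        cov = multilook(cov, *params.multilook_window)
    pauli = pauli_features(cov)
    if params.prefilter:
        pre_cfg = MeanShiftConfig(hs=2.5, hr=params.hr, min_region=1,
                                  max_iter=params.max_iter, tol=params.tol)
        pauli, _ = meanshift_filter(pauli, pre_cfg)
    cfg = params.meanshift_config()
    _, joint = meanshift_filter(pauli, cfg)
    lbl = enforce_min_region(label_modes(joint, cfg), pauli, cfg.min_region)
    edge = oriented_nms(detect_edges(cov, params.window))
    logger.info(
        "date %s: %d over-segmentation regions", cov.date_tag, lbl.n_regions
    )
    return lbl, edge


def combine_and_cut(per_date_labels: list, per_date_edges: list,
                    params: PipelineParams) -> PipelineResult:
    """Cross-date stages: merge, fuse, build the graph, cut, project."""
    merged = merge_labelmaps(per_date_labels)
    fused = fuse_edges(per_date_edges)
    logger.info("merged over-segmentation: %d regions", merged.n_regions)
    graph = build_affinity(merged, fused, alpha_deg=params.alpha_deg,
                           sigma_c=params.sigma_c)
    k = min(params.k, graph.n_regions)
    assignment = partition_graph(graph, k, seed=params.seed, method=params.method)
    segmentation = regions_to_pixels(merged, assignment)
    logger.info("final segmentation: %d segments", segmentation.n_regions)
    counts = {
        "per_date_regions": [m.n_regions for m in per_date_labels],
        "merged_regions": merged.n_regions,
        "final_segments": segmentation.n_regions,
    }
    return PipelineResult(
        per_date_labels=per_date_labels,
        per_date_edges=per_date_edges,
        merged=merged,
        fused=fused,
        graph=graph,
        assignment=assignment,
        segmentation=segmentation,
        counts=counts,
    )


def segment_timeseries(covs: list[CovarianceImage],
                       params: PipelineParams) -> PipelineResult:
    """Run the whole pipeline on co-registered covariance images (>= 1 date)."""
    if not covs:
        raise ValueError("need at least one covariance image")
    shape = covs[0].shape
    for t, c in enumerate(covs):
        if c.shape != shape:
            raise ValueError(
                f"image at date index {t} has shape {c.shape}, expected {shape}"
            )
    stages = []
    for cov in covs:
        stages.append(_run_stage(f"per-date processing ({cov.date_tag})",
                                 per_date_stages, cov, params))
    labels = [s[0] for s in stages]
    edges = [s[1] for s in stages]
    return _run_stage("graph partitioning", combine_and_cut, labels, edges, params)


def _run_stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def pipeline_stats(height: int, width: int, n_regions: int) -> dict:
    """Problem-size bookkeeping recorded in every run manifest.

    Building a pixel-level affinity matrix costs C(n_pixels, 2) pairwise
    operations; the region graph costs C(n_regions, 2).  The ratio is the
    cost reduction bought by over-segmentation.
    """
    n_pixels = height * width
    pixel_pairs = math.comb(n_pixels, 2)
    region_pairs = math.comb(max(n_regions, 2), 2)
    return {
        "n_pixels": n_pixels,
        "pixel_pairs": pixel_pairs,
        "region_pairs": region_pairs,
        "cost_reduction_factor": pixel_pairs / region_pairs,
    }


def run_pipeline(covs: list[CovarianceImage], params: PipelineParams,
                 out_dir: str | Path) -> PipelineResult:
    """Run the pipeline and write every intermediate artifact plus a manifest.

    Artifacts (TIFF unless noted): per-date label maps and thinned edge
    maps, the merged label map, the fused edge map, region centers (CSV),
    the affinity matrix (Matrix Market), the final segmentation, and
    ``manifest.json`` recording parameters, seeds and per-stage region
    counts — enough to reproduce the run exactly.
    """
    import pandas as pd
    from scipy.io import mmwrite

    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = segment_timeseries(covs, params)
    tags = [c.date_tag or f"date{t}" for t, c in enumerate(covs)]
    for tag, lbl, edge in zip(tags, result.per_date_labels, result.per_date_edges):
        pio.write_labelmap(out / f"labels_{tag}.tif", lbl)
        pio.write_edge_strength(out / f"edges_{tag}.tif", edge.strength)
    pio.write_labelmap(out / "merged_labels.tif", result.merged)
    pio.write_edge_strength(out / "fused_edges.tif", result.fused.strength)
    pio.write_labelmap(out / "segmentation.tif", result.segmentation)
    pd.DataFrame(
        {
            "region_id": np.arange(1, result.graph.n_regions + 1),
            "row": result.graph.centers[:, 0],
            "col": result.graph.centers[:, 1],
        }
    ).to_csv(out / "centers.csv", index=False)
    mmwrite(out / "affinity.mtx", np.asarray(result.graph.affinity))
    h, w = covs[0].shape
    manifest = {
        "dates": tags,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
        "seed": params.seed,
        "sigma_c": result.graph.sigma_c,
        "counts": result.counts,
        "stats": pipeline_stats(h, w, result.counts["merged_regions"]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result
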