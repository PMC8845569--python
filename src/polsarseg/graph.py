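"""Region graph construction: extensibility centers and edge-based affinity.

Each over-segmentation region is represented by a single interior pixel —
the maximiser of its *extensibility*

    E(p in S) = prod_i L(alpha * i),   i = 1..360/alpha,

where L(a) is the ray-cast distance (0.5-pixel steps) from p to the first
sample outside the region along azimuth a.  For regular shapes this is the
geometric centre; for irregular shapes it is a deep interior point.

Pairwise dissimilarity between regions x, y is the maximum thinned edge
strength along the straight line between their centers,
D_c(x, y) = max_{z on l} D*(z), and the affinity is the Gaussian kernel
W(x, y) = exp(-D_c^2 / (2 sigma_c^2)).  A line crossing a strong edge ridge
therefore yields near-zero affinity regardless of where along the line the
crossing happens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as bresenham_line

from .core import LabelMap
from .edges import EdgeMap

__all__ = ["RegionGraph", "region_center", "line_max_edge", "build_affinity"]


@dataclass
class RegionGraph:
    """Region centers plus symmetric dissimilarity/affinity matrices."""

    centers: np.ndarray        # (N, 2) int, (row, col) inside each region
    dissimilarity: np.ndarray  # (N, N) float, >= 0, zero diagonal
    affinity: np.ndarray       # (N, N) float in (0, 1], unit diagonal
    sigma_c: float

    @property
    def n_regions(self) -> int:
        return len(self.centers)

    def validate(self) -> None:
        n = self.n_regions
        for name, m in (("dissimilarity", self.dissimilarity),
                        ("affinity", self.affinity)):
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix must be {n}x{n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} matrix must be symmetric")
        if (self.dissimilarity < 0).any():
            raise ValueError("dissimilarities must be >= 0")
        if not np.allclose(np.diag(self.affinity), 1.0):
            raise ValueError("affinity diagonal must be 1")
        if (self.affinity <= 0).any() or (self.affinity > 1 + 1e-12).any():
            raise ValueError("affinities must lie in (0, 1]")
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")


def region_center(lbl: LabelMap, region_id: int, alpha_deg: float = 10.0
                  ) -> tuple[int, int]:
    """Extensibility-maximising representative pixel of one region.

    Casts ``360/alpha_deg`` rays from every pixel of the region in 0.5-pixel
    steps; a ray's length L is the distance of the first sample falling
    outside the region (so L >= 0.5 even on boundary pixels, and the product
    of lengths never vanishes).  Returns the pixel with the largest product,
    ties broken by smallest (row, col).
    """
    if 360.0 % alpha_deg != 0:
        raise ValueError("alpha_deg must divide 360")
    mask = lbl.labels == region_id
    pix = np.argwhere(mask)
    if len(pix) == 0:
        raise ValueError(f"region {region_id} is empty")
    if len(pix) == 1:
        return int(pix[0, 0]), int(pix[0, 1])

    n_rays = int(round(360.0 / alpha_deg))
    angles = np.deg2rad(alpha_deg * np.arange(1, n_rays + 1))
    dirs = np.stack([np.sin(angles), np.cos(angles)], axis=1)  # (n_rays, 2)

    rmin, cmin = pix.min(axis=0)
    rmax, cmax = pix.max(axis=0)
    # membership lookup padded by one so off-bbox samples read False
    box = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    box[1:-1, 1:-1] = mask[rmin:rmax + 1, cmin:cmax + 1]
    diag = float(np.hypot(rmax - rmin + 2, cmax - cmin + 2))
    steps = np.arange(1, int(np.ceil(diag / 0.5)) + 2) * 0.5  # (S,)

    best_logE = -np.inf
    best_px = (int(pix[0, 0]), int(pix[0, 1]))
    chunk = max(1, int(2e6) // (n_rays * len(steps)))
    for start in range(0, len(pix), chunk):
        p = pix[start:start + chunk].astype(float)  # (n, 2)
        # sample positions: (n, n_rays, S, 2)
        pos = p[:, None, None, :] + steps[None, None, :, None] * dirs[None, :, None, :]
        ir = np.floor(pos[..., 0] - rmin + 0.5).astype(int) + 1
        ic = np.floor(pos[..., 1] - cmin + 0.5).astype(int) + 1
        ir = np.clip(ir, 0, box.shape[0] - 1)
        ic = np.clip(ic, 0, box.shape[1] - 1)
        inside = box[ir, ic]  # (n, n_rays, S)
        first_out = np.argmin(inside, axis=2)  # index of first False
        length = (first_out + 1) * 0.5
        logE = np.sum(np.log(length), axis=1)  # (n,)
        k = int(np.argmax(logE))
        # ties broken by row-major order: strict > keeps the earliest (and
        # pix is generated in row-major order by argwhere)
        if logE[k] > best_logE + 0.0:
            cand = np.nonzero(logE >= logE[k])[0]
            k = int(cand[0])
            if logE[k] > best_logE:
                best_logE = float(logE[k])
                best_px = (int(pix[start + k, 0]), int(pix[start + k, 1]))
    return best_px


def line_max_edge(edges: EdgeMap, p: tuple[int, int], q: tuple[int, int]) -> float:
    """Maximum thinned edge strength along the Bresenham segment p -> q.

    Bresenham rasterisation is direction dependent; both directions are
    rasterised and the larger maximum returned, which makes the result
    symmetric in (p, q).  Endpoints are included.
    """
    h, w = edges.shape
    for r, c in (p, q):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"pixel ({r}, {c}) outside the {h}x{w} grid")
    rr, cc = bresenham_line(p[0], p[1], q[0], q[1])
    fwd = float(edges.strength[rr, cc].max())
    rr, cc = bresenham_line(q[0], q[1], p[0], p[1])
    bwd = float(edges.strength[rr, cc].max())
    return max(fwd, bwd)


def build_affinity(lbl: LabelMap, edges: EdgeMap, alpha_deg: float = 10.0,
                   sigma_c: float | None = None) -> RegionGraph:
    """Build the full region graph from a label map and a thinned edge map.

    ``sigma_c`` defaults to 0.1 times the largest pairwise dissimilarity
    (a standard normalized-cuts kernel-scale heuristic); if every
    dissimilarity is zero it falls back to 1.
    """
    if lbl.shape != edges.shape:
        raise ValueError("label map and edge map grids differ")
    n = lbl.n_regions
    centers = np.array(
        [region_center(lbl, rid, alpha_deg) for rid in range(1, n + 1)], dtype=int
    )
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = line_max_edge(
                edges, tuple(centers[i]), tuple(centers[j])
            )
    if sigma_c is None:
        dmax = float(d.max(initial=0.0))
        sigma_c = 0.1 * dmax if dmax > 0 else 1.0
    w = np.exp(-(d**2) / (2.0 * sigma_c**2))
    np.fill_diagonal(w, 1.0)
    graph = RegionGraph(centers, d, w, float(sigma_c))
    graph.validate()
    return graph
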