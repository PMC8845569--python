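"""Wishart likelihood-ratio edge detection for PolSAR covariance rasters.

Edge strength between two pixel populations is measured by the
likelihood-ratio test of equality of their covariance matrices under the
complex Wishart model.  With half-window sample means S_i, S_j over N_i and
N_j pixels and the pooled estimate S = (N_i S_i + N_j S_j)/(N_i + N_j), the
(look-normalised) log likelihood-ratio statistic is

    D(S_i, S_j) = (N_i + N_j) ln|S| - N_i ln|S_i| - N_j ln|S_j|  >= 0,

zero iff the two sample means coincide and growing with their dissimilarity.
The detector slides an odd window over the image, splits it into two halves
along four candidate edge orientations (0, 45, 90, 135 degrees — the angle
of the edge *line*, not of the gradient), and keeps the per-pixel maximum
D_max with its orientation theta*.  Oriented non-maximal suppression then
thins the response perpendicular to theta*, and the per-pixel maximum over
dates fuses a time series into one edge map.

D is independent of the number of looks: the 1/n normalisation cancels the
n in the Wishart likelihood exponents, so maps from dates with different
look counts are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CovarianceImage, batched_safe_logdet, safe_logdet

__all__ = [
    "EdgeMap",
    "RegionStats",
    "wishart_distance",
    "directional_halves",
    "detect_edges",
    "oriented_nms",
    "fuse_edges",
]

DIRECTIONS = (0, 45, 90, 135)

# offsets perpendicular to each edge-line orientation, used by the NMS
_PERP = {
    0: ((-1, 0), (1, 0)),     # horizontal edge: compare up/down
    90: ((0, -1), (0, 1)),    # vertical edge: compare left/right
    45: ((-1, -1), (1, 1)),   # anti-diagonal edge: compare along the main diagonal
    135: ((-1, 1), (1, -1)),  # main-diagonal edge: compare along the anti-diagonal
}


@dataclass
class RegionStats:
    """Sample count and mean covariance of a pixel population."""

    n_samples: float
    mean_cov: np.ndarray  # 3x3 Hermitian

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        m = np.asarray(self.mean_cov)
        if m.shape != (3, 3) or not np.allclose(m, m.conj().T, rtol=1e-9, atol=1e-12):
            raise ValueError("mean_cov must be 3x3 Hermitian")


@dataclass
class EdgeMap:
    """Per-pixel maximum edge strength D_max and its orientation theta*.

    ``direction_deg`` is meaningful only where ``strength > 0``.
    """

    strength: np.ndarray       # float (H, W), >= 0
    direction_deg: np.ndarray  # int (H, W), values in DIRECTIONS

    def __post_init__(self) -> None:
        self.strength = np.asarray(self.strength, dtype=float)
        self.direction_deg = np.asarray(self.direction_deg)
        if self.strength.shape != self.direction_deg.shape:
            raise ValueError("strength and direction grids must match")

    @property
    def shape(self) -> tuple[int, int]:
        return self.strength.shape

    def validate(self) -> None:
        if not np.isfinite(self.strength).all():
            raise ValueError("edge strengths must be finite")
        if (self.strength < 0).any():
            raise ValueError("edge strengths must be non-negative")


def wishart_distance(a: RegionStats, b: RegionStats) -> float:
    """Wishart likelihood-ratio dissimilarity between two regions.

    Symmetric, non-negative (clamped at tiny negative round-off), zero for
    identical statistics.
    """
    a.validate()
    b.validate()
    na, nb = a.n_samples, b.n_samples
    if np.array_equal(a.mean_cov, b.mean_cov):
        return 0.0  # pooled mean equals both means: D is exactly zero
    pooled = (na * np.asarray(a.mean_cov) + nb * np.asarray(b.mean_cov)) / (na + nb)
    # grouped so the evaluation is commutative in (a, b): exact symmetry
    d = (na + nb) * safe_logdet(pooled) - (
        na * safe_logdet(a.mean_cov) + nb * safe_logdet(b.mean_cov)
    )
    return max(d, 0.0)


def directional_halves(window: int, direction: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-offset sets of the two half-windows split by an edge line.

    For an odd ``window`` w, returns two disjoint, equal-sized offset arrays
    (each w(w-1)/2 offsets) that mirror each other through the split line;
    the line itself (centre row/column or diagonal) is excluded.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("edge-detector window must be odd and >= 3")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    half = window // 2
    rr, cc = np.mgrid[-half:half + 1, -half:half + 1]
    if direction == 0:
        side = rr          # rows above vs below the centre row
    elif direction == 90:
        side = cc          # columns left vs right of the centre column
    elif direction == 45:
        side = rr + cc     # open triangles split by the anti-diagonal
    else:  # 135
        side = rr - cc     # open triangles split by the main diagonal
    neg = np.stack([rr[side < 0], cc[side < 0]], axis=1)
    pos = np.stack([rr[side > 0], cc[side > 0]], axis=1)
    return neg, pos


def _half_mean_covariance(data: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Mean covariance over an offset set at every pixel (reflect-padded)."""
    h, w = data.shape[:2]
    half = int(np.abs(offsets).max())
    k = 2 * half + 1
    kernel = np.zeros((k, k))
    for dr, dc in offsets:
        kernel[dr + half, dc + half] = 1.0 / len(offsets)
    out = np.empty((h, w, 3, 3), dtype=complex)
    for i in range(3):
        for j in range(i, 3):
            re = ndimage.correlate(np.real(data[..., i, j]), kernel, mode="reflect")
            im = ndimage.correlate(np.imag(data[..., i, j]), kernel, mode="reflect")
            out[..., i, j] = re + 1j * im
            if i != j:
                out[..., j, i] = re - 1j * im
    return out


def detect_edges(cov: CovarianceImage, window: int = 7) -> EdgeMap:
    """Four-direction Wishart edge detector.

    At every pixel and for each orientation, the covariances of the two
    directional half-windows are averaged (reflect padding at borders) and
    their Wishart dissimilarity computed; the maximum over orientations is
    kept together with its orientation (ties resolved toward the smaller
    angle).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("edge-detector window must be odd and >= 3")
    h, w = cov.shape
    if window >= 2 * min(h, w):
        raise ValueError(f"window {window} too large for a {h}x{w} image")
    strengths = np.empty((len(DIRECTIONS), h, w))
    for k, theta in enumerate(DIRECTIONS):
        neg, pos = directional_halves(window, theta)
        n = float(len(neg))
        mean_a = _half_mean_covariance(cov.data, neg)
        mean_b = _half_mean_covariance(cov.data, pos)
        ld_a = batched_safe_logdet(mean_a)
        ld_b = batched_safe_logdet(mean_b)
        ld_pool = batched_safe_logdet(0.5 * (mean_a + mean_b))
        strengths[k] = 2 * n * ld_pool - n * ld_a - n * ld_b
    strengths = np.clip(strengths, 0.0, None)
    best = np.argmax(strengths, axis=0)  # first (smallest-angle) max wins ties
    direction = np.asarray(DIRECTIONS, dtype=np.int16)[best]
    strength = np.take_along_axis(strengths, best[None], axis=0)[0]
    return EdgeMap(strength, direction)


def oriented_nms(edges: EdgeMap) -> EdgeMap:
    """Thin an edge map perpendicular to each pixel's orientation.

    A pixel keeps its strength iff it is >= both neighbours one step along
    the direction perpendicular to its theta*; border pixels compare only
    against in-grid neighbours.  Ties (plateaus) are kept.
    """
    edges.validate()
    h, w = edges.shape
    padded = np.full((h + 2, w + 2), -np.inf)
    padded[1:-1, 1:-1] = edges.strength
    keep = np.zeros((h, w), dtype=bool)
    for theta, ((r1, c1), (r2, c2)) in _PERP.items():
        sel = edges.direction_deg == theta
        n1 = padded[1 + r1:h + 1 + r1, 1 + c1:w + 1 + c1]
        n2 = padded[1 + r2:h + 1 + r2, 1 + c2:w + 1 + c2]
        keep |= sel & (edges.strength >= n1) & (edges.strength >= n2)
    return EdgeMap(np.where(keep, edges.strength, 0.0), edges.direction_deg.copy())


def fuse_edges(edge_maps: list[EdgeMap]) -> EdgeMap:
    """Per-pixel maximum over dates; orientation taken from the winning date.

    Ties go to the earliest date.  The fused strength dominates every input
    pointwise by construction.
    """
    if not edge_maps:
        raise ValueError("need at least one edge map")
    shape = edge_maps[0].shape
    for t, e in enumerate(edge_maps):
        if e.shape != shape:
            raise ValueError(
                f"edge map at date index {t} has shape {e.shape}, expected {shape}"
            )
    stack = np.stack([e.strength for e in edge_maps])
    dirs = np.stack([e.direction_deg for e in edge_maps])
    best = np.argmax(stack, axis=0)  # first max -> earliest date on ties
    strength = np.take_along_axis(stack, best[None], axis=0)[0]
    direction = np.take_along_axis(dirs, best[None], axis=0)[0]
    return EdgeMap(strength, direction)
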