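"""Joint spatial-range mean-shift over-segmentation of Pauli feature images.

Mean-shift is mode seeking on a kernel density estimate.  Each pixel is a
point in a 5-D joint space — two spatial coordinates scaled by the spatial
bandwidth ``hs`` and three Pauli amplitudes scaled by the range bandwidth
``hr`` — and is iteratively moved to the weighted mean of the sample points
around its current position:

    M(x) = sum_i G((x_i - x)/h) x_i / sum_i G((x_i - x)/h)

with a separable Gaussian kernel over the spatial and range blocks and
uniform sample weights.  Pixels whose convergence points coincide (within
half a bandwidth in each block) belong to the same density mode; splitting
the mode groups into 4-connected components yields the over-segmentation.
A minimum-region-size pass then merges fragments smaller than ``min_region``
pixels into their most similar 4-adjacent neighbour.

Over-segmentation is the contract: regions should never straddle a true
parcel boundary, while splitting parcels into several regions is expected
and repaired later by graph partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .core import InvalidDataError, LabelMap, PauliImage

__all__ = [
    "MeanShiftConfig",
    "meanshift_filter",
    "label_modes",
    "enforce_min_region",
    "oversegment",
]


@dataclass
class MeanShiftConfig:
    """Bandwidths and stopping rules for the joint-space mean-shift.

    hs : spatial bandwidth in pixels.
    hr : range bandwidth in linear Pauli amplitude units.
    min_region : minimum region size M in pixels enforced after mode labelling.
    max_iter, tol : per-pixel iteration cap and joint-space convergence
        threshold (displacement in bandwidth-normalised units).
    """

    hs: float = 7.0
    hr: float = 6.5
    min_region: int = 1
    max_iter: int = 100
    tol: float = 1e-3

    def validate(self) -> None:
        if self.hs <= 0 or self.hr <= 0:
            raise ValueError("bandwidths hs, hr must be positive")
        if self.min_region < 1:
            raise ValueError("min_region must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def meanshift_filter(img: PauliImage, cfg: MeanShiftConfig
                     ) -> tuple[PauliImage, np.ndarray]:
    """Run mean-shift to convergence at every pixel.

    Returns the filtered image (range part of each pixel's convergence point)
    and the full converged joint points as an ``(H, W, 5)`` array in raw units
    ``(row, col, f1, f2, f3)``.

    Sample points beyond ``3*hs`` spatial distance carry negligible Gaussian
    weight and are excluded (kernel truncation), so one update costs
    O(hs^2) rather than O(N) per pixel.
    """
    cfg.validate()
    feats = img.features
    if not np.isfinite(feats).all():
        r, c = np.argwhere(~np.isfinite(feats).all(axis=-1))[0]
        raise InvalidDataError(f"non-finite Pauli feature at pixel ({r}, {c})")
    h, w = img.shape
    hs, hr = cfg.hs, cfg.hr

    rows, cols = np.mgrid[0:h, 0:w]
    # current joint state, one row per pixel: (row, col, f1, f2, f3)
    cur_s = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    cur_r = feats.reshape(-1, 3).astype(float)

    radius = int(np.ceil(3.0 * hs))
    dr, dc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    keep = (dr * dr + dc * dc) <= (3.0 * hs) ** 2
    offsets = np.stack([dr[keep], dc[keep]], axis=1)  # (K, 2)
    n_off = len(offsets)

    active = np.ones(h * w, dtype=bool)
    # chunk so the (pixels x neighbours) scratch arrays stay modest
    chunk = max(1, int(4e6) // max(n_off, 1))
    for _ in range(cfg.max_iter):
        idx_active = np.nonzero(active)[0]
        if idx_active.size == 0:
            break
        for start in range(0, idx_active.size, chunk):
            idx = idx_active[start:start + chunk]
            s = cur_s[idx]  # (n, 2)
            r = cur_r[idx]  # (n, 3)
            center = np.rint(s).astype(int)
            nbr = center[:, None, :] + offsets[None, :, :]  # (n, K, 2)
            valid = (
                (nbr[..., 0] >= 0) & (nbr[..., 0] < h)
                & (nbr[..., 1] >= 0) & (nbr[..., 1] < w)
            )
            nr = np.clip(nbr[..., 0], 0, h - 1)
            nc = np.clip(nbr[..., 1], 0, w - 1)
            ds2 = ((nr - s[:, None, 0]) ** 2 + (nc - s[:, None, 1]) ** 2) / hs**2
            nf = feats[nr, nc]  # (n, K, 3)
            dr2 = np.sum((nf - r[:, None, :]) ** 2, axis=-1) / hr**2
            wgt = np.exp(-0.5 * (ds2 + dr2))
            wgt[~valid | (ds2 > 9.0)] = 0.0
            wsum = wgt.sum(axis=1)
            wsum[wsum == 0] = 1.0  # isolated point: stays put
            new_s = np.stack(
                [(wgt * nr).sum(axis=1) / wsum, (wgt * nc).sum(axis=1) / wsum], axis=1
            )
            new_r = (wgt[..., None] * nf).sum(axis=1) / wsum[:, None]
            disp2 = (
                np.sum((new_s - s) ** 2, axis=1) / hs**2
                + np.sum((new_r - r) ** 2, axis=1) / hr**2
            )
            cur_s[idx] = new_s
            cur_r[idx] = new_r
            active[idx] = disp2 >= cfg.tol**2
    joint = np.concatenate([cur_s, cur_r], axis=1).reshape(h, w, 5)
    return PauliImage(cur_r.reshape(h, w, 3)), joint


def label_modes(joint: np.ndarray, cfg: MeanShiftConfig) -> LabelMap:
    """Group convergence points into modes and split into 4-connected regions.

    Two pixels share a mode when their convergence points are transitively
    linked through pairs lying within ``hs/2`` spatially and ``hr/2`` in
    range.  Each mode is then split into its 4-connected components and the
    components relabelled 1..N.
    """
    cfg.validate()
    h, w, _ = joint.shape
    pts_s = joint[..., :2].reshape(-1, 2)
    pts_r = joint[..., 2:].reshape(-1, 3)
    tree = cKDTree(pts_s)
    pairs = tree.query_pairs(cfg.hs / 2.0, output_type="ndarray")
    if len(pairs):
        d_r = np.linalg.norm(pts_r[pairs[:, 0]] - pts_r[pairs[:, 1]], axis=1)
        pairs = pairs[d_r <= cfg.hr / 2.0]
    # transitive closure via union of the pair graph
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = h * w
    if len(pairs):
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, comp = connected_components(g, directed=False)
    else:
        comp = np.arange(n)
    group = comp.reshape(h, w).astype(np.int64) + 1
    labels = measure.label(group, connectivity=1)
    return LabelMap(labels.astype(np.int32))


def enforce_min_region(lbl: LabelMap, img: PauliImage, m: int) -> LabelMap:
    """Merge every region smaller than ``m`` pixels into its nearest neighbour.

    Iteratively takes the smallest undersized region (ties: lowest id) and
    merges it into the 4-adjacent region whose mean Pauli feature vector is
    closest in Euclidean distance, until no region is smaller than ``m``.
    Ids are relabelled contiguously at the end.  If the whole image holds
    fewer than ``m`` pixels the single remaining region is returned as is.
    """
    if m < 1:
        raise ValueError("minimum region size must be >= 1")
    labels = lbl.labels.astype(np.int64).copy()
    feats = img.features.reshape(-1, 3)
    flat = labels.ravel()
    n = int(flat.max())
    sizes = np.bincount(flat, minlength=n + 1).astype(np.int64)
    sums = np.zeros((n + 1, 3))
    np.add.at(sums, flat, feats)

    adj: list[set] = [set() for _ in range(n + 1)]
    right = np.stack([labels[:, :-1].ravel(), labels[:, 1:].ravel()], axis=1)
    down = np.stack([labels[:-1, :].ravel(), labels[1:, :].ravel()], axis=1)
    edges = np.concatenate([right, down])
    edges = edges[edges[:, 0] != edges[:, 1]]
    for a, b in np.unique(edges, axis=0):
        adj[a].add(int(b))
        adj[b].add(int(a))

    alive = np.ones(n + 1, dtype=bool)
    alive[0] = False
    while True:
        small = np.nonzero(alive & (sizes < m) & (np.arange(n + 1) > 0))[0]
        if small.size == 0:
            break
        order = np.lexsort((small, sizes[small]))
        sid = int(small[order[0]])
        nbrs = sorted(adj[sid])
        if not nbrs:
            break  # single region covering the whole image
        mean_s = sums[sid] / sizes[sid]
        dists = [np.linalg.norm(sums[t] / sizes[t] - mean_s) for t in nbrs]
        target = int(nbrs[int(np.argmin(dists))])
        labels[labels == sid] = target
        sizes[target] += sizes[sid]
        sums[target] += sums[sid]
        sizes[sid] = 0
        alive[sid] = False
        for t in adj[sid]:
            adj[t].discard(sid)
            if t != target:
                adj[t].add(target)
                adj[target].add(t)
        adj[target].discard(target)
        adj[sid] = set()

    old_ids = np.unique(labels)
    remap = np.zeros(old_ids.max() + 1, dtype=np.int32)
    remap[old_ids] = np.arange(1, len(old_ids) + 1)
    return LabelMap(remap[labels])


def oversegment(img: PauliImage, cfg: MeanShiftConfig) -> LabelMap:
    """Full per-date over-segmentation: filter -> mode labelling -> min size."""
    _, joint = meanshift_filter(img, cfg)
    lbl = label_modes(joint, cfg)
    return enforce_min_region(lbl, img, cfg.min_region)
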