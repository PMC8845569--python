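"""Normalized-cuts partitioning of the region affinity graph.

The normalized cut of a bipartition (A, B) of a weighted graph is

    Ncut(A, B) = cut(A, B)/assoc(A, V) + cut(A, B)/assoc(B, V),

with cut(A, B) the total cross weight and assoc(A, V) a side's total
connection to the whole graph.  Normalising by association penalises
cutting off small isolated groups, which the plain minimum cut favours.
Self-loops (the unit affinity diagonal) are excluded from both sums.

k-way partitioning uses the standard spectral relaxation: the k
smallest-eigenvalue eigenvectors of the symmetric-normalised Laplacian
D^{-1/2} (D - W) D^{-1/2} form an embedding whose row-normalised rows are
clustered by k-means.  A recursive two-way variant (repeatedly splitting by
the thresholded Fiedler vector) is provided for comparison.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .core import LabelMap
from .graph import RegionGraph

__all__ = ["cut_value", "ncut_value", "partition_graph", "regions_to_pixels"]


def _check_partition(n: int, part_a, part_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(sorted(part_a), dtype=int)
    b = np.asarray(sorted(part_b), dtype=int)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sides of a bipartition must be nonempty")
    if np.intersect1d(a, b).size:
        raise ValueError("bipartition sides must be disjoint")
    if np.union1d(a, b).size != n:
        raise ValueError("bipartition must cover all nodes")
    return a, b


def cut_value(w: np.ndarray, part_a, part_b) -> float:
    """Total affinity crossing a bipartition: sum over x in A, y in B of W[x, y]."""
    w = np.asarray(w, dtype=float)
    a, b = _check_partition(w.shape[0], part_a, part_b)
    return float(w[np.ix_(a, b)].sum())


def _assoc(w: np.ndarray, side: np.ndarray) -> float:
    """Total connection of a side to the whole graph, self-loops excluded."""
    return float(w[side, :].sum() - w[side, side].sum())


def ncut_value(w: np.ndarray, part_a, part_b) -> float:
    """Normalized-cut cost of a bipartition, in [0, 2]."""
    w = np.asarray(w, dtype=float)
    a, b = _check_partition(w.shape[0], part_a, part_b)
    cut = float(w[np.ix_(a, b)].sum())
    assoc_a, assoc_b = _assoc(w, a), _assoc(w, b)
    if assoc_a <= 0 or assoc_b <= 0:
        raise ValueError("a side of the bipartition has zero association")
    return cut / assoc_a + cut / assoc_b


def _spectral_embedding(w: np.ndarray, k: int) -> np.ndarray:
    """Rows of the k bottom eigenvectors of the normalised Laplacian."""
    from scipy.linalg import eigh

    w0 = np.array(w, dtype=float)
    np.fill_diagonal(w0, 0.0)
    d = w0.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    lap = np.eye(len(w0)) - d_isqrt[:, None] * w0 * d_isqrt[None, :]
    lap = 0.5 * (lap + lap.T)
    if len(lap) <= 2000:
        _, vec = eigh(lap, subset_by_index=[0, k - 1])
    else:
        from scipy.sparse.linalg import eigsh

        _, vec = eigsh(lap, k=k, sigma=-1e-5, which="LM", tol=1e-8)
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    return vec / np.maximum(norms, 1e-12)


def partition_graph(graph: RegionGraph | np.ndarray, k: int, seed: int = 0,
                    method: str = "kmeans") -> np.ndarray:
    """Partition the region graph into k segments.

    Parameters
    ----------
    graph : RegionGraph or affinity matrix.
    k : number of segments, 1 <= k <= n_regions.
    seed : seed for the k-means restarts; the result is deterministic
        for a fixed seed.
    method : ``"kmeans"`` (spectral embedding + k-means, the default) or
        ``"recursive"`` (repeated two-way cuts).

    Returns
    -------
    ndarray of length n_regions mapping region index (region id - 1) to a
    segment label in 1..k.  Every segment is nonempty.
    """
    w = graph.affinity if isinstance(graph, RegionGraph) else np.asarray(graph)
    n = w.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return np.ones(n, dtype=np.int32)
    if k == n:
        return np.arange(1, n + 1, dtype=np.int32)
    if method == "kmeans":
        emb = _spectral_embedding(w, k)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(emb)
        return labels.astype(np.int32) + 1
    if method == "recursive":
        return _recursive_partition(w, k)
    raise ValueError(f"unknown method {method!r}")


def _best_two_way(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Best Fiedler-vector sweep split of a (sub)graph; returns mask and Ncut."""
    n = w.shape[0]
    emb = _spectral_embedding(w, 2)[:, 1]
    order = np.argsort(emb, kind="stable")
    best_mask, best_val = None, np.inf
    for cutpos in range(1, n):
        a = order[:cutpos]
        b = order[cutpos:]
        try:
            val = ncut_value(w, a, b)
        except ValueError:
            continue
        if val < best_val:
            mask = np.zeros(n, dtype=bool)
            mask[a] = True
            best_mask, best_val = mask, val
    if best_mask is None:  # fully disconnected subgraph: arbitrary split
        best_mask = np.zeros(n, dtype=bool)
        best_mask[0] = True
        best_val = 0.0
    return best_mask, best_val


def _recursive_partition(w: np.ndarray, k: int) -> np.ndarray:
    n = w.shape[0]
    labels = np.ones(n, dtype=np.int32)
    # candidate split per segment: (ncut value, mask)
    splits: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}

    def compute_split(seg: int) -> None:
        idx = np.nonzero(labels == seg)[0]
        if len(idx) < 2:
            return
        mask, val = _best_two_way(w[np.ix_(idx, idx)])
        splits[seg] = (val, idx, mask)

    compute_split(1)
    next_id = 2
    while next_id <= k and splits:
        # split the segment whose candidate cut has the largest Ncut cost
        seg = max(splits, key=lambda s: splits[s][0])
        _, idx, mask = splits.pop(seg)
        labels[idx[mask]] = next_id
        compute_split(seg)
        compute_split(next_id)
        next_id += 1
    return labels


def regions_to_pixels(lbl: LabelMap, assignment: np.ndarray) -> LabelMap:
    """Project a region -> segment assignment back to the pixel grid.

    ``assignment[i]`` is the segment of region id ``i + 1``.  The output is
    relabelled 1..k' over the nonempty segments.  Segments may be spatially
    disconnected (distinct parcels grouped into one class-like segment keep
    one id).
    """
    assignment = np.asarray(assignment)
    n = lbl.n_regions
    if len(assignment) < n:
        raise ValueError(
            f"assignment covers {len(assignment)} regions, label map has {n}"
        )
    seg = assignment[lbl.labels - 1]
    used = np.unique(seg)
    remap = {int(s): i + 1 for i, s in enumerate(used)}
    out = np.vectorize(remap.__getitem__, otypes=[np.int32])(seg)
    return LabelMap(out)
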