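"""Spatial neighborhood statistics on per-core cell graphs.

TMA cores are physically disjoint tissues, so the k-nearest-neighbor graph
(k = 6 by default, Euclidean on generic coordinates, symmetrized by edge
union) is built per core with cross-core edges forbidden. Three statistics
are computed on it:

* neighborhood enrichment — permutation z-score of the shared-edge count
  between two phenotype classes against a label-shuffled null (high z:
  the classes neighbor each other more often than chance; low z: depletion);
* interaction matrix — raw class × class shared-edge counts;
* co-occurrence curves — distance-binned conditional probability of a
  target class near an anchor class, normalized by the target's overall
  frequency, computed per core and averaged. Under complete spatial
  randomness of labels the score is 1 at every distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import KDTree, distance_matrix

__all__ = [
    "SpatialGraph",
    "EnrichmentResult",
    "CooccurrenceCurve",
    "build_graph",
    "neighborhood_enrichment",
    "interaction_matrix",
    "co_occurrence",
]


@dataclass
class SpatialGraph:
    """Undirected per-core cell adjacency graph.

    ``edges`` holds unique undirected pairs (i < j) of positional indices
    into ``cell_ids``/``coords``; no edge joins different cores.
    """

    cell_ids: np.ndarray
    coords: np.ndarray  # (n, 2), µm
    core_ids: np.ndarray
    edges: np.ndarray  # (E, 2) int, i < j
    k: int = 6
    method: str = "knn_union"

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


def build_graph(
    coords: np.ndarray,
    core_ids: np.ndarray | None = None,
    cell_ids: np.ndarray | None = None,
    k: int = 6,
) -> SpatialGraph:
    """Per-core kNN graph, symmetrized by edge union.

    Each cell is joined to its ``k`` nearest neighbors within its own core;
    the union of directed edges gives the undirected edge set, so every node
    has degree >= k (when the core has > k cells). Exact-distance ties are
    broken toward lower cell index for determinism. Duplicate coordinates
    are allowed (zero-length edges) but warned about.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    core_ids = np.zeros(n, dtype=int) if core_ids is None else np.asarray(core_ids)
    cell_ids = np.arange(n) if cell_ids is None else np.asarray(cell_ids)
    if k < 1:
        raise ValueError("k must be >= 1")

    edge_set: set[tuple[int, int]] = set()
    for core in np.unique(core_ids):
        idx = np.flatnonzero(core_ids == core)
        if len(idx) < k + 1:
            raise ValueError(
                f"core {core!r} has {len(idx)} cells; need >= {k + 1} for k={k}"
            )
        pts = coords[idx]
        if len(np.unique(pts, axis=0)) < len(pts):
            warnings.warn(
                f"core {core!r} contains duplicate coordinates (distance-0 edges)",
                stacklevel=2,
            )
        tree = KDTree(pts)
        dist, nbr = tree.query(pts, k=k + 1)
        for local_i in range(len(idx)):
            # drop self; on exact ties KDTree returns lowest index first,
            # keep deterministic order by (distance, index)
            order = sorted(
                (float(d), int(j))
                for d, j in zip(dist[local_i], nbr[local_i])
                if j != local_i
            )[:k]
            gi = int(idx[local_i])
            for _, local_j in order:
                gj = int(idx[local_j])
                edge_set.add((min(gi, gj), max(gi, gj)))
    edges = np.array(sorted(edge_set), dtype=int).reshape(-1, 2)
    return SpatialGraph(
        cell_ids=cell_ids, coords=coords, core_ids=core_ids, edges=edges, k=k
    )


def _pair_counts(edges: np.ndarray, codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Symmetric class × class edge-count matrix (each edge counted once)."""
    a = codes[edges[:, 0]]
    b = codes[edges[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    flat = np.bincount(lo * n_classes + hi, minlength=n_classes * n_classes)
    m = flat.reshape(n_classes, n_classes)
    return m + np.triu(m, 1).T


@dataclass
class EnrichmentResult:
    classes: list[str]
    observed: np.ndarray  # (C, C) edge counts
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    zscore: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        c = self.classes
        for i in range(len(c)):
            for j in range(i, len(c)):
                rows.append(
                    dict(
                        class_a=c[i],
                        class_b=c[j],
                        observed=int(self.observed[i, j]),
                        perm_mean=self.perm_mean[i, j],
                        perm_sd=self.perm_sd[i, j],
                        zscore=self.zscore[i, j],
                    )
                )
        return pd.DataFrame(rows)


def neighborhood_enrichment(
    graph: SpatialGraph,
    labels,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation z-scores for class–class edge counts.

    Labels are permuted uniformly over all nodes (the graph stays fixed);
    z = (observed − null mean) / null sd per unordered class pair, homotypic
    pairs included. Pairs with zero null variance yield NaN with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError("labels length must match graph nodes")
    if pd.isna(labels).any():
        raise ValueError("every node must be labeled")
    classes, codes = np.unique(labels, return_inverse=True)
    n_classes = len(classes)
    obs = _pair_counts(graph.edges, codes, n_classes)

    rng = np.random.default_rng(seed)
    perm = np.empty((n_permutations, n_classes, n_classes))
    shuffled = codes.copy()
    for p in range(n_permutations):
        rng.shuffle(shuffled)
        perm[p] = _pair_counts(graph.edges, shuffled, n_classes)
    mean = perm.mean(axis=0)
    sd = perm.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    if np.any(sd == 0):
        warnings.warn(
            "zero permutation variance for some class pairs; z set to NaN",
            stacklevel=2,
        )
        z[sd == 0] = np.nan
    return EnrichmentResult(
        classes=[str(c) for c in classes],
        observed=obs,
        perm_mean=mean,
        perm_sd=sd,
        zscore=z,
        n_permutations=n_permutations,
        seed=seed,
    )


def interaction_matrix(graph: SpatialGraph, labels) -> pd.DataFrame:
    """Class × class shared-edge counts (each undirected edge counted once;
    homotypic edges on the diagonal). Unordered-pair sums equal |E|."""
    labels = np.asarray(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError("labels length must match graph nodes")
    if pd.isna(labels).any():
        raise ValueError("every node must be labeled")
    classes, codes = np.unique(labels, return_inverse=True)
    m = _pair_counts(graph.edges, codes, len(classes))
    return pd.DataFrame(m, index=classes, columns=classes)


@dataclass
class CooccurrenceCurve:
    classes: list[str]
    bin_edges: np.ndarray  # (B+1,), µm, strictly increasing
    score: np.ndarray  # (C_anchor, C_target, B) core-averaged
    per_core: dict = field(default_factory=dict)  # core -> (C, C, B)
    n_cores_used: np.ndarray | None = None  # (C, C) cores contributing

    def curve(self, anchor: str, target: str) -> np.ndarray:
        i = self.classes.index(anchor)
        j = self.classes.index(target)
        return self.score[i, j]


def co_occurrence(
    coords: np.ndarray,
    labels,
    bin_edges: np.ndarray,
    core_ids: np.ndarray | None = None,
) -> CooccurrenceCurve:
    """Distance-binned co-occurrence ratio, per core then averaged.

    For anchor class A, target class B and half-open distance bin
    ``(lo, hi]``: score = P(label = B | cell at bin-distance of an A cell)
    / P(label = B), with probabilities over (anchor, other-cell) pairs and
    the core's overall class frequencies; anchors are excluded from their
    own neighbor sets. Cores lacking the anchor or the target are skipped
    for that pair and counted in ``n_cores_used``; empty bins give NaN.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    n = len(coords)
    core_ids = np.zeros(n, dtype=int) if core_ids is None else np.asarray(core_ids)
    classes, codes = np.unique(labels, return_inverse=True)
    n_classes, n_bins = len(classes), len(bin_edges) - 1

    per_core: dict = {}
    acc = np.zeros((n_classes, n_classes, n_bins))
    used = np.zeros((n_classes, n_classes), dtype=int)
    for core in np.unique(core_ids):
        idx = np.flatnonzero(core_ids == core)
        c_codes = codes[idx]
        counts = np.bincount(c_codes, minlength=n_classes)
        p_global = counts / counts.sum()
        d = distance_matrix(coords[idx], coords[idx])
        np.fill_diagonal(d, np.nan)  # anchors excluded from own neighbor set
        which_bin = np.searchsorted(bin_edges, d, side="left") - 1  # (lo, hi]
        score = np.full((n_classes, n_classes, n_bins), np.nan)
        for ai in range(n_classes):
            if counts[ai] == 0:
                continue
            rows = c_codes == ai
            wb = which_bin[rows]  # anchors × others
            tc = np.broadcast_to(c_codes, wb.shape)
            valid = (wb >= 0) & (wb < n_bins) & ~np.isnan(d[rows])
            for b in range(n_bins):
                sel = valid & (wb == b)
                total = sel.sum()
                if total == 0:
                    continue
                t_counts = np.bincount(tc[sel], minlength=n_classes)
                with np.errstate(divide="ignore", invalid="ignore"):
                    score[ai, :, b] = np.where(
                        p_global > 0, (t_counts / total) / p_global, np.nan
                    )
        per_core[core] = score
        # a core lacking the anchor or the target yields NaN for that pair
        # and is skipped in the average (nan-mean over cores, per bin)
        acc += np.where(np.isfinite(score), score, 0.0)
        used += (counts > 0)[:, None] & (counts > 0)[None, :]
    finite_counts = np.zeros_like(acc)
    for score in per_core.values():
        finite_counts += np.isfinite(score)
    avg = np.where(finite_counts > 0, acc / np.maximum(finite_counts, 1), np.nan)
    return CooccurrenceCurve(
        classes=[str(c) for c in classes],
        bin_edges=bin_edges,
        score=avg,
        per_core=per_core,
        n_cores_used=used,
    )


def default_bin_edges(
    coords: np.ndarray, core_ids: np.ndarray | None = None, n_bins: int = 50
) -> np.ndarray:
    """50 equal-width bins from 0 to half the (largest) core diameter."""
    coords = np.asarray(coords, dtype=float)
    core_ids = (
        np.zeros(len(coords), dtype=int) if core_ids is None else np.asarray(core_ids)
    )
    max_half = 0.0
    for core in np.unique(core_ids):
        pts = coords[core_ids == core]
        span = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        max_half = max(max_half, span / 2)
    return np.linspace(0.0, max(max_half, 1e-9), n_bins + 1)
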