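"""Unsupervised phenotype discovery.

Cells are clustered with Leiden (resolution 0.8 by default) on the kNN graph
of the winsorized, Z-normalized marker space — the same normalization as the
supervised path. A 2D UMAP embedding (n_neighbors 40, min_dist 0.5) can be
attached for visualization only; cluster ids never depend on it. Raw
clusters are merged into metaclusters by explicit, auditable configuration
(with an agglomerative profile-similarity suggestion helper), morphology
artifact clusters can be dropped through the same FilterReport machinery as
QC, and per-cluster Z-profile matrices plus averaged single-cell image crops
support cluster annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import FilterStage, _leiden_cluster

__all__ = [
    "ClusterModel",
    "embed_and_cluster",
    "merge_metaclusters",
    "cluster_profile",
    "suggest_merge_map",
    "average_cell_crops",
]

REMOVE = "__remove__"  # merge-map value that drops a cluster's cells


@dataclass
class ClusterModel:
    """Per-cell cluster assignment plus parameters and optional embedding."""

    labels: pd.Series  # cluster label per cell (str)
    n_neighbors: int
    min_dist: float
    resolution: float
    seed: int
    embedding: np.ndarray | None = None  # (n, 2), visualization only
    merge_map: dict[str, str] = field(default_factory=dict)
    removal_stage: FilterStage | None = None

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.labels.unique(), key=lambda c: (len(c), c))

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def embed_and_cluster(
    normalized: pd.DataFrame,
    n_neighbors: int = 40,
    min_dist: float = 0.5,
    resolution: float = 0.8,
    seed: int = 0,
    compute_embedding: bool = False,
) -> ClusterModel:
    """Leiden partition of the marker-space kNN graph.

    ``normalized`` must already be winsorized + Z-normalized marker columns
    (markers only — no DAPI/autofluorescence/QC columns).
    """
    if len(normalized) <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} cells, got {len(normalized)}"
        )
    x = normalized.to_numpy(dtype=np.float32)
    labels = _leiden_cluster(x, n_neighbors, resolution, seed)
    embedding = None
    if compute_embedding:
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.neighbors(
                adata, n_neighbors=n_neighbors, use_rep="X", random_state=seed
            )
            sc.tl.umap(adata, min_dist=min_dist, random_state=seed)
        embedding = np.asarray(adata.obsm["X_umap"])
    return ClusterModel(
        labels=pd.Series(labels.astype(str), index=normalized.index, name="cluster"),
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        resolution=resolution,
        seed=seed,
        embedding=embedding,
    )


def merge_metaclusters(
    model: ClusterModel, merge_map: dict[str, str]
) -> ClusterModel:
    """Relabel raw clusters into metaclusters.

    ``merge_map`` maps raw cluster id → metacluster label; unmapped clusters
    keep their identity. The special target ``"__remove__"`` drops those
    cells (e.g. a false-positive morphology cluster), recorded as a
    :class:`~plexcell.qc.FilterStage`.
    """
    existing = set(model.labels.unique())
    bad = set(merge_map) - existing
    if bad:
        raise ValueError(f"merge map keys are not existing clusters: {sorted(bad)}")

    new = model.labels.map(lambda c: merge_map.get(c, c))
    remove_mask = new == REMOVE
    removal_stage = None
    if remove_mask.any():
        removed_ids = list(model.labels.index[remove_mask])
        removal_stage = FilterStage(
            name="cluster_removal",
            n_input=len(model.labels),
            n_removed=int(remove_mask.sum()),
            n_output=int((~remove_mask).sum()),
            cutoffs={},
            removed={
                int(i): [f"removed_cluster_{model.labels.loc[i]}"]
                for i in removed_ids
            },
        )
        new = new[~remove_mask]
    return ClusterModel(
        labels=new.rename("cluster"),
        n_neighbors=model.n_neighbors,
        min_dist=model.min_dist,
        resolution=model.resolution,
        seed=model.seed,
        embedding=(
            model.embedding[~remove_mask.to_numpy()]
            if model.embedding is not None
            else None
        ),
        merge_map={**model.merge_map, **merge_map},
        removal_stage=removal_stage,
    )


def cluster_profile(
    normalized: pd.DataFrame, labels: pd.Series, marker_order: list[str] | None = None
) -> pd.DataFrame:
    """Per-cluster mean of Z-normalized marker values.

    Rows are clusters (sorted id order), columns markers (panel order).
    Clusters that became empty after removal yield NaN rows and a warning
    rather than disappearing silently.
    """
    markers = marker_order if marker_order is not None else list(normalized.columns)
    aligned = labels.reindex(normalized.index)
    groups = normalized[markers].groupby(aligned, observed=False).mean()
    if groups.isna().any(axis=1).any():
        warnings.warn("empty cluster(s) produced NaN profile rows", stacklevel=2)
    key = {c: (len(str(c)), str(c)) for c in groups.index}
    return groups.loc[sorted(groups.index, key=key.get)]


def suggest_merge_map(
    profiles: pd.DataFrame, n_metaclusters: int, prefix: str = "meta"
) -> dict[str, str]:
    """Agglomerative (Ward, Euclidean) merge suggestion from cluster profiles.

    Mirrors the manual practice of merging neighboring clusters with
    analogous expression patterns; the returned map is a starting point for
    curation, keyed by raw cluster id.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    if n_metaclusters >= len(profiles):
        return {}
    z = linkage(profiles.to_numpy(), method="ward")
    assignment = fcluster(z, t=n_metaclusters, criterion="maxclust")
    return {
        str(raw): f"{prefix}_{meta}"
        for raw, meta in zip(profiles.index, assignment)
    }


def average_cell_crops(
    stack: np.ndarray,
    centroids: np.ndarray,
    labels: pd.Series | np.ndarray,
    selected_class: str,
    n: int = 2000,
    crop_size_px: int = 33,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Pixel-wise mean of centered single-cell crops for one class.

    A seeded sample of up to ``n`` class members (without replacement; all
    members when the class is smaller) is cropped around each centroid and
    averaged per channel, yielding the class's mean spatial expression
    profile (e.g. nuclear vs cytoplasmic localization of its signature
    markers). Cells whose crop would leave the image are skipped and
    counted. Returns ``(mean_stack (C, s, s), n_skipped)``.
    """
    if crop_size_px % 2 != 1:
        raise ValueError("crop_size_px must be odd")
    labels = np.asarray(labels)
    idx = np.flatnonzero(labels == selected_class)
    if idx.size == 0:
        raise ValueError(f"class {selected_class!r} not present")
    rng = np.random.default_rng(seed)
    if idx.size > n:
        idx = rng.choice(idx, size=n, replace=False)
    half = crop_size_px // 2
    _, h, w = stack.shape
    acc = np.zeros((stack.shape[0], crop_size_px, crop_size_px), dtype=np.float64)
    used = 0
    skipped = 0
    for i in idx:
        cx, cy = centroids[i]
        r, c = int(round(cy)), int(round(cx))
        if r - half < 0 or r + half >= h or c - half < 0 or c + half >= w:
            skipped += 1
            continue
        acc += stack[:, r - half : r + half + 1, c - half : c + half + 1]
        used += 1
    if used == 0:
        raise ValueError("all selected cells fall too close to the image edge")
    return acc / used, skipped
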