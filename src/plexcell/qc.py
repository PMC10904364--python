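"""Two-stage single-cell data cleaning.

Stage 1 removes autofluorescent artifacts (chiefly erythrocytes, which are
bright in every acquisition channel including the unstained autofluorescence
images but carry only faint DAPI): Leiden clustering of median/SD-normalized
marker + autofluorescence means, then flagging clusters whose mean exceeds
the global mean in (by default) every channel.

Stage 2 removes low-quality detections by empirical-quantile cuts on four
features — segmentation detection probability, DAPI mean intensity, nucleus
area and circularity: the lowest 5% of each feature is dropped, plus the
highest 0.1% of area. Cuts combine by union; every removal is accounted for
in a :class:`FilterReport`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterStage",
    "FilterReport",
    "ArtifactClusteringConfig",
    "normalize_median_sd",
    "flag_artifact_clusters",
    "quantile_filter",
    "run_cleaning",
    "QC_FEATURES",
]

QC_FEATURES = ("detection_probability", "dapi_mean", "area_um2", "circularity")


@dataclass
class FilterStage:
    """Accounting for one cleaning stage."""

    name: str
    n_input: int
    n_removed: int
    n_output: int
    cutoffs: dict[str, float] = field(default_factory=dict)
    removed: dict[int, list[str]] = field(default_factory=dict)  # cell_id -> reasons

    def __post_init__(self) -> None:
        if self.n_input - self.n_removed != self.n_output:
            raise ValueError(
                f"stage {self.name!r}: n_input - n_removed != n_output "
                f"({self.n_input} - {self.n_removed} != {self.n_output})"
            )
        if len(self.removed) != self.n_removed:
            raise ValueError(
                f"stage {self.name!r}: {len(self.removed)} removal records "
                f"for n_removed={self.n_removed}"
            )


@dataclass
class FilterReport:
    """Chained stage accounting; totals must conserve cell counts."""

    stages: list[FilterStage] = field(default_factory=list)

    def add_stage(self, stage: FilterStage) -> None:
        if self.stages:
            prev = self.stages[-1]
            if stage.n_input != prev.n_output:
                raise ValueError(
                    f"stage {stage.name!r} input {stage.n_input} does not "
                    f"chain from previous output {prev.n_output}"
                )
            seen = set().union(*(s.removed for s in self.stages))
            overlap = seen & set(stage.removed)
            if overlap:
                raise ValueError(
                    f"cells removed twice across stages: {sorted(overlap)[:5]}..."
                )
        self.stages.append(stage)

    @property
    def n_input(self) -> int:
        return self.stages[0].n_input if self.stages else 0

    @property
    def n_output(self) -> int:
        return self.stages[-1].n_output if self.stages else 0

    @property
    def total_removed(self) -> int:
        return sum(s.n_removed for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "total_removed": self.total_removed,
            "stages": [
                {
                    "name": s.name,
                    "n_input": s.n_input,
                    "n_removed": s.n_removed,
                    "n_output": s.n_output,
                    "cutoffs": s.cutoffs,
                    "removed": {str(k): v for k, v in s.removed.items()},
                }
                for s in self.stages
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ArtifactClusteringConfig:
    """Parameters of the stage-1 erythrocyte/artifact cluster exclusion.

    ``channels=None`` means all panel markers plus the first two
    autofluorescence channels, DAPI excluded. ``flag_fraction`` is the
    fraction of channels in which a cluster's mean must exceed the global
    mean to be flagged (1.0 = every channel).
    """

    n_neighbors: int = 40
    min_dist: float = 0.5
    resolution: float = 1.0
    channels: list[str] | None = None
    flag_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not 0 < self.flag_fraction <= 1:
            raise ValueError("flag_fraction must be in (0, 1]")


def normalize_median_sd(columns: pd.DataFrame) -> pd.DataFrame:
    """Per-column robust-location scaling: (x − median) / sd."""
    out = {}
    for name, col in columns.items():
        x = col.to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {name!r} has zero standard deviation")
        out[name] = (x - np.median(x)) / sd
    return pd.DataFrame(out, index=columns.index)


def _leiden_cluster(
    features: np.ndarray, n_neighbors: int, resolution: float, seed: int
) -> np.ndarray:
    """Leiden partition of the kNN graph of a feature matrix."""
    import anndata as ad
    import scanpy as sc

    if features.shape[0] <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} cells, "
            f"got {features.shape[0]}"
        )
    adata = ad.AnnData(np.asarray(features, dtype=np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X", random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    return adata.obs["leiden"].astype(int).to_numpy()


def flag_artifact_clusters(
    table: pd.DataFrame, config: ArtifactClusteringConfig | None = None
) -> tuple[np.ndarray, list[int], pd.DataFrame]:
    """Cluster cells and flag artifact clusters bright across channels.

    Returns ``(cluster_labels, flagged_cluster_ids, review)`` where
    ``review`` is a per-cluster table of sizes, per-channel means and the
    flag decision — the interactive-curation view; automatic pipelines apply
    the flags directly.
    """
    config = config or ArtifactClusteringConfig()
    if config.channels is None:
        drop = {"cell_id", "x", "y", "x_um", "y_um", "core_id", "dapi_mean",
                "detection_probability", "area_um2", "circularity"}
        channels = [
            c for c in table.columns
            if c not in drop and pd.api.types.is_numeric_dtype(table[c])
        ]
    else:
        channels = list(config.channels)
    missing = [c for c in channels if c not in table.columns]
    if missing:
        raise ValueError(f"channels missing from table: {missing}")

    norm = normalize_median_sd(table[channels])
    labels = _leiden_cluster(
        norm.to_numpy(), config.n_neighbors, config.resolution, config.seed
    )

    global_mean = norm.mean(axis=0)
    rows = []
    flagged = []
    for cid in np.unique(labels):
        sub = norm.iloc[labels == cid]
        above = (sub.mean(axis=0) > global_mean).to_numpy()
        is_flagged = above.sum() >= config.flag_fraction * len(channels)
        if is_flagged:
            flagged.append(int(cid))
        rows.append(
            {
                "cluster": int(cid),
                "n_cells": int((labels == cid).sum()),
                "n_channels_above_mean": int(above.sum()),
                "flagged": bool(is_flagged),
                **{f"mean_{c}": float(m) for c, m in sub.mean(axis=0).items()},
            }
        )
    review = pd.DataFrame(rows)
    return labels, flagged, review


def quantile_filter(
    table: pd.DataFrame,
    lower_frac: float = 0.05,
    area_upper_frac: float = 0.001,
    features: tuple[str, ...] = QC_FEATURES,
    area_feature: str = "area_um2",
    fixed_cutoffs: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, FilterStage]:
    """Empirical-quantile QC filter (stage 2).

    A cell is removed if, for ANY feature, its value is strictly below that
    feature's ``lower_frac`` quantile — or strictly above the
    ``1 − area_upper_frac`` quantile of area. Ties at a cutoff are kept, so
    the removed fraction never exceeds the nominal one. ``fixed_cutoffs``
    overrides the realized quantiles with dataset-specific constants
    (``feature`` → lower cutoff, ``"area_upper"`` → upper area cutoff).
    """
    if not 0 <= lower_frac < 1 or not 0 <= area_upper_frac < 1:
        raise ValueError("fractions must be in [0, 1)")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    fixed_cutoffs = fixed_cutoffs or {}

    reasons: dict[int, list[str]] = {}
    cutoffs: dict[str, float] = {}
    cell_ids = table["cell_id"].to_numpy()

    def mark(mask: np.ndarray, reason: str) -> None:
        for cid in cell_ids[mask]:
            reasons.setdefault(int(cid), []).append(reason)

    for feat in features:
        x = table[feat].to_numpy(dtype=float)
        lo = fixed_cutoffs.get(feat, float(np.quantile(x, lower_frac)))
        cutoffs[f"{feat}_lower"] = lo
        mark(x < lo, f"low_{feat}")
    area = table[area_feature].to_numpy(dtype=float)
    hi = fixed_cutoffs.get("area_upper", float(np.quantile(area, 1 - area_upper_frac)))
    cutoffs[f"{area_feature}_upper"] = hi
    mark(area > hi, f"high_{area_feature}")

    keep_mask = ~np.isin(cell_ids, np.array(list(reasons), dtype=cell_ids.dtype))
    kept = table.loc[keep_mask].copy()
    stage = FilterStage(
        name="quantile_filter",
        n_input=len(table),
        n_removed=len(reasons),
        n_output=len(kept),
        cutoffs=cutoffs,
        removed=reasons,
    )
    return kept, stage


def run_cleaning(
    table: pd.DataFrame,
    artifact_config: ArtifactClusteringConfig | None = None,
    lower_frac: float = 0.05,
    area_upper_frac: float = 0.001,
    features: tuple[str, ...] = QC_FEATURES,
    fixed_cutoffs: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full two-stage cleaning: artifact clusters, then quantile filter."""
    report = FilterReport()

    labels, flagged, _review = flag_artifact_clusters(table, artifact_config)
    flag_mask = np.isin(labels, flagged)
    removed = {
        int(cid): [f"artifact_cluster_{c}"]
        for cid, c in zip(table["cell_id"][flag_mask], labels[flag_mask])
    }
    stage1_out = table.loc[~flag_mask].copy()
    report.add_stage(
        FilterStage(
            name="artifact_clusters",
            n_input=len(table),
            n_removed=int(flag_mask.sum()),
            n_output=len(stage1_out),
            cutoffs={"n_flagged_clusters": float(len(flagged))},
            removed=removed,
        )
    )

    clean, stage2 = quantile_filter(
        stage1_out,
        lower_frac=lower_frac,
        area_upper_frac=area_upper_frac,
        features=features,
        fixed_cutoffs=fixed_cutoffs,
    )
    report.add_stage(stage2)
    return clean, report
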