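"""End-to-end pipeline orchestration: "slide in, data out".

Stages run in order simulate/ingest → feature extraction → QC cleaning →
phenotyping (supervised rule tree and/or unsupervised clustering) → spatial
statistics. Every stage reads and writes plain CSV/JSON so any stage can be
re-run standalone on the previous stage's output; a :class:`RunManifest`
records stage order, file hashes, cell accounting and the resolved
configuration, making a run reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .panel import AF_CHANNELS, MarkerPanel, phantom_panel

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Block):
    simulate: bool = True
    extract: bool = True
    qc: bool = True
    phenotype: bool = True
    cluster: bool = True
    spatial: bool = True


class SimulateParams(_Block):
    n_cells: int = 300
    n_erythrocytes: int = 30
    noise_sd: float = 30.0
    n_cores: int = 4
    image: bool = False  # False: draw the expression table directly


class ExtractParams(_Block):
    dilation_px: int = 5
    pixel_size_um: float = 0.23


class QcParams(_Block):
    n_neighbors: int = 40
    resolution: float = 1.0
    flag_fraction: float = 1.0
    lower_frac: float = 0.05
    area_upper_frac: float = 0.001


class PhenotypeParams(_Block):
    winsorize_upper_frac: float = 0.0001
    n_sigma: float = 6.0
    rules_path: str | None = None  # default: phantom ruleset
    arcsinh_cofactor: float = 150.0
    unknown_probability_cutoff: float = 0.5


class ClusterParams(_Block):
    n_neighbors: int = 40
    min_dist: float = 0.5
    resolution: float = 0.8
    compute_embedding: bool = False
    n_metaclusters: int | None = None


class SpatialParams(_Block):
    k: int = 6
    n_permutations: int = 1000
    n_bins: int = 25
    labels_column: str = "phenotype"


class PipelineConfig(_Block):
    """Resolved pipeline configuration; unknown keys are rejected."""

    out_dir: str = "plexcell_run"
    seed: int = 0
    panel_path: str | None = None
    input_table: str | None = None
    input_stack: str | None = None
    input_labels: str | None = None
    stages: StageToggles = Field(default_factory=StageToggles)
    simulate: SimulateParams = Field(default_factory=SimulateParams)
    extract: ExtractParams = Field(default_factory=ExtractParams)
    qc: QcParams = Field(default_factory=QcParams)
    phenotype: PhenotypeParams = Field(default_factory=PhenotypeParams)
    cluster: ClusterParams = Field(default_factory=ClusterParams)
    spatial: SpatialParams = Field(default_factory=SpatialParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


class RunManifest:
    """Stage order, output hashes and cell accounting of one run."""

    def __init__(self, seed: int):
        self.seed = seed
        self.stages: list[dict] = []
        self.counts: dict[str, int] = {}

    def record(self, name: str, outputs: dict[str, Path], **info) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {
                    k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in outputs.items()
                },
                **info,
            }
        )

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "stages": self.stages,
            "counts": self.counts,
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_panel(config: PipelineConfig) -> MarkerPanel:
    if config.panel_path:
        return MarkerPanel.from_yaml(config.panel_path)
    return phantom_panel()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages; returns the manifest (also written to
    ``out_dir/manifest.json`` with the resolved config beside it)."""
    from . import clustering, features, qc, rules, spatial, synthetic, thresholds

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        fh.write(config.model_dump_json(indent=2))
    manifest = RunManifest(seed=config.seed)
    panel = _load_panel(config)

    table: pd.DataFrame | None = None
    stack = labels_img = None
    channel_names = None

    # --- simulate / ingest -------------------------------------------------
    if config.input_table:
        table = pd.read_csv(config.input_table)
    elif config.input_stack and config.input_labels:
        import tifffile

        stack = tifffile.imread(config.input_stack)
        labels_img = np.asarray(tifffile.imread(config.input_labels))
        channel_names = ["DAPI", *AF_CHANNELS, *panel.names]
    elif config.stages.simulate:
        sim = config.simulate
        spec = synthetic.TissuePhantomSpec(
            n_cells=sim.n_cells,
            n_erythrocytes=sim.n_erythrocytes,
            noise_sd=sim.noise_sd,
            n_cores=sim.n_cores,
            seed=config.seed,
            panel=panel,
        )
        if sim.image:
            stack, labels_img, gt = synthetic.simulate_tissue_image(spec)
            channel_names = spec.channel_names
        else:
            table, gt = synthetic.simulate_expression_table(spec)
        gt_path = out / "ground_truth.json"
        gt.to_json(gt_path, orient="records")
        manifest.record("simulate", {"ground_truth": gt_path}, n_objects=len(gt))

    # --- feature extraction --------------------------------------------------
    if stack is not None and config.stages.extract:
        corrected = features.subtract_background_stack(stack, panel, channel_names)
        cell_labels = features.expand_nuclei(labels_img, config.extract.dilation_px)
        table = features.measure_cells(
            corrected, labels_img, cell_labels, panel, channel_names,
            pixel_size_um=config.extract.pixel_size_um,
        )
        raw = features.measure_cells(
            stack, labels_img, cell_labels, features.nuclear_panel(panel),
            channel_names, pixel_size_um=config.extract.pixel_size_um,
        )
        for m in panel.names:
            table[f"raw_{m}"] = raw[m].to_numpy()
        path = out / "cells.csv"
        table.to_csv(path, index=False)
        manifest.record("extract", {"cells": path}, n_cells=len(table))
        manifest.counts["n_segmented"] = len(table)
    elif table is not None:
        manifest.counts["n_segmented"] = len(table)
        path = out / "cells.csv"
        table.to_csv(path, index=False)
        manifest.record("ingest", {"cells": path}, n_cells=len(table))

    if table is None:
        manifest.write(out / "manifest.json")
        return manifest

    # --- QC cleaning ---------------------------------------------------------
    if config.stages.qc:
        raw_cols = [c for c in table.columns if c.startswith("raw_")]
        channels = (raw_cols or panel.names) + [
            af for af in AF_CHANNELS if af in table.columns
        ]
        cfg = qc.ArtifactClusteringConfig(
            n_neighbors=config.qc.n_neighbors,
            resolution=config.qc.resolution,
            flag_fraction=config.qc.flag_fraction,
            channels=channels,
            seed=config.seed,
        )
        table, report = qc.run_cleaning(
            table,
            artifact_config=cfg,
            lower_frac=config.qc.lower_frac,
            area_upper_frac=config.qc.area_upper_frac,
        )
        rpath = out / "filter_report.json"
        report.to_json(rpath)
        cpath = out / "cells_clean.csv"
        table.to_csv(cpath, index=False)
        manifest.record(
            "qc", {"cells_clean": cpath, "filter_report": rpath},
            n_removed=report.total_removed,
        )
        manifest.counts["n_removed_qc"] = report.total_removed
        manifest.counts["n_clean"] = len(table)

    # --- supervised phenotyping -----------------------------------------------
    normalized = thresholds.normalize_table(
        table, panel.names, upper_frac=config.phenotype.winsorize_upper_frac
    )
    if config.stages.phenotype:
        fitted = thresholds.fit_thresholds(normalized, n_sigma=config.phenotype.n_sigma)
        tpath = out / "thresholds.json"
        thresholds.thresholds_to_json(fitted, tpath)
        binary = thresholds.binarize(normalized, fitted)
        ruleset = (
            rules.RuleSet.from_yaml(config.phenotype.rules_path, markers=panel.names)
            if config.phenotype.rules_path
            else rules.phantom_ruleset()
        )
        table = table.copy()
        table["phenotype"] = rules.classify_tree(binary, ruleset).to_numpy()
        lpath = out / "cells_labeled.csv"
        table.to_csv(lpath, index=False)
        manifest.record(
            "phenotype", {"cells_labeled": lpath, "thresholds": tpath},
            n_cells=len(table),
            class_counts=table["phenotype"].value_counts().to_dict(),
        )
        manifest.counts["n_labeled"] = len(table)

    # --- unsupervised phenotyping ----------------------------------------------
    if config.stages.cluster:
        model = clustering.embed_and_cluster(
            normalized.loc[table.index],
            n_neighbors=config.cluster.n_neighbors,
            min_dist=config.cluster.min_dist,
            resolution=config.cluster.resolution,
            seed=config.seed,
            compute_embedding=config.cluster.compute_embedding,
        )
        profile = clustering.cluster_profile(
            normalized.loc[table.index], model.labels, marker_order=panel.names
        )
        if config.cluster.n_metaclusters:
            merge_map = clustering.suggest_merge_map(
                profile, config.cluster.n_metaclusters
            )
            model = clustering.merge_metaclusters(model, merge_map)
            profile = clustering.cluster_profile(
                normalized.loc[model.labels.index], model.labels,
                marker_order=panel.names,
            )
            table = table.loc[model.labels.index]
        table = table.copy()
        table["cluster"] = model.labels.to_numpy()
        if model.embedding is not None:
            table["umap_x"] = model.embedding[:, 0]
            table["umap_y"] = model.embedding[:, 1]
        ppath = out / "cluster_profiles.csv"
        profile.to_csv(ppath)
        kpath = out / "cells_clustered.csv"
        table.to_csv(kpath, index=False)
        manifest.record(
            "cluster", {"cells_clustered": kpath, "profiles": ppath},
            n_clusters=int(model.labels.nunique()),
        )

    # --- spatial statistics -------------------------------------------------------
    if config.stages.spatial:
        col = config.spatial.labels_column
        if col not in table.columns:
            col = "cluster" if "cluster" in table.columns else None
        if col is not None:
            coords = table[["x_um", "y_um"]].to_numpy()
            core_ids = (
                table["core_id"].to_numpy()
                if "core_id" in table.columns
                else np.zeros(len(table), dtype=int)
            )
            graph = spatial.build_graph(
                coords, core_ids=core_ids,
                cell_ids=table["cell_id"].to_numpy(), k=config.spatial.k,
            )
            labels = table[col].to_numpy()
            enr = spatial.neighborhood_enrichment(
                graph, labels,
                n_permutations=config.spatial.n_permutations, seed=config.seed,
            )
            epath = out / "neighborhood_enrichment.csv"
            enr.to_frame().to_csv(epath, index=False)
            ipath = out / "interaction_matrix.csv"
            spatial.interaction_matrix(graph, labels).to_csv(ipath)
            edges = spatial.default_bin_edges(
                coords, core_ids, n_bins=config.spatial.n_bins
            )
            cooc = spatial.co_occurrence(coords, labels, edges, core_ids)
            rows = []
            for i, a in enumerate(cooc.classes):
                for j, b in enumerate(cooc.classes):
                    for bi in range(len(edges) - 1):
                        rows.append(
                            dict(
                                anchor=a, target=b,
                                bin_lo=edges[bi], bin_hi=edges[bi + 1],
                                score=cooc.score[i, j, bi],
                            )
                        )
            opath = out / "co_occurrence.csv"
            pd.DataFrame(rows).to_csv(opath, index=False)
            manifest.record(
                "spatial",
                {"enrichment": epath, "interaction": ipath, "co_occurrence": opath},
                n_edges=graph.n_edges,
                labels_column=col,
            )

    manifest.write(out / "manifest.json")
    return manifest
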