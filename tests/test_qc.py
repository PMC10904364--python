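"""Two-stage data cleaning: artifact clusters, quantile filter, accounting."""

import numpy as np
import pandas as pd
import pytest

from plexcell.qc import (
    ArtifactClusteringConfig,
    FilterReport,
    FilterStage,
    flag_artifact_clusters,
    normalize_median_sd,
    quantile_filter,
    run_cleaning,
)


def qc_table(n=1000, seed=0):
    """Table with distinct QC feature values and cell ids."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "detection_probability": rng.permutation(np.linspace(0.01, 0.99, n)),
            "dapi_mean": rng.permutation(np.linspace(100, 5000, n)),
            "area_um2": rng.permutation(np.linspace(5, 150, n)),
            "circularity": rng.permutation(np.linspace(0.2, 1.0, n)),
        }
    )


# --- normalize_median_sd ---------------------------------------------------

def test_median_sd_small_example():
    out = normalize_median_sd(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
    sd = np.std([1, 2, 3])
    assert np.allclose(out["a"], (np.array([1, 2, 3]) - 2) / sd)


def test_median_sd_constant_column_errors():
    with pytest.raises(ValueError, match="b"):
        normalize_median_sd(pd.DataFrame({"b": [5.0, 5.0, 5.0]}))


def test_median_sd_centers_median_at_zero():
    rng = np.random.default_rng(1)
    out = normalize_median_sd(pd.DataFrame({"x": rng.lognormal(size=501)}))
    assert abs(np.median(out["x"])) < 1e-9


# --- quantile_filter -------------------------------------------------------

def test_lower_tail_counting_oracle():
    """1000 distinct values per feature: the 5% rule removes exactly 50 per
    feature, the 0.1% area rule exactly 1."""
    table = qc_table()
    kept, stage = quantile_filter(
        table, lower_frac=0.05, area_upper_frac=0.0,
        features=("detection_probability",),
    )
    assert stage.n_removed == 50
    kept, stage = quantile_filter(
        table, lower_frac=0.0, area_upper_frac=0.001,
        features=("detection_probability",),
    )
    assert stage.n_removed == 1
    removed_id = next(iter(stage.removed))
    assert table.set_index("cell_id").loc[removed_id, "area_um2"] == table.area_um2.max()


def test_identical_values_remove_nothing():
    table = qc_table()
    for col in ("detection_probability", "dapi_mean", "area_um2", "circularity"):
        table[col] = 1.0
    kept, stage = quantile_filter(table)
    assert stage.n_removed == 0
    assert len(kept) == len(table)


def test_union_of_criteria_and_reasons():
    table = qc_table()
    kept, stage = quantile_filter(table)
    brute = set()
    for feat in ("detection_probability", "dapi_mean", "area_um2", "circularity"):
        cut = np.quantile(table[feat], 0.05)
        brute |= set(table.cell_id[table[feat] < cut])
    brute |= set(table.cell_id[table.area_um2 > np.quantile(table.area_um2, 0.999)])
    assert set(stage.removed) == brute
    assert stage.n_input - stage.n_removed == stage.n_output


def test_rank_invariance_under_monotone_rescaling():
    table = qc_table()
    _, s1 = quantile_filter(table)
    table2 = table.copy()
    table2["dapi_mean"] = np.exp(table2["dapi_mean"] / 2000.0)
    _, s2 = quantile_filter(table2)
    assert set(s1.removed) == set(s2.removed)


def test_zero_fractions_are_identity():
    table = qc_table()
    kept, stage = quantile_filter(table, lower_frac=0.0, area_upper_frac=0.0)
    assert stage.n_removed == 0
    pd.testing.assert_frame_equal(kept, table)


def test_missing_feature_errors():
    with pytest.raises(ValueError, match="missing"):
        quantile_filter(qc_table().drop(columns=["circularity"]))


def test_fixed_cutoff_override():
    table = qc_table()
    _, stage = quantile_filter(
        table, features=("detection_probability",), area_upper_frac=0.0,
        fixed_cutoffs={"detection_probability": 0.65},
    )
    assert stage.cutoffs["detection_probability_lower"] == 0.65
    assert stage.n_removed == int((table.detection_probability < 0.65).sum())


# --- FilterReport ----------------------------------------------------------

def test_report_conservation_enforced():
    with pytest.raises(ValueError, match="n_input - n_removed"):
        FilterStage("s", n_input=10, n_removed=3, n_output=8)


def test_report_chain_and_disjointness():
    r = FilterReport()
    r.add_stage(FilterStage("a", 10, 2, 8, removed={1: ["x"], 2: ["x"]}))
    with pytest.raises(ValueError, match="chain"):
        r.add_stage(FilterStage("b", 9, 1, 8, removed={3: ["y"]}))
    with pytest.raises(ValueError, match="twice"):
        r.add_stage(FilterStage("b", 8, 1, 7, removed={1: ["y"]}))
    r.add_stage(FilterStage("b", 8, 1, 7, removed={3: ["y"]}))
    assert r.total_removed == 3 and r.n_input == 10 and r.n_output == 7


# --- artifact clustering ---------------------------------------------------

def test_planted_artifacts_flagged(phantom_table):
    table, gt = phantom_table
    labels, flagged, review = flag_artifact_clusters(
        table, ArtifactClusteringConfig(seed=0)
    )
    flag_mask = np.isin(labels, flagged)
    art = gt.is_artifact.to_numpy()
    recall = (flag_mask & art).sum() / art.sum()
    fpr = (flag_mask & ~art).sum() / (~art).sum()
    assert recall >= 0.90
    assert fpr <= 0.05
    assert review.flagged.sum() == len(flagged)


def test_homogeneous_table_has_no_flagged_clusters():
    rng = np.random.default_rng(4)
    n = 300
    table = pd.DataFrame(
        {"cell_id": np.arange(n)}
        | {f"m{i}": rng.normal(100, 10, n) for i in range(5)}
        | {"AF_TRITC": rng.normal(20, 2, n), "AF_Cy5": rng.normal(20, 2, n)}
    )
    cfg = ArtifactClusteringConfig(
        seed=0, channels=[f"m{i}" for i in range(5)] + ["AF_TRITC", "AF_Cy5"]
    )
    _, flagged, _ = flag_artifact_clusters(table, cfg)
    assert flagged == []


def test_too_few_cells_errors():
    table = qc_table(n=20)
    table["m"] = 1.0 + np.arange(20)
    with pytest.raises(ValueError, match="n_neighbors"):
        flag_artifact_clusters(table, ArtifactClusteringConfig(channels=["m"]))


# --- run_cleaning ----------------------------------------------------------

def test_cleaning_matches_brute_force(phantom_table, default_spec):
    """Output equals independent sequential application of the two rules."""
    table, gt = phantom_table
    cfg = ArtifactClusteringConfig(seed=0)
    clean, report = run_cleaning(table, cfg)

    labels, flagged, _ = flag_artifact_clusters(table, cfg)
    stage1 = table.loc[~np.isin(labels, flagged)]
    drop = set()
    for feat in ("detection_probability", "dapi_mean", "area_um2", "circularity"):
        cut = np.quantile(stage1[feat], 0.05)
        drop |= set(stage1.cell_id[stage1[feat] < cut])
    drop |= set(
        stage1.cell_id[stage1.area_um2 > np.quantile(stage1.area_um2, 0.999)]
    )
    expected = stage1.loc[~stage1.cell_id.isin(drop)]
    assert list(clean.cell_id) == list(expected.cell_id)
    assert report.total_removed == sum(s.n_removed for s in report.stages)
    assert report.n_input - report.total_removed == report.n_output == len(clean)


def test_cleaning_is_subset_no_duplicates(clean_labeled_table, phantom_table):
    merged, report = clean_labeled_table
    table, _ = phantom_table
    assert merged.cell_id.is_unique
    assert set(merged.cell_id) <= set(table.cell_id)
    removed_ids = set().union(*(s.removed for s in report.stages))
    assert removed_ids.isdisjoint(set(merged.cell_id))
    assert len(removed_ids) == report.total_removed
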