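"""Feature extraction: background subtraction, nucleus expansion, measurement."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import distance_transform_edt

from plexcell.features import (
    expand_nuclei,
    measure_cells,
    positive_area_fraction,
    subtract_background,
)
from plexcell.panel import MarkerDef, MarkerPanel

CHANNELS = ["DAPI", "AF_TRITC", "AF_Cy5", "NUC", "CYT"]


def tiny_panel():
    return MarkerPanel(
        markers=[
            MarkerDef("NUC", "TRITC", 1, "nucleus"),
            MarkerDef("CYT", "Cy5", 1, "cytoplasm"),
        ]
    )


# --- subtract_background ---------------------------------------------------

def test_subtraction_pixels_and_zero_floor():
    marker = np.array([[100, 30]], dtype=np.uint16)
    af = np.array([[30, 100]], dtype=np.uint16)
    out = subtract_background(marker, af)
    assert out.tolist() == [[70, 0]]
    assert out.dtype == np.uint16


def test_subtraction_oracle_on_random_pair():
    rng = np.random.default_rng(0)
    marker = rng.integers(0, 5000, size=(64, 64)).astype(np.uint16)
    af = rng.integers(0, 5000, size=(64, 64)).astype(np.uint16)
    out = subtract_background(marker, af)
    assert out.min() >= 0
    no_floor = marker >= af
    assert np.array_equal(
        out[no_floor].astype(int) + af[no_floor].astype(int), marker[no_floor]
    )
    assert np.all(out[~no_floor] == 0)


def test_subtraction_shape_mismatch_errors():
    with pytest.raises(ValueError, match="shape"):
        subtract_background(np.zeros((4, 4)), np.zeros((4, 5)))


# --- expand_nuclei ---------------------------------------------------------

def test_expansion_matches_rasterized_disk_oracle():
    """A disk nucleus of radius 10 grown by 5 px covers ~ a disk of radius 15."""
    yy, xx = np.mgrid[:64, :64]
    disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2).astype(np.int32)
    grown = expand_nuclei(disk, 5)
    area = (grown == 1).sum()
    assert abs(area - np.pi * 15**2) / (np.pi * 15**2) < 0.03
    # oracle: exactly the pixels within distance 5 of the disk
    oracle = distance_transform_edt(disk == 0) <= 5
    assert np.array_equal(grown > 0, oracle | (disk > 0))


def test_expansion_zero_radius_is_identity():
    labels = np.zeros((16, 16), dtype=np.int32)
    labels[4:8, 4:8] = 3
    assert np.array_equal(expand_nuclei(labels, 0), labels)


def test_expansion_is_collision_free_and_equidistant():
    labels = np.zeros((32, 48), dtype=np.int32)
    labels[14:18, 10:14] = 1
    labels[14:18, 20:24] = 2  # 6 px gap
    grown = expand_nuclei(labels, 5)
    # nucleus pixels keep labels; regions stay disjoint by construction
    assert np.array_equal(grown[labels > 0], labels[labels > 0])
    d1 = distance_transform_edt(labels != 1)
    d2 = distance_transform_edt(labels != 2)
    contested = (grown == 1) & (d2 < d1)
    assert not contested.any()
    contested = (grown == 2) & (d1 < d2)
    assert not contested.any()


def test_expansion_rejects_negative_radius():
    with pytest.raises(ValueError):
        expand_nuclei(np.zeros((4, 4), dtype=np.int32), -1)


def test_expansion_idempotent_at_zero_radius():
    rng = np.random.default_rng(1)
    labels = np.zeros((40, 40), dtype=np.int32)
    for i, (r, c) in enumerate(rng.integers(5, 35, size=(5, 2)), start=1):
        labels[r - 2 : r + 2, c - 2 : c + 2] = i
    grown = expand_nuclei(labels, 4)
    assert np.array_equal(expand_nuclei(grown, 0), grown)


# --- measure_cells ---------------------------------------------------------

def _label_phantom():
    """Constructed label-mask phantom: 2 square nuclei, ring = expansion."""
    nuclei = np.zeros((48, 48), dtype=np.int32)
    nuclei[8:18, 8:18] = 1
    nuclei[28:40, 26:40] = 2
    cells = expand_nuclei(nuclei, 5)
    return nuclei, cells


def test_uniform_image_gives_uniform_means():
    nuclei, cells = _label_phantom()
    stack = np.full((5, 48, 48), 42.0)
    t = measure_cells(stack, nuclei, cells, tiny_panel(), CHANNELS)
    assert np.allclose(t["NUC"], 42.0)
    assert np.allclose(t["CYT"], 42.0)
    assert np.allclose(t["dapi_mean"], 42.0)


def test_compartment_means_recovered_exactly():
    """Noise-free phantom: nuclear value 800 inside nuclei, 100 in the ring."""
    nuclei, cells = _label_phantom()
    stack = np.zeros((5, 48, 48))
    nuc_plane = np.where(nuclei > 0, 800.0, 0.0)
    cyt_plane = np.where((cells > 0) & (nuclei == 0), 100.0, 0.0)
    stack[CHANNELS.index("NUC")] = nuc_plane + np.where(nuclei == 0, 55.0, 0)
    stack[CHANNELS.index("CYT")] = cyt_plane
    t = measure_cells(stack, nuclei, cells, tiny_panel(), CHANNELS)
    assert np.allclose(t["NUC"], 800.0)  # nuclear marker ignores outside
    assert np.allclose(t["CYT"], 100.0)  # cytoplasmic marker ignores nucleus


def test_area_in_square_microns():
    nuclei = np.zeros((32, 32), dtype=np.int32)
    nuclei[4:14, 4:14] = 1  # 100 pixels
    cells = expand_nuclei(nuclei, 5)
    t = measure_cells(
        np.zeros((5, 32, 32)), nuclei, cells, tiny_panel(), CHANNELS,
        pixel_size_um=0.23,
    )
    assert t["area_um2"].iloc[0] == pytest.approx(100 * 0.23**2)  # 5.29


def test_mean_intensity_linearity():
    nuclei, cells = _label_phantom()
    rng = np.random.default_rng(2)
    stack = rng.uniform(0, 1000, size=(5, 48, 48))
    t1 = measure_cells(stack, nuclei, cells, tiny_panel(), CHANNELS)
    t3 = measure_cells(3.0 * stack, nuclei, cells, tiny_panel(), CHANNELS)
    for col in ["NUC", "CYT", "dapi_mean", "AF_TRITC", "AF_Cy5"]:
        assert np.allclose(t3[col], 3.0 * t1[col])


def test_compartment_partition():
    """Nucleus mask and cytoplasm ring partition the cell mask."""
    nuclei, cells = _label_phantom()
    for lab in (1, 2):
        nuc = nuclei == lab
        ring = (cells == lab) & (nuclei == 0)
        cell = cells == lab
        assert np.array_equal(nuc | ring, cell)
        assert not (nuc & ring).any()


def test_missing_marker_channel_errors():
    nuclei, cells = _label_phantom()
    with pytest.raises(ValueError, match="NUC"):
        measure_cells(
            np.zeros((3, 48, 48)), nuclei, cells, tiny_panel(),
            ["DAPI", "AF_TRITC", "AF_Cy5"],
        )


def test_circularity_near_one_for_disk():
    yy, xx = np.mgrid[:64, :64]
    nuclei = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2).astype(np.int32)
    cells = expand_nuclei(nuclei, 5)
    t = measure_cells(np.zeros((5, 64, 64)), nuclei, cells, tiny_panel(), CHANNELS)
    assert 0.85 < t["circularity"].iloc[0] <= 1.15


# --- positive_area_fraction -------------------------------------------------

def test_area_fraction_edge_cases():
    img = np.zeros((10, 10))
    mask = np.ones((10, 10), dtype=bool)
    assert positive_area_fraction(img, mask, 1.0) == 0.0
    img[:5] = 10.0
    assert positive_area_fraction(img, mask, 1.0) == 0.5
    with pytest.raises(ValueError, match="empty"):
        positive_area_fraction(img, np.zeros((10, 10), dtype=bool), 1.0)


def test_area_fraction_median_threshold_counting_oracle():
    rng = np.random.default_rng(3)
    img = rng.uniform(0, 100, size=(50, 50))
    mask = np.ones_like(img, dtype=bool)
    thr = float(np.median(img))
    frac = positive_area_fraction(img, mask, thr)
    oracle = (img > thr).sum() / img.size
    assert frac == oracle
    assert abs(frac - 0.5) <= 1 / img.size + 1e-12
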