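"""Seeded synthetic seqIF fixtures.

Two generators emulate the statistical structure of a background-subtracted
TMA acquisition at the level each pipeline stage consumes:

* :func:`simulate_tissue_image` — a multichannel 16-bit stack
  ``[DAPI, AF_TRITC, AF_Cy5, marker_1 .. marker_K]`` plus an integer nuclei
  label image. Nuclei are non-overlapping ellipses; nuclear markers are
  painted only inside nuclei, cytoplasmic markers in a surrounding annulus;
  erythrocyte-like artifacts are bright in every channel (autofluorescence
  included) with only faint DAPI, mimicking the out-of-focus red blood cells
  that survive nuclei segmentation on real slides.
* :func:`simulate_expression_table` — the single-cell table directly, with
  phenotype-conditional Gaussian marker means, QC features (detection
  probability, DAPI mean, nucleus area, circularity) and per-core spatially
  clustered coordinates so spatial statistics have known sign.

Both are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .panel import AF_CHANNELS, DAPI_CHANNEL, NUCLEUS, MarkerPanel, phantom_panel

__all__ = [
    "TissuePhantomSpec",
    "simulate_tissue_image",
    "simulate_expression_table",
    "write_fixture_dir",
]

#: DAPI intensity painted inside real nuclei (16-bit counts).
DAPI_LEVEL = 3000.0
#: Fraction of DAPI_LEVEL painted inside erythrocytes (faint DAPI signal).
ERYTHROCYTE_DAPI_FRAC = 0.2


def default_marker_means() -> dict[str, dict[str, float]]:
    """Positive compartment intensities per phenotype for the default panel.

    Unlisted (phenotype, marker) pairs fall back to ``negative_mean``
    (residual background). The 450-count gap between positive signal and the
    50-count background at the default ``noise_sd`` of 30 gives ~15 sigma of
    separation, comfortably above the >=8 sigma regime the phenotyping
    recovery guarantees assume. The all-negative "Other" phenotype keeps
    every marker's positive fraction a minority, as on real tissue.
    """
    return {
        "Tumor": {"PanCK": 500.0},
        "T helper": {"CD3": 500.0, "CD4": 500.0},
        "T cytotoxic": {"CD3": 500.0, "CD8": 500.0},
        "Macrophage": {"CD68": 500.0},
        "Other": {},
    }


@dataclass
class TissuePhantomSpec:
    """Parameters of the synthetic tissue phantom.

    Defaults describe a small four-phenotype TMA-like field: ~10% planted
    erythrocyte artifacts bright in all channels, a per-channel
    autofluorescence baseline, 0.23 µm pixels, and four circular cores with
    one Gaussian hotspot per phenotype per core.
    """

    image_shape: tuple[int, int] = (768, 768)
    pixel_size: float = 0.23  # µm per pixel
    n_cells: int = 300
    phenotype_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "Tumor": 0.25,
            "T helper": 0.20,
            "T cytotoxic": 0.15,
            "Macrophage": 0.12,
            "Other": 0.28,
        }
    )
    marker_means: dict[str, dict[str, float]] = field(
        default_factory=default_marker_means
    )
    noise_sd: float = 30.0
    negative_mean: float = 50.0  # residual background of negative cells
    n_erythrocytes: int = 30
    erythrocyte_brightness: float = 3000.0
    autofluorescence_level: float = 20.0
    n_cores: int = 4
    seed: int = 0
    panel: MarkerPanel = field(default_factory=phantom_panel)
    dilation_px: int = 5  # annulus width for cytoplasmic painting

    def __post_init__(self) -> None:
        total = sum(self.phenotype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"phenotype_fractions must sum to 1 (got {total!r})"
            )
        if any(f < 0 for f in self.phenotype_fractions.values()):
            raise ValueError("phenotype fractions must be non-negative")
        if self.image_shape[0] <= 0 or self.image_shape[1] <= 0:
            raise ValueError("image_shape must be positive")
        if self.noise_sd < 0 or self.autofluorescence_level < 0:
            raise ValueError("intensities must be non-negative")
        if self.erythrocyte_brightness < 0:
            raise ValueError("erythrocyte_brightness must be non-negative")
        if self.n_cells < 0 or self.n_erythrocytes < 0 or self.n_cores < 1:
            raise ValueError("counts must be non-negative, n_cores >= 1")

    @property
    def channel_names(self) -> list[str]:
        return [DAPI_CHANNEL, *AF_CHANNELS, *self.panel.names]

    @property
    def phenotypes(self) -> list[str]:
        return list(self.phenotype_fractions)


# ---------------------------------------------------------------------------
# geometry helpers

def _core_centers(spec: TissuePhantomSpec) -> tuple[np.ndarray, float]:
    """Lay circular cores on a grid; returns (centers (n,2) as (y,x), radius)."""
    h, w = spec.image_shape
    ncols = int(np.ceil(np.sqrt(spec.n_cores)))
    nrows = int(np.ceil(spec.n_cores / ncols))
    cell_h, cell_w = h / nrows, w / ncols
    radius = 0.45 * min(cell_h, cell_w)
    centers = []
    for i in range(spec.n_cores):
        r, c = divmod(i, ncols)
        centers.append(((r + 0.5) * cell_h, (c + 0.5) * cell_w))
    return np.asarray(centers), radius


def _hotspots(
    spec: TissuePhantomSpec, rng: np.random.Generator
) -> dict[tuple[int, str], np.ndarray]:
    """One Gaussian hotspot centre per (core, phenotype), inside the core."""
    centers, radius = _core_centers(spec)
    spots: dict[tuple[int, str], np.ndarray] = {}
    for core in range(spec.n_cores):
        for ph in spec.phenotypes:
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.6 * radius)
            spots[(core, ph)] = centers[core] + rad * np.array(
                [np.sin(ang), np.cos(ang)]
            )
    return spots


def _sample_position(
    core_center: np.ndarray,
    core_radius: float,
    hotspot: np.ndarray,
    sd: float,
    rng: np.random.Generator,
    shape: tuple[int, int],
    margin: float,
) -> np.ndarray:
    """Draw a point from the hotspot Gaussian, truncated to the core disk."""
    for _ in range(200):
        p = hotspot + rng.normal(0.0, sd, size=2)
        if (
            np.hypot(*(p - core_center)) <= core_radius
            and margin <= p[0] < shape[0] - margin
            and margin <= p[1] < shape[1] - margin
        ):
            return p
    # fall back to uniform in the core
    for _ in range(200):
        ang = rng.uniform(0, 2 * np.pi)
        rad = core_radius * np.sqrt(rng.uniform())
        p = core_center + rad * np.array([np.sin(ang), np.cos(ang)])
        if margin <= p[0] < shape[0] - margin and margin <= p[1] < shape[1] - margin:
            return p
    raise RuntimeError("could not place object inside core")


def _ellipse_masks(
    center: np.ndarray,
    a: float,
    b: float,
    theta: float,
    dilate: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks (within a local bounding box) of an ellipse and its
    dilation by ``dilate``; returns (yy, xx index grids flattened? no —
    (slice-based) global coordinate arrays) as (rows, cols, inner, outer)."""
    rmax = a + dilate + 1.0
    y0, x0 = center
    ylo, yhi = int(max(0, np.floor(y0 - rmax))), int(min(shape[0], np.ceil(y0 + rmax) + 1))
    xlo, xhi = int(max(0, np.floor(x0 - rmax))), int(min(shape[1], np.ceil(x0 + rmax) + 1))
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    dy, dx = yy - y0, xx - x0
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    inner = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    outer = (u / (a + dilate)) ** 2 + (v / (b + dilate)) ** 2 <= 1.0
    return (slice(ylo, yhi), slice(xlo, xhi)), inner, outer


def _eccentricity(a: float, b: float) -> float:
    return float(np.sqrt(1.0 - (min(a, b) / max(a, b)) ** 2))


def _detection_probability(ecc: float, rng: np.random.Generator) -> float:
    """Logistic in eccentricity plus noise: elongated, poorly star-convex
    nuclei get lower scores, giving the QC filter a meaningful lower tail."""
    p = 1.0 / (1.0 + np.exp(8.0 * (ecc - 0.9))) + rng.normal(0.0, 0.04)
    return float(np.clip(p, 0.0, 1.0))


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))))


# ---------------------------------------------------------------------------
# image phantom

def simulate_tissue_image(
    spec: TissuePhantomSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render the phantom to a 16-bit stack plus nuclei label image.

    Returns
    -------
    stack : uint16 array, shape (3 + K, H, W)
        Channels ordered ``[DAPI, AF_TRITC, AF_Cy5, marker_1 .. marker_K]``.
    labels : int32 array, shape (H, W)
        Nuclei label image; label i corresponds to ``nucleus_label`` i in the
        ground truth (erythrocytes included — they are segmented objects on
        real slides too).
    ground_truth : DataFrame
        cell_id, nucleus_label, true_phenotype (NA for artifacts),
        is_artifact, x, y (pixels), core_id.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    k = len(spec.panel)
    stack = np.zeros((3 + k, h, w), dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)

    stack[1] += spec.autofluorescence_level
    stack[2] += spec.autofluorescence_level
    stack[3:] += spec.autofluorescence_level

    centers, core_radius = _core_centers(spec)
    spots = _hotspots(spec, rng)
    hotspot_sd = 0.35 * core_radius
    marker_idx = {m: 3 + i for i, m in enumerate(spec.panel.names)}

    records = []
    next_label = 1
    phenos = spec.phenotypes
    fracs = np.array([spec.phenotype_fractions[p] for p in phenos])

    def place(a, b, theta, core, hotspot, max_tries=300):
        for attempt in range(max_tries):
            # prefer the phenotype hotspot; fall back to anywhere in the
            # core once the hotspot neighborhood is saturated
            sd = hotspot_sd if attempt < max_tries // 2 else core_radius
            pos = _sample_position(
                centers[core], core_radius, hotspot, sd, rng,
                (h, w), margin=a + spec.dilation_px + 2,
            )
            box, inner, outer = _ellipse_masks(
                pos, a, b, theta, spec.dilation_px, (h, w)
            )
            if not occupied[box][outer].any():
                return pos, box, inner, outer
        raise RuntimeError(
            f"failed to place non-overlapping nucleus after {max_tries} tries: "
            f"cell density too high for image_shape {spec.image_shape}"
        )

    # --- real cells
    for _ in range(spec.n_cells):
        core = int(rng.integers(spec.n_cores))
        ph = phenos[int(rng.choice(len(phenos), p=fracs))]
        a = rng.uniform(4.0, 8.0)
        b = rng.uniform(3.0, a)
        theta = rng.uniform(0, np.pi)
        pos, box, inner, outer = place(a, b, theta, core, spots[(core, ph)])
        occupied[box] |= outer
        labels[box][inner] = next_label
        stack[0][box][inner] += DAPI_LEVEL
        ring = outer & ~inner
        means = spec.marker_means.get(ph, {})
        for m in spec.panel.names:
            level = means.get(m, spec.negative_mean)
            if level <= 0:
                continue
            ch = marker_idx[m]
            if spec.panel[m].compartment == NUCLEUS:
                stack[ch][box][inner] += level
            else:
                stack[ch][box][ring] += level
        records.append(
            dict(
                cell_id=next_label,
                nucleus_label=next_label,
                true_phenotype=ph,
                is_artifact=False,
                x=pos[1],
                y=pos[0],
                core_id=core,
            )
        )
        next_label += 1

    # --- erythrocyte-like artifacts: bright everywhere, faint DAPI
    for _ in range(spec.n_erythrocytes):
        core = int(rng.integers(spec.n_cores))
        a = rng.uniform(3.0, 5.0)
        b = rng.uniform(2.5, a)
        theta = rng.uniform(0, np.pi)
        hotspot = centers[core]  # artifacts scattered around the core centre
        pos, box, inner, outer = place(a, b, theta, core, hotspot)
        occupied[box] |= outer
        labels[box][inner] = next_label
        stack[0][box][inner] += ERYTHROCYTE_DAPI_FRAC * DAPI_LEVEL
        for ch in range(1, 3 + k):
            stack[ch][box][inner] += spec.erythrocyte_brightness
        records.append(
            dict(
                cell_id=next_label,
                nucleus_label=next_label,
                true_phenotype=pd.NA,
                is_artifact=True,
                x=pos[1],
                y=pos[0],
                core_id=core,
            )
        )
        next_label += 1

    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
    stack = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)

    gt = pd.DataFrame(
        records,
        columns=[
            "cell_id", "nucleus_label", "true_phenotype", "is_artifact",
            "x", "y", "core_id",
        ],
    )
    return stack, labels, gt


# ---------------------------------------------------------------------------
# expression-table phantom

def simulate_expression_table(
    spec: TissuePhantomSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the single-cell expression table directly (no rasterization).

    Marker means are phenotype-conditional Gaussians floored at zero, on top
    of the autofluorescence baseline; artifacts get ``erythrocyte_brightness``
    in every channel including the AF columns. Coordinates follow per-core
    phenotype hotspots; QC columns carry realistic lower tails.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    centers, core_radius = _core_centers(spec)
    spots = _hotspots(spec, rng)
    hotspot_sd = 0.35 * core_radius
    phenos = spec.phenotypes
    fracs = np.array([spec.phenotype_fractions[p] for p in phenos])
    markers = spec.panel.names

    rows, gt_rows = [], []
    n_total = spec.n_cells + spec.n_erythrocytes
    for cid in range(1, n_total + 1):
        artifact = cid > spec.n_cells
        core = int(rng.integers(spec.n_cores))
        if artifact:
            ph = None
            hotspot = centers[core]
            a = rng.uniform(3.0, 5.0)
            b = rng.uniform(2.5, a)
        else:
            ph = phenos[int(rng.choice(len(phenos), p=fracs))]
            hotspot = spots[(core, ph)]
            a = rng.uniform(4.0, 8.0)
            b = rng.uniform(3.0, a)
        pos = _sample_position(
            centers[core], core_radius, hotspot, hotspot_sd, rng, (h, w), margin=1.0
        )
        area_px = np.pi * a * b
        area_um2 = area_px * spec.pixel_size**2
        circ = 4 * np.pi * area_px / _ellipse_perimeter(a, b) ** 2
        ecc = _eccentricity(a, b)
        row = dict(
            cell_id=cid,
            x=pos[1],
            y=pos[0],
            x_um=pos[1] * spec.pixel_size,
            y_um=pos[0] * spec.pixel_size,
            core_id=core,
        )
        if artifact:
            for m in markers:
                row[m] = max(
                    0.0, rng.normal(spec.erythrocyte_brightness, spec.noise_sd)
                )
            for af in AF_CHANNELS:
                row[af] = max(
                    0.0, rng.normal(spec.erythrocyte_brightness, spec.noise_sd)
                )
            row["dapi_mean"] = max(
                0.0,
                rng.normal(ERYTHROCYTE_DAPI_FRAC * DAPI_LEVEL, spec.noise_sd),
            )
            row["detection_probability"] = float(np.clip(rng.uniform(0.3, 0.9), 0, 1))
            row["circularity"] = rng.uniform(0.4, 0.8)
        else:
            means = spec.marker_means.get(ph, {})
            for m in markers:
                row[m] = max(
                    0.0, rng.normal(means.get(m, spec.negative_mean), spec.noise_sd)
                )
            for af in AF_CHANNELS:
                row[af] = max(
                    0.0,
                    rng.normal(spec.autofluorescence_level, max(spec.noise_sd, 1e-12) * 0.5),
                )
            row["dapi_mean"] = max(0.0, rng.normal(DAPI_LEVEL, 10 * spec.noise_sd))
            row["detection_probability"] = _detection_probability(ecc, rng)
            row["circularity"] = float(np.clip(circ * rng.normal(1.0, 0.03), 0.05, 1.0))
        row["area_um2"] = area_um2
        rows.append(row)
        gt_rows.append(
            dict(
                cell_id=cid,
                nucleus_label=cid,
                true_phenotype=ph if ph is not None else pd.NA,
                is_artifact=artifact,
                x=pos[1],
                y=pos[0],
                core_id=core,
            )
        )

    table = pd.DataFrame(rows)
    gt = pd.DataFrame(gt_rows)
    return table, gt


# ---------------------------------------------------------------------------
# fixture output

def write_fixture_dir(spec: TissuePhantomSpec, outdir, image: bool = True) -> dict:
    """Write the phantom to disk: OME-TIFF stack + label TIFF + table CSV +
    ground-truth JSON. Returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    table, gt = simulate_expression_table(spec)
    paths["table"] = outdir / "cells.csv"
    table.to_csv(paths["table"], index=False)
    if image:
        stack, labels, gt_img = simulate_tissue_image(spec)
        paths["stack"] = outdir / "stack.ome.tif"
        tifffile.imwrite(
            paths["stack"],
            stack,
            ome=True,
            metadata={"axes": "CYX", "Channel": {"Name": spec.channel_names}},
        )
        paths["labels"] = outdir / "nuclei_labels.tif"
        tifffile.imwrite(paths["labels"], labels)
        paths["image_ground_truth"] = outdir / "image_ground_truth.json"
        gt_img.to_json(paths["image_ground_truth"], orient="records")
    paths["ground_truth"] = outdir / "ground_truth.json"
    gt.to_json(paths["ground_truth"], orient="records")
    with open(outdir / "panel.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(spec.panel.to_dict(), fh, sort_keys=False)
    with open(outdir / "spec.json", "w") as fh:
        json.dump(
            {
                k: v
                for k, v in spec.__dict__.items()
                if k not in ("panel", "marker_means")
            },
            fh,
            indent=2,
            default=str,
        )
    return paths
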