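"""Phenotype quantification statistics.

Three families of measurement used when scoring fusion-oncogene
phenotypes in embryos and myoblast cultures:

* **ΔΔCt relative expression** from qRT-PCR cycle thresholds with
  technical replicates (fold change = 2^(-ΔΔCt) against a reference
  gene and a calibrator sample);
* **thresholded positive-pixel counts and ratios** for fluorescence
  images (e.g. TUNEL-positive pixels normalized to GFP-positive
  pixels, or transgene pixel persistence between two timepoints
  imaged with identical settings);
* **myogenic-nuclei and fusion-capacity indices** from paired label
  masks of nuclei and myosin-heavy-chain-positive cells: the myogenic
  index is the fraction of all nuclei inside a MyHC+ cell, and the
  fusion capacity the fraction inside MyHC+ cells containing more than
  three nuclei (multi-nucleated myotubes).

Pixel positivity is strict (intensity > threshold); when no threshold
is supplied, Otsu's method on the image histogram provides one and the
chosen value is reported.  Nuclei are assigned to the cell label under
their centroid pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

__all__ = [
    "DdCtResult",
    "CellMasks",
    "FusionMetrics",
    "PixelQuant",
    "read_ct_table",
    "delta_delta_ct",
    "count_positive_pixels",
    "pixel_ratio",
    "persistence_counts",
    "assign_nuclei_to_cells",
    "fusion_metrics",
]


# ---------------------------------------------------------------------------
# ΔΔCt relative quantification


@dataclass(frozen=True)
class DdCtResult:
    """Relative expression of one gene in one sample.

    ``fold_change`` is 2^(-ΔΔCt); ``sd_ddct`` is the spread of the
    per-replicate ΔΔCt values (cycles), propagated to the linear scale
    as the asymmetric range [fold_low, fold_high] = 2^(-(ΔΔCt ± sd)).
    All three spread fields are None for a single technical replicate.
    """

    gene_id: str
    sample_id: str
    ddct: float
    fold_change: float
    sd_ddct: float | None
    fold_low: float | None
    fold_high: float | None


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV Ct table (gene_id, sample_id, replicate_index, ct)."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample_id", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return table


def _mean_ct(table: pd.DataFrame, gene: str, sample: str) -> float:
    sub = table[(table["gene_id"] == gene) & (table["sample_id"] == sample)]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not measured in sample {sample!r}")
    return float(sub["ct"].mean())


def delta_delta_ct(
    table: pd.DataFrame, target: str, reference: str, calibrator: str
) -> list[DdCtResult]:
    """ΔΔCt relative quantification of ``target`` across samples.

    Per sample, ΔCt = mean Ct(target) - mean Ct(reference);
    ΔΔCt = ΔCt(sample) - ΔCt(calibrator); fold change = 2^(-ΔΔCt).
    The replicate spread is the standard deviation of per-target-replicate
    ΔΔCt values (each target replicate paired with the sample's reference
    mean).  The calibrator sample's fold change is exactly 1.
    """
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    samples = list(dict.fromkeys(table["sample_id"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} absent from table")
    dct_cal = _mean_ct(table, target, calibrator) - _mean_ct(
        table, reference, calibrator
    )
    results: list[DdCtResult] = []
    for sample in samples:
        ref_mean = _mean_ct(table, reference, sample)
        reps = table[
            (table["gene_id"] == target) & (table["sample_id"] == sample)
        ]["ct"].to_numpy(dtype=float)
        ddct = float(reps.mean() - ref_mean - dct_cal)
        if reps.size > 1:
            per_rep = reps - ref_mean - dct_cal
            sd = float(per_rep.std(ddof=1))
            fold_low, fold_high = 2.0 ** -(ddct + sd), 2.0 ** -(ddct - sd)
        else:
            sd = fold_low = fold_high = None
        results.append(
            DdCtResult(
                gene_id=target,
                sample_id=sample,
                ddct=ddct,
                fold_change=2.0 ** -ddct,
                sd_ddct=sd,
                fold_low=fold_low,
                fold_high=fold_high,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Positive-pixel quantification


@dataclass(frozen=True)
class PixelQuant:
    """Positive-pixel count for one channel at one threshold."""

    channel_id: str
    threshold: float
    n_positive: int


def count_positive_pixels(
    image: np.ndarray, threshold: float | str = "auto", channel_id: str = "channel"
) -> PixelQuant:
    """Count pixels strictly above a threshold.

    ``threshold="auto"`` applies Otsu's method to the image histogram;
    the chosen value is recorded on the result.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if threshold == "auto":
        threshold = float(threshold_otsu(image))
    n = int(np.count_nonzero(image > threshold))
    return PixelQuant(channel_id=channel_id, threshold=float(threshold), n_positive=n)


def pixel_ratio(numerator: PixelQuant, denominator: PixelQuant) -> float:
    """Ratio of positive-pixel counts (e.g. TUNEL / GFP).

    A zero denominator flags the ratio undefined by returning NaN
    rather than raising.
    """
    if denominator.n_positive == 0:
        return math.nan
    return numerator.n_positive / denominator.n_positive


def persistence_counts(
    image_t1: np.ndarray, image_t2: np.ndarray, threshold: float
) -> tuple[int, int]:
    """Positive-pixel counts of two timepoints under one shared threshold.

    Both images must have been acquired (or simulated) with identical
    settings; a single threshold is therefore applied to both.  Image
    dimensions may differ (counts are absolute).
    """
    c1 = count_positive_pixels(image_t1, threshold).n_positive
    c2 = count_positive_pixels(image_t2, threshold).n_positive
    return c1, c2


# ---------------------------------------------------------------------------
# Fusion / myogenic indices from label masks


@dataclass
class CellMasks:
    """Paired label images: nuclei and myosin-positive cells.

    Zero is background in both; nucleus and cell labels are independent
    namespaces.  Both images share one shape.
    """

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray

    def __post_init__(self) -> None:
        self.nuclei_labels = np.asarray(self.nuclei_labels)
        self.cell_labels = np.asarray(self.cell_labels)
        if self.nuclei_labels.shape != self.cell_labels.shape:
            raise ValueError("nuclei and cell label images must share a shape")


@dataclass(frozen=True)
class FusionMetrics:
    """Myogenic-nuclei and fusion-capacity statistics."""

    total_nuclei: int
    myogenic_nuclei: int
    myogenic_index: float
    fusion_capacity: float
    per_cell_nuclei: dict[int, int]


def assign_nuclei_to_cells(masks: CellMasks) -> dict[int, int]:
    """Assign each nucleus to the cell label at its centroid pixel.

    Returns {nucleus label -> cell label}, with 0 meaning unassigned
    (centroid over background).
    """
    assignment: dict[int, int] = {}
    for prop in regionprops(masks.nuclei_labels):
        r, c = (int(round(v)) for v in prop.centroid)
        r = min(max(r, 0), masks.cell_labels.shape[0] - 1)
        c = min(max(c, 0), masks.cell_labels.shape[1] - 1)
        assignment[int(prop.label)] = int(masks.cell_labels[r, c])
    return assignment


def fusion_metrics(masks: CellMasks, fusion_min_nuclei: int = 4) -> FusionMetrics:
    """Myogenic index and fusion capacity from label masks.

    myogenic_index = nuclei inside any MyHC+ cell / total nuclei;
    fusion_capacity = nuclei inside MyHC+ cells holding at least
    ``fusion_min_nuclei`` nuclei / total nuclei.  The default of 4
    encodes the strict "more than 3 nuclei per myofiber" rule as an
    inclusive bound.
    """
    assignment = assign_nuclei_to_cells(masks)
    total = len(assignment)
    if total == 0:
        raise ValueError("no nuclei in the label image")
    per_cell: dict[int, int] = {}
    for cell in assignment.values():
        if cell > 0:
            per_cell[cell] = per_cell.get(cell, 0) + 1
    # cells present in the mask but holding no nuclei still count as cells
    for label in np.unique(masks.cell_labels):
        if label > 0:
            per_cell.setdefault(int(label), 0)
    myogenic = sum(per_cell.values())
    fused = sum(n for n in per_cell.values() if n >= fusion_min_nuclei)
    return FusionMetrics(
        total_nuclei=total,
        myogenic_nuclei=myogenic,
        myogenic_index=myogenic / total,
        fusion_capacity=fused / total,
        per_cell_nuclei=per_cell,
    )
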