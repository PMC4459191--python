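"""Fluorescence-based outcome scoring of an optoporation run.

Cells are segmented from the DAPI channel (histogram normalisation,
grey-scale opening to suppress small peaks, extended h-maxima transform,
connected components) and then classified in two steps:

1. DAPI gate — DAPI slowly crosses intact membranes, so a per-cell mean
   below the control threshold (control mean + 2 SD) means the membrane
   was not affected: INTACT.  Above it, the membrane was perforated.
2. Viability gate — among perforated cells, high ethidium bromide marks
   DEAD cells (EtBr is excluded by intact membranes); no EtBr plus clear
   calcein (hydrolysed only by living cells) marks OPTOPORATED_ALIVE.
   Cells above the DAPI gate with neither signal are AMBIGUOUS — the
   cases that would go to manual inspection at the bench.

The summary statistics are the dead-cell ratio r_d = N_d / N_total and
the optoporation-efficiency ratio r_o = N_DAPI_and_calcein / N_total.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import measure, morphology

__all__ = [
    "CellClass",
    "SegmentationParams",
    "SegmentedCell",
    "ThresholdSet",
    "OutcomeSummary",
    "normalize_histogram",
    "suppress_peaks",
    "segment_dapi",
    "compute_dapi_threshold",
    "compute_background_threshold",
    "learn_thresholds",
    "classify_cell",
    "classify_cells",
    "summarize_outcomes",
    "tabulate_by_condition",
    "score_images",
]


class CellClass(str, Enum):
    INTACT = "intact"
    OPTOPORATED_ALIVE = "optoporated_alive"
    DEAD = "dead"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the DAPI segmentation.

    opening_radius_px: disk radius of the grey-scale opening that
    suppresses small intensity peaks (0 disables it).
    h_value: depth of the extended h-maxima transform — maxima shallower
    than this (in grayscale counts, post-normalisation) are merged away.
    min_cell_area_px: components smaller than this are discarded.
    """

    opening_radius_px: int = 3
    h_value: float = 200.0
    min_cell_area_px: int = 20

    def __post_init__(self) -> None:
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be >= 0")
        if self.h_value <= 0:
            raise ValueError("h_value must be positive")
        if self.min_cell_area_px < 1:
            raise ValueError("min_cell_area_px must be >= 1")


@dataclass
class SegmentedCell:
    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    mean_dapi: float
    mean_etbr: float
    mean_calcein: float
    saturated_dapi: bool = False


@dataclass(frozen=True)
class ThresholdSet:
    """Intensity gates learned from untreated control images.

    The DAPI gate is control-cell mean + 2 SD.  The EtBr and calcein
    gates are built the same way from the background pixels of the
    respective control channel (control cells are alive, so their calcein
    signal cannot serve as a negative reference).
    """

    dapi_threshold: float
    etbr_threshold: float
    calcein_threshold: float
    mode: str = "sample"  # sample | gaussian_fit

    def __post_init__(self) -> None:
        if min(self.dapi_threshold, self.etbr_threshold, self.calcein_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.mode not in ("sample", "gaussian_fit"):
            raise ValueError("mode must be 'sample' or 'gaussian_fit'")


def normalize_histogram(
    image: np.ndarray,
    bit_depth: int = 12,
    low_pct: float = 0.5,
    high_pct: float = 99.5,
) -> np.ndarray:
    """Percentile contrast stretch onto the full bit-depth range.

    The 0.5th/99.5th percentiles map to 0 and ``2**bit_depth - 1``; values
    beyond are clipped.  Constant images are returned unchanged.  Output
    is float64.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    p_lo, p_hi = np.percentile(image, [low_pct, high_pct])
    if p_hi <= p_lo:
        return image.copy()
    top = 2**bit_depth - 1
    return np.clip((image - p_lo) / (p_hi - p_lo) * top, 0.0, top)


def suppress_peaks(image: np.ndarray, opening_radius_px: int) -> np.ndarray:
    """Grey-scale morphological opening with a disk; radius 0 is identity."""
    if opening_radius_px < 0:
        raise ValueError("opening_radius_px must be >= 0")
    image = np.asarray(image)
    if opening_radius_px == 0:
        return image.copy()
    return morphology.opening(image, morphology.disk(opening_radius_px))


def segment_dapi(
    image: np.ndarray,
    params: SegmentationParams,
    etbr: np.ndarray | None = None,
    calcein: np.ndarray | None = None,
    bit_depth: int = 12,
) -> tuple[np.ndarray, list[SegmentedCell]]:
    """Segment cells from a normalised, opened DAPI image.

    Extended h-maxima (regional maxima after h-suppression of depth
    ``h_value``) are labelled as connected components; components below
    ``min_cell_area_px`` are discarded and the rest relabelled 1..K in
    raster order of their first pixel.  Per-cell channel means are taken
    over the component pixels in each registered channel.  ``etbr`` /
    ``calcein`` must share the DAPI image shape; channel means default to
    0 where a channel is not supplied.
    """
    image = np.asarray(image, dtype=float)
    for name, ch in (("etbr", etbr), ("calcein", calcein)):
        if ch is not None and np.asarray(ch).shape != image.shape:
            raise ValueError(f"{name} channel shape {np.asarray(ch).shape} != DAPI shape {image.shape}")

    maxima = morphology.h_maxima(image, params.h_value)
    raw_labels = measure.label(maxima, connectivity=2)
    if raw_labels.max() == 0:
        return np.zeros_like(raw_labels, dtype=np.int32), []

    areas = np.bincount(raw_labels.ravel())
    keep = np.flatnonzero(areas >= params.min_cell_area_px)
    keep = keep[keep > 0]
    # relabel 1..K preserving raster order of first pixels (measure.label
    # already assigns labels in that order)
    remap = np.zeros(raw_labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    labels = remap[raw_labels]

    cells: list[SegmentedCell] = []
    saturation = 2**bit_depth - 1
    index = np.arange(1, keep.size + 1)
    if keep.size:
        centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index)
        mean_dapi = ndimage.mean(image, labels, index)
        mean_etbr = (
            ndimage.mean(np.asarray(etbr, dtype=float), labels, index)
            if etbr is not None
            else np.zeros(keep.size)
        )
        mean_calcein = (
            ndimage.mean(np.asarray(calcein, dtype=float), labels, index)
            if calcein is not None
            else np.zeros(keep.size)
        )
        max_dapi = ndimage.maximum(image, labels, index)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index)
        for k in range(keep.size):
            cells.append(
                SegmentedCell(
                    label=int(index[k]),
                    area_px=int(sizes[k]),
                    centroid=(float(centroids[k][0]), float(centroids[k][1])),
                    mean_dapi=float(mean_dapi[k]),
                    mean_etbr=float(mean_etbr[k]),
                    mean_calcein=float(mean_calcein[k]),
                    saturated_dapi=bool(max_dapi[k] >= saturation),
                )
            )
    return labels, cells


def compute_dapi_threshold(control_mean_intensities, mode: str = "sample") -> float:
    """DAPI gate from living control cells: mean + 2 standard deviations.

    ``sample`` uses the sample statistics directly (SD with n-1
    denominator).  ``gaussian_fit`` instead fits a Gaussian to the binned
    intensity histogram and returns mu + 2*sigma — robust when a
    saturation pile-up distorts the sample moments.
    """
    values = np.asarray(control_mean_intensities, dtype=float).ravel()
    if mode == "sample":
        if values.size < 2:
            raise ValueError("sample mode needs at least 2 control values")
        return float(values.mean() + 2.0 * values.std(ddof=1))
    if mode == "gaussian_fit":
        if values.size < 10:
            raise ValueError("gaussian_fit mode needs at least 10 control values")
        nbins = int(np.clip(values.size // 10, 10, 60))
        counts, edges = np.histogram(values, bins=nbins)
        centres = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, amp, mu, sigma):
            return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        p0 = (counts.max(), values.mean(), max(values.std(), 1e-6))
        popt, _ = optimize.curve_fit(gauss, centres, counts, p0=p0, maxfev=10000)
        return float(popt[1] + 2.0 * abs(popt[2]))
    raise ValueError("mode must be 'sample' or 'gaussian_fit'")


def compute_background_threshold(channel_image: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean + 2 SD of the background pixels of a control channel image.

    Used for the EtBr and calcein gates, where "signal" means clearly
    above the dark background rather than above a cell population.
    """
    values = np.asarray(channel_image, dtype=float)[np.asarray(background_mask, dtype=bool)]
    if values.size < 2:
        raise ValueError("background mask selects fewer than 2 pixels")
    return float(values.mean() + 2.0 * values.std(ddof=1))


def learn_thresholds(
    control_dapi: np.ndarray,
    control_etbr: np.ndarray,
    control_calcein: np.ndarray,
    params: SegmentationParams,
    bit_depth: int = 12,
    mode: str = "sample",
) -> ThresholdSet:
    """Learn the full gate set from an untreated control image triple.

    The DAPI gate comes from the segmented control cells; the EtBr and
    calcein gates from DAPI-dark background pixels (the extended maxima
    mark only nucleus caps, so DAPI darkness is what excludes cell
    skirts from the background estimate).
    """
    norm = suppress_peaks(
        normalize_histogram(control_dapi, bit_depth=bit_depth), params.opening_radius_px
    )
    labels, cells = segment_dapi(norm, params, bit_depth=bit_depth)
    if len(cells) < 2:
        raise ValueError("control image yielded fewer than 2 cells; cannot learn thresholds")
    raw_means = ndimage.mean(
        np.asarray(control_dapi, dtype=float), labels, [c.label for c in cells]
    )
    background = (labels == 0) & (norm < params.h_value)
    return ThresholdSet(
        dapi_threshold=compute_dapi_threshold(raw_means, mode=mode),
        etbr_threshold=compute_background_threshold(control_etbr, background),
        calcein_threshold=compute_background_threshold(control_calcein, background),
        mode=mode,
    )


def classify_cell(cell: SegmentedCell, thresholds: ThresholdSet) -> CellClass:
    """Two-step decision rule for one segmented cell."""
    if cell.mean_dapi <= thresholds.dapi_threshold:
        return CellClass.INTACT
    if cell.mean_etbr >= thresholds.etbr_threshold:
        return CellClass.DEAD
    if cell.mean_calcein >= thresholds.calcein_threshold:
        return CellClass.OPTOPORATED_ALIVE
    return CellClass.AMBIGUOUS


def classify_cells(cells, thresholds: ThresholdSet) -> list[CellClass]:
    return [classify_cell(c, thresholds) for c in cells]


@dataclass(frozen=True)
class OutcomeSummary:
    """Counts and ratios over one region of interest."""

    n_total: int
    n_intact: int
    n_dead: int
    n_dapi_and_calcein: int
    n_ambiguous: int
    r_d: float
    r_o: float

    def to_dict(self) -> dict:
        return {
            "N_total": self.n_total,
            "N_intact": self.n_intact,
            "N_d": self.n_dead,
            "N_DAPI_and_calcein": self.n_dapi_and_calcein,
            "N_ambiguous": self.n_ambiguous,
            "r_d": self.r_d,
            "r_o": self.r_o,
        }


def summarize_outcomes(classes) -> OutcomeSummary:
    """r_d = N_d / N_total and r_o = N_DAPI_and_calcein / N_total."""
    classes = list(classes)
    if not classes:
        raise ValueError("no cells to summarise")
    n = len(classes)
    n_dead = sum(c == CellClass.DEAD for c in classes)
    n_opto = sum(c == CellClass.OPTOPORATED_ALIVE for c in classes)
    n_intact = sum(c == CellClass.INTACT for c in classes)
    n_amb = sum(c == CellClass.AMBIGUOUS for c in classes)
    return OutcomeSummary(
        n_total=n,
        n_intact=n_intact,
        n_dead=n_dead,
        n_dapi_and_calcein=n_opto,
        n_ambiguous=n_amb,
        r_d=n_dead / n,
        r_o=n_opto / n,
    )


def tabulate_by_condition(groups: dict[str, OutcomeSummary]) -> pd.DataFrame:
    """Tidy table of outcome ratios per experimental condition."""
    if not groups:
        raise ValueError("no conditions to tabulate")
    rows = [{"condition": name, **summary.to_dict()} for name, summary in groups.items()]
    return pd.DataFrame(rows).set_index("condition")


def score_images(
    dapi: np.ndarray,
    etbr: np.ndarray,
    calcein: np.ndarray,
    params: SegmentationParams,
    thresholds: ThresholdSet,
    bit_depth: int = 12,
):
    """Full chain: normalise, open, segment, classify, summarise.

    Channel means for classification are measured on the RAW (unscaled)
    channels; the normalised image is used only to drive segmentation.
    Returns (label_image, cells, classes, summary).
    """
    dapi = np.asarray(dapi)
    norm = normalize_histogram(dapi, bit_depth=bit_depth)
    opened = suppress_peaks(norm, params.opening_radius_px)
    labels, cells = segment_dapi(opened, params, etbr=etbr, calcein=calcein, bit_depth=bit_depth)
    # replace the means measured on the normalised DAPI by raw-channel means
    if cells:
        index = [c.label for c in cells]
        raw_dapi = ndimage.mean(np.asarray(dapi, dtype=float), labels, index)
        raw_max = ndimage.maximum(np.asarray(dapi, dtype=float), labels, index)
        for c, m, mx in zip(cells, raw_dapi, raw_max):
            c.mean_dapi = float(m)
            c.saturated_dapi = bool(mx >= 2**bit_depth - 1)
    classes = classify_cells(cells, thresholds)
    summary = summarize_outcomes(classes) if cells else None
    return labels, cells, classes, summary
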