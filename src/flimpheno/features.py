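"""Cell segmentation and per-cell feature aggregation.

Per-pixel fit and phasor maps are reduced to one row per cell carrying the
twelve classification features: eight curve-fit features (alpha1, tau1, tau2,
tau_m for NAD(P)H and FAD) and four phasor features (G, S for each channel),
each the unweighted mean over the cell's valid pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters, measure

from .fitting import FitResult
from .phasor import PhasorMap

__all__ = [
    "SegmentationConfig",
    "DECAY_FEATURES",
    "PHASOR_FEATURES",
    "FEATURE_COLUMNS",
    "segment_cells",
    "aggregate_features",
    "merge_tables",
]

DECAY_FEATURES = [
    "nadph_alpha1",
    "nadph_tau1",
    "nadph_tau2",
    "nadph_tau_m",
    "fad_alpha1",
    "fad_tau1",
    "fad_tau2",
    "fad_tau_m",
]
PHASOR_FEATURES = ["nadph_g", "nadph_s", "fad_g", "fad_s"]
FEATURE_COLUMNS = DECAY_FEATURES + PHASOR_FEATURES

_ID_COLUMNS = ["field_id", "cell_id", "group"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Intensity-threshold segmentation settings (a CellProfiler stand-in)."""

    smoothing_sigma: float = 1.0
    threshold: float | None = None  # None -> global Otsu
    min_area: int = 10
    max_area: int = 10_000
    min_valid_pixels: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("areas must satisfy 0 < min_area < max_area")


def segment_cells(intensity: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Label cells in a total-photon intensity image.

    Gaussian smoothing, global Otsu (or fixed) threshold, connected-component
    labeling, then an area filter.  Deterministic; an empty mask is a valid
    result (e.g. a blank image).
    """
    if config is None:
        config = SegmentationConfig()
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 2 or np.any(intensity < 0):
        raise ValueError("intensity must be a nonnegative 2-D image")
    smoothed = filters.gaussian(intensity, sigma=config.smoothing_sigma, preserve_range=True)
    if config.threshold is None:
        if smoothed.max() == smoothed.min():
            return np.zeros(intensity.shape, dtype=np.uint16)
        thresh = filters.threshold_otsu(smoothed)
    else:
        thresh = config.threshold
    labels = measure.label(smoothed > thresh)
    out = np.zeros(intensity.shape, dtype=np.uint16)
    next_label = 1
    for region in measure.regionprops(labels):
        if config.min_area <= region.area <= config.max_area:
            out[labels == region.label] = next_label
            next_label += 1
    return out


def _cell_means(values: np.ndarray, valid: np.ndarray, mask: np.ndarray, labels: np.ndarray):
    """Mean of ``values`` over valid pixels of each label; also the valid count."""
    means = np.full(labels.size, np.nan)
    counts = np.zeros(labels.size, dtype=int)
    for k, label in enumerate(labels):
        sel = (mask == label) & valid
        counts[k] = int(sel.sum())
        if counts[k]:
            means[k] = float(values[sel].mean())
    return means, counts


def aggregate_features(
    fit_nadph: FitResult,
    fit_fad: FitResult,
    ph_nadph: PhasorMap,
    ph_fad: PhasorMap,
    mask: np.ndarray,
    group: str,
    field_id: int = 0,
    min_valid_pixels: int = 10,
) -> pd.DataFrame:
    """One feature row per cell: unweighted pixel means of the 12 quantities.

    For each cell, every quantity is averaged over pixels that are inside the
    cell and valid in that quantity's source map.  Cells whose smallest
    per-map valid-pixel count falls below ``min_valid_pixels`` are dropped.
    """
    mask = np.asarray(mask)
    for name, arr in (
        ("NAD(P)H fit", fit_nadph.valid),
        ("FAD fit", fit_fad.valid),
        ("NAD(P)H phasor", ph_nadph.valid),
        ("FAD phasor", ph_fad.valid),
    ):
        if arr.shape != mask.shape:
            raise ValueError(f"{name} map dimensions {arr.shape} != mask {mask.shape}")

    labels = np.unique(mask)
    labels = labels[labels > 0]
    sources = {
        "nadph_alpha1": (fit_nadph.alpha1, fit_nadph.valid),
        "nadph_tau1": (fit_nadph.tau1, fit_nadph.valid),
        "nadph_tau2": (fit_nadph.tau2, fit_nadph.valid),
        "nadph_tau_m": (fit_nadph.tau_m, fit_nadph.valid),
        "fad_alpha1": (fit_fad.alpha1, fit_fad.valid),
        "fad_tau1": (fit_fad.tau1, fit_fad.valid),
        "fad_tau2": (fit_fad.tau2, fit_fad.valid),
        "fad_tau_m": (fit_fad.tau_m, fit_fad.valid),
        "nadph_g": (ph_nadph.g, ph_nadph.valid),
        "nadph_s": (ph_nadph.s, ph_nadph.valid),
        "fad_g": (ph_fad.g, ph_fad.valid),
        "fad_s": (ph_fad.s, ph_fad.valid),
    }
    data = {"field_id": field_id, "cell_id": labels, "group": group}
    min_counts = np.full(labels.size, np.iinfo(np.int64).max)
    for column, (values, valid) in sources.items():
        means, counts = _cell_means(values, valid, mask, labels)
        data[column] = means
        min_counts = np.minimum(min_counts, counts)
    table = pd.DataFrame(data)
    table["n_valid_pixels"] = min_counts
    keep = (table["n_valid_pixels"] >= min_valid_pixels) & table[FEATURE_COLUMNS].notna().all(
        axis=1
    )
    return table.loc[keep].reset_index(drop=True)


def merge_tables(tables, group_labels=None) -> pd.DataFrame:
    """Concatenate per-field feature tables, rejecting duplicate (field, cell) ids.

    ``group_labels``, when given, overrides the ``group`` column of each table
    in order.  An empty table list yields an empty table with the full schema.
    """
    schema = _ID_COLUMNS + FEATURE_COLUMNS + ["n_valid_pixels"]
    tables = list(tables)
    if not tables:
        return pd.DataFrame(columns=schema)
    if group_labels is not None:
        if len(group_labels) != len(tables):
            raise ValueError("group_labels length must match number of tables")
        tables = [t.assign(group=g) for t, g in zip(tables, group_labels)]
    for t in tables:
        if list(t.columns) != list(tables[0].columns):
            raise ValueError("cannot merge tables with mismatched columns")
    merged = pd.concat(tables, ignore_index=True)
    dup = merged.duplicated(subset=["field_id", "cell_id"])
    if dup.any():
        pairs = merged.loc[dup, ["field_id", "cell_id"]].values.tolist()
        raise ValueError(f"duplicate (field_id, cell_id) pairs: {pairs[:5]}")
    return merged
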