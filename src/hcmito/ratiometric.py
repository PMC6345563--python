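"""Ratiometric red:green quantification of labeled cell regions.

Implements the measurement chain: maximum z-projection, background
estimation from a cell-free 30x30 um square, background-subtracted
per-cell channel means, red:green ratios, per-neuromast median
normalization, Hoechst label-retention calls, area-normalized nuclear
intensity, percent-of-control scaling, and per-fish aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedRatioError

log = logging.getLogger(__name__)

BACKGROUND_SQUARE_UM = 30.0   # side length of the cell-free background mask


@dataclass
class ChannelStack:
    """Multi-channel 3D stack (z, y, x) with physical voxel calibration."""

    channels: Dict[str, np.ndarray]   # name -> (z, y, x) array, AU
    pixel_size_xy: float              # um / voxel
    z_step: float                     # um

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("stack has no channels")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ConfigError(f"channel shapes differ: {shapes}")
        first = next(iter(shapes.values()))
        if len(first) != 3 or first[0] < 1:
            raise ConfigError("channels must be 3D (z, y, x) with >= 1 plane")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ConfigError("pixel_size_xy and z_step must be > 0")
        self.channels = {ch: np.asarray(a, dtype=float)
                         for ch, a in self.channels.items()}

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape


@dataclass
class RegionSet:
    """Integer label map of cell regions (0 = unassigned) plus the
    cell-free background square, both on the projected (y, x) grid."""

    cell_labels: np.ndarray                 # (y, x) int array
    background_slices: Tuple[slice, slice]  # axis-aligned square

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        if not np.issubdtype(self.cell_labels.dtype, np.integer):
            raise ConfigError("cell labels must be integer-valued")
        bg = self.background_mask()
        if np.any(self.cell_labels[bg] != 0):
            raise ConfigError("background region overlaps a cell label")

    def background_mask(self) -> np.ndarray:
        mask = np.zeros(self.cell_labels.shape, dtype=bool)
        mask[self.background_slices] = True
        if not mask.any():
            raise ConfigError("background region is empty")
        return mask

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]


@dataclass
class CellMeasure:
    """One cell's measured quantities along the ratio pipeline."""

    cell_id: int
    neuromast_id: str
    fish_id: str
    red_mean: float
    green_mean: float
    ratio: Optional[float] = None            # None when green_mean <= 0
    normalized_ratio: Optional[float] = None
    hoechst: Optional[bool] = None
    outcome: str = "na"                      # 'live' | 'die' | 'na'


@dataclass
class GroupSummary:
    """n / mean / SD of one group of values, tagged with its units."""

    n: int
    mean: float
    sd: float
    units: str = "normalized ratio"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("group summary requires n >= 1")
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")

    @classmethod
    def from_values(cls, values: Sequence[float],
                    units: str = "normalized ratio") -> "GroupSummary":
        vals = np.asarray(values, dtype=float)
        if vals.size == 0:
            raise ConfigError("cannot summarize an empty group")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return cls(n=int(vals.size), mean=float(np.mean(vals)), sd=sd, units=units)


def max_project(stack: ChannelStack) -> Dict[str, np.ndarray]:
    """Per-channel maximum intensity projection over z."""
    return {ch: arr.max(axis=0) for ch, arr in stack.channels.items()}


def background_square_slices(image_shape: tuple, origin_yx: tuple,
                             pixel_size_xy: float) -> Tuple[slice, slice]:
    """Axis-aligned 30x30 um square at the given (y, x) pixel origin;
    side length = round(30 / pixel_size) pixels."""
    side = int(round(BACKGROUND_SQUARE_UM / pixel_size_xy))
    y0, x0 = int(origin_yx[0]), int(origin_yx[1])
    if side < 1 or y0 < 0 or x0 < 0 or y0 + side > image_shape[0] \
            or x0 + side > image_shape[1]:
        raise ConfigError("background square does not fit inside the image")
    return (slice(y0, y0 + side), slice(x0, x0 + side))


def estimate_background(image: np.ndarray, regions: RegionSet) -> Tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of the background-square pixels.

    The RegionSet constructor guarantees the square excludes all cells.
    """
    mask = regions.background_mask()
    vals = np.asarray(image, dtype=float)[mask]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


def cell_mean_intensity(image: np.ndarray, cell_mask: np.ndarray,
                        background_mean: float,
                        clip_negative: bool = False) -> float:
    """Background-subtracted mean intensity within one cell mask.

    Negative results propagate by default so error accumulation stays
    visible; clip_negative=True floors at zero.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ConfigError("cell mask is empty")
    val = float(np.mean(np.asarray(image, dtype=float)[cell_mask])) - background_mean
    return max(val, 0.0) if clip_negative else val


def red_green_ratio(red_mean: float, green_mean: float) -> float:
    """red_mean / green_mean; undefined (error) when green_mean <= 0."""
    if green_mean <= 0:
        raise UndefinedRatioError(
            f"green mean {green_mean!r} <= 0; ratio undefined")
    return red_mean / green_mean


def normalize_to_neuromast_median(df: pd.DataFrame,
                                  ratio_col: str = "ratio",
                                  group_col: str = "neuromast_id") -> pd.Series:
    """Divide each cell's ratio by the median ratio of its neuromast.

    Cells with undefined (NaN) ratios are excluded from the median and
    receive NaN. Raises ConfigError if any group median is <= 0.
    """
    if df.empty:
        raise ConfigError("no cells to normalize")
    medians = df.groupby(group_col)[ratio_col].transform("median")
    bad = df.groupby(group_col)[ratio_col].median()
    bad = bad[~(bad > 0)]
    if len(bad):
        raise ConfigError(
            f"non-positive neuromast median ratio for: {list(bad.index)}")
    return df[ratio_col] / medians


def call_label_retention(intensity: float, background_mean: float,
                         background_sd: float) -> bool:
    """Hoechst label-retention rule: intensity strictly greater than
    background mean + 1 SD."""
    if background_sd < 0:
        raise ConfigError("background_sd must be >= 0")
    return intensity > background_mean + background_sd


def area_normalized_nuclear_intensity(image: np.ndarray, mask: np.ndarray,
                                      background_mean: float) -> Tuple[float, float]:
    """(area-normalized, raw) background-subtracted mean intensity of a
    combined nuclear mask on a single image plane.

    Normalizing the mean by the mask area (pixels) controls for the
    number of distinguishable cells; both values are returned because the
    per-pixel units are not comparable across magnifications.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ConfigError("nuclear mask is empty")
    mean = float(np.mean(np.asarray(image, dtype=float)[mask])) - background_mean
    return mean / area, mean


def percent_of_control(values: Sequence[float], control_mean: float) -> np.ndarray:
    """Scale values to percent of the control-group mean (control -> 100)."""
    if control_mean <= 0:
        raise ConfigError("control mean must be > 0")
    return np.asarray(values, dtype=float) * 100.0 / control_mean


def aggregate_per_fish(df: pd.DataFrame, value_col: str,
                       fish_col: str = "fish_id") -> pd.Series:
    """Arithmetic mean of per-neuromast values per fish; the per-fish n is
    the statistical unit for downstream group comparisons."""
    if df.empty:
        raise ConfigError("nothing to aggregate")
    return df.groupby(fish_col)[value_col].mean()


def measure_stack(stack: ChannelStack, regions: RegionSet,
                  clip_negative: bool = False) -> pd.DataFrame:
    """Run the full per-cell measurement chain on one stack.

    Returns a tidy frame with one row per labeled cell: background-
    subtracted red/green means, the red:green ratio (NaN when green <= 0,
    with the exclusion logged), and Hoechst retention when a nuclear
    channel is present (measured on the nuclear max projection).
    """
    proj = max_project(stack)
    for ch in ("red", "green"):
        if ch not in proj:
            raise ConfigError(f"stack lacks required channel '{ch}'")
    bg = {ch: estimate_background(img, regions) for ch, img in proj.items()}
    rows = []
    n_excluded = 0
    for cid in regions.cell_ids:
        mask = regions.cell_labels == cid
        red = cell_mean_intensity(proj["red"], mask, bg["red"][0], clip_negative)
        green = cell_mean_intensity(proj["green"], mask, bg["green"][0], clip_negative)
        try:
            ratio = red_green_ratio(red, green)
        except UndefinedRatioError:
            ratio = np.nan
            n_excluded += 1
        row = {"cell_id": int(cid), "red_mean": red, "green_mean": green,
               "ratio": ratio}
        if "nuclear" in proj:
            nuc = float(np.mean(proj["nuclear"][mask]))
            row["hoechst"] = call_label_retention(nuc, *bg["nuclear"])
        rows.append(row)
    if n_excluded:
        log.warning("excluded %d cell(s) with undefined red:green ratio",
                    n_excluded)
    df = pd.DataFrame(rows)
    df.attrs["n_excluded_undefined_ratio"] = n_excluded
    return df
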