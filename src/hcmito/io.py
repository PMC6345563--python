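"""File formats: OME-TIFF stacks, TIFF label maps, CSV tables, JSON
reports, and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import SimulationConfig, config_to_dict
from .errors import ConfigError
from .ratiometric import ChannelStack, RegionSet, background_square_slices

SCHEMA_VERSION = 1

CELL_CSV_COLUMNS = ["cell_id", "fish_id", "neuromast_id", "red_mean",
                    "green_mean", "ratio", "normalized_ratio", "hoechst",
                    "outcome"]


def write_ome_stack(stack: ChannelStack, path,
                    channel_order: Optional[Sequence[str]] = None) -> Path:
    """Write a ChannelStack as float32 OME-TIFF (axes CZYX) with physical
    pixel sizes in the metadata."""
    path = Path(path)
    order = list(channel_order or stack.channels)
    missing = [c for c in order if c not in stack.channels]
    if missing:
        raise ConfigError(f"channels not in stack: {missing}")
    arr = np.stack([stack.channels[c] for c in order]).astype(np.float32)
    tifffile.imwrite(
        path, arr, ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": order},
            "PhysicalSizeX": stack.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeZUnit": "µm",
        })
    return path


def read_channel_stack(path, channel_order: Sequence[str],
                       pixel_size_xy: Optional[float] = None,
                       z_step: Optional[float] = None) -> ChannelStack:
    """Read an OME-TIFF stack with a declared channel order.

    Pixel sizes come from the OME metadata; explicit arguments override
    it, and missing metadata without an override is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = {}
        if tif.ome_metadata:
            ome = tifffile.xml2dict(tif.ome_metadata)
            try:
                meta = ome["OME"]["Image"]["Pixels"]
            except (KeyError, TypeError):
                meta = {}
    if arr.ndim == 3:        # single channel stored CZYX -> ZYX
        arr = arr[None]
    if arr.ndim != 4:
        raise ConfigError(f"{path}: expected a CZYX stack, got shape {arr.shape}")
    if arr.shape[0] != len(channel_order):
        raise ConfigError(
            f"{path}: stack has {arr.shape[0]} channels but "
            f"{len(channel_order)} were declared")
    px = pixel_size_xy if pixel_size_xy is not None else meta.get("PhysicalSizeX")
    zs = z_step if z_step is not None else meta.get("PhysicalSizeZ")
    if px is None or zs is None:
        raise ConfigError(
            f"{path}: missing pixel-size metadata and no override provided")
    channels = {name: arr[i] for i, name in enumerate(channel_order)}
    return ChannelStack(channels=channels, pixel_size_xy=float(px),
                        z_step=float(zs))


def write_label_map(regions: RegionSet, path) -> Path:
    """16-bit single-channel TIFF of the cell label map."""
    path = Path(path)
    tifffile.imwrite(path, regions.cell_labels.astype(np.uint16))
    return path


def read_label_map(path, background_origin_yx, pixel_size_xy: float) -> RegionSet:
    """Read an integer label map and attach the background square.

    The RegionSet constructor rejects a background square overlapping
    any cell label; an empty map (no cells) is an error.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ConfigError(f"{path}: label map must be integer-valued")
    if arr.ndim != 2:
        raise ConfigError(f"{path}: label map must be a single 2D channel")
    if not (arr > 0).any():
        raise ConfigError(f"{path}: no cells in label map")
    slices = background_square_slices(arr.shape, background_origin_yx,
                                      pixel_size_xy)
    return RegionSet(cell_labels=arr, background_slices=slices)


def write_cell_table(df: pd.DataFrame, path) -> Path:
    """Per-cell CSV with the documented fixed header (missing measurement
    columns are emitted empty)."""
    path = Path(path)
    out = df.copy()
    for col in CELL_CSV_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[CELL_CSV_COLUMNS].to_csv(path, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("cell_id", "neuromast_id") if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: cell table missing columns {missing}")
    if "outcome" in df.columns:
        df["outcome"] = df["outcome"].fillna("na")
    return df


def write_trace_table(traces, path) -> Path:
    """Long-format trace CSV: cell_id, channel, frame_time_s, intensity."""
    path = Path(path)
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "cell_id": tr.cell_id, "channel": tr.channel,
            "frame_time_s": tr.frame_times, "intensity": tr.raw_values}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted with every pipeline run: configuration
    snapshot, software version, seed, input checksums, and per-stage
    included/excluded counts that must reconcile."""

    seed: int
    config_snapshot: dict = field(default_factory=dict)
    software_version: str = ""
    input_checksums: Dict[str, str] = field(default_factory=dict)
    stage_counts: Dict[str, dict] = field(default_factory=dict)

    def record_inputs(self, paths) -> None:
        for p in paths:
            if p is not None:
                self.input_checksums[str(p)] = sha256_file(p)

    def record_stage(self, stage: str, n_in: int, n_included: int,
                     exclusions: Optional[Dict[str, int]] = None) -> None:
        exclusions = exclusions or {}
        n_excluded = sum(exclusions.values())
        if n_included + n_excluded != n_in:
            raise ConfigError(
                f"stage '{stage}': counts do not reconcile "
                f"({n_included} + {n_excluded} != {n_in})")
        self.stage_counts[stage] = {
            "n_input": n_in, "n_included": n_included,
            "exclusions": exclusions}

    def as_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "software_version": self.software_version,
            "config": self.config_snapshot,
            "input_checksums": self.input_checksums,
            "stage_counts": self.stage_counts,
        }


def simulation_manifest(config: SimulationConfig, version: str) -> RunManifest:
    return RunManifest(seed=config.seed,
                       config_snapshot=config_to_dict(config),
                       software_version=version)
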