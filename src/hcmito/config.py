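"""Configuration dataclasses for simulation and pipeline runs.

The simulation defaults encode the study conditions this package emulates:
stimulus-evoked calcium kinetics with cytoplasmic 75% rise time 8.9 s /
peak 1.3 and mitochondrial 13 s / 1.5, and neomycin-exposure cohorts whose
median-normalized red:green ratios follow Live ~ N(0.77, 0.37) and
Die ~ N(1.30, 0.34) with a death fraction of 74/216.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError

#: ln(4): a saturating exponential reaches 75% of its asymptote after
#: rise_tau * ln(4) seconds, so t75 parameterizes rise_tau directly.
LN4 = math.log(4.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class TraceParams:
    """Kinetic parameters for one channel's stimulus-response trace.

    ``amplitude`` is the asymptotic fractional increase over baseline
    (so the noise-free normalized trace saturates toward 1 + amplitude);
    ``rise_t75`` is the time to 75% of that asymptote, from which the
    rise time constant is rise_t75 / ln 4.
    """

    baseline_level: float = 100.0   # AU
    amplitude: float = 0.3          # dimensionless fractional rise
    rise_t75: float = 8.9           # s, time to 75% of asymptote
    decay_tau: float = 5.0          # s, post-stimulus exponential decay
    noise_sd: float = 0.0           # AU, additive Gaussian noise

    def __post_init__(self) -> None:
        _require(self.baseline_level > 0, "baseline_level must be > 0")
        _require(self.amplitude >= 0, "amplitude must be >= 0")
        _require(self.rise_t75 > 0, "rise_t75 must be > 0")
        _require(self.decay_tau > 0, "decay_tau must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")

    @property
    def rise_tau(self) -> float:
        return self.rise_t75 / LN4


def default_trace_params() -> dict:
    """Cytoplasmic vs mitochondrial calcium-response defaults."""
    return {
        "cyto": TraceParams(baseline_level=100.0, amplitude=0.3,
                            rise_t75=8.9, decay_tau=5.0, noise_sd=0.0),
        "mito": TraceParams(baseline_level=100.0, amplitude=0.5,
                            rise_t75=13.0, decay_tau=30.0, noise_sd=0.0),
    }


@dataclass
class GroupDist:
    """Normal distribution (on the median-normalized ratio scale) for one group."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        _require(self.sd >= 0, "sd must be >= 0")


def default_ratio_dist() -> dict:
    return {"live": GroupDist(0.77, 0.37), "die": GroupDist(1.30, 0.34)}


@dataclass
class CohortParams:
    """Cohort layout and outcome model for the neomycin-exposure simulation.

    The default layout (15 cells x 3 neuromasts x n_fish) mirrors the
    study's 216 cells across ~14 neuromasts from six fish; death_frac
    defaults to 74/216.
    """

    n_fish: int = 6
    neuromasts_per_fish: int = 3
    cells_per_neuromast: int = 15
    frac_older: float = 0.36
    ratio_dist: dict = field(default_factory=default_ratio_dist)
    outcome_model: str = "group_conditional"   # or "logistic"
    death_frac: float = 74.0 / 216.0
    beta0: float = -4.0
    beta1: float = 3.5

    def __post_init__(self) -> None:
        _require(self.n_fish >= 1, "n_fish must be >= 1")
        _require(2 <= self.neuromasts_per_fish <= 4,
                 "neuromasts_per_fish must be in 2..4")
        _require(self.cells_per_neuromast >= 1,
                 "cells_per_neuromast must be >= 1")
        _require(0.0 <= self.frac_older <= 1.0, "frac_older must be in [0,1]")
        _require(self.outcome_model in ("group_conditional", "logistic"),
                 "outcome_model must be 'group_conditional' or 'logistic'")
        if self.outcome_model == "group_conditional":
            _require(0.0 < self.death_frac < 1.0,
                     "death_frac must be in (0,1)")
        for name in ("live", "die"):
            _require(name in self.ratio_dist,
                     f"ratio_dist must define group '{name}'")

    @property
    def n_cells(self) -> int:
        return self.n_fish * self.neuromasts_per_fish * self.cells_per_neuromast


@dataclass
class ImageParams:
    """Geometry and optics of the rendered neuromast z-stack."""

    shape_zyx: tuple = (9, 160, 160)   # voxels
    pixel_size_xy: float = 0.4         # um / voxel
    z_step: float = 2.0                # um, matches 2-um optical sectioning
    cell_radius: float = 2.8           # um
    puncta_per_cell: int = 8
    psf_sigma: float = 0.3             # um, Gaussian PSF in xy
    background_level: float = 20.0     # AU
    camera_noise_sd: float = 0.0       # AU
    include_nuclear: bool = True
    green_amplitude: float = 400.0     # AU per punctum before blur
    nuclear_amplitude: float = 120.0   # AU, Hoechst-positive nuclei

    def __post_init__(self) -> None:
        _require(len(self.shape_zyx) == 3 and all(int(s) >= 1 for s in self.shape_zyx),
                 "shape_zyx must be three positive integers")
        self.shape_zyx = tuple(int(s) for s in self.shape_zyx)
        _require(self.pixel_size_xy > 0, "pixel_size_xy must be > 0")
        _require(self.z_step > 0, "z_step must be > 0")
        _require(self.cell_radius > 0, "cell_radius must be > 0")
        _require(self.puncta_per_cell >= 1, "puncta_per_cell must be >= 1")
        _require(self.psf_sigma > 0, "psf_sigma must be > 0")
        _require(self.background_level >= 0, "background_level must be >= 0")
        _require(self.camera_noise_sd >= 0, "camera_noise_sd must be >= 0")


@dataclass
class SimulationConfig:
    """Master configuration for all three synthetic artifact kinds.

    Identical (seed, config) pairs produce bit-identical artifacts; each
    artifact kind (traces / cohort / stack) draws from its own child
    stream of the master seed so adding one does not perturb the others.
    """

    seed: int = 0
    frame_interval: float = 1.0        # s
    n_baseline_frames: int = 10
    stimulus_duration: float = 40.0    # s
    post_stimulus_duration: float = 30.0  # s
    n_traces_per_channel: int = 21
    trace_params: dict = field(default_factory=default_trace_params)
    cohort_params: CohortParams = field(default_factory=CohortParams)
    image_params: ImageParams = field(default_factory=ImageParams)

    def __post_init__(self) -> None:
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.n_baseline_frames >= 3, "n_baseline_frames must be >= 3")
        _require(self.stimulus_duration > 0, "stimulus_duration must be > 0")
        _require(self.post_stimulus_duration >= 0,
                 "post_stimulus_duration must be >= 0")
        _require(self.n_traces_per_channel >= 1,
                 "n_traces_per_channel must be >= 1")

    # -- derived frame-window geometry (half-open index windows) --------
    @property
    def n_stimulus_frames(self) -> int:
        return int(round(self.stimulus_duration / self.frame_interval))

    @property
    def n_post_frames(self) -> int:
        return int(round(self.post_stimulus_duration / self.frame_interval))

    @property
    def n_frames(self) -> int:
        return self.n_baseline_frames + self.n_stimulus_frames + self.n_post_frames

    @property
    def baseline_window(self) -> tuple:
        return (0, self.n_baseline_frames)

    @property
    def stimulus_window(self) -> tuple:
        return (self.n_baseline_frames,
                self.n_baseline_frames + self.n_stimulus_frames)


def _dict_to_config(d: dict) -> SimulationConfig:
    d = dict(d)
    if "trace_params" in d:
        d["trace_params"] = {k: TraceParams(**v) if isinstance(v, dict) else v
                             for k, v in d["trace_params"].items()}
    if "cohort_params" in d and isinstance(d["cohort_params"], dict):
        cp = dict(d["cohort_params"])
        if "ratio_dist" in cp:
            cp["ratio_dist"] = {k: GroupDist(**v) if isinstance(v, dict) else v
                                for k, v in cp["ratio_dist"].items()}
        d["cohort_params"] = CohortParams(**cp)
    if "image_params" in d and isinstance(d["image_params"], dict):
        d["image_params"] = ImageParams(**d["image_params"])
    return SimulationConfig(**d)


def load_simulation_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file (missing keys -> defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return _dict_to_config(raw.get("simulation", raw))
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Plain-dict snapshot of a config (for manifests / YAML round-trip)."""
    return asdict(cfg)


@dataclass
class PipelineConfig:
    """End-to-end pipeline run configuration.

    Paths may be None when the corresponding stage is skipped (e.g. a
    counts-only classification run needs no images).
    """

    out_dir: Path
    seed: int = 0
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stack_path: Optional[Path] = None
    label_map_path: Optional[Path] = None
    channel_order: tuple = ("red", "green", "nuclear")
    pixel_size_xy: Optional[float] = None   # overrides TIFF metadata
    trace_table_path: Optional[Path] = None
    cell_table_path: Optional[Path] = None
    counts_path: Optional[Path] = None
    zero_cell_policy: str = "flag"          # or "haldane"
    clip_negative_means: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        _require(self.zero_cell_policy in ("flag", "haldane"),
                 "zero_cell_policy must be 'flag' or 'haldane'")
        for attr in ("stack_path", "label_map_path", "trace_table_path",
                     "cell_table_path", "counts_path"):
            p = getattr(self, attr)
            if p is not None:
                p = Path(p)
                setattr(self, attr, p)
                _require(p.exists(), f"{attr} does not exist: {p}")


def load_pipeline_config(path) -> PipelineConfig:
    """Read a PipelineConfig from YAML; the `simulation:` block nests a
    SimulationConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    sim = raw.pop("simulation", None)
    if sim is not None:
        raw["simulation"] = _dict_to_config(sim)
    if "channel_order" in raw:
        raw["channel_order"] = tuple(raw["channel_order"])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
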