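"""Synthetic-data generation with ground truth.

Three artifact kinds, each drawn from its own child stream of the master
seed so artifacts can be added without perturbing one another:

* stimulus-response fluorescence traces (saturating-exponential rise
  toward baseline*(1+amplitude) during the stimulus, exponential decay
  after it, additive Gaussian noise);
* cell cohorts whose median-normalized red:green ratios follow the
  configured outcome-group normals (truncated at zero) and are then
  re-normalized so every neuromast's median is exactly 1;
* neuromast image stacks rendering each cell as a cluster of
  PSF-blurred puncta whose red:green intensity ratio equals the cell's
  true ratio, over a uniform background with optional camera noise,
  together with the ground-truth label map and a cell-free 30x30 um
  background square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import SimulationConfig, TraceParams
from .errors import ConfigError, GenerationError
from .ratiometric import (ChannelStack, RegionSet, background_square_slices,
                          normalize_to_neuromast_median)
from .traces import FluorescenceTrace

_STREAMS = {"traces": 0, "cohort": 1, "stack": 2}


def _rng(seed: int, kind: str) -> np.random.Generator:
    """One independent, reproducible stream per artifact kind."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[kind],)))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def noise_free_curve(times: np.ndarray, params: TraceParams,
                     t_on: float, t_off: float) -> np.ndarray:
    """Noise-free normalized (F/F0) trace values at the given times."""
    a, tau_r, tau_d = params.amplitude, params.rise_tau, params.decay_tau
    out = np.ones_like(times, dtype=float)
    rising = (times >= t_on) & (times < t_off)
    out[rising] = 1.0 + a * (1.0 - np.exp(-(times[rising] - t_on) / tau_r))
    a_end = a * (1.0 - math.exp(-(t_off - t_on) / tau_r))
    after = times >= t_off
    out[after] = 1.0 + a_end * np.exp(-(times[after] - t_off) / tau_d)
    return out


def true_kinetics(params: TraceParams, config: SimulationConfig) -> dict:
    """Analytic noise-free kinetics on the configured sampling grid.

    true_peak is the curve's maximum over the sampled frames (attained at
    stimulus offset); true_rise_time_75 solves the 75%-of-peak-excess
    crossing in continuous time; true_area sums the baseline excess over
    the stimulus-window frames.
    """
    dt = config.frame_interval
    d = config.stimulus_duration
    a, tau = params.amplitude, params.rise_tau
    sat = 1.0 - math.exp(-d / tau)
    peak = 1.0 + a * sat
    if a > 0:
        t75 = -tau * math.log(1.0 - 0.75 * sat)
    else:
        t75 = None
    i = np.arange(config.n_stimulus_frames)
    area = float(a * np.sum(1.0 - np.exp(-i * dt / tau)))
    return {"true_peak": peak, "true_rise_time_75": t75, "true_area": area}


def generate_traces(config: SimulationConfig
                    ) -> Tuple[list, pd.DataFrame]:
    """Generate noisy traces for every configured channel.

    Returns the traces and a ground-truth table (one row per trace) with
    the noise-free kinetics. Raises ConfigError when the stimulus window
    does not fit in the trace.
    """
    if config.n_stimulus_frames < 1:
        raise ConfigError("stimulus window shorter than one frame interval")
    if config.stimulus_window[1] > config.n_frames:
        raise ConfigError("stimulus window exceeds the trace duration")
    rng = _rng(config.seed, "traces")
    times = np.arange(config.n_frames) * config.frame_interval
    t_on = times[config.n_baseline_frames]
    t_off = t_on + config.stimulus_duration
    traces, truth_rows = [], []
    for channel in sorted(config.trace_params):
        params = config.trace_params[channel]
        curve = noise_free_curve(times, params, t_on, t_off) * params.baseline_level
        truth = true_kinetics(params, config)
        for k in range(config.n_traces_per_channel):
            raw = curve + rng.normal(0.0, params.noise_sd, size=curve.size)
            cell_id = f"{channel}_{k:03d}"
            traces.append(FluorescenceTrace(
                frame_times=times.copy(), raw_values=raw, channel=channel,
                baseline_window=config.baseline_window,
                stimulus_window=config.stimulus_window, cell_id=cell_id))
            truth_rows.append({"cell_id": cell_id, "channel": channel, **truth})
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """N(mean, sd) truncated to (0, inf) by rejection (ratios are
    nonnegative by construction)."""
    if sd == 0:
        if mean <= 0:
            raise ConfigError("degenerate ratio distribution at a non-positive mean")
        return np.full(size, mean)
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        out[need] = draw
        need &= out <= 0
    return out


def generate_cell_cohort(config: SimulationConfig
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of cells across fish and neuromasts.

    group_conditional mode draws each cell's outcome Bernoulli(death_frac)
    and then its ratio from that outcome group's truncated normal;
    logistic mode draws the ratio from the two-group mixture and the
    outcome with P(die) = expit(beta0 + beta1*ratio). Ratios are then
    re-normalized so each neuromast's median is exactly 1; Hoechst status
    marks the top frac_older fraction of each neuromast by pre-
    normalization ratio (older cells are redder).

    Returns (cohort table, ground-truth table); the cohort table is what
    the measurement pipeline would produce, the truth table additionally
    carries the pre-normalization draw and the age group.
    """
    cp = config.cohort_params
    rng = _rng(config.seed, "cohort")
    dists = {g: (cp.ratio_dist[g].mean, cp.ratio_dist[g].sd)
             for g in ("live", "die")}
    rows = []
    cell_id = 1   # 0 is reserved for unassigned pixels in label maps
    for f in range(cp.n_fish):
        for m in range(cp.neuromasts_per_fish):
            n = cp.cells_per_neuromast
            if cp.outcome_model == "group_conditional":
                die = rng.random(n) < cp.death_frac
                ratios = np.empty(n)
                for g, sel in (("die", die), ("live", ~die)):
                    if sel.any():
                        ratios[sel] = _truncated_normal(
                            rng, *dists[g], size=int(sel.sum()))
            else:
                comp_die = rng.random(n) < cp.death_frac
                ratios = np.empty(n)
                for g, sel in (("die", comp_die), ("live", ~comp_die)):
                    if sel.any():
                        ratios[sel] = _truncated_normal(
                            rng, *dists[g], size=int(sel.sum()))
                p_die = 1.0 / (1.0 + np.exp(-(cp.beta0 + cp.beta1 * ratios)))
                die = rng.random(n) < p_die
            n_older = int(round(cp.frac_older * n))
            order = np.argsort(ratios)          # ascending; top ranks are older
            older = np.zeros(n, dtype=bool)
            if n_older:
                older[order[-n_older:]] = True
            for i in range(n):
                rows.append({
                    "cell_id": cell_id + i,
                    "fish_id": f"fish{f + 1:02d}",
                    "neuromast_id": f"fish{f + 1:02d}_nm{m + 1}",
                    "true_ratio": ratios[i],
                    "outcome": "die" if die[i] else "live",
                    "age_group": "older" if older[i] else "younger",
                    "hoechst": bool(older[i]),
                })
            cell_id += n
    truth = pd.DataFrame(rows)
    truth["normalized_ratio"] = normalize_to_neuromast_median(
        truth, ratio_col="true_ratio")
    cohort = truth[["cell_id", "fish_id", "neuromast_id", "true_ratio",
                    "normalized_ratio", "hoechst", "outcome"]].copy()
    return cohort, truth


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

@dataclass
class StackTruth:
    """Per-cell placement and intensity truth for one rendered stack."""

    placements: pd.DataFrame       # cell_id, y, x (pixels), true_ratio, hoechst
    background_slices: tuple


def _ring_positions(n_cells: int, r_cell_px: float,
                    center_yx: Tuple[float, float]) -> np.ndarray:
    """Deterministic non-overlapping layout: center spot plus concentric
    rings with arc spacing 2.4 cell radii (a rosette, like a neuromast)."""
    spacing = 2.4 * r_cell_px
    pos = [center_yx]
    ring = 1
    while len(pos) < n_cells:
        radius = ring * spacing
        cap = max(1, int(math.floor(2 * math.pi * radius / spacing)))
        for k in range(cap):
            if len(pos) >= n_cells:
                break
            ang = 2 * math.pi * k / cap + 0.25 * ring
            pos.append((center_yx[0] + radius * math.sin(ang),
                        center_yx[1] + radius * math.cos(ang)))
        ring += 1
    return np.asarray(pos[:n_cells])


def generate_neuromast_stack(config: SimulationConfig,
                             cohort: pd.DataFrame,
                             neuromast_id: Optional[str] = None
                             ) -> Tuple[ChannelStack, RegionSet, StackTruth]:
    """Render one neuromast's cells into a multi-channel z-stack.

    Each cell is a cluster of Gaussian-blurred puncta; green intensity is
    fixed and red intensity is green * true_ratio, so the rendered
    red:green ratio on the cell mask equals the cell's true ratio. The
    label map uses the cohort's cell ids; the 30x30 um background square
    is auto-placed in the far corner and verified disjoint from every
    cell disk.
    """
    ip = config.image_params
    if neuromast_id is None:
        neuromast_id = cohort["neuromast_id"].iloc[0] if len(cohort) else ""
    cells = cohort[cohort["neuromast_id"] == neuromast_id] if len(cohort) else cohort
    rng = _rng(config.seed, "stack")
    nz, ny, nx = ip.shape_zyx
    r_px = ip.cell_radius / ip.pixel_size_xy

    bg_slices = background_square_slices(
        (ny, nx), (ny - int(round(30.0 / ip.pixel_size_xy)) - 2,
                   nx - int(round(30.0 / ip.pixel_size_xy)) - 2),
        ip.pixel_size_xy)

    labels = np.zeros((ny, nx), dtype=np.uint16)
    channel_names = ["red", "green"] + (["nuclear"] if ip.include_nuclear else [])
    vols = {ch: np.zeros((nz, ny, nx)) for ch in channel_names}
    yy, xx = np.mgrid[0:ny, 0:nx]

    n = len(cells)
    placements = []
    if n:
        center = (0.28 * ny, 0.28 * nx)
        pos = _ring_positions(n, r_px, center)
        zc = nz // 2
        bg_mask = np.zeros((ny, nx), dtype=bool)
        bg_mask[bg_slices] = True
        for (cy, cx), (_, cell) in zip(pos, cells.iterrows()):
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2
            if not disk.any() or cy - r_px < 0 or cx - r_px < 0 \
                    or cy + r_px >= ny or cx + r_px >= nx:
                raise GenerationError(
                    f"cell {cell['cell_id']} does not fit inside the image")
            if (disk & (labels > 0)).any():
                raise GenerationError("cell disks overlap; reduce cell_radius")
            if (disk & bg_mask).any():
                raise GenerationError(
                    "background square cannot be placed disjoint from cells")
            labels[disk] = int(cell["cell_id"])
            per_punctum = ip.green_amplitude / ip.puncta_per_cell
            for _ in range(ip.puncta_per_cell):
                dy, dx = rng.uniform(-0.6 * r_px, 0.6 * r_px, size=2)
                dz = rng.integers(-min(1, zc), min(1, nz - 1 - zc) + 1)
                iy, ix = int(round(cy + dy)), int(round(cx + dx))
                vols["green"][zc + dz, iy, ix] += per_punctum
                vols["red"][zc + dz, iy, ix] += per_punctum * cell["true_ratio"]
            if ip.include_nuclear and bool(cell.get("hoechst", False)):
                vols["nuclear"][zc][disk] += ip.nuclear_amplitude
            placements.append({"cell_id": int(cell["cell_id"]),
                               "y": float(cy), "x": float(cx),
                               "true_ratio": float(cell["true_ratio"]),
                               "hoechst": bool(cell.get("hoechst", False))})

    sigma = (ip.psf_sigma / ip.z_step, ip.psf_sigma / ip.pixel_size_xy,
             ip.psf_sigma / ip.pixel_size_xy)
    for ch in channel_names:
        # nuclei are whole-cell disks; the sub-pixel PSF only matters for
        # the punctate mitochondrial channels
        vol = vols[ch] if ch == "nuclear" else gaussian_filter(vols[ch],
                                                               sigma=sigma)
        vol = vol + ip.background_level
        if ip.camera_noise_sd > 0:
            vol += rng.normal(0.0, ip.camera_noise_sd, size=vol.shape)
        vols[ch] = vol

    stack = ChannelStack(channels=vols, pixel_size_xy=ip.pixel_size_xy,
                         z_step=ip.z_step)
    regions = RegionSet(cell_labels=labels, background_slices=bg_slices)
    truth = StackTruth(placements=pd.DataFrame(placements),
                       background_slices=bg_slices)
    return stack, regions, truth
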