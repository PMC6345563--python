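"""Stimulus-response trace kinetics: dF/F0 normalization, integrated area,
peak response, and 75% rise time.

All metrics operate on the baseline-normalized scale F/F0 where F0 is the
arithmetic mean of the pre-stimulus baseline frames, so every metric is
invariant to multiplicative rescaling of the raw trace. Windows are
half-open frame-index ranges [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidBaselineError, UndefinedResponseError


@dataclass
class FluorescenceTrace:
    """One cell's raw fluorescence time series with analysis windows.

    baseline_window and stimulus_window are half-open frame-index ranges;
    the baseline must end at or before the stimulus starts and contain at
    least three frames.
    """

    frame_times: np.ndarray        # s, strictly increasing
    raw_values: np.ndarray         # AU, >= 0
    channel: str = "other"         # 'cyto' | 'mito' | 'other'
    baseline_window: tuple = (0, 3)
    stimulus_window: tuple = (3, 4)
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        n = self.raw_values.size
        if self.frame_times.size != n:
            raise ConfigError("frame_times and raw_values differ in length")
        if n and np.any(np.diff(self.frame_times) <= 0):
            raise ConfigError("frame_times must be strictly increasing")
        b0, b1 = self.baseline_window
        s0, s1 = self.stimulus_window
        if not (0 <= b0 < b1 <= n and 0 <= s0 < s1 <= n):
            raise ConfigError("analysis windows must lie within the trace")
        if b1 > s0:
            raise ConfigError("baseline window must end at or before stimulus onset")
        if b1 - b0 < 3:
            raise ConfigError("baseline window must contain >= 3 frames")

    @property
    def stimulus_onset(self) -> int:
        return self.stimulus_window[0]


@dataclass
class KineticsResult:
    """The three response metrics for one trace."""

    cell_id: Optional[str]
    channel: str
    integrated_area: float
    peak: float
    rise_time_75: Optional[float]   # None when no positive response exists


def normalize_trace(trace: FluorescenceTrace) -> np.ndarray:
    """Return F/F0 with F0 the mean of the baseline-window frames.

    Raises InvalidBaselineError if F0 <= 0.
    """
    b0, b1 = trace.baseline_window
    f0 = float(np.mean(trace.raw_values[b0:b1]))
    if f0 <= 0:
        raise InvalidBaselineError(f"baseline mean F0={f0!r} is not positive")
    return trace.raw_values / f0


def integrated_area(normalized: np.ndarray, stimulus_window: tuple,
                    baseline_excess: bool = True) -> float:
    """Sum the response over the stimulus window.

    By default sums the baseline excess (F/F0 - 1), which is zero for a
    flat trace; with baseline_excess=False sums raw F/F0 values instead.
    """
    s0, s1 = stimulus_window
    normalized = np.asarray(normalized, dtype=float)
    if not (0 <= s0 < s1 <= normalized.size):
        raise ConfigError("stimulus window empty or outside the trace")
    seg = normalized[s0:s1]
    return float(np.sum(seg - 1.0)) if baseline_excess else float(np.sum(seg))


def peak_response(normalized: np.ndarray, stimulus_onset: int) -> float:
    """Maximum of F/F0 from stimulus onset to the end of the trace."""
    normalized = np.asarray(normalized, dtype=float)
    if not (0 <= stimulus_onset < normalized.size):
        raise ConfigError("stimulus onset outside the trace")
    return float(np.max(normalized[stimulus_onset:]))


def rise_time_75(normalized: np.ndarray, frame_times: Sequence[float],
                 stimulus_onset: int) -> float:
    """Seconds from stimulus onset to the first crossing of
    1 + 0.75*(peak - 1), with linear interpolation between frames.

    The threshold is 75% of the peak's excess over baseline; a threshold
    of 0.75*peak would sit below baseline for peaks < 4/3. Raises
    UndefinedResponseError when peak <= 1 (no positive response); callers
    report such traces as missing, not zero.
    """
    normalized = np.asarray(normalized, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    peak = peak_response(normalized, stimulus_onset)
    if peak <= 1.0:
        raise UndefinedResponseError("peak <= baseline; rise time undefined")
    threshold = 1.0 + 0.75 * (peak - 1.0)
    t_on = frame_times[stimulus_onset]
    seg = normalized[stimulus_onset:]
    times = frame_times[stimulus_onset:]
    idx = int(np.argmax(seg >= threshold))
    if seg[idx] < threshold:   # pragma: no cover - cannot happen: peak >= threshold
        raise UndefinedResponseError("threshold never reached")
    if idx == 0 or seg[idx] == threshold:
        return float(times[idx] - t_on)
    t_lo, t_hi = times[idx - 1], times[idx]
    v_lo, v_hi = seg[idx - 1], seg[idx]
    t_cross = t_lo + (threshold - v_lo) / (v_hi - v_lo) * (t_hi - t_lo)
    return float(t_cross - t_on)


def analyze_trace(trace: FluorescenceTrace,
                  baseline_excess: bool = True) -> KineticsResult:
    """Compute all three metrics for one trace; rise time is None when the
    trace has no positive response."""
    norm = normalize_trace(trace)
    area = integrated_area(norm, trace.stimulus_window, baseline_excess)
    peak = peak_response(norm, trace.stimulus_onset)
    try:
        t75 = rise_time_75(norm, trace.frame_times, trace.stimulus_onset)
    except UndefinedResponseError:
        t75 = None
    return KineticsResult(trace.cell_id, trace.channel, area, peak, t75)


def summarize_kinetics(results: Sequence[KineticsResult],
                       grouping: str = "channel") -> pd.DataFrame:
    """Per-group n / mean / SD / SE for each metric.

    Grouping is by the named KineticsResult attribute (default: channel);
    rows are sorted by group so the summary is invariant to input order.
    Raises ConfigError on empty input.
    """
    if len(results) == 0:
        raise ConfigError("no kinetics results to summarize")
    df = pd.DataFrame([{
        "cell_id": r.cell_id,
        "channel": r.channel,
        "integrated_area": r.integrated_area,
        "peak": r.peak,
        "rise_time_75": r.rise_time_75,
    } for r in results])
    rows = []
    for key, grp in df.groupby(grouping, sort=True):
        for metric in ("integrated_area", "peak", "rise_time_75"):
            vals = grp[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows.append({
                "group": key, "metric": metric, "n": int(vals.size),
                "mean": float(np.mean(vals)), "sd": sd,
                "se": sd / np.sqrt(vals.size),
            })
    return pd.DataFrame(rows)


TRACE_CSV_COLUMNS = ["cell_id", "channel", "frame_time_s", "intensity"]


def traces_from_table(df: pd.DataFrame, baseline_window: tuple,
                      stimulus_window: tuple) -> list:
    """Build FluorescenceTrace objects from a long-format trace table
    (columns: cell_id, channel, frame_time_s, intensity)."""
    missing = [c for c in TRACE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"trace table missing columns: {missing}")
    out = []
    for (cell_id, channel), grp in df.groupby(["cell_id", "channel"], sort=True):
        grp = grp.sort_values("frame_time_s")
        out.append(FluorescenceTrace(
            frame_times=grp["frame_time_s"].to_numpy(),
            raw_values=grp["intensity"].to_numpy(),
            channel=str(channel),
            baseline_window=tuple(baseline_window),
            stimulus_window=tuple(stimulus_window),
            cell_id=str(cell_id),
        ))
    return out
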