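"""Growth-rate estimation from microcolony area trajectories.

The growth rate of a microcolony is the maximum slope of ln(area) vs.
time over all 3-consecutive-timepoint windows with a good fit (R² ≥ 0.9);
the maximum avoids bias from lag phases and late-observation slowdown.
Per-timepoint (centered-window) rate series feed a run-based classifier
for colonies that switch between fast and slow growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import ColonyTrack

__all__ = [
    "GrowthEstimate",
    "SwitchConfig",
    "SwitchCall",
    "estimate_growth_rate",
    "pointwise_growth_rates",
    "classify_switching",
    "survival_call",
]


@dataclass(frozen=True)
class GrowthEstimate:
    """Fitted growth rate for one colony.

    ``rate`` is the maximum qualifying window slope (h^-1), ``ok`` False
    when no window reached the R² threshold (no estimate — not zero).
    """

    colony_id: int
    rate: float | None
    window_start_index: int | None
    r_squared: float | None
    ok: bool


@dataclass(frozen=True)
class SwitchConfig:
    """Cutoffs and run rules for growth-rate switching calls.

    ``c1``/``c2`` are the lower/upper rate cutoffs (equal in single-cutoff
    mode).  A switch needs ``run_length`` consecutive qualifying
    timepoints on each side, and the switch time must avoid the first
    (slow→fast) or last (fast→slow) ``edge_exclusion`` frames — runs of 3
    for densely sampled sorted-bin data, 2 for the shorter screen series.
    """

    c1: float
    c2: float
    run_length: int = 3
    edge_exclusion: int = 3

    def __post_init__(self) -> None:
        if self.c1 > self.c2:
            raise ValueError("c1 (lower cutoff) must be <= c2 (upper cutoff)")
        if self.run_length < 2:
            raise ValueError("run_length must be >= 2")


@dataclass(frozen=True)
class SwitchCall:
    direction: str  # "fast_to_slow" | "slow_to_fast"
    switch_index: int  # frame index of the first timepoint in the new regime


def _window_fit(times: np.ndarray, log_areas: np.ndarray) -> tuple[float, float] | None:
    """OLS slope and R² of log-area on time; None when R² is undefined
    (zero-variance response)."""
    t_c = times - times.mean()
    y_c = log_areas - log_areas.mean()
    sst = float(y_c @ y_c)
    if sst == 0.0 or float(t_c @ t_c) == 0.0:
        return None
    slope = float(t_c @ y_c) / float(t_c @ t_c)
    ssr = sst - slope * float(t_c @ y_c)
    r2 = 1.0 - ssr / sst
    return slope, r2


def estimate_growth_rate(
    track: ColonyTrack,
    r2_min: float = 0.9,
    window: int = 3,
) -> GrowthEstimate:
    """Maximum-window log-linear growth rate of a colony track.

    Regresses ln(area) on time (hours, from frame metadata) over every
    ``window``-consecutive-timepoint stretch, keeps fits with
    R² ≥ ``r2_min`` and reports the maximum slope (earliest window on
    ties).  Tracks with fewer than ``window`` usable frames, or with no
    qualifying window, carry ``ok=False``.
    """
    times = np.asarray(track.times, dtype=float)
    areas = np.asarray(track.areas, dtype=float)
    if len(times) < window:
        return GrowthEstimate(track.colony_id, None, None, None, ok=False)
    logs = np.log(areas)
    best: tuple[float, int, float] | None = None  # (slope, start, r2)
    for s in range(len(times) - window + 1):
        fit = _window_fit(times[s:s + window], logs[s:s + window])
        if fit is None:
            continue
        slope, r2 = fit
        if r2 < r2_min:
            continue
        if best is None or slope > best[0]:
            best = (slope, s, r2)
    if best is None:
        return GrowthEstimate(track.colony_id, None, None, None, ok=False)
    return GrowthEstimate(track.colony_id, rate=best[0], window_start_index=best[1],
                          r_squared=best[2], ok=True)


def pointwise_growth_rates(track: ColonyTrack, r2_min: float = 0.9) -> np.ndarray:
    """Per-timepoint rates from centered 3-point regressions.

    Each interior timepoint gets the slope of ln(area) on time over
    (previous, self, next); endpoints and windows with R² < ``r2_min``
    (including the undefined R² of a constant-area window) are NaN.
    """
    times = np.asarray(track.times, dtype=float)
    areas = np.asarray(track.areas, dtype=float)
    out = np.full(len(times), np.nan)
    if len(times) < 3:
        return out
    logs = np.log(areas)
    for i in range(1, len(times) - 1):
        fit = _window_fit(times[i - 1:i + 2], logs[i - 1:i + 2])
        if fit is None:
            continue
        slope, r2 = fit
        if r2 >= r2_min:
            out[i] = slope
    return out


def _runs(qualifies: np.ndarray, run_length: int) -> list[tuple[int, int]]:
    """(start, end) of maximal True runs of length >= run_length; NaN-driven
    False values break runs."""
    runs = []
    start = None
    for i, q in enumerate(qualifies):
        if q and start is None:
            start = i
        elif not q and start is not None:
            if i - start >= run_length:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(qualifies) - start >= run_length:
        runs.append((start, len(qualifies) - 1))
    return runs


def classify_switching(
    rate_series: np.ndarray,
    config: SwitchConfig,
    n_frames: int | None = None,
) -> SwitchCall | None:
    """Detect growth-rate regime switches in a per-timepoint rate series.

    fast→slow: a run of ≥ ``run_length`` timepoints above ``c2`` followed
    (later) by a run of ≥ ``run_length`` below ``c1``, with the switch
    (first slow timepoint) outside the last ``edge_exclusion`` frames.
    slow→fast is symmetric, excluding the first ``edge_exclusion`` frames
    (lag-phase protection).  Missing (NaN) rates break runs.  fast→slow is
    checked first; a series qualifying in neither direction returns None.
    """
    rates = np.asarray(rate_series, dtype=float)
    if n_frames is None:
        n_frames = len(rates)
    valid = ~np.isnan(rates)
    above = valid & (rates > config.c2)
    below = valid & (rates < config.c1)
    if config.c1 == config.c2:  # single-cutoff mode: >= / < partition
        above = valid & (rates >= config.c1)
        below = valid & (rates < config.c1)

    fast_runs = _runs(above, config.run_length)
    slow_runs = _runs(below, config.run_length)

    for f_start, f_end in fast_runs:
        for s_start, _ in slow_runs:
            if s_start > f_end and s_start < n_frames - config.edge_exclusion:
                return SwitchCall("fast_to_slow", switch_index=s_start)
    for s_start, s_end in slow_runs:
        for f_start, _ in fast_runs:
            if f_start > s_end and f_start >= config.edge_exclusion:
                return SwitchCall("slow_to_fast", switch_index=f_start)
    return None


def survival_call(rate_after_first_interval: float, cutoff: float = 0.02) -> bool:
    """Survivor iff the post-first-timepoint growth rate exceeds the cutoff
    (0.02 h^-1; the boundary itself is a non-survivor)."""
    return rate_after_first_interval > cutoff
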