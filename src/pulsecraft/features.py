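"""Per-pulse derived quantities.

* amplitude percentile bins (within-embryo deciles, comparable across movies)
* the standard mean-centred area-response window (-30 s to +45 s around the
  Gaussian centre, resampled to a common frame interval)
* myosin persistence (normalized difference of the post- and pre-peak minima)
* maximum constriction rate (peak of -dA/dt within the pulse window)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EmbryoDataset, ValidationError

STANDARD_WINDOW = (-30.0, 45.0)  # s, relative to the pulse centre


def assign_amplitude_bins(pulses: pd.DataFrame) -> pd.Series:
    """Within-embryo decile (1-10) of each pulse's Gaussian amplitude.

    Percentile rank is (ordinal rank - 0.5)/n with ties broken by
    (center, pulse_id); bin = ceil(10 * rank). Bin 10 is the 91st-100th
    percentile. Raw intensities are not comparable across movies, so ranks
    are computed per embryo and the labels pooled afterwards.
    """
    bins = pd.Series(index=pulses.index, dtype="Int64")
    for _, grp in pulses.groupby("embryo_id"):
        if len(grp) == 0:
            continue
        order = grp.sort_values(["amplitude", "center", "pulse_id"]).index
        n = len(order)
        for rank, idx in enumerate(order, start=1):
            pct = (rank - 0.5) / n
            bins.loc[idx] = int(math.ceil(10 * pct))
    return bins


@dataclass
class ResponseWindow:
    """Mean-centred area trajectory on the standard pulse window."""

    rel_times: np.ndarray
    values: np.ndarray
    n_imputed: int
    complete: bool


def _window_grid(target_interval: float, window=STANDARD_WINDOW) -> np.ndarray:
    return np.arange(window[0], window[1] + 1e-9, target_interval)


def _resample(
    center: float,
    times: np.ndarray,
    values: np.ndarray,
    target_interval: float,
    window=STANDARD_WINDOW,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Linear resampling onto the standard window; no extrapolation.

    Interior gaps (NaN runs) are imputed linearly and counted; grid points
    outside the observed span are NaN and mark the window incomplete.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if not (times[0] <= center <= times[-1]):
        raise ValidationError("pulse centre lies outside the observed time span")
    rel = _window_grid(target_interval, window)
    grid = center + rel
    obs = ~np.isnan(values)
    if obs.sum() < 2:
        raise ValidationError("fewer than two observed samples")
    t_obs, v_obs = times[obs], values[obs]

    inside = (grid >= t_obs[0] - 1e-9) & (grid <= t_obs[-1] + 1e-9)
    out = np.full(len(grid), np.nan)
    out[inside] = np.interp(grid[inside], t_obs, v_obs)

    nominal = np.median(np.diff(times))
    gaps = np.diff(t_obs)
    n_imputed = 0
    for k, gap in enumerate(gaps):
        if gap > 1.5 * nominal:  # a raw sample is missing in this span
            in_gap = (grid > t_obs[k]) & (grid < t_obs[k + 1])
            n_imputed += int(np.sum(in_gap & inside))
    complete = bool(inside.all())
    return rel, out, n_imputed, complete


def extract_response(
    center: float,
    times: np.ndarray,
    area: np.ndarray,
    target_interval: float,
    window=STANDARD_WINDOW,
) -> ResponseWindow:
    """Mean-centred area response on the standard window around a pulse.

    The mean apical area over the window is subtracted so the window
    captures the local, relative change in apical area; windows reaching
    past the movie are flagged incomplete (and excluded from clustering).
    """
    rel, values, n_imputed, complete = _resample(center, times, area, target_interval, window)
    mean = np.nanmean(values) if np.any(~np.isnan(values)) else np.nan
    return ResponseWindow(rel_times=rel, values=values - mean, n_imputed=n_imputed, complete=complete)


@dataclass
class PersistenceRecord:
    i_min_before: float
    i_min_after: float
    i_mean: float

    @property
    def persistence(self) -> float:
        return (self.i_min_after - self.i_min_before) / self.i_mean


def myosin_persistence(
    center: float,
    times: np.ndarray,
    myosin: np.ndarray,
    target_interval: float,
    window=STANDARD_WINDOW,
) -> PersistenceRecord:
    """Myosin persistence of a pulse.

    The minimum myosin intensity after the pulse centre minus the minimum
    before it, normalized by the mean intensity through the pulse window.
    Positive values indicate residual (persistent) myosin structures after
    the pulse dissipates.
    """
    rel, values, _, _ = _resample(center, times, myosin, target_interval, window)
    before = values[(rel < 0) & ~np.isnan(values)]
    after = values[(rel > 0) & ~np.isnan(values)]
    if len(before) == 0 or len(after) == 0:
        raise ValidationError("pulse window has no observed data on one side of the centre")
    i_mean = float(np.nanmean(values))
    if not i_mean > 0:
        raise ValidationError("non-positive mean myosin intensity in pulse window")
    return PersistenceRecord(
        i_min_before=float(before.min()),
        i_min_after=float(after.min()),
        i_mean=i_mean,
    )


def max_constriction_rate(
    center: float,
    times: np.ndarray,
    area: np.ndarray,
    target_interval: float,
    smoothing: int = 3,
    window=STANDARD_WINDOW,
) -> float:
    """Maximum rate of apical-area reduction during a pulse (μm²/s).

    The resampled area is smoothed with a centred moving average, the
    derivative taken by central differences, and the maximum of -dA/dt
    returned. Positive values mean constriction; expansion-only windows
    give a negative value (reported, not clipped).
    """
    rel, values, _, _ = _resample(center, times, area, target_interval, window)
    keep = ~np.isnan(values)
    rel, values = rel[keep], values[keep]
    if len(values) < max(3, smoothing):
        raise ValidationError("too few samples for a constriction-rate estimate")
    if smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        values = np.convolve(values, kernel, mode="valid")
        half = (smoothing - 1) // 2
        rel = rel[half : half + len(values)]
    deriv = np.gradient(values, rel)
    return float(np.max(-deriv))


def compute_pulse_features(
    pulses: pd.DataFrame,
    dataset: EmbryoDataset,
    target_interval: float | None = None,
    smoothing: int = 3,
) -> tuple[pd.DataFrame, dict[str, ResponseWindow]]:
    """Append feature columns to the pulses table and collect response windows.

    Adds ``amplitude_bin``, ``persistence``, ``max_constriction_rate`` and
    ``response_complete``. Returns the augmented table plus a mapping
    pulse_id -> ResponseWindow for downstream clustering.
    """
    if target_interval is None:
        target_interval = float(dataset.frame_interval)
    pulses = pulses.copy()
    pulses["amplitude_bin"] = assign_amplitude_bins(pulses)

    persistence, rate, complete = [], [], []
    windows: dict[str, ResponseWindow] = {}
    for _, row in pulses.iterrows():
        track = dataset.cells[str(row["cell_id"])]
        try:
            win = extract_response(row["center"], track.times, track.area, target_interval)
        except ValidationError:
            win = None
        if win is not None:
            windows[str(row["pulse_id"])] = win
        complete.append(bool(win.complete) if win is not None else False)
        try:
            rec = myosin_persistence(row["center"], track.times, track.myosin, target_interval)
            persistence.append(rec.persistence)
        except ValidationError:
            persistence.append(np.nan)
        try:
            rate.append(
                max_constriction_rate(
                    row["center"], track.times, track.area, target_interval, smoothing=smoothing
                )
            )
        except ValidationError:
            rate.append(np.nan)
    pulses["persistence"] = persistence
    pulses["max_constriction_rate"] = rate
    pulses["response_complete"] = complete
    return pulses, windows


def responses_to_frame(windows: dict[str, ResponseWindow]) -> pd.DataFrame:
    """Wide table pulse_id x rel_time of mean-centred area responses."""
    if not windows:
        return pd.DataFrame()
    rel = next(iter(windows.values())).rel_times
    data = {pid: win.values for pid, win in windows.items()}
    df = pd.DataFrame(data, index=rel).T
    df.index.name = "pulse_id"
    return df
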