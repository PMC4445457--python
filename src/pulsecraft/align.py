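"""Temporal alignment of embryos to a common developmental clock.

Movies are aligned by setting t = 0 either at the onset of net tissue
contraction (the first sustained decrease of the smoothed mean apical area)
or at the point where the mean apical area crosses 40 μm², the typical
apical area at the end of cellularization. The latter is the convention for
Twist-depleted embryos, which lack a crisp contraction onset.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AlignmentError, EmbryoDataset


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window forced odd)."""
    if window <= 1:
        return values.astype(float)
    window = window if window % 2 == 1 else window + 1
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.nanmean(values[lo:hi])
    return out


def align_embryo(
    dataset: EmbryoDataset,
    mode: str = "area_threshold",
    threshold: float = 40.0,
    smoothing_window: int = 5,
    slope_tol: float = 0.05,
    run_length: int = 3,
    store: bool = True,
) -> float:
    """Determine the alignment offset (raw-clock time of t = 0).

    Parameters
    ----------
    mode
        ``"area_threshold"``: first time the smoothed mean apical area crosses
        below ``threshold`` (linear interpolation between frames).
        ``"onset_of_contraction"``: first time the smoothed mean-area
        derivative stays below ``-slope_tol`` for ``run_length`` consecutive
        frames.
    threshold
        μm²; default 40, the end-of-cellularization apical area.
    slope_tol
        μm²/s; sustained-decline criterion for onset mode.

    Returns
    -------
    float
        Offset in seconds on the dataset's current clock. Stored on the
        dataset when ``store`` is true.
    """
    times, area = dataset.mean_area()
    if len(times) < max(smoothing_window, run_length):
        raise AlignmentError("fewer frames than the smoothing/run-length window")
    smoothed = _smooth(area, smoothing_window)

    if mode == "area_threshold":
        offset = _threshold_crossing(times, smoothed, threshold)
    elif mode == "onset_of_contraction":
        offset = _onset(times, smoothed, slope_tol, run_length)
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    if store:
        dataset.alignment_offset = float(offset)
    return float(offset)


def _threshold_crossing(times, area, threshold) -> float:
    if area[0] <= threshold:
        return times[0]
    below = np.where(area < threshold)[0]
    if len(below) == 0:
        eq = np.where(np.isclose(area, threshold))[0]
        if len(eq):
            return times[eq[0]]
        raise AlignmentError(
            f"mean apical area never crosses below {threshold} μm²"
        )
    i = int(below[0])
    a0, a1 = area[i - 1], area[i]
    t0, t1 = times[i - 1], times[i]
    return t0 + (a0 - threshold) / (a0 - a1) * (t1 - t0)


def _onset(times, area, slope_tol, run_length) -> float:
    deriv = np.gradient(area, times)
    declining = deriv < -slope_tol
    run = 0
    for i, flag in enumerate(declining):
        run = run + 1 if flag else 0
        if run >= run_length:
            return times[i - run_length + 1]
    raise AlignmentError(
        f"no run of {run_length} frames with mean-area slope < -{slope_tol} μm²/s"
    )
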