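"""Temporal organization of pulses.

Timing distributions by amplitude bin or behaviour class, Jensen-Shannon
divergence between those distributions, the trend of the inter-pulse period
over developmental time, and the matrix of class transitions between
consecutive pulses of the same cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

LN2 = float(np.log(2.0))


@dataclass
class TimingDistribution:
    group: object
    bin_edges: np.ndarray
    probabilities: np.ndarray
    n: int
    timing_sd: float


def timing_distributions(
    pulses: pd.DataFrame,
    group_by: str = "amplitude_bin",
    bin_width: float = 30.0,
) -> list[TimingDistribution]:
    """Histogram-based timing distributions per group, on shared edges.

    All groups share bin edges spanning the pooled time range so that the
    resulting probability vectors are directly comparable (a requirement for
    the pairwise JSD). Also reports each group's s.d. of pulse timing.
    Empty groups are skipped.
    """
    centers = pulses["center"].to_numpy(dtype=float)
    if len(centers) == 0:
        raise ValidationError("no pulses")
    lo = bin_width * np.floor(centers.min() / bin_width)
    hi = bin_width * np.ceil(centers.max() / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)

    out = []
    for key, grp in pulses.groupby(group_by, observed=True, dropna=True):
        t = grp["center"].to_numpy(dtype=float)
        if len(t) == 0:
            continue
        counts, _ = np.histogram(t, bins=edges)
        out.append(
            TimingDistribution(
                group=key,
                bin_edges=edges,
                probabilities=counts / counts.sum(),
                n=len(t),
                timing_sd=float(np.std(t, ddof=1)) if len(t) > 1 else 0.0,
            )
        )
    return out


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def jsd(r: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) between probability vectors.

    JSD(R, Q) = KL(R || M)/2 + KL(Q || M)/2 with M = (R + Q)/2, using the
    0 * log(0/x) = 0 convention. Symmetric, non-negative, bounded by ln 2
    (attained on disjoint supports).
    """
    r = np.asarray(r, dtype=float)
    q = np.asarray(q, dtype=float)
    if r.shape != q.shape:
        raise ValidationError("distributions differ in length")
    if np.any(r < 0) or np.any(q < 0):
        raise ValidationError("negative probability entries")
    if abs(r.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValidationError("probability vectors must sum to 1")
    m = 0.5 * (r + q)
    return 0.5 * _kl(r, m) + 0.5 * _kl(q, m)


def jsd_matrix(distributions: list[TimingDistribution]) -> tuple[list, np.ndarray]:
    """Pairwise JSD between timing distributions (symmetric, zero diagonal)."""
    edges = distributions[0].bin_edges
    for d in distributions:
        if len(d.bin_edges) != len(edges) or not np.allclose(d.bin_edges, edges):
            raise ValidationError("distributions do not share bin edges")
    k = len(distributions)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = jsd(distributions[i].probabilities, distributions[j].probabilities)
            mat[i, j] = mat[j, i] = v
    return [d.group for d in distributions], mat


@dataclass
class PeriodTrend:
    intervals: np.ndarray       # s, consecutive within-cell pulse intervals
    midpoints: np.ndarray       # s, midpoint of the two pulse centres
    slope_s_per_min: float
    intercept: float
    r: float
    p: float
    n: int
    degenerate: bool = False


def period_trend(pulses: pd.DataFrame) -> PeriodTrend:
    """Inter-pulse interval versus developmental time.

    Consecutive within-cell intervals are timestamped at the midpoint of the
    two pulse centres and fitted by ordinary least squares; the slope is
    reported in seconds per minute (negative = pulses become more frequent).
    """
    intervals, mids = [], []
    for _, grp in pulses.groupby("cell_id"):
        t = np.sort(grp["center"].to_numpy(dtype=float))
        if len(t) < 2:
            continue
        d = np.diff(t)
        intervals.extend(d)
        mids.extend((t[:-1] + t[1:]) / 2)
    intervals = np.asarray(intervals)
    mids = np.asarray(mids)
    if len(intervals) < 1:
        raise ValidationError("fewer than one inter-pulse interval in dataset")
    if len(intervals) < 2 or np.ptp(mids) == 0:
        return PeriodTrend(intervals, mids, 0.0, float(np.mean(intervals)), 0.0, 1.0,
                           len(intervals), degenerate=True)
    fit = stats.linregress(mids, intervals)
    return PeriodTrend(
        intervals=intervals,
        midpoints=mids,
        slope_s_per_min=float(fit.slope * 60.0),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=len(intervals),
    )


@dataclass
class TransitionMatrix:
    classes: tuple
    counts: np.ndarray
    probabilities: np.ndarray  # row-normalized; all-NaN row when no counts


def transition_matrix(
    pulses: pd.DataFrame,
    classes: tuple = ("ratcheted", "unratcheted", "unconstricting"),
) -> TransitionMatrix:
    """Class-transition probabilities between consecutive pulses of a cell.

    Uncategorized pulses are skipped so a transition links the flanking
    categorized pulses (keeping cell-level sequences maximal). Row r, column
    c holds P(next pulse class = c | current pulse class = r).
    """
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for _, grp in pulses.groupby("cell_id"):
        grp = grp.sort_values("center")
        seq = [c for c in grp["class_label"] if c in index]
        for a, b in zip(seq[:-1], seq[1:]):
            counts[index[a], index[b]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / counts.sum(axis=1, keepdims=True)
    return TransitionMatrix(classes=tuple(classes), counts=counts, probabilities=probs)
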